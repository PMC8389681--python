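"""End-to-end orchestration: ingest -> consensus -> localization ->
network -> DEG -> co-expression -> survival -> enrichment/annotation.

The pipeline runs from one input directory (as produced by
:func:`generate_inputs` or assembled by hand in the same layout) and
writes a reproducible report bundle with a manifest carrying the config
hash, the seed and per-file checksums.  Identical config + seed gives a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cons
from . import enrichment as enr
from . import expression as expr
from . import localization as loc
from . import network as net
from . import survival as surv
from . import synthetic as syn
from .consensus import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "generate_inputs", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    input_dir: Path
    output_dir: Path
    enzymes: list[str] = field(default_factory=lambda: list(syn.ENZYMES_17))
    min_sources: int = 3
    localization_policy: str = "overlap"
    missing_policy: str = "keep_with_flag"
    fc_threshold: float = 3.0
    alpha: float = 0.01
    r_cutoffs: tuple[float, float, float] = (0.4, 0.6, 0.7)
    coexpr_scope: str = "tumor"
    screen: surv.ScreenCriteria = field(default_factory=surv.ScreenCriteria)
    ora_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if not self.enzymes:
            raise ConfigurationError("enzyme list must be non-empty")
        if not (0 < self.alpha < 1 and 0 < self.ora_alpha < 1):
            raise ConfigurationError("alpha thresholds must be in (0, 1)")
        if self.fc_threshold <= 0:
            raise ConfigurationError("fc_threshold must be > 0")
        if list(self.r_cutoffs) != sorted(self.r_cutoffs):
            raise ConfigurationError("r_cutoffs must be increasing")

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    summary: dict
    config: PipelineConfig


def generate_inputs(
    config: syn.SyntheticConfig, outdir: str | Path, dialect: str = "tsv"
) -> Path:
    """Write a complete synthetic input directory plus the truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tables, truth = syn.gen_interactome_sources(config)
    syn.write_source_tables(tables, outdir / "sources", dialect=dialect)

    symbols = sorted({config.enzymes[i] for i in range(len(config.enzymes))} |
                     {r.id_a for t in tables.values() for r in t} |
                     {r.id_b for t in tables.values() for r in t})
    with open(outdir / "mapping.tsv", "w") as fh:
        fh.write("accession\talias\tsymbol\n")
        for s in symbols:
            fh.write(f"{s}\t{s}\t{s}\n")

    profiles = syn.gen_localization_profiles(config, truth)
    syn.write_localization_table(profiles, outdir / "localization.tsv")

    cohorts = syn.gen_expression_cohorts(config, truth)
    for cohort in cohorts.values():
        syn.write_expression_cohort(cohort, outdir)

    for cohort_id, (scohort, _high) in syn.gen_survival_cohorts(config, truth).items():
        syn.write_survival_cohort(scohort, outdir / f"survival_{cohort_id}.tsv")

    collection, _query = syn.gen_genesets(config, truth)
    enr.write_gmt(collection, outdir / "collection.gmt")

    truth.to_json(outdir / "truth.json")
    return outdir / "truth.json"


def _stage(name):
    """Wrap a stage so failures abort with the stage name."""
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("ingest")
def _ingest(cfg: PipelineConfig, registry):
    records = []
    src_dir = cfg.input_dir / "sources"
    if not src_dir.is_dir():
        raise ConfigurationError(f"missing sources directory {src_dir}")
    for path in sorted(src_dir.iterdir()):
        name = path.stem
        if name not in registry:
            continue
        entry = registry[name]
        if path.suffix == ".mitab" and entry.dialect != "mitab25":
            entry = dataclasses.replace(entry, dialect="mitab25")
        recs, _bad = cons.parse_source_table(path, entry)
        records.extend(recs)
    return records


@_stage("consensus")
def _consensus(cfg: PipelineConfig, records, registry):
    records = cons.filter_by_source_policy(records, registry)
    mapping = cons.load_mapping_table(cfg.input_dir / "mapping.tsv")
    normalized, unmapped = cons.normalize_identifiers(records, mapping)
    edges = cons.aggregate_consensus(normalized, cfg.enzymes, cfg.min_sources)
    per_enzyme, grand = cons.summarize_retrieval(normalized, cfg.enzymes)
    return edges, normalized, unmapped, per_enzyme, grand


@_stage("localization")
def _localization(cfg: PipelineConfig, edges):
    vocabulary = loc.default_vocabulary()
    profiles = loc.load_localization_table(cfg.input_dir / "localization.tsv", vocabulary)
    return loc.apply_localization_filter(
        edges, profiles, policy=cfg.localization_policy, missing=cfg.missing_policy
    )


@_stage("deg")
def _degs(cfg: PipelineConfig):
    results = []
    cohorts = {}
    for mpath in sorted(cfg.input_dir.glob("expr_*.tsv")):
        cohort_id = mpath.stem.removeprefix("expr_")
        gpath = cfg.input_dir / f"groups_{cohort_id}.tsv"
        cohort = expr.ExpressionCohort.from_tsv(mpath, gpath, cohort_id)
        cohorts[cohort_id] = cohort
        results.extend(expr.call_degs(cohort, cfg.fc_threshold, cfg.alpha))
    return results, cohorts


@_stage("coexpression")
def _coexpression(cfg: PipelineConfig, deg_results, cohorts, edges):
    tasks = expr.select_coexpression_tasks(deg_results, edges)
    out = []
    for enzyme, partner, cohort_id in tasks:
        cohort = cohorts[cohort_id]
        if partner not in cohort.matrix.index:
            continue
        out.append(
            expr.pearson_coexpression(
                cohort, (enzyme, partner), scope=cfg.coexpr_scope, cutoffs=cfg.r_cutoffs
            )
        )
    return out


@_stage("survival")
def _survival(cfg: PipelineConfig):
    results = []
    for path in sorted(cfg.input_dir.glob("survival_*.tsv")):
        cohort_id = path.stem.removeprefix("survival_")
        cohort = surv.SurvivalCohort.from_tsv(path, cohort_id)
        results.extend(
            surv.screen_prognostic({"score": cohort.score}, cohort, cfg.screen)
        )
    return results


@_stage("enrichment")
def _enrichment(cfg: PipelineConfig, list_a, list_b):
    gmt_path = cfg.input_dir / "collection.gmt"
    ora_results = []
    if gmt_path.exists() and list_a:
        collection = enr.read_gmt(gmt_path)
        if set(list_a) & collection.universe:
            ora_results = enr.ora_hypergeometric(list_a, collection, cfg.ora_alpha)
    class_map = enr.load_modifying_class_map()
    classes, class_summary = enr.classify_modifying(list_b, class_map)
    flags = []
    driver = cfg.input_dir / "drivers.tsv"
    essential = cfg.input_dir / "essential.tsv"
    if driver.exists() and essential.exists():
        flags = enr.flag_annotations(list_b, driver, essential)
    return ora_results, classes, class_summary, flags


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> ReportBundle:
    """Execute all stages in fixed order and return the report bundle.

    Refuses to overwrite an existing bundle directory unless ``force``.
    """
    manifest_path = cfg.output_dir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{cfg.output_dir} already holds a bundle; pass force=True to overwrite"
        )
    registry = cons.default_registry()
    reg_path = cfg.input_dir / "registry.json"
    if reg_path.exists():
        registry = cons.load_registry(reg_path)

    records = _ingest(cfg, registry)
    edges, normalized, unmapped, per_enzyme, grand = _consensus(cfg, records, registry)
    filtered, status = _localization(cfg, edges)

    classifications = net.classify_partners(filtered) if filtered else []
    lists = net.partner_lists(classifications)
    summary = net.network_summary(filtered) if filtered else {
        "n_enzymes": 0, "n_partners": 0, "n_unique": 0, "n_common": 0, "tiers": {}}
    graph = net.build_network(filtered, status)

    deg_results, cohorts = _degs(cfg)
    coexpr = _coexpression(cfg, deg_results, cohorts, filtered)
    surv_results = _survival(cfg)
    ora_results, classes, class_summary, flags = _enrichment(
        cfg, lists["list_a"], lists["list_b"]
    )

    tables = {
        "consensus_edges": pd.DataFrame(
            [
                {
                    "enzyme": e.enzyme, "partner": e.partner, "n_sources": e.n_sources,
                    "sources": ";".join(sorted(e.supporting_sources)),
                    "is_enzyme_enzyme": e.is_enzyme_enzyme,
                }
                for e in edges
            ]
        ),
        "filtered_edges": pd.DataFrame(
            [
                {
                    "enzyme": e.enzyme, "partner": e.partner, "n_sources": e.n_sources,
                    "sources": ";".join(sorted(e.supporting_sources)),
                    "localization_pass": status.get(e.pair, ""),
                }
                for e in filtered
            ]
        ),
        "partner_classes": pd.DataFrame(
            [
                {
                    "partner": c.partner, "enzyme_degree": c.enzyme_degree,
                    "class": c.partner_class, "connector_tier": c.connector_tier,
                }
                for c in classifications
            ]
        ),
        "retrieval_summary": pd.DataFrame(
            [{"enzyme": e, "n_raw_partners": n} for e, n in sorted(per_enzyme.items())]
        ),
        "deg": pd.DataFrame(
            [
                {
                    "gene": r.gene, "cohort": r.cohort_id, "fc": r.fc, "log2fc": r.log2fc,
                    "p": r.p_value, "q": r.q_value, "is_deg": r.is_deg,
                }
                for r in deg_results
            ]
        ),
        "coexpression": pd.DataFrame(
            [
                {
                    "enzyme": r.enzyme, "partner": r.partner, "cohort": r.cohort_id,
                    "r": r.r, "n": r.n, "band": r.band, "negative": r.negative,
                }
                for r in coexpr
            ]
        ),
        "survival": pd.DataFrame(
            [
                {
                    "unit": r.unit, "cohort": r.cohort_id, "n": r.n_cases, "hr": r.hr,
                    "ci_low": r.ci_low, "ci_high": r.ci_high, "logrank_p": r.logrank_p,
                    "q": r.q_value, "passes_default": r.passes_default,
                    "passes_strict": r.passes_strict,
                }
                for r in surv_results
            ]
        ),
        "enrichment": pd.DataFrame(
            [
                {
                    "term": r.term_id, "name": r.name, "k": r.k, "K": r.K, "n": r.n,
                    "N": r.N, "ratio": r.enrichment_ratio, "p": r.p_value, "q": r.q_value,
                    "significant": r.significant,
                }
                for r in ora_results
            ]
        ),
        "modifying_classes": pd.DataFrame(
            [{"partner": p, "class": c} for p, c in sorted(classes.items())]
        ),
        "annotation_flags": pd.DataFrame(
            [
                {
                    "gene": f.gene, "is_cancer_driver": f.is_cancer_driver,
                    "mutation_frequency": f.mutation_frequency,
                    "is_common_essential": f.is_common_essential,
                }
                for f in flags
            ]
        ),
    }
    full_summary = {
        "retrieval_grand_total": grand,
        "n_unmapped_records": len(unmapped),
        "network": summary,
        "lists": {k: len(v) for k, v in lists.items()},
        "modifying": class_summary,
    }
    bundle = ReportBundle(tables=tables, summary=full_summary, config=cfg)
    write_report(bundle, graph)
    return bundle


def write_report(bundle: ReportBundle, graph=None) -> Path:
    """Write the bundle with deterministic file names and a manifest of
    config hash, seed, row counts and sha256 checksums."""
    outdir = bundle.config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, df in bundle.tables.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        entries[path.name] = {
            "rows": int(df.shape[0]),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
    if graph is not None:
        for fmt, suffix in (("graphml", "graphml"), ("sif", "sif"), ("tsv", "edges.tsv")):
            path = net.export_network(graph, outdir / f"network.{suffix}", fmt)
            entries[path.name] = {
                "rows": graph.number_of_edges(),
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle.summary, fh, indent=1, sort_keys=True)
    entries["summary.json"] = {
        "rows": None,
        "sha256": hashlib.sha256((outdir / "summary.json").read_bytes()).hexdigest(),
    }
    manifest = {
        "config_hash": bundle.config.config_hash(),
        "seed": bundle.config.seed,
        "files": entries,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest_path


def verify_manifest(outdir: str | Path) -> bool:
    """Re-hash every bundle file and compare against the manifest."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    for name, entry in manifest["files"].items():
        digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        if digest != entry["sha256"]:
            return False
    return True
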