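"""Synthetic multi-source interactomes, localization tables, expression
and survival cohorts, and gene-set collections with recorded ground
truth.

Every generator is a pure function of (config, seed): each one draws
from its own pseudo-random stream derived from the master seed by a
fixed offset, so adding a generator never perturbs another's output.
The recorded :class:`PlantedTruth` is the oracle for every downstream
stage — planted consensus edges are forced into at least ``min_sources``
sources while noise edges are confined to fewer, so the consensus stage
can be held to exact precision/recall; planted fold changes,
correlations and hazard ratios likewise carry their target values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import (
    ConfigurationError,
    SourceRecord,
    default_registry,
)
from .expression import ExpressionCohort
from .localization import (
    CompartmentVocabulary,
    LocalizationProfile,
    default_vocabulary,
    enzyme_localization_table,
    profiles_concordant,
)
from .survival import SurvivalCohort
from .enrichment import GeneSetCollection

__all__ = [
    "CohortSpec",
    "SurvivalSpec",
    "GenesetSpec",
    "SyntheticConfig",
    "PlantedTruth",
    "gen_interactome_sources",
    "gen_localization_profiles",
    "gen_expression_cohort",
    "gen_survival_cohort",
    "gen_geneset_collection",
    "write_source_tables",
    "write_localization_table",
    "write_expression_cohort",
    "write_survival_cohort",
]

# fixed per-generator stream offsets (master seed + offset seeds the stream)
_STREAM = {
    "interactome": 11,
    "localization": 23,
    "expression": 37,
    "survival": 53,
    "genesets": 71,
}

ENZYMES_17 = [
    "HMGCR", "MVK", "PMVK", "MVD", "FDPS", "FDFT1", "SQLE", "LSS",
    "DHCR24", "CYP51A1", "TM7SF2", "MSMO1", "NSDHL", "HSD17B7",
    "EBP", "SC5D", "DHCR7",
]


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class CohortSpec:
    cohort_id: str
    n_tumor: int
    n_normal: int

    def __post_init__(self) -> None:
        if self.n_tumor < 3 or self.n_normal < 3:
            raise ConfigurationError(
                f"cohort {self.cohort_id}: need >= 3 samples per group"
            )


@dataclass(frozen=True)
class SurvivalSpec:
    n_samples: int = 1000
    baseline_hazard: float = 0.02  # events per month in the low group
    planted_hr: float = 0.4  # hazard multiplier for the high group
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ConfigurationError("survival_spec.n_samples must be >= 10")
        if self.planted_hr <= 0:
            raise ConfigurationError("survival_spec.planted_hr must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("survival_spec.baseline_hazard must be > 0")
        _check_prob(self.censoring_rate, "survival_spec.censoring_rate")


@dataclass(frozen=True)
class GenesetSpec:
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    universe_size: int = 1000
    query_size: int = 30
    planted_overlap: int = 12

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi <= self.universe_size:
            raise ConfigurationError("geneset_spec.term_size_range invalid")
        if self.planted_overlap > min(hi, self.query_size):
            raise ConfigurationError(
                "geneset_spec.planted_overlap exceeds term or query size"
            )


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic sub-interactome.

    Defaults mirror the study design: 17 pathway enzymes, 13 source
    browsers, a three-browser consensus threshold, cohorts with
    TCGA-like tumor/normal sample counts, planted fold changes at the
    FC >= 3 screening scale, correlations in the banding ranges and a
    protective hazard ratio of 0.4.
    """

    seed: int = 0
    n_enzymes: int = 17
    n_partners: int = 200
    n_sources: int = 13
    min_sources: int = 3
    detection_prob: float = 0.9
    noise_edge_rate: float = 5.0  # expected spurious assertions per source
    n_planted_consensus: int = 40
    planted_consensus_edges: list[tuple[str, str]] | None = None
    concordant_fraction: float = 0.6
    cohort_specs: list[CohortSpec] = field(
        default_factory=lambda: [
            CohortSpec("THYM", 118, 339),
            CohortSpec("READ", 92, 318),
            CohortSpec("PAAD", 179, 171),
            CohortSpec("DLBC", 100, 100),
            CohortSpec("PRAD", 100, 100),
        ]
    )
    planted_fc: dict[str, float] = field(
        default_factory=lambda: {
            # up-regulated pathway enzymes at the DEG screening scale
            "SQLE": 4.0, "MSMO1": 3.5, "EBP": 3.5, "MVK": 4.0, "FDPS": 3.2,
        }
    )
    planted_rho: dict[tuple[str, str, str], float] = field(default_factory=dict)
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    geneset_spec: GenesetSpec = field(default_factory=GenesetSpec)

    def __post_init__(self) -> None:
        _check_prob(self.detection_prob, "detection_prob")
        _check_prob(self.concordant_fraction, "concordant_fraction")
        if self.noise_edge_rate < 0:
            raise ConfigurationError("noise_edge_rate must be >= 0")
        if self.n_sources < self.min_sources:
            raise ConfigurationError("n_sources must be >= min_sources")
        if self.min_sources < 1:
            raise ConfigurationError("min_sources must be >= 1")
        for fc in self.planted_fc.values():
            if fc <= 0:
                raise ConfigurationError("planted_fc values must be > 0")
        for key, rho in self.planted_rho.items():
            if not -1.0 < rho < 1.0:
                raise ConfigurationError(f"planted_rho[{key}] must be in (-1, 1)")

    @property
    def enzymes(self) -> list[str]:
        if self.n_enzymes <= len(ENZYMES_17):
            return ENZYMES_17[: self.n_enzymes]
        extra = [f"ENZ{i:02d}" for i in range(len(ENZYMES_17) + 1, self.n_enzymes + 1)]
        return ENZYMES_17 + extra

    @property
    def partners(self) -> list[str]:
        return [f"PTN{i:04d}" for i in range(1, self.n_partners + 1)]

    def _rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAM[stream]])


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators; the downstream oracle."""

    true_edges: list[tuple[str, str]] = field(default_factory=list)
    true_consensus_edges: list[tuple[str, str]] = field(default_factory=list)
    noise_edges: list[tuple[str, str]] = field(default_factory=list)
    concordant_edges: list[tuple[str, str]] = field(default_factory=list)
    deg_genes: dict[str, list[str]] = field(default_factory=dict)
    correlated_pairs: list[tuple[str, str, str, float]] = field(default_factory=list)
    prognostic: dict = field(default_factory=dict)
    enriched_terms: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            raw = json.load(fh)
        truth = cls()
        truth.true_edges = [tuple(e) for e in raw["true_edges"]]
        truth.true_consensus_edges = [tuple(e) for e in raw["true_consensus_edges"]]
        truth.noise_edges = [tuple(e) for e in raw["noise_edges"]]
        truth.concordant_edges = [tuple(e) for e in raw["concordant_edges"]]
        truth.deg_genes = raw["deg_genes"]
        truth.correlated_pairs = [tuple(p) for p in raw["correlated_pairs"]]
        truth.prognostic = raw["prognostic"]
        truth.enriched_terms = raw["enriched_terms"]
        return truth


# ---------------------------------------------------------------------------
# Interactome sources

_EVIDENCE_FOR_SOURCE = {
    "mentha": "physical association",
    "mint": "physical association",
    "iid": "experimental",
    "hint": "binary",
}
_CONF_FLOOR = {"funcoup": 0.9, "bioplex": 0.9, "hippie": 0.6}


def _source_names(n_sources: int) -> list[str]:
    base = list(default_registry().keys())
    if n_sources <= len(base):
        return base[:n_sources]
    return base + [f"src{i:02d}" for i in range(len(base) + 1, n_sources + 1)]


def _make_record(source: str, a: str, b: str, rng: np.random.Generator) -> SourceRecord:
    floor = _CONF_FLOOR.get(source)
    conf = float(rng.uniform(floor + 1e-6, 1.0)) if floor is not None else float(rng.uniform(0.3, 1.0))
    return SourceRecord(
        source_name=source,
        id_a=a,
        id_b=b,
        id_namespace="gene_symbol",
        confidence=conf,
        evidence_type=_EVIDENCE_FOR_SOURCE.get(source),
        publication_count=int(rng.integers(1, 6)),
    )


def gen_interactome_sources(
    config: SyntheticConfig,
) -> tuple[dict[str, list[SourceRecord]], PlantedTruth]:
    """Generate per-source assertion tables with a planted consensus core.

    Each planted edge is forced into ``min_sources`` distinct sources
    and reported by every other source with probability
    ``detection_prob``.  Noise edges are drawn without replacement from
    the non-planted pairs and each confined to at most
    ``min_sources - 1`` sources, so no noise edge can ever reach the
    consensus threshold and the recorded truth is an exact oracle.
    """
    rng = config._rng("interactome")
    sources = _source_names(config.n_sources)
    enzymes = config.enzymes
    partners = config.partners

    if config.planted_consensus_edges is not None:
        planted = [tuple(e) for e in config.planted_consensus_edges]
    else:
        n_plant = min(config.n_planted_consensus, len(enzymes) * len(partners))
        all_idx = rng.choice(len(enzymes) * len(partners), size=n_plant, replace=False)
        planted = [
            (enzymes[i // len(partners)], partners[i % len(partners)]) for i in sorted(all_idx)
        ]
    planted_set = set(planted)

    tables: dict[str, list[SourceRecord]] = {s: [] for s in sources}
    for enzyme, partner in planted:
        forced = set(rng.choice(len(sources), size=config.min_sources, replace=False))
        for i, source in enumerate(sources):
            if i in forced or rng.random() < config.detection_prob:
                tables[source].append(_make_record(source, enzyme, partner, rng))

    # noise: expected `noise_edge_rate` assertions per source; each noise
    # pair is assigned to 1..min_sources-1 sources (mean min_sources/2)
    noise: list[tuple[str, str]] = []
    max_support = max(config.min_sources - 1, 1)
    mean_support = (1 + max_support) / 2.0
    n_noise = int(round(config.noise_edge_rate * len(sources) / mean_support))
    if n_noise > 0:
        pool = [
            (e, p)
            for e in enzymes
            for p in partners
            if (e, p) not in planted_set
        ]
        idx = rng.choice(len(pool), size=min(n_noise, len(pool)), replace=False)
        for i in sorted(idx):
            enzyme, partner = pool[i]
            noise.append((enzyme, partner))
            support = int(rng.integers(1, max_support + 1)) if config.min_sources > 1 else 1
            chosen = rng.choice(len(sources), size=support, replace=False)
            for j in chosen:
                tables[sources[j]].append(_make_record(sources[j], enzyme, partner, rng))

    truth = PlantedTruth(
        true_edges=sorted(planted_set),
        true_consensus_edges=sorted(planted_set),
        noise_edges=sorted(noise),
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Localization

def gen_localization_profiles(
    config: SyntheticConfig,
    truth: PlantedTruth,
    vocabulary: CompartmentVocabulary | None = None,
) -> dict[str, LocalizationProfile]:
    """Assign compartments so a configured fraction of consensus edges is
    localization-concordant.

    Enzymes named after the real pathway keep their shipped profiles.
    Concordant partners receive one compartment of their enzyme;
    discordant partners receive compartments disjoint from *all* of
    their enzymes' compartments.  The realized concordant edge set is
    evaluated explicitly and recorded in the truth, so the oracle stays
    exact even for partners bound to several enzymes.
    """
    rng = config._rng("localization")
    vocabulary = vocabulary or default_vocabulary()
    vocab_terms = sorted(vocabulary.terms)

    profiles: dict[str, LocalizationProfile] = {}
    shipped = enzyme_localization_table()
    for enzyme in config.enzymes:
        if enzyme in shipped:
            profiles[enzyme] = shipped[enzyme]
        else:
            terms = rng.choice(vocab_terms, size=2, replace=False)
            profiles[enzyme] = LocalizationProfile(enzyme, frozenset(terms))

    edges = [tuple(e) for e in truth.true_consensus_edges]
    partner_enzymes: dict[str, set[str]] = {}
    for enzyme, partner in edges:
        partner_enzymes.setdefault(partner, set()).add(enzyme)
    partner_list = sorted(partner_enzymes)
    rng.shuffle(partner_list)
    n_conc = int(round(config.concordant_fraction * len(partner_list)))
    for rank, partner in enumerate(partner_list):
        enzyme_terms: set[str] = set()
        for enzyme in partner_enzymes[partner]:
            enzyme_terms |= profiles[enzyme].compartments
        if rank < n_conc:
            # one shared term per bound enzyme, so the partner is
            # concordant with every enzyme it binds
            shared = {
                str(rng.choice(sorted(profiles[enzyme].compartments)))
                for enzyme in sorted(partner_enzymes[partner])
            }
            extra = str(rng.choice(vocab_terms))
            profiles[partner] = LocalizationProfile(partner, frozenset(shared | {extra}))
        else:
            pool = [t for t in vocab_terms if t not in enzyme_terms]
            size = min(2, len(pool))
            terms = rng.choice(pool, size=size, replace=False)
            profiles[partner] = LocalizationProfile(partner, frozenset(str(t) for t in terms))

    # remaining (noise-only) partners get arbitrary profiles
    for _, partner in truth.noise_edges:
        if partner not in profiles:
            terms = rng.choice(vocab_terms, size=2, replace=False)
            profiles[partner] = LocalizationProfile(partner, frozenset(str(t) for t in terms))

    truth.concordant_edges = sorted(
        (e, p)
        for (e, p) in edges
        if profiles_concordant(profiles[e], profiles[p])
    )
    return profiles


# ---------------------------------------------------------------------------
# Expression

def gen_expression_cohort(
    spec: CohortSpec,
    planted_fc: dict[str, float],
    planted_rho: dict[tuple[str, str], float],
    genes: list[str],
    seed_rng: np.random.Generator,
) -> ExpressionCohort:
    """Simulate one tumor/normal cohort on the log2(TPM+1) scale.

    Homoscedastic normal noise (sd 1) around per-gene baselines; DEG
    genes have the tumor mean shifted by log2(FC) so the pseudo-counted
    median ratio recovers the planted FC; correlated pairs are drawn
    from a bivariate normal with the target rho among tumor samples.
    """
    for (a, b), rho in planted_rho.items():
        if not -1.0 < rho < 1.0:
            raise ConfigurationError(f"planted rho for ({a}, {b}) must be in (-1, 1)")
    in_pair: set[str] = set()
    for a, b in planted_rho:
        if a in in_pair or b in in_pair:
            raise ConfigurationError("a gene may appear in at most one correlated pair")
        in_pair.update((a, b))

    rng = seed_rng
    n_t, n_n = spec.n_tumor, spec.n_normal
    baseline = {g: float(rng.uniform(3.0, 8.0)) for g in genes}
    tumor = np.empty((len(genes), n_t))
    normal = np.empty((len(genes), n_n))
    index = {g: i for i, g in enumerate(genes)}

    for g in genes:
        i = index[g]
        shift = float(np.log2(planted_fc.get(g, 1.0)))
        normal[i] = rng.normal(baseline[g], 1.0, size=n_n)
        if g not in in_pair:
            tumor[i] = rng.normal(baseline[g] + shift, 1.0, size=n_t)

    for (a, b), rho in planted_rho.items():
        cov = np.array([[1.0, rho], [rho, 1.0]])
        mean = [
            baseline[a] + float(np.log2(planted_fc.get(a, 1.0))),
            baseline[b] + float(np.log2(planted_fc.get(b, 1.0))),
        ]
        draws = rng.multivariate_normal(mean, cov, size=n_t, method="cholesky")
        tumor[index[a]] = draws[:, 0]
        tumor[index[b]] = draws[:, 1]

    # keep the matrix on a non-negative log2(TPM+1)-like scale
    tumor = np.clip(tumor, 0.0, None)
    normal = np.clip(normal, 0.0, None)
    samples = [f"{spec.cohort_id}_T{i:04d}" for i in range(n_t)] + [
        f"{spec.cohort_id}_N{i:04d}" for i in range(n_n)
    ]
    matrix = pd.DataFrame(np.hstack([tumor, normal]), index=genes, columns=samples)
    groups = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=samples, name="group")
    return ExpressionCohort(spec.cohort_id, matrix, groups)


def gen_expression_cohorts(
    config: SyntheticConfig, truth: PlantedTruth
) -> dict[str, ExpressionCohort]:
    """All cohorts of the config, sharing one expression stream."""
    rng = config._rng("expression")
    genes = config.enzymes + sorted({p for _, p in truth.true_consensus_edges})
    cohorts = {}
    truth.deg_genes = {}
    truth.correlated_pairs = []
    for spec in config.cohort_specs:
        rho_here = {
            (a, b): rho
            for (a, b, cid), rho in config.planted_rho.items()
            if cid == spec.cohort_id
        }
        cohorts[spec.cohort_id] = gen_expression_cohort(
            spec, config.planted_fc, rho_here, genes, rng
        )
        truth.deg_genes[spec.cohort_id] = sorted(
            g for g, fc in config.planted_fc.items() if fc >= 3.0 and g in genes
        )
        truth.correlated_pairs.extend(
            (a, b, spec.cohort_id, rho) for (a, b), rho in sorted(rho_here.items())
        )
    return cohorts


# ---------------------------------------------------------------------------
# Survival

def _censoring_horizon(hazards: np.ndarray, target_rate: float) -> float:
    """Administrative horizon t_max with expected censoring ~= target.

    For exponential T with hazard h and C ~ U(0, t_max), the censoring
    probability is (1 - exp(-h t_max)) / (h t_max); solved by bisection
    on the cohort average.
    """
    def mean_censoring(t_max: float) -> float:
        x = hazards * t_max
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if mean_censoring(mid) > target_rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def gen_survival_cohort(
    spec: SurvivalSpec, rng: np.random.Generator, cohort_id: str = "SURV"
) -> tuple[SurvivalCohort, np.ndarray]:
    """Simulate a two-group survival cohort with a planted hazard ratio.

    Event times are exponential: hazard ``baseline_hazard`` in the low
    group and ``baseline_hazard * planted_hr`` in the high group.
    Scores are well separated across the median so a median split
    recovers the planted groups exactly.  Censoring is
    administrative-uniform on [0, t_max], with t_max solved to meet the
    configured censoring fraction.
    """
    n = spec.n_samples
    n_high = n // 2
    high = np.zeros(n, dtype=bool)
    high[:n_high] = True
    rng.shuffle(high)
    score = np.where(high, rng.uniform(6.0, 8.0, size=n), rng.uniform(2.0, 4.0, size=n))
    hazard = np.where(high, spec.baseline_hazard * spec.planted_hr, spec.baseline_hazard)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0.0:
        t_max = _censoring_horizon(hazard, spec.censoring_rate)
        t_cens = rng.uniform(0.0, t_max, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time = t_event
        event = np.ones(n, dtype=int)
    time = np.maximum(time, 1e-9)
    return SurvivalCohort(cohort_id, time, event, score), high


def gen_survival_cohorts(
    config: SyntheticConfig, truth: PlantedTruth
) -> dict[str, tuple[SurvivalCohort, np.ndarray]]:
    rng = config._rng("survival")
    cohort, high = gen_survival_cohort(config.survival_spec, rng)
    truth.prognostic = {
        "planted_hr": config.survival_spec.planted_hr,
        "n_samples": config.survival_spec.n_samples,
        "n_high": int(high.sum()),
    }
    return {cohort.cohort_id: (cohort, high)}


# ---------------------------------------------------------------------------
# Gene sets

def gen_geneset_collection(
    spec: GenesetSpec,
    rng: np.random.Generator,
    query: list[str] | None = None,
    universe: list[str] | None = None,
) -> tuple[GeneSetCollection, list[str], str]:
    """Generate a GMT-style collection with one planted enriched term.

    Returns (collection, query list, planted term id).  The planted term
    overlaps the query in exactly ``planted_overlap`` genes; all other
    terms are uniform draws from the universe.  A caller-supplied
    universe is padded with filler genes up to ``universe_size``.
    """
    if universe is None:
        universe = [f"G{i:05d}" for i in range(1, spec.universe_size + 1)]
    elif len(universe) < spec.universe_size:
        universe = list(universe) + [
            f"G{i:05d}" for i in range(1, spec.universe_size - len(universe) + 1)
        ]
    if query is None:
        query = [str(g) for g in rng.choice(universe, size=spec.query_size, replace=False)]
    overlap = min(spec.planted_overlap, len(query))
    if overlap < 1:
        raise ConfigurationError("query too small to plant an enriched term")
    lo, hi = spec.term_size_range
    terms = []
    planted_id = "T_PLANTED"
    size = int(rng.integers(max(lo, overlap), hi + 1))
    inside = rng.choice(query, size=overlap, replace=False)
    outside_pool = sorted(set(universe) - set(query))
    outside = rng.choice(outside_pool, size=size - overlap, replace=False)
    terms.append((planted_id, "planted enriched term", frozenset(map(str, inside)) | frozenset(map(str, outside))))
    for i in range(1, spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=size, replace=False)
        terms.append((f"T{i:04d}", f"random term {i}", frozenset(map(str, genes))))
    collection = GeneSetCollection.from_terms(terms, universe=universe)
    return collection, list(query), planted_id


def gen_genesets(config: SyntheticConfig, truth: PlantedTruth):
    """Collection whose planted term targets the pipeline's own query
    (the partners surviving both selection rounds)."""
    rng = config._rng("genesets")
    query = sorted({p for _, p in truth.concordant_edges}) or sorted(
        {p for _, p in truth.true_consensus_edges}
    )
    universe = config.partners + config.enzymes
    collection, query, planted_id = gen_geneset_collection(
        config.geneset_spec, rng, query=query, universe=universe
    )
    truth.enriched_terms = [planted_id]
    return collection, query


# ---------------------------------------------------------------------------
# Writers (plain-text dialects used by the pipeline)

def write_source_tables(
    tables: dict[str, list[SourceRecord]], outdir: str | Path, dialect: str = "tsv"
) -> dict[str, Path]:
    """Write per-source edge files in TSV or PSI-MITAB 2.5."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for source, records in tables.items():
        if dialect == "tsv":
            path = outdir / f"{source}.tsv"
            with open(path, "w") as fh:
                for r in records:
                    conf = "" if r.confidence is None else f"{r.confidence:.6f}"
                    ev = r.evidence_type or ""
                    pubs = "" if r.publication_count is None else str(r.publication_count)
                    fh.write(f"{r.source_name}\t{r.id_a}\t{r.id_b}\t{conf}\t{ev}\t{pubs}\n")
        elif dialect == "mitab25":
            path = outdir / f"{source}.mitab"
            with open(path, "w") as fh:
                for r in records:
                    ev = r.evidence_type or "physical association"
                    pubs = "|".join(
                        f"pubmed:{1000 + i}" for i in range(r.publication_count or 1)
                    )
                    conf = "-" if r.confidence is None else f"score:{r.confidence:.6f}"
                    cols = [
                        f"genename:{r.id_a}", f"genename:{r.id_b}", "-", "-", "-", "-",
                        "psi-mi:\"MI:0004\"(affinity chromatography)", "-", pubs,
                        "taxid:9606(human)", "taxid:9606(human)",
                        f"psi-mi:\"MI:0915\"({ev})", f"psi-mi:\"MI:0000\"({r.source_name})",
                        "-", conf,
                    ]
                    fh.write("\t".join(cols) + "\n")
        else:
            raise ConfigurationError(f"unknown dialect {dialect!r}")
        paths[source] = path
    return paths


def write_localization_table(
    profiles: dict[str, LocalizationProfile], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for protein in sorted(profiles):
            fh.write(f"{protein}\t{';'.join(sorted(profiles[protein].compartments))}\n")
    return path


def write_expression_cohort(cohort: ExpressionCohort, outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mpath = outdir / f"expr_{cohort.cohort_id}.tsv"
    gpath = outdir / f"groups_{cohort.cohort_id}.tsv"
    cohort.matrix.to_csv(mpath, sep="\t", index_label="gene", float_format="%.6f")
    cohort.groups.rename("group").to_csv(gpath, sep="\t", index_label="sample")
    return mpath, gpath


def write_survival_cohort(cohort: SurvivalCohort, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample": [f"S{i:05d}" for i in range(cohort.n)],
            "time_months": cohort.time,
            "event": cohort.event,
            "score": cohort.score,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path
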