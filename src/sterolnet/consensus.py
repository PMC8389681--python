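"""Multi-source PPI ingestion and consensus selection (selection round 1).

Interaction assertions are harvested from a registry of interactome
browsers, filtered by each browser's own confidence policy, normalized to
canonical gene symbols, and finally aggregated into enzyme–partner edges
supported by at least ``min_sources`` independent browsers.  Browsers are
counted as independent even when they index overlapping primary databases:
the consensus rule is phrased per browser, not per primary experiment.
"""

from __future__ import annotations

import json
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SourceRecord",
    "SourceRegistryEntry",
    "ConsensusEdge",
    "ConfigurationError",
    "default_registry",
    "parse_source_table",
    "filter_by_source_policy",
    "load_mapping_table",
    "normalize_identifiers",
    "aggregate_consensus",
    "summarize_retrieval",
    "write_consensus_edges",
]


class ConfigurationError(ValueError):
    """Raised when a registry, mapping table or parameter is malformed."""


@dataclass
class SourceRecord:
    """One interaction assertion reported by one source database."""

    source_name: str
    id_a: str
    id_b: str
    id_namespace: str = "gene_symbol"  # or "uniprot_ac"
    confidence: float | None = None
    evidence_type: str | None = None
    publication_count: int | None = None


@dataclass(frozen=True)
class SourceRegistryEntry:
    """Per-source parsing dialect and confidence policy.

    ``min_confidence`` is an exclusive lower bound (the browsers publish
    their cut-offs as "Score > x"), ``allowed_evidence`` restricts to a
    set of interaction-type terms, ``min_publications`` is inclusive.
    """

    source_name: str
    dialect: str = "tsv"  # {"tsv", "mitab25"}
    min_confidence: float | None = None
    allowed_evidence: frozenset[str] | None = None
    min_publications: int | None = None

    def __post_init__(self) -> None:
        if self.dialect not in {"tsv", "mitab25"}:
            raise ConfigurationError(
                f"unknown dialect {self.dialect!r} for source {self.source_name!r}"
            )
        if self.min_confidence is not None and self.min_confidence < 0:
            raise ConfigurationError(
                f"min_confidence must be non-negative for {self.source_name!r}"
            )
        if self.min_publications is not None and self.min_publications < 0:
            raise ConfigurationError(
                f"min_publications must be non-negative for {self.source_name!r}"
            )

    def accepts(self, record: SourceRecord) -> bool:
        """Whether *record* satisfies every threshold of this entry."""
        if self.min_confidence is not None:
            if record.confidence is None or not record.confidence > self.min_confidence:
                return False
        if self.allowed_evidence is not None:
            if record.evidence_type is None or record.evidence_type not in self.allowed_evidence:
                return False
        if self.min_publications is not None:
            if record.publication_count is None or record.publication_count < self.min_publications:
                return False
        return True


@dataclass
class ConsensusEdge:
    """An enzyme–partner pair with the set of browsers that assert it."""

    enzyme: str
    partner: str
    supporting_sources: frozenset[str]
    is_enzyme_enzyme: bool = False

    @property
    def n_sources(self) -> int:
        return len(self.supporting_sources)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.enzyme, self.partner)


# ---------------------------------------------------------------------------
# Source registry

_PHYSICAL = frozenset({"physical interaction", "physical association", "direct interaction"})


def default_registry() -> dict[str, SourceRegistryEntry]:
    """Registry of 13 interactome browsers with their confidence policies.

    Thresholds follow each browser's documented export settings: FunCoup
    (confidence > 0.9), HIPPIE (score > 0.6), BioPlex (interaction
    probability > 0.9), APID (>= 1 publication), Mentha (physical
    interactions only), IID (experimentally detected only), MINT
    (association / physical association), HINT (binary).  Browsers with
    no stated policy accept every record.
    """
    entries = [
        SourceRegistryEntry("funcoup", min_confidence=0.9),
        SourceRegistryEntry("mentha", allowed_evidence=_PHYSICAL),
        SourceRegistryEntry("corum"),
        SourceRegistryEntry("exocarta"),
        SourceRegistryEntry("apid", min_publications=1),
        SourceRegistryEntry(
            "mint", allowed_evidence=frozenset({"association", "physical association"})
        ),
        SourceRegistryEntry("signor"),
        SourceRegistryEntry("huri"),
        SourceRegistryEntry("iid", allowed_evidence=frozenset({"exp", "experimental"})),
        SourceRegistryEntry("bioplex", min_confidence=0.9),
        SourceRegistryEntry("wikipi"),
        SourceRegistryEntry("hippie", min_confidence=0.6),
        SourceRegistryEntry("hint", allowed_evidence=frozenset({"binary"})),
    ]
    return {e.source_name: e for e in entries}


def load_registry(path: str | Path) -> dict[str, SourceRegistryEntry]:
    """Load a source registry from a JSON file.

    The file maps source name -> {dialect, min_confidence,
    allowed_evidence, min_publications}; missing keys mean "no policy".
    """
    with open(path) as fh:
        raw = json.load(fh)
    registry: dict[str, SourceRegistryEntry] = {}
    for name, spec in raw.items():
        allowed = spec.get("allowed_evidence")
        registry[name] = SourceRegistryEntry(
            source_name=name,
            dialect=spec.get("dialect", "tsv"),
            min_confidence=spec.get("min_confidence"),
            allowed_evidence=frozenset(allowed) if allowed is not None else None,
            min_publications=spec.get("min_publications"),
        )
    return registry


# ---------------------------------------------------------------------------
# Parsing

_MITAB_ID_RE = re.compile(r"^(?P<db>[^:]+):(?P<acc>.+)$")
_MITAB_PAREN_RE = re.compile(r"\(([^)]*)\)")

_NAMESPACE_MAP = {
    "uniprotkb": "uniprot_ac",
    "uniprot": "uniprot_ac",
    "entrez gene/locuslink": "gene_symbol",
    "hgnc": "gene_symbol",
    "genename": "gene_symbol",
}


def _parse_mitab_id(token: str) -> tuple[str, str] | None:
    """'uniprotkb:Q14534' -> ('uniprot_ac', 'Q14534')."""
    m = _MITAB_ID_RE.match(token.strip())
    if m is None or not m.group("acc"):
        return None
    db = m.group("db").strip().lower()
    acc = m.group("acc").strip().strip('"')
    return _NAMESPACE_MAP.get(db, db), acc


def _parse_mitab_line(line: str, source_name: str) -> SourceRecord | None:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 15:
        return None
    a = _parse_mitab_id(cols[0])
    b = _parse_mitab_id(cols[1])
    if a is None or b is None:
        return None
    ns_a, id_a = a
    ns_b, id_b = b
    if ns_a != ns_b:
        # mixed-namespace rows are rare; keep the record, downstream
        # mapping handles both namespaces through one lookup table
        pass
    # interaction type, column 12: psi-mi:"MI:0915"(physical association)
    evidence = None
    if cols[11] not in ("-", ""):
        m = _MITAB_PAREN_RE.search(cols[11])
        evidence = m.group(1) if m else cols[11]
    # publications, column 9: pipe-separated identifiers
    pubs = None
    if cols[8] not in ("-", ""):
        pubs = len([p for p in cols[8].split("|") if p])
    # confidence, column 15: e.g. intact-miscore:0.73
    confidence = None
    if cols[14] not in ("-", ""):
        last = cols[14].split("|")[-1]
        try:
            confidence = float(last.split(":")[-1])
        except ValueError:
            confidence = None
    return SourceRecord(
        source_name=source_name,
        id_a=id_a,
        id_b=id_b,
        id_namespace=ns_a,
        confidence=confidence,
        evidence_type=evidence,
        publication_count=pubs,
    )


def _parse_tsv_line(line: str, source_name: str) -> SourceRecord | None:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 3:
        return None
    src = cols[0].strip() or source_name
    id_a, id_b = cols[1].strip(), cols[2].strip()
    if not id_a or not id_b:
        return None
    confidence = None
    if len(cols) > 3 and cols[3].strip() not in ("", "-"):
        try:
            confidence = float(cols[3])
        except ValueError:
            return None
    evidence = cols[4].strip() or None if len(cols) > 4 else None
    pubs = None
    if len(cols) > 5 and cols[5].strip() not in ("", "-"):
        try:
            pubs = int(cols[5])
        except ValueError:
            return None
    ns = "uniprot_ac" if re.fullmatch(r"[OPQ][0-9][A-Z0-9]{3}[0-9]", id_a) else "gene_symbol"
    return SourceRecord(src, id_a, id_b, ns, confidence, evidence, pubs)


def parse_source_table(
    path: str | Path, registry_entry: SourceRegistryEntry
) -> tuple[list[SourceRecord], int]:
    """Parse one source export into records.

    Returns ``(records, n_malformed)``.  Malformed lines are counted and
    logged but never fatal; an empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    if registry_entry.dialect == "mitab25":
        line_parser = _parse_mitab_line
    elif registry_entry.dialect == "tsv":
        line_parser = _parse_tsv_line
    else:  # pragma: no cover - blocked by entry validation
        raise ConfigurationError(f"unknown dialect {registry_entry.dialect!r}")

    records: list[SourceRecord] = []
    n_malformed = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            rec = line_parser(line, registry_entry.source_name)
            if rec is None:
                n_malformed += 1
            else:
                records.append(rec)
    if n_malformed:
        logger.warning("%s: %d malformed lines skipped", path.name, n_malformed)
    if not records:
        logger.warning("%s: no records parsed", path.name)
    return records, n_malformed


def filter_by_source_policy(
    records: list[SourceRecord], registry: dict[str, SourceRegistryEntry]
) -> list[SourceRecord]:
    """Keep each record iff it satisfies all thresholds of its own source."""
    kept = []
    for rec in records:
        entry = registry.get(rec.source_name)
        if entry is None:
            raise ConfigurationError(f"record from unregistered source {rec.source_name!r}")
        if entry.accepts(rec):
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# Identifier normalization

def load_mapping_table(path: str | Path) -> dict[str, str]:
    """Load an (accession, alias, symbol) TSV into one lookup dictionary.

    Both the accession and the alias column map to the canonical symbol;
    every canonical symbol also maps to itself.  Conflicting duplicate
    rows are a configuration error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = {"accession", "alias", "symbol"}
    if not expected.issubset(df.columns):
        raise ConfigurationError(f"mapping table must have columns {sorted(expected)}")
    return build_mapping(
        list(zip(df["accession"], df["symbol"])) + list(zip(df["alias"], df["symbol"]))
    )


def build_mapping(pairs: list[tuple[str, str]]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for key, symbol in pairs:
        key, symbol = key.strip(), symbol.strip()
        if not key or not symbol:
            continue
        if key in mapping and mapping[key] != symbol:
            raise ConfigurationError(
                f"conflicting mapping for {key!r}: {mapping[key]!r} vs {symbol!r}"
            )
        mapping[key] = symbol
        mapping.setdefault(symbol, symbol)
    return mapping


def normalize_identifiers(
    records: list[SourceRecord], mapping: dict[str, str]
) -> tuple[list[SourceRecord], list[SourceRecord]]:
    """Map both interactors to canonical gene symbols.

    Pairs are canonicalized lexicographically (re-oriented to
    (enzyme, partner) later, at aggregation).  Records with an unmapped
    identifier are excluded and returned separately for reporting.
    """
    normalized: list[SourceRecord] = []
    unmapped: list[SourceRecord] = []
    for rec in records:
        a = mapping.get(rec.id_a)
        b = mapping.get(rec.id_b)
        if a is None or b is None:
            unmapped.append(rec)
            continue
        lo, hi = sorted((a, b))
        normalized.append(
            SourceRecord(
                source_name=rec.source_name,
                id_a=lo,
                id_b=hi,
                id_namespace="gene_symbol",
                confidence=rec.confidence,
                evidence_type=rec.evidence_type,
                publication_count=rec.publication_count,
            )
        )
    return normalized, unmapped


# ---------------------------------------------------------------------------
# Consensus aggregation

def _orient(rec: SourceRecord, enzymes: set[str]) -> tuple[str, str] | None:
    """Orient a pair as (enzyme, partner); None if no interactor is a target."""
    a_is = rec.id_a in enzymes
    b_is = rec.id_b in enzymes
    if a_is and b_is:
        lo, hi = sorted((rec.id_a, rec.id_b))
        return lo, hi  # enzyme-enzyme pairs anchor on the smaller symbol
    if a_is:
        return rec.id_a, rec.id_b
    if b_is:
        return rec.id_b, rec.id_a
    return None


def aggregate_consensus(
    records: list[SourceRecord],
    enzymes: list[str] | set[str],
    min_sources: int = 3,
    keep_self: bool = False,
) -> list[ConsensusEdge]:
    """Select enzyme–partner pairs asserted by >= ``min_sources`` browsers.

    Duplicate assertions within one source count once.  Self-interactions
    are excluded unless ``keep_self``.  Edges between two target enzymes
    are retained and flagged ``is_enzyme_enzyme`` (they are reported, not
    silently dropped, because pathway enzymes may physically cluster).
    For an enzyme–enzyme pair both orientations collapse onto the
    lexicographically smaller enzyme.
    """
    if not enzymes:
        raise ConfigurationError("enzyme list must be non-empty")
    if min_sources < 1:
        raise ConfigurationError("min_sources must be >= 1")
    enzyme_set = set(enzymes)
    support: dict[tuple[str, str], set[str]] = defaultdict(set)
    for rec in records:
        oriented = _orient(rec, enzyme_set)
        if oriented is None:
            continue
        enzyme, partner = oriented
        if enzyme == partner and not keep_self:
            continue
        support[(enzyme, partner)].add(rec.source_name)
    edges = [
        ConsensusEdge(
            enzyme=enz,
            partner=par,
            supporting_sources=frozenset(sources),
            is_enzyme_enzyme=par in enzyme_set and par != enz,
        )
        for (enz, par), sources in sorted(support.items())
        if len(sources) >= min_sources
    ]
    return edges


def summarize_retrieval(
    records: list[SourceRecord], enzymes: list[str] | set[str]
) -> tuple[dict[str, int], int]:
    """Distinct raw partners per enzyme and the grand pair total,
    before any consensus filtering."""
    enzyme_set = set(enzymes)
    partners: dict[str, set[str]] = {e: set() for e in sorted(enzyme_set)}
    pairs: set[tuple[str, str]] = set()
    for rec in records:
        oriented = _orient(rec, enzyme_set)
        if oriented is None:
            continue
        enzyme, partner = oriented
        if enzyme == partner:
            continue
        partners[enzyme].add(partner)
        pairs.add((enzyme, partner))
    return {e: len(p) for e, p in partners.items()}, len(pairs)


def write_consensus_edges(edges: list[ConsensusEdge], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "enzyme": [e.enzyme for e in edges],
            "partner": [e.partner for e in edges],
            "n_sources": [e.n_sources for e in edges],
            "sources": [";".join(sorted(e.supporting_sources)) for e in edges],
            "is_enzyme_enzyme": [e.is_enzyme_enzyme for e in edges],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_consensus_edges(path: str | Path) -> list[ConsensusEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"enzyme": str, "partner": str})
    return [
        ConsensusEdge(
            enzyme=row.enzyme,
            partner=row.partner,
            supporting_sources=frozenset(str(row.sources).split(";")),
            is_enzyme_enzyme=bool(row.is_enzyme_enzyme),
        )
        for row in df.itertuples()
    ]
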