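"""Hypergeometric over-representation analysis against GMT collections,
Benjamini–Hochberg adjustment, and curated-class annotation of partners
(modifying-protein classes, cancer-driver and essential-gene flags).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConfigurationError

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "AnnotationFlags",
    "read_gmt",
    "write_gmt",
    "ora_hypergeometric",
    "bh_adjust",
    "load_modifying_class_map",
    "classify_modifying",
    "flag_annotations",
]

MODIFYING_CLASSES = (
    "protein_kinase",
    "protein_phosphatase",
    "ubiquitin_ligase",
    "deubiquitinase",
    "protease",
    "other_modifier",
)


@dataclass
class GeneSetCollection:
    terms: list[tuple[str, str, frozenset[str]]]  # (term_id, name, genes)
    universe: frozenset[str]

    @classmethod
    def from_terms(
        cls, terms: list[tuple[str, str, frozenset[str]]], universe=None
    ) -> "GeneSetCollection":
        if universe is None:
            # WebGestalt-style reference set: all genes the collection annotates
            universe = frozenset().union(*(g for _, _, g in terms)) if terms else frozenset()
        else:
            universe = frozenset(universe)
            terms = [(tid, name, genes & universe) for tid, name, genes in terms]
        terms = [t for t in terms if t[2]]
        return cls(terms, universe)


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    k: int  # overlap
    n: int  # query size in universe
    K: int  # term size
    N: int  # universe size
    p_value: float
    q_value: float = np.nan
    enrichment_ratio: float = np.nan
    significant: bool = False


@dataclass
class AnnotationFlags:
    gene: str
    is_cancer_driver: bool
    mutation_frequency: float | None
    is_common_essential: bool


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (term, description, genes...).

    Genes duplicated within a term are deduplicated; terms with no genes
    are dropped with a warning; a line with fewer than 3 columns raises
    with its line number.
    """
    import logging

    terms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ConfigurationError(f"GMT line {lineno}: fewer than 3 columns")
            genes = frozenset(g.strip() for g in cols[2:] if g.strip())
            if not genes:
                logging.getLogger(__name__).warning(
                    "GMT line %d: empty term %s dropped", lineno, cols[0]
                )
                continue
            terms.append((cols[0], cols[1], genes))
    return GeneSetCollection.from_terms(terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, name, genes in collection.terms:
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora_hypergeometric(
    query, collection: GeneSetCollection, alpha_fdr: float = 0.05, use_fdr: bool = True
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a query list.

    The query is restricted to the collection's universe first.  With
    ``use_fdr`` the significant set is q <= alpha_fdr; with
    ``use_fdr=False`` the raw p is gated instead (the per-collection
    threshold mode some annotation sources use).
    """
    query_set = frozenset(query) & collection.universe
    if not query_set:
        raise ConfigurationError("query has no genes in the collection universe")
    N = len(collection.universe)
    n = len(query_set)
    results = []
    for term_id, name, genes in collection.terms:
        K = len(genes)
        k = len(genes & query_set)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        ratio = (k / n) / (K / N) if k > 0 else 0.0
        results.append(EnrichmentResult(term_id, name, k, n, K, N, min(p, 1.0),
                                        enrichment_ratio=ratio))
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
        r.significant = (q <= alpha_fdr) if use_fdr else (r.p_value <= alpha_fdr)
    return results


def load_modifying_class_map(path: str | Path | None = None) -> dict[str, str]:
    """Load the modifying-protein class map (symbol -> class).

    Without a path, the curated map shipped with the package is used:
    kinases, phosphatases, ubiquitin ligases, deubiquitinases and
    proteases known to act on the cholesterol synthesis enzymes.
    """
    if path is None:
        ref = resources.files("sterolnet.data") / "modifying_classes.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    if not {"symbol", "class"}.issubset(df.columns):
        raise ConfigurationError("class map needs 'symbol' and 'class' columns")
    bad = set(df["class"]) - set(MODIFYING_CLASSES)
    if bad:
        raise ConfigurationError(f"unknown modifying classes: {sorted(bad)}")
    dup = df[df.duplicated("symbol", keep=False)]
    if not dup.empty and dup.groupby("symbol")["class"].nunique().max() > 1:
        raise ConfigurationError("conflicting duplicate rows in class map")
    return dict(zip(df["symbol"], df["class"]))


def classify_modifying(
    partners, class_map: dict[str, str]
) -> tuple[dict[str, str], dict]:
    """Assign each partner its modifying-protein class.

    Unmapped partners get class "none".  The summary reports the count
    and integer percentage of modifying partners and the per-class
    distribution.
    """
    partners = list(dict.fromkeys(partners))
    classes = {p: class_map.get(p, "none") for p in partners}
    counts = Counter(c for c in classes.values() if c != "none")
    n_mod = sum(counts.values())
    total = len(partners)
    summary = {
        "n_partners": total,
        "n_modifying": n_mod,
        "percent_modifying": round(100.0 * n_mod / total) if total else 0,
        "class_counts": dict(counts),
    }
    return classes, summary


def _load_symbol_table(path: str | Path, value_col: str | None = None):
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"symbol": str})
    if "symbol" not in df.columns:
        raise ConfigurationError(f"{path}: expected a 'symbol' column")
    df = df.drop_duplicates("symbol")
    values = None
    if value_col and value_col in df.columns:
        values = dict(zip(df["symbol"], df[value_col].astype(float)))
    return set(df["symbol"]), values


def flag_annotations(
    partners, driver_table: str | Path, essential_table: str | Path
) -> list[AnnotationFlags]:
    """Flag each partner as cancer driver and/or common-essential.

    Flags derive only from the supplied tables (TSV with a 'symbol'
    column; the driver table may carry 'mutation_frequency').
    """
    drivers, freqs = _load_symbol_table(driver_table, "mutation_frequency")
    essentials, _ = _load_symbol_table(essential_table)
    out = []
    for gene in dict.fromkeys(partners):
        out.append(
            AnnotationFlags(
                gene=gene,
                is_cancer_driver=gene in drivers,
                mutation_frequency=(freqs or {}).get(gene),
                is_common_essential=gene in essentials,
            )
        )
    return out
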