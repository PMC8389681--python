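"""Tumor/normal differential expression and DEG-conditioned Pearson
co-expression banding.

Fold change is the ratio of pseudo-counted group medians on the linear
scale, recovered from the log2(TPM+1)-like matrix.  A gene is a DEG when
FC >= 3 and the two-group test gives p <= 0.01 (the FC gate, not the
multiplicity-adjusted q, drives selection; BH q-values are reported for
context).  Pairwise Pearson correlations are computed only in cohorts
where the enzyme is a DEG, then banded: |r| in [0.4, 0.6) is "average",
|r| >= 0.6 is "strong", below 0.4 no band; negative correlations at or
beyond -0.4 are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConfigurationError, ConsensusEdge
from .enrichment import bh_adjust

__all__ = [
    "ExpressionCohort",
    "DegResult",
    "CoexpressionResult",
    "compute_fold_change",
    "call_degs",
    "select_coexpression_tasks",
    "pearson_coexpression",
    "assign_band",
]


@dataclass
class ExpressionCohort:
    """One cancer cohort: genes x samples on a log2(TPM+1)-like scale."""

    cohort_id: str
    matrix: pd.DataFrame  # index: genes, columns: sample IDs
    groups: pd.Series  # sample -> {"tumor", "normal"}

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.matrix.columns)
        if self.groups.isna().any():
            missing = list(self.groups[self.groups.isna()].index[:3])
            raise ConfigurationError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - {"tumor", "normal"}
        if bad:
            raise ConfigurationError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ConfigurationError("expression matrix contains non-finite values")

    def samples(self, group: str) -> pd.DataFrame:
        return self.matrix.loc[:, self.groups == group]

    @classmethod
    def from_tsv(cls, matrix_path, groups_path, cohort_id: str) -> "ExpressionCohort":
        matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
        g = pd.read_csv(groups_path, sep="\t", index_col=0)
        return cls(cohort_id, matrix, g.iloc[:, 0])


@dataclass
class DegResult:
    gene: str
    cohort_id: str
    fc: float
    log2fc: float
    p_value: float
    q_value: float = np.nan
    is_deg: bool = False


@dataclass
class CoexpressionResult:
    enzyme: str
    partner: str
    cohort_id: str
    r: float
    n: int
    band: str  # {"none", "average", "strong"}
    negative: bool
    degenerate: bool = False


def compute_fold_change(
    cohort: ExpressionCohort, gene: str, pseudo: float = 1.0
) -> tuple[float, float]:
    """Tumor/normal fold change from pseudo-counted linear-scale medians.

    With pseudo = 1 and values stored as log2(x+1), the group median of
    the linear values plus the pseudo-count is exactly 2**median(log2),
    so FC reduces to 2**(median difference on the log scale).
    """
    if gene not in cohort.matrix.index:
        raise KeyError(f"gene {gene!r} not in cohort {cohort.cohort_id!r}")
    tumor = cohort.samples("tumor").loc[gene].to_numpy()
    normal = cohort.samples("normal").loc[gene].to_numpy()
    if tumor.size < 1 or normal.size < 1:
        raise ConfigurationError("both groups need at least one sample")
    med_t = float(np.median(np.exp2(tumor) - 1.0))
    med_n = float(np.median(np.exp2(normal) - 1.0))
    fc = (med_t + pseudo) / (med_n + pseudo)
    return fc, float(np.log2(fc))


def _group_p_value(tumor: np.ndarray, normal: np.ndarray, test: str) -> float:
    if np.ptp(np.concatenate([tumor, normal])) == 0.0:
        return 1.0  # constant gene: no evidence either way
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(tumor, normal, alternative="two-sided").pvalue)
    if test == "welch":
        return float(stats.ttest_ind(tumor, normal, equal_var=False).pvalue)
    raise ConfigurationError(f"unknown test {test!r}")


def call_degs(
    cohort: ExpressionCohort,
    fc_threshold: float = 3.0,
    alpha: float = 0.01,
    pseudo: float = 1.0,
    test: str = "mannwhitney",
) -> list[DegResult]:
    """Call DEGs with FC >= threshold and p <= alpha.

    The two-sided Mann–Whitney rank test on the log2 matrix is the
    default (robust to the heavy right tails of TPM data); Welch's t is
    available behind ``test="welch"``.  The FC gate is direction-free
    only in the sense that the paper screens up-regulation: FC >= 3 on
    the tumor/normal ratio.
    """
    tumor = cohort.samples("tumor")
    normal = cohort.samples("normal")
    if tumor.shape[1] < 3 or normal.shape[1] < 3:
        raise ConfigurationError("need >= 3 samples per group for DEG testing")
    results = []
    for gene in cohort.matrix.index:
        fc, log2fc = compute_fold_change(cohort, gene, pseudo=pseudo)
        p = _group_p_value(tumor.loc[gene].to_numpy(), normal.loc[gene].to_numpy(), test)
        results.append(DegResult(gene, cohort.cohort_id, fc, log2fc, p))
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
        r.is_deg = (r.fc >= fc_threshold) and (r.p_value <= alpha)
    return results


def select_coexpression_tasks(
    deg_results: list[DegResult], edges: list[ConsensusEdge]
) -> list[tuple[str, str, str]]:
    """(enzyme, partner, cohort) triples where the enzyme is a DEG."""
    deg_cohorts: dict[str, set[str]] = {}
    for r in deg_results:
        if r.is_deg:
            deg_cohorts.setdefault(r.gene, set()).add(r.cohort_id)
    tasks = []
    for edge in edges:
        for cohort_id in sorted(deg_cohorts.get(edge.enzyme, ())):
            tasks.append((edge.enzyme, edge.partner, cohort_id))
    return tasks


def assign_band(
    r: float, cutoffs: tuple[float, float, float] = (0.4, 0.6, 0.7)
) -> tuple[str, bool]:
    """Band a Pearson coefficient: none / average / strong + negative flag.

    Boundaries are closed from below (0.4 is "average", 0.6 is
    "strong") because the banding rule treats 0.4 as a pass cut-off.
    |r| above the strong band's nominal upper edge remains "strong" —
    there is no category above it.
    """
    if not -1.0 <= r <= 1.0 + 1e-12:
        raise ConfigurationError(f"Pearson r out of range: {r}")
    lo, hi, _top = cutoffs
    a = abs(r)
    if a < lo:
        band = "none"
    elif a < hi:
        band = "average"
    else:
        band = "strong"
    return band, r <= -lo


def pearson_coexpression(
    cohort: ExpressionCohort,
    pair: tuple[str, str],
    scope: str = "tumor",
    min_samples: int = 10,
    cutoffs: tuple[float, float, float] = (0.4, 0.6, 0.7),
) -> CoexpressionResult:
    """Sample Pearson correlation for one enzyme–partner pair.

    ``scope`` selects the samples ("tumor" by default — co-expression is
    asked about the tumor state — or "all").  A zero-variance gene gives
    a degenerate result with band "none" instead of an error.
    """
    enzyme, partner = pair
    if scope == "tumor":
        mat = cohort.samples("tumor")
    elif scope == "all":
        mat = cohort.matrix
    else:
        raise ConfigurationError(f"unknown scope {scope!r}")
    for gene in pair:
        if gene not in mat.index:
            raise KeyError(f"gene {gene!r} not in cohort {cohort.cohort_id!r}")
    x = mat.loc[enzyme].to_numpy(dtype=float)
    y = mat.loc[partner].to_numpy(dtype=float)
    n = x.size
    if n < min_samples:
        raise ConfigurationError(
            f"{n} samples < min_samples={min_samples} in cohort {cohort.cohort_id!r}"
        )
    if enzyme == partner:
        r = 1.0
    elif np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return CoexpressionResult(enzyme, partner, cohort.cohort_id, np.nan, n, "none", False, True)
    else:
        r = float(stats.pearsonr(x, y).statistic)
    band, negative = assign_band(r, cutoffs)
    return CoexpressionResult(enzyme, partner, cohort.cohort_id, r, n, band, negative)
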