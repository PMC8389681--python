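"""Median-split prognostic screening: Kaplan–Meier curves, two-group
log-rank tests, binary-covariate Cox hazard ratios and multi-gene
signature scores.

Samples are dichotomized at the median expression (or signature score);
the hazard ratio compares the high group against the low group, so
HR < 1 means lower mortality with high expression.  Two gates are
applied: the default map gate (BH-FDR q <= 0.05) and the strict filter
(raw p < 0.001, HR <= 0.5 or HR >= 2, and >= 200 cases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConfigurationError
from .enrichment import bh_adjust

__all__ = [
    "SurvivalCohort",
    "ScreenCriteria",
    "SurvivalResult",
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_hr_binary",
    "signature_score",
    "screen_prognostic",
]


@dataclass
class SurvivalCohort:
    """Per-sample follow-up for one cohort: time (months), event, score."""

    cohort_id: str
    time: np.ndarray
    event: np.ndarray
    score: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.score = np.asarray(self.score, dtype=float)
        if not (self.time > 0).all():
            raise ConfigurationError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ConfigurationError("event flags must be 0/1")
        if not (self.time.shape == self.event.shape == self.score.shape):
            raise ConfigurationError("time/event/score lengths differ")

    @classmethod
    def from_tsv(cls, path, cohort_id: str, days: bool = False) -> "SurvivalCohort":
        df = pd.read_csv(path, sep="\t")
        time = df["time_months"].to_numpy(dtype=float)
        if days:
            time = time / 30.44
        return cls(cohort_id, time, df["event"].to_numpy(), df["score"].to_numpy(dtype=float))

    @property
    def n(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class ScreenCriteria:
    alpha_default: float = 0.05
    strict_p: float = 0.001
    hr_low: float = 0.5
    hr_high: float = 2.0
    min_cases: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.strict_p < self.alpha_default:
            raise ConfigurationError("require 0 < strict_p < alpha_default")
        if not self.hr_low < 1 < self.hr_high:
            raise ConfigurationError("require hr_low < 1 < hr_high")


@dataclass
class SurvivalResult:
    unit: str
    cohort_id: str
    n_cases: int
    hr: float
    ci_low: float
    ci_high: float
    logrank_p: float
    wald_p: float
    q_value: float = np.nan
    passes_default: bool = False
    passes_strict: bool = False
    degenerate: bool = False


def median_split(scores: np.ndarray) -> np.ndarray:
    """High/low labels at the median; ties go to the low group.

    Returns a boolean array, True for the high group (score > median).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise ConfigurationError("median split needs >= 4 samples")
    median = np.median(scores)
    high = scores > median
    if not high.any() or high.all():
        raise ConfigurationError("degenerate median split (constant scores?)")
    return high


def km_estimate(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a frame with columns (time, n_at_risk, n_events, survival);
    S(0) = 1, the curve is right-continuous and steps only at event
    times.  Censored times reduce the risk set without a step.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ConfigurationError("empty group")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq = np.unique(time[event == 1])
    n = time.size
    rows = []
    surv = 1.0
    for t in uniq:
        at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        surv *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def _event_table(time: np.ndarray, event: np.ndarray, group: np.ndarray):
    """Per-event-time (d, d1, n, n1) arrays for two-group statistics."""
    order = np.argsort(time, kind="stable")
    time, event, group = time[order], event[order], group[order].astype(int)
    event_times = np.unique(time[event == 1])
    # at-risk counts via reverse cumulative sums over unique times
    d = np.zeros(event_times.size)
    d1 = np.zeros(event_times.size)
    n = np.zeros(event_times.size)
    n1 = np.zeros(event_times.size)
    for i, t in enumerate(event_times):
        at = time >= t
        n[i] = at.sum()
        n1[i] = group[at].sum()
        here = (time == t) & (event == 1)
        d[i] = here.sum()
        d1[i] = group[here].sum()
    return d, d1, n, n1


def logrank_test(
    time: np.ndarray, event: np.ndarray, high: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    Uses the hypergeometric variance at each distinct event time; the
    two-sided p comes from chi-square with 1 df.
    """
    from scipy import stats

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    high = np.asarray(high, dtype=bool)
    if event[high].sum() < 1 or event[~high].sum() < 1:
        raise ConfigurationError("both groups need at least one event")
    d, d1, n, n1 = _event_table(time, event, high)
    expected = d * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    var = np.where(n > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0
    chi2 = float((d1.sum() - expected.sum()) ** 2 / v)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def cox_hr_binary(
    time: np.ndarray,
    event: np.ndarray,
    high: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[float, tuple[float, float], float, bool]:
    """Binary-covariate Cox proportional-hazards fit.

    Newton iteration on the Breslow partial likelihood; converged when
    |score| < tol.  Returns (hr, (ci_low, ci_high), wald_p, degenerate).
    Monotone likelihood (all events in one group) yields a flagged
    degenerate result with an infinite-HR marker instead of a crash.
    """
    from scipy import stats

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    high = np.asarray(high, dtype=bool)
    if event.sum() < 2 or event[high].sum() < 1 or event[~high].sum() < 1:
        hr = np.inf if event[high].sum() > event[~high].sum() else 0.0
        return hr, (np.nan, np.nan), np.nan, True

    d, d1, n, n1 = _event_table(time, event, high)
    n0 = n - n1
    beta = 0.0
    for _ in range(max_iter):
        e = np.exp(beta)
        denom = n0 + n1 * e
        frac = n1 * e / denom
        score = d1.sum() - float(np.sum(d * frac))
        info = float(np.sum(d * (n0 * n1 * e) / denom**2))
        if info <= 0:
            return np.exp(beta), (np.nan, np.nan), np.nan, True
        step = score / info
        beta += step
        if abs(score) < tol:
            break
        if abs(beta) > 50:  # monotone likelihood escaping to infinity
            return (np.inf if beta > 0 else 0.0), (np.nan, np.nan), np.nan, True
    se = 1.0 / np.sqrt(info)
    z = beta / se
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.959963984540054 * se)), float(np.exp(beta + 1.959963984540054 * se)))
    wald_p = float(2.0 * stats.norm.sf(abs(z)))
    return hr, ci, wald_p, False


def signature_score(
    expression: pd.DataFrame, gene_set: list[str]
) -> tuple[pd.Series, list[str]]:
    """Per-sample mean log2(TPM+1) over the signature genes present.

    Returns (scores, missing_genes); raises if no signature gene is in
    the matrix.
    """
    present = [g for g in gene_set if g in expression.index]
    missing = [g for g in gene_set if g not in expression.index]
    if not present:
        raise ConfigurationError("no signature gene present in the expression matrix")
    return expression.loc[present].mean(axis=0), missing


def screen_prognostic(
    units: dict[str, np.ndarray],
    cohort: SurvivalCohort,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> list[SurvivalResult]:
    """Screen scoring units (genes or signatures) in one cohort.

    Each unit supplies a per-sample score; the cohort supplies time and
    event.  q-values are BH over the units of this cohort; the default
    gate uses q <= alpha_default, the strict gate uses the raw log-rank
    p together with the HR and case-count conditions.
    """
    results: list[SurvivalResult] = []
    for unit, scores in units.items():
        scores = np.asarray(scores, dtype=float)
        if scores.shape != cohort.time.shape:
            raise ConfigurationError(f"score length mismatch for unit {unit!r}")
        try:
            high = median_split(scores)
            _, p = logrank_test(cohort.time, cohort.event, high)
            hr, ci, wald_p, degen = cox_hr_binary(cohort.time, cohort.event, high)
        except ConfigurationError:
            results.append(
                SurvivalResult(unit, cohort.cohort_id, cohort.n, np.nan, np.nan, np.nan,
                               np.nan, np.nan, degenerate=True)
            )
            continue
        results.append(
            SurvivalResult(unit, cohort.cohort_id, cohort.n, hr, ci[0], ci[1], p, wald_p,
                           degenerate=degen)
        )
    ps = [r.logrank_p for r in results]
    finite = [p if np.isfinite(p) else 1.0 for p in ps]
    qs = bh_adjust(finite)
    for r, q in zip(results, qs):
        r.q_value = q
        if r.degenerate or not np.isfinite(r.hr):
            continue
        r.passes_default = q <= criteria.alpha_default
        r.passes_strict = (
            r.logrank_p < criteria.strict_p
            and (r.hr <= criteria.hr_low or r.hr >= criteria.hr_high)
            and r.n_cases >= criteria.min_cases
        )
    return results
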