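"""Kaplan–Meier, log-rank, binary Cox and the strict prognostic screen."""

import numpy as np
import pandas as pd
import pytest

from sterolnet.consensus import ConfigurationError
from sterolnet.enrichment import bh_adjust
from sterolnet.survival import (
    ScreenCriteria,
    SurvivalCohort,
    cox_hr_binary,
    km_estimate,
    logrank_test,
    median_split,
    screen_prognostic,
    signature_score,
)
from sterolnet.synthetic import SurvivalSpec, gen_survival_cohort


class TestMedianSplit:
    def test_even_split(self):
        high = median_split(np.array([1.0, 2.0, 3.0, 4.0]))
        assert high.tolist() == [False, False, True, True]

    def test_ties_to_low(self):
        high = median_split(np.array([1.0, 2.0, 2.0, 3.0]))
        assert high.tolist() == [False, False, False, True]

    def test_large_distinct_counts(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(np.arange(1000.0))
        assert median_split(scores).sum() in (499, 500)

    def test_constant_scores_rejected(self):
        with pytest.raises(ConfigurationError):
            median_split(np.ones(10))


class TestKaplanMeier:
    def test_closed_form_all_events(self):
        curve = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        assert curve["survival"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert curve["n_at_risk"].tolist() == [3, 2, 1]

    def test_all_censored_flat_curve(self):
        curve = km_estimate(np.array([1.0, 2.0]), np.array([0, 0]))
        assert curve.empty  # no steps; S stays 1

    def test_monotone_in_unit_interval(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 200)
        e = rng.integers(0, 2, 200)
        s = km_estimate(t, e)["survival"].to_numpy()
        assert ((0 <= s) & (s <= 1)).all()
        assert (np.diff(s) <= 1e-12).all()

    def test_close_to_true_exponential_curve(self):
        rng = np.random.default_rng(2)
        lam = 0.05
        t = rng.exponential(1 / lam, 200)
        curve = km_estimate(t, np.ones(200, dtype=int))
        sup = np.max(np.abs(curve["survival"] - np.exp(-lam * curve["time"])))
        assert sup <= 0.08


class TestLogRank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.ones(8, dtype=int)
        high = np.array([False] * 4 + [True] * 4)
        chi2, p = logrank_test(t, e, high)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        cohort, high = gen_survival_cohort(SurvivalSpec(n_samples=200, planted_hr=0.5), rng)
        chi2_a, _ = logrank_test(cohort.time, cohort.event, high)
        chi2_b, _ = logrank_test(cohort.time * 365.25, cohort.event, high)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-10)

    def test_power_at_strong_effect(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            cohort, high = gen_survival_cohort(
                SurvivalSpec(n_samples=400, planted_hr=0.4, censoring_rate=0.2), rng
            )
            _, p = logrank_test(cohort.time, cohort.event, high)
            hits += p < 0.001
        assert hits >= 19

    def test_requires_events_in_both_groups(self):
        with pytest.raises(ConfigurationError):
            logrank_test(np.array([1.0, 2.0]), np.array([1, 0]), np.array([False, True]))


class TestCox:
    def test_matches_lifelines_on_planted_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        cohort, high = gen_survival_cohort(
            SurvivalSpec(n_samples=500, planted_hr=0.4, censoring_rate=0.3), rng
        )
        hr, ci, wald_p, degen = cox_hr_binary(cohort.time, cohort.event, high)
        df = pd.DataFrame({"t": cohort.time, "e": cohort.event, "x": high.astype(int)})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert not degen
        assert hr == pytest.approx(float(np.exp(cph.params_.iloc[0])), rel=1e-6)
        lo, hi = cph.confidence_intervals_.iloc[0]
        assert ci[0] == pytest.approx(float(np.exp(lo)), rel=1e-4)
        assert ci[1] == pytest.approx(float(np.exp(hi)), rel=1e-4)

    def test_null_estimate_near_one(self):
        rng = np.random.default_rng(8)
        cohort, high = gen_survival_cohort(
            SurvivalSpec(n_samples=500, planted_hr=1.0, censoring_rate=0.0), rng
        )
        hr, _, _, _ = cox_hr_binary(cohort.time, cohort.event, high)
        assert abs(np.log(hr)) < 0.25

    def test_log_hr_bias_shrinks_with_n(self):
        biases = []
        for n in (100, 400, 1600):
            logs = []
            for s in range(8):
                rng = np.random.default_rng(1000 * n + s)
                cohort, high = gen_survival_cohort(
                    SurvivalSpec(n_samples=n, planted_hr=0.4, censoring_rate=0.0), rng
                )
                hr, _, _, _ = cox_hr_binary(cohort.time, cohort.event, high)
                logs.append(np.log(hr))
            biases.append(abs(np.mean(logs) - np.log(0.4)))
        assert biases[2] < 0.1 and biases[2] <= biases[0] + 0.05

    def test_one_event_degenerate_flag(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 0, 0])
        high = np.array([True, True, False, False])
        hr, ci, p, degen = cox_hr_binary(t, e, high)
        assert degen and not np.isfinite(ci[0])

    def test_wald_and_logrank_agree_in_magnitude(self):
        rng = np.random.default_rng(9)
        cohort, high = gen_survival_cohort(
            SurvivalSpec(n_samples=400, planted_hr=0.5, censoring_rate=0.2), rng
        )
        _, _, wald_p, _ = cox_hr_binary(cohort.time, cohort.event, high)
        _, lr_p = logrank_test(cohort.time, cohort.event, high)
        assert abs(np.log10(wald_p) - np.log10(lr_p)) < 2


class TestSignatureAndScreen:
    def test_signature_score_arithmetic(self):
        mat = pd.DataFrame([[2.0, 6.0], [4.0, 0.0]], index=["a", "b"], columns=["s1", "s2"])
        scores, missing = signature_score(mat, ["a", "b", "zzz"])
        assert scores.tolist() == [3.0, 3.0]
        assert missing == ["zzz"]
        single, _ = signature_score(mat, ["a"])
        assert single.tolist() == [2.0, 6.0]

    def test_no_gene_present_rejected(self):
        mat = pd.DataFrame([[1.0]], index=["a"], columns=["s"])
        with pytest.raises(ConfigurationError):
            signature_score(mat, ["x"])

    def test_strict_filter_gates(self):
        rng = np.random.default_rng(10)
        cohort, _ = gen_survival_cohort(
            SurvivalSpec(n_samples=500, planted_hr=0.4, censoring_rate=0.2), rng
        )
        results = screen_prognostic({"planted": cohort.score}, cohort)
        (res,) = results
        assert res.passes_strict and res.hr <= 0.5 and res.logrank_p < 0.001

    def test_strict_filter_hr_gate_blocks_weak_effect(self):
        # even vanishing p cannot pass with HR between 0.5 and 2
        rng = np.random.default_rng(11)
        cohort, _ = gen_survival_cohort(
            SurvivalSpec(n_samples=2000, planted_hr=0.75, censoring_rate=0.0), rng
        )
        (res,) = screen_prognostic({"u": cohort.score}, cohort)
        assert res.logrank_p < 1e-4 and not res.passes_strict

    def test_case_count_gate(self):
        rng = np.random.default_rng(12)
        cohort, _ = gen_survival_cohort(
            SurvivalSpec(n_samples=100, planted_hr=0.2, censoring_rate=0.0), rng
        )
        (res,) = screen_prognostic({"u": cohort.score}, cohort)
        assert not res.passes_strict  # n < 200 regardless of p and HR

    def test_criteria_validation(self):
        with pytest.raises(ConfigurationError):
            ScreenCriteria(hr_low=1.5)


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_worked_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_q_never_below_p_and_monotone(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        # q is weakly monotone in p (ties in q are allowed by step-up)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_adjust([0.5, 1.2])
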