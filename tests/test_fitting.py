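"""Quantile summaries, the G2 statistic, and the constrained fit."""

import numpy as np
import pytest
from scipy.stats import norm

from ddmix.fitting import (
    DATA_DF,
    FitConfig,
    FitResult,
    N_PARAMS_REPORTED,
    SparseSampleError,
    _evaluate,
    _ParamSpace,
    compute_quantiles,
    fit_subject,
    goodness_of_fit,
    gsquare,
    heuristic_start,
    summarize_trials,
)
from ddmix.params import canonical_design
from ddmix.synthetic import simulate_dataset


class TestComputeQuantiles:
    def test_median_by_linear_interpolation(self):
        assert compute_quantiles(np.arange(1, 11), probs=(0.5,)) == pytest.approx(5.5)

    def test_constant_sample(self):
        q = compute_quantiles(np.full(20, 0.4))
        np.testing.assert_allclose(q, 0.4)

    def test_large_sample_matches_normal_inverse_cdf(self, rng):
        x = rng.standard_normal(100_000)
        q = compute_quantiles(x)
        assert abs(q[0] - norm.ppf(0.1)) < 0.02

    def test_nondecreasing(self, rng):
        q = compute_quantiles(rng.exponential(size=500))
        assert np.all(np.diff(q) >= 0)

    def test_sparse_sample_signals_fallback(self):
        with pytest.raises(SparseSampleError):
            compute_quantiles(np.arange(9))


class TestGsquare:
    def test_perfect_fit_is_zero(self):
        p = np.array([0.25, 0.25, 0.5])
        assert gsquare(p, p, 100) == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        expected = 200 * (0.5 * np.log(0.5 / 0.6) + 0.5 * np.log(0.5 / 0.4))
        assert gsquare([0.5, 0.5], [0.6, 0.4], 100) == pytest.approx(expected)

    def test_linear_in_trial_count(self):
        p, pi = [0.3, 0.7], [0.4, 0.6]
        assert gsquare(p, pi, 200) == pytest.approx(2 * gsquare(p, pi, 100))

    def test_empty_observed_bins_contribute_nothing(self):
        assert gsquare([0.0, 1.0], [0.3, 0.7], 50) == pytest.approx(
            2 * 50 * np.log(1 / 0.7)
        )

    def test_nonnegative(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            pi = rng.dirichlet(np.ones(6))
            assert gsquare(p, pi, 100) >= 0

    def test_underflow_clipping_warns(self):
        with pytest.warns(RuntimeWarning):
            gsquare([0.5, 0.5], [1.0 - 1e-12, 1e-12], 100)

    def test_mismatched_sums_rejected(self):
        with pytest.raises(ValueError):
            gsquare([0.5, 0.4], [0.5, 0.5], 100)


class TestGoodnessOfFit:
    @staticmethod
    def _result(g2):
        return FitResult(
            design=canonical_design(), gsquare=g2, df=450, df_free=450,
            data_df=475, n_free=25, n_params_reported=25,
            per_cell_gsquare=np.zeros(25), predicted_pi=np.zeros((25, 2, 10)),
            summary=None, po_zeroed=[], tied_fast_conditions=False,
            converged=True,
        )

    def test_critical_value_at_450_df(self):
        gof = goodness_of_fit(self._result(400.0))
        assert gof.critical_value == pytest.approx(500.5, abs=0.05)

    def test_mean_reported_fit_grades_good(self):
        # between one and two times the critical value
        assert goodness_of_fit(self._result(654.4)).grade == "good"

    def test_zero_statistic_grades_good(self):
        assert goodness_of_fit(self._result(0.0)).grade == "good"

    def test_large_statistic_grades_poor(self):
        assert goodness_of_fit(self._result(1200.0)).grade == "poor"


class TestParamSpace:
    def test_roundtrip_identity(self, canonical):
        space = _ParamSpace(False, np.zeros(5, dtype=bool), 0.1)
        d2 = space.unpack(space.pack(canonical))
        np.testing.assert_allclose(d2.a, canonical.a, rtol=1e-6)
        np.testing.assert_allclose(d2.v, canonical.v, rtol=1e-6)
        np.testing.assert_allclose(d2.p_o, canonical.p_o, atol=2e-6)
        assert d2.mu_g == pytest.approx(canonical.mu_g, rel=1e-6)

    def test_free_parameter_counts(self):
        assert _ParamSpace(False, np.zeros(5, dtype=bool), 0.1).n_free == N_PARAMS_REPORTED
        assert _ParamSpace(True, np.zeros(5, dtype=bool), 0.1).n_free == 23
        fixed = np.array([False, False, True, True, True])
        assert _ParamSpace(True, fixed, 0.1).n_free == 20

    def test_any_vector_yields_valid_design(self, rng):
        space = _ParamSpace(True, np.zeros(5, dtype=bool), 0.1)
        for _ in range(20):
            d = space.unpack(rng.normal(0, 3, size=space.n_free))
            assert d.s_z < min(d.a)
            assert d.t_er[0] - d.s_t / 2 > 0


class TestSummaries:
    def test_observed_proportions_sum_to_one(self, small_dataset):
        sub = small_dataset[small_dataset["subject"] == 1]
        summary = summarize_trials(sub)
        np.testing.assert_allclose(summary.pobs.sum(axis=(1, 2)), 1.0, atol=1e-12)
        assert summary.data_df <= DATA_DF

    def test_missing_cell_rejected(self, small_dataset):
        broken = small_dataset[
            ~((small_dataset["speed_cond"] == 2) & (small_dataset["contrast_cond"] == 3))
        ]
        with pytest.raises(ValueError, match="speed=2, contrast=3"):
            summarize_trials(broken)

    def test_heuristic_start_is_valid_and_ordered(self, small_dataset, canonical):
        start = heuristic_start(small_dataset, FitConfig())
        assert start.p_o[0] > start.p_o[4]
        assert all(x > 0 for x in start.a)


class TestFitting:
    def test_short_fit_improves_on_start_and_respects_structure(self, small_dataset):
        cfg = FitConfig(restarts=0, maxfev_primary=400, tie_fast_conditions=True)
        start = heuristic_start(small_dataset, cfg)
        summary = summarize_trials(small_dataset)
        g_start, _, _ = _evaluate(start, summary, cfg)
        res = fit_subject(small_dataset, cfg)
        assert res.gsquare <= g_start
        assert res.design.a[0] == res.design.a[1]  # tied fast conditions
        assert res.design.t_er[0] == res.design.t_er[1]
        assert all(0 <= p <= 1 for p in res.design.p_o)
        assert res.df == 450 and res.n_params_reported == 25

    def test_low_guess_rates_zeroed_and_drift_order_recovered(self, canonical):
        """Generating p_o = 0.05 everywhere: the zeroing rule must drive
        every fitted p_o to exactly 0, and the contrast-ordered drift
        rates must come back in their generating order."""
        design = canonical.replace(p_o=(0.05,) * 5)
        df = simulate_dataset(design, n_subjects=1, n_trials_per_cell=200,
                              seed=4, between_subject_sd=0.0)
        cfg = FitConfig(restarts=0, maxfev_primary=4000, maxfev_restart=2000)
        res = fit_subject(df, cfg)
        assert res.design.p_o == (0.0,) * 5
        assert sorted(res.po_zeroed) == [1, 2, 3, 4, 5]
        assert np.all(np.diff(res.design.v) > 0)
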