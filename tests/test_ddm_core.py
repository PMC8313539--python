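"""Wiener first-passage probabilities, densities and defective CDFs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from ddmix import ddm_core
from ddmix.params import ParameterError, TrialVariability, WienerParams


def wiener(a=0.08, z=None, v=0.3, s=0.1):
    return WienerParams(a=a, z=a / 2 if z is None else z, v=v, s=s)


class TestResponseProb:
    def test_zero_drift_symmetric_start_is_half(self):
        assert ddm_core.response_prob(wiener(v=0.0)) == pytest.approx(0.5)

    def test_upper_and_lower_sum_to_one(self):
        p = wiener(v=0.546)
        total = ddm_core.response_prob(p, "upper") + ddm_core.response_prob(p, "lower")
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_start_adjacent_to_upper_with_strong_drift(self):
        p = WienerParams(a=0.08, z=0.079, v=5.0, s=0.1)
        assert ddm_core.response_prob(p, "upper") > 0.99

    def test_matches_euler_simulation(self):
        p = wiener(v=0.546)
        analytic = ddm_core.response_prob(p, "upper")
        rts, up = ddm_core.sample_first_passage(200_000, p, dt=1e-4, seed=42)
        se = np.sqrt(analytic * (1 - analytic) / up.size)
        assert abs(up.mean() - analytic) < 3 * se

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            WienerParams(a=-0.1, z=0.05, v=0.0)
        with pytest.raises(ParameterError):
            WienerParams(a=0.1, z=0.15, v=0.0)
        with pytest.raises(ParameterError):
            WienerParams(a=0.1, z=0.05, v=0.0, s=0.0)


class TestFptDensity:
    def test_zero_at_and_before_start(self):
        p = wiener()
        assert ddm_core.fpt_density(0.0, p) == 0.0
        assert ddm_core.fpt_density(-1.0, p) == 0.0
        # no instantaneous absorption from an interior start
        assert ddm_core.fpt_density(1e-6, p) == pytest.approx(0.0, abs=1e-12)

    def test_conservation(self):
        p = WienerParams(a=0.063, z=0.0315, v=0.108, s=0.1)
        total = sum(
            quad(lambda t: ddm_core.fpt_density(t, p, b), 0, 10, limit=200)[0]
            for b in ("upper", "lower")
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_density_integral_equals_series_cdf(self):
        p = wiener(a=0.072, v=0.283)
        for t in (0.05, 0.2, 0.8):
            integral = quad(lambda u: ddm_core.fpt_density(u, p, "lower"), 0, t)[0]
            assert integral == pytest.approx(
                ddm_core.decision_cdf(t, p, "lower"), abs=1e-8
            )

    def test_matches_simulated_decision_times(self):
        """Euler-simulated first-passage times agree with the analytic
        density (KS distance on the pooled-decision-time CDF)."""
        p = WienerParams(a=0.083, z=0.0415, v=0.283, s=0.1)
        rts, _ = ddm_core.sample_first_passage(400_000, p, dt=1e-4, seed=9)
        grid = np.linspace(1e-3, 3.0, 500)
        analytic = ddm_core.decision_cdf(grid, p, "upper") + ddm_core.decision_cdf(
            grid, p, "lower"
        )
        empirical = np.searchsorted(np.sort(rts), grid, side="right") / rts.size
        assert np.max(np.abs(empirical - analytic)) < 0.005


class TestDefectiveCdf:
    def test_degenerate_variability_is_shifted_cdf(self):
        p = wiener(a=0.063, v=0.108)
        var = TrialVariability(t_er=0.3)
        for t in (0.31, 0.5, 1.2):
            assert ddm_core.defective_cdf(t, p, var, "upper") == pytest.approx(
                ddm_core.decision_cdf(t - 0.3, p, "upper"), abs=1e-12
            )

    def test_zero_before_minimum_nondecision_time(self, slow_cell):
        p, var = slow_cell
        t = var.t_er - var.s_t / 2 - 1e-6
        assert ddm_core.defective_cdf(t, p, var, "upper") == 0.0
        assert ddm_core.defective_cdf(0.0, p, var, "lower") == 0.0

    def test_limits_sum_to_response_probabilities(self, slow_cell):
        p, var = slow_cell
        up = ddm_core.defective_cdf(60.0, p, var, "upper")
        lo = ddm_core.defective_cdf(60.0, p, var, "lower")
        assert up + lo == pytest.approx(1.0, abs=1e-4)
        assert up == pytest.approx(
            ddm_core.response_prob_with_variability(p, var, "upper"), abs=1e-6
        )

    def test_agrees_with_quadrature_reference(self, slow_cell):
        """Closed-form s_z / s_t integration vs the all-quadrature scheme."""
        p, var = slow_cell
        ts = np.array([0.36, 0.45, 0.5, 0.6, 0.9, 1.5, 3.0])
        fast = ddm_core.defective_cdf(ts, p, var, "upper", tol=1e-10)
        ref = ddm_core.defective_cdf_quadrature(
            ts, p, var, "upper", gl_order=40, tol=1e-10
        )
        assert np.max(np.abs(fast - ref)) < 1e-6

    def test_invalid_start_point_range_rejected(self):
        p = wiener(a=0.08)
        var = TrialVariability(s_z=0.09, t_er=0.3)
        with pytest.raises(ParameterError):
            ddm_core.defective_cdf(0.5, p, var, "upper")


# -- property-based invariants ----------------------------------------------

valid_params = st.builds(
    lambda a, zf, v: WienerParams(a=a, z=zf * a, v=v, s=0.1),
    a=st.floats(0.04, 0.2),
    zf=st.floats(0.2, 0.8),
    v=st.floats(-0.8, 0.8),
)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(valid_params, st.floats(0.0, 0.3), st.floats(0.0, 0.8))
def test_conservation_property(p, eta, szf):
    """Upper and lower defective CDFs sum to 1 in the long-time limit."""
    s_z = szf * 2 * min(p.z, p.a - p.z) * 0.9
    var = TrialVariability(eta=eta, s_z=s_z, t_er=0.3, s_t=0.1)
    up = ddm_core.defective_cdf(80.0, p, var, "upper")
    lo = ddm_core.defective_cdf(80.0, p, var, "lower")
    assert up + lo == pytest.approx(1.0, abs=1e-4)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(valid_params)
def test_monotonicity_property(p):
    """Defective CDFs are nondecreasing in t."""
    var = TrialVariability(eta=0.15, s_z=0.3 * min(p.z, p.a - p.z), t_er=0.35, s_t=0.12)
    ts = np.linspace(0.05, 4.0, 60)
    for b in ("upper", "lower"):
        f = ddm_core.defective_cdf(ts, p, var, b)
        assert np.all(np.diff(f) >= -1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(valid_params)
def test_reflection_symmetry_property(p):
    """P(upper | a, z, v) equals P(lower | a, a-z, -v)."""
    mirrored = WienerParams(a=p.a, z=p.a - p.z, v=-p.v, s=p.s)
    assert ddm_core.response_prob(p, "upper") == pytest.approx(
        ddm_core.response_prob(mirrored, "lower"), abs=1e-12
    )


def test_response_prob_increasing_in_drift():
    probs = [ddm_core.response_prob(wiener(v=v)) for v in np.linspace(-0.6, 0.6, 13)]
    assert np.all(np.diff(probs) > 0)
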