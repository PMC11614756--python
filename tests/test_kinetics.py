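"""Trace normalisation and polynomial initial-rate estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qdtherm import (FluorescenceTrace, RelativeTrace, RunConfig,
                     fit_polynomial, initial_rate_of, normalize_trace)
from qdtherm.kinetics import TraceError

from conftest import ols_vandermonde_oracle


def make_trace(intensities, interval=5.0, condition="ATP", well="W1"):
    n = len(intensities)
    return FluorescenceTrace(
        well_id=well,
        times=np.arange(n) * interval,
        intensities=np.asarray(intensities, dtype=float),
        condition=condition,
        preparation_id="prep1",
    )


class TestNormalize:
    @pytest.mark.parametrize("raw, expected", [
        ((500.0, 500.0, 500.0, 500.0), (1, 1, 1, 1)),
        ((200.0, 100.0, 50.0, 25.0), (1, 0.5, 0.25, 0.125)),
    ])
    def test_exact_ratios(self, raw, expected):
        rel = normalize_trace(make_trace(raw))
        np.testing.assert_allclose(rel.relative_intensity, expected, rtol=0)

    def test_scale_invariance_exact(self):
        raw = np.array([812.0, 640.0, 555.0, 500.0, 470.0])
        a = normalize_trace(make_trace(raw))
        b = normalize_trace(make_trace(3.7 * raw))
        np.testing.assert_allclose(
            a.relative_intensity, b.relative_intensity, rtol=1e-14)
        assert b.relative_intensity[0] == 1.0

    def test_rejects_nonpositive_start(self):
        with pytest.raises(TraceError):
            FluorescenceTrace("w", np.arange(4) * 5.0,
                              np.array([0.0, 1, 1, 1]), "ATP", "p")


class TestFitPolynomial:
    def test_exact_quadratic_interpolated(self):
        # y = 1 - 0.002 t + 1e-6 t^2 has no residual at degree 2
        t = np.arange(0, 121, 5.0)
        y = 1.0 - 0.002 * t + 1e-6 * t**2
        est = fit_polynomial(RelativeTrace(t, y), degree=2)
        np.testing.assert_allclose(est.coefficients, [1.0, -0.002, 1e-6],
                                   rtol=1e-9, atol=1e-12)
        assert est.initial_decay_rate == pytest.approx(0.002, rel=1e-9)
        assert est.r_squared == pytest.approx(1.0)

    def test_flat_trace_zero_rate_and_r2_convention(self):
        t = np.arange(0, 121, 5.0)
        est = fit_polynomial(RelativeTrace(t, np.ones_like(t)), degree=2)
        assert est.initial_decay_rate == pytest.approx(0.0, abs=1e-12)
        assert est.r_squared == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        t = np.arange(25) * 5.0
        y = 1.0 - 0.001 * t + rng.normal(0, 0.01, len(t))
        y[0] = 1.0
        est = fit_polynomial(RelativeTrace(t, np.maximum(y, 1e-3)), degree=2)
        expected = ols_vandermonde_oracle(t, np.maximum(y, 1e-3), 2)
        np.testing.assert_allclose(est.coefficients, expected, rtol=1e-8)

    @pytest.mark.parametrize("degree", [1, 2, 3, 4])
    def test_oracle_equivalence_across_degrees(self, degree):
        rng = np.random.default_rng(degree)
        for n in (degree + 2, 12, 30):
            t = np.sort(rng.uniform(0, 120, n))
            t[0] = 0.0
            y = rng.uniform(0.5, 1.5, n)
            y /= y[0]
            est = fit_polynomial(RelativeTrace(t, y), degree)
            expected = ols_vandermonde_oracle(t, y, degree)
            np.testing.assert_allclose(est.coefficients, expected, rtol=1e-8,
                                       atol=1e-14)

    def test_degree_must_be_below_n(self):
        t = np.arange(3) * 5.0
        with pytest.raises(TraceError):
            fit_polynomial(RelativeTrace(t, np.ones(3)), degree=3)


class TestInitialRate:
    def test_scale_invariant_through_raw_counts(self, run_config):
        t = np.arange(0, 121, 5.0)
        y = 1.0 - 0.002 * t + 1e-5 * t**2
        a = initial_rate_of(make_trace(y), run_config)
        b = initial_rate_of(make_trace(800.0 * y), run_config)
        assert a.initial_decay_rate == pytest.approx(
            b.initial_decay_rate, rel=1e-12)

    @pytest.mark.parametrize("rho", [0.0005, 0.001, 0.002, 0.003])
    def test_recovers_hyperbolic_rate_in_low_curvature_regime(
            self, rho, run_config):
        # exact hyperbola, no noise: degree-2 bias stays under 5 %
        t = np.arange(0, 121, 5.0)
        y = 1.0 / (1.0 + rho * t)
        est = initial_rate_of(make_trace(y), run_config)
        assert est.initial_decay_rate == pytest.approx(rho, rel=0.05)

    def test_null_reaction_rate_near_zero(self, run_config):
        rng = np.random.default_rng(5)
        t = np.arange(0, 121, 5.0)
        noise_sd = 0.005
        y = np.ones_like(t) + rng.normal(0, noise_sd, len(t))
        y[0] = 1.0
        est = initial_rate_of(make_trace(y * 1000), run_config)
        # OLS slope noise at this noise level stays well under 1e-3 /s
        assert abs(est.initial_decay_rate) < 5e-4

    def test_window_truncates_fit(self):
        cfg = RunConfig(window_end_s=60.0)
        t = np.arange(0, 121, 5.0)
        y = 1.0 - 0.001 * t
        est = initial_rate_of(make_trace(y), cfg)
        assert est.window[1] <= 60.0


@settings(deadline=None, derandomize=True)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e6),
    rho=st.floats(min_value=-0.002, max_value=0.003),
)
def test_property_rate_scale_invariance_and_sign(scale, rho):
    """Rescaling raw counts never moves the rate; trace direction sets sign."""
    t = np.arange(0, 121, 5.0)
    y = 1.0 / (1.0 + rho * t)
    cfg = RunConfig()
    base = initial_rate_of(make_trace(y), cfg).initial_decay_rate
    scaled = initial_rate_of(make_trace(scale * y), cfg).initial_decay_rate
    assert scaled == pytest.approx(base, rel=1e-9, abs=1e-15)
    if rho > 1e-6:       # strictly decreasing trace
        assert base > 0
    elif rho < -1e-6:    # strictly increasing trace
        assert base < 0
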