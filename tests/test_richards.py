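"""Richards curve: closed forms, numeric oracles, and parameter recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq, minimize_scalar

from wheatnr import (
    FitConfig,
    GrainFillSeries,
    RichardsModel,
    RichardsParams,
    filling_traits,
    fit_richards,
    richards_rate,
    richards_weight,
)
from wheatnr.richards import TraitOrderingError, _inflection_u


def numeric_third_derivative_zeros(p: RichardsParams) -> tuple[float, float]:
    """Independent oracle: zeros of d3W/dt3 located by bisection on the
    central second difference of the filling rate."""
    h = 1e-3 / p.k  # step scaled to the curve's time constant

    def f3(t):
        # fourth-order central second difference of the rate
        return (-richards_rate(p, t + 2 * h) + 16 * richards_rate(p, t + h)
                - 30 * richards_rate(p, t) + 16 * richards_rate(p, t - h)
                - richards_rate(p, t - 2 * h)) / (12 * h**2)

    t_star = math.log(p.B / p.N) / p.k  # rate maximum, where f3 < 0
    span = 10.0 / p.k
    lo = brentq(f3, t_star - span, t_star, xtol=1e-10)
    hi = brentq(f3, t_star, t_star + span, xtol=1e-10)
    return lo, hi


def numeric_rate_maximum(p: RichardsParams) -> float:
    t_star = math.log(p.B / p.N) / p.k
    res = minimize_scalar(lambda t: -richards_rate(p, t),
                          bounds=(t_star - 5 / p.k, t_star + 5 / p.k),
                          method="bounded", options={"xatol": 1e-12})
    return -res.fun


class TestWeightAndRate:
    P = RichardsParams(A=40, B=20, k=0.2, N=1)

    def test_asymptote(self):
        assert richards_weight(self.P, 1e4) == pytest.approx(40.0, rel=1e-12)

    def test_halfway_point_logistic(self):
        # B e^{-kt} = 1  =>  W = A / 2 for the logistic case
        t = math.log(20) / 0.2
        assert richards_weight(self.P, t) == pytest.approx(20.0, rel=1e-12)

    def test_direct_formula_evaluation(self):
        # independent arithmetic evaluation of the formula
        p = RichardsParams(A=45, B=15, k=0.25, N=0.8)
        t = 18.0
        expected = 45.0 * (1.0 + 15.0 * math.exp(-0.25 * 18.0)) ** (-1.0 / 0.8)
        assert richards_weight(p, t) == pytest.approx(expected, rel=1e-12)

    def test_rate_vanishes_at_asymptote(self):
        assert richards_rate(self.P, 1e4) == pytest.approx(0.0, abs=1e-12)

    def test_rate_matches_finite_difference(self):
        h = 1e-5
        for t in (2.0, 8.39, 15.0, 30.0):
            fd = (richards_weight(self.P, t + h) - richards_weight(self.P, t - h)) / (2 * h)
            assert richards_rate(self.P, t) == pytest.approx(fd, rel=1e-6)

    def test_overflow_safe_at_extreme_times(self):
        p = RichardsParams(A=40, B=20, k=50.0, N=0.5)
        assert richards_weight(p, 1e6) == pytest.approx(40.0)
        w = richards_weight(p, -1e6)
        assert np.isfinite(w) and w >= 0.0
        assert np.isfinite(richards_rate(p, -1e6))

    def test_invalid_params_rejected(self):
        for bad in [(0, 20, 0.2, 1), (40, -1, 0.2, 1), (40, 20, 0, 1), (40, 20, 0.2, np.nan)]:
            with pytest.raises(ValueError):
                RichardsParams(*bad)

    @given(t1=st.floats(-50, 80), t2=st.floats(-50, 80))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_time(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert richards_weight(self.P, lo) <= richards_weight(self.P, hi) + 1e-12


class TestFillingTraits:
    def test_gfr_max_logistic_closed_form(self):
        # at N = 1 the maximum rate reduces to k A / 4
        tr = filling_traits(RichardsParams(40, 20, 0.2, 1))
        assert tr.gfr_max == pytest.approx(0.2 * 40 / 4, rel=1e-12)

    def test_gfr_mean_closed_form(self):
        tr = filling_traits(RichardsParams(40, 20, 0.2, 1))
        assert tr.gfr_mean == pytest.approx(40 * 0.2 / (2 * 3), rel=1e-12)

    def test_t3_is_99_percent_of_asymptote(self, param_draws):
        for p in param_draws:
            tr = filling_traits(p)
            assert richards_weight(p, tr.t3) / p.A == pytest.approx(0.99, abs=1e-10)

    def test_phase_ordering(self, param_draws):
        for p in param_draws:
            tr = filling_traits(p)
            assert tr.t1 < tr.t2 < tr.t3
            assert tr.t_slow == tr.t1
            assert tr.t_fast == pytest.approx(tr.t2 - tr.t1)
            assert tr.t_slight == pytest.approx(tr.t3 - tr.t2)
            assert tr.gfr_mean < tr.gfr_max

    def test_t1_t2_match_numeric_third_derivative_zeros(self, param_draws):
        for p in param_draws[:60]:
            tr = filling_traits(p)
            z1, z2 = numeric_third_derivative_zeros(p)
            assert tr.t1 == pytest.approx(z1, abs=1e-6)
            assert tr.t2 == pytest.approx(z2, abs=1e-6)

    def test_gfr_max_matches_numeric_maximum(self, param_draws):
        for p in param_draws[:60]:
            tr = filling_traits(p)
            assert tr.gfr_max == pytest.approx(numeric_rate_maximum(p), rel=1e-8)

    def test_tfast_independent_of_b(self):
        k, n = 0.2, 0.7
        tfasts = [filling_traits(RichardsParams(40, b, k, n)).t_fast
                  for b in np.linspace(1, 50, 25)]
        assert np.ptp(tfasts) < 1e-10

    def test_scaling_in_a(self):
        lo = filling_traits(RichardsParams(20, 20, 0.2, 1))
        hi = filling_traits(RichardsParams(40, 20, 0.2, 1))
        assert hi.gfr_max == pytest.approx(2 * lo.gfr_max, rel=1e-12)
        assert hi.gfr_mean == pytest.approx(2 * lo.gfr_mean, rel=1e-12)
        assert hi.t1 == pytest.approx(lo.t1)  # times unaffected by A

    def test_ordering_violation_raises_named_error(self):
        # very large N violates (100/99)^N - 1 < u2
        with pytest.raises(TraitOrderingError, match="T3 > T2"):
            filling_traits(RichardsParams(40, 20, 0.2, 500.0))

    def test_negative_t1_flagged_not_clamped(self):
        # B < u1 puts the slow-phase end before anthesis
        n = 1.0
        u1, _ = _inflection_u(n)
        tr = filling_traits(RichardsParams(40, u1 * 0.5, 0.2, n))
        assert tr.t1 < 0 and tr.t1_nonpositive


class TestFit:
    GRID = np.arange(0, 37, 6.0)

    def test_noiseless_recovery(self):
        true = RichardsParams(42, 18, 0.22, 0.9)
        w = richards_weight(true, self.GRID)
        params, diag = fit_richards(GrainFillSeries("p", self.GRID, w))
        assert diag.converged and diag.r_squared > 1 - 1e-10
        for name in ("A", "B", "k", "N"):
            assert getattr(params, name) == pytest.approx(getattr(true, name), rel=1e-4)

    def test_noisy_recovery_of_asymptote(self):
        true = RichardsParams(42, 18, 0.22, 0.9)
        w = richards_weight(true, self.GRID)
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            ws = np.maximum(w + rng.normal(0, 0.5, len(w)), 0.01)
            params, _ = fit_richards(GrainFillSeries("p", self.GRID, ws))
            hits += abs(params.A - true.A) / true.A < 0.05
        assert hits >= 38  # >= 95 %

    def test_logistic_data_recovers_shape_exponent_near_one(self):
        true = RichardsParams(40, 20, 0.25, 1.0)
        w = richards_weight(true, self.GRID)
        params, _ = fit_richards(GrainFillSeries("p", self.GRID, w))
        assert params.N == pytest.approx(1.0, abs=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            GrainFillSeries("p", [0, 6, 12, 18], [1, 5, 20, 30])

    def test_model_results_facade(self):
        true = RichardsParams(42, 18, 0.22, 0.9)
        res = RichardsModel(self.GRID, richards_weight(true, self.GRID)).fit(FitConfig())
        assert res.traits.t_fast > 0
        assert res.predict(36.0) == pytest.approx(richards_weight(true, 36.0), rel=1e-6)
        assert "Richards" in res.summary()
        assert np.all(np.isfinite(res.bse()))
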