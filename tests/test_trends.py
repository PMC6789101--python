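"""Mann-Kendall, Sen's slope and TFPW against oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ecoeff.errors import SeriesTooShortError
from ecoeff.synthetic import ar1_series
from ecoeff.trends import (
    kendall_tau,
    lag1_autocorr,
    mk_statistic,
    mk_statistic_bruteforce,
    mk_test,
    percentage_change,
    sens_slope,
    sens_slope_bruteforce,
    tfpw_mk_test,
    tfpw_transform,
)


def _random_series_battery(n_series=200, seed=0):
    """Random short series with ties (values drawn from a small integer set)."""
    rng = np.random.default_rng(seed)
    for _ in range(n_series):
        n = rng.integers(4, 13)
        if rng.random() < 0.5:
            yield rng.integers(0, 4, size=n).astype(float)  # heavy ties
        else:
            yield rng.normal(size=n)


class TestMKStatistic:
    def test_monotone_series_closed_form(self):
        # all 10 pairs concordant; varS = 5*4*15/18 = 50/3
        S, var_s = mk_statistic([1, 2, 3, 4, 5])
        assert S == 10
        assert var_s == pytest.approx(50.0 / 3.0, rel=1e-14)

    def test_antisymmetry(self):
        S, _ = mk_statistic([5, 4, 3, 2, 1])
        assert S == -10

    def test_matches_bruteforce_oracle(self):
        for x in _random_series_battery():
            S, v = mk_statistic(x)
            Sb, vb = mk_statistic_bruteforce(x)
            assert S == Sb
            assert v == pytest.approx(vb, rel=1e-13)

    def test_too_short_rejected(self):
        with pytest.raises(SeriesTooShortError, match="too short"):
            mk_statistic([1.0, 2.0, 3.0])


class TestMKTest:
    def test_constant_series_degenerate(self):
        res = mk_test([3, 3, 3, 3, 3])
        assert res.S == 0 and res.z == 0.0 and res.p == 1.0
        assert not res.significant

    def test_linear_series_closed_form(self):
        # Z = (10-1)/sqrt(50/3) = 2.2045..., p ~ 0.0275 < 0.05
        res = mk_test([1, 2, 3, 4, 5], alpha=0.05)
        assert res.z == pytest.approx(9.0 / np.sqrt(50.0 / 3.0), rel=1e-12)
        assert res.p == pytest.approx(0.0275, abs=5e-4)
        assert res.significant

    def test_tau_matches_scipy(self):
        for x in _random_series_battery(50, seed=3):
            tau_scipy = stats.kendalltau(np.arange(len(x)), x).statistic
            assert kendall_tau(x) == pytest.approx(tau_scipy, abs=1e-10)

    def test_type_one_error_iid(self):
        rng = np.random.default_rng(2024)
        rej = sum(mk_test(rng.standard_normal(110)).significant for _ in range(1000))
        assert 0.035 <= rej / 1000 <= 0.065

    @given(st.lists(st.floats(-1e6, 1e6).map(lambda v: round(v, 3)),
                    min_size=5, max_size=30),
           st.floats(0.1, 10.0), st.floats(-100.0, 100.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_shift_scale_equivariance(self, xs, a, b):
        # values rounded to 1e-3 so a*x+b cannot absorb tiny distinctions
        x = np.asarray(xs)
        r1 = mk_test(x)
        r2 = mk_test(a * x + b)
        assert r1.S == r2.S
        assert r1.p == pytest.approx(r2.p, rel=1e-9, abs=1e-12)
        assert r2.sen_slope == pytest.approx(a * r1.sen_slope, rel=1e-9, abs=1e-9)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_reversal_antisymmetry(self, xs):
        x = np.asarray(xs)
        r1, r2 = mk_test(x), mk_test(x[::-1])
        assert r1.S == -r2.S
        assert r1.tau == pytest.approx(-r2.tau, abs=1e-12)
        assert r1.sen_slope == pytest.approx(-r2.sen_slope, rel=1e-9, abs=1e-9)


class TestSensSlope:
    def test_exact_linear_recovery(self):
        t = np.arange(30)
        assert sens_slope(2.0 * t + 7.0) == pytest.approx(2.0, rel=1e-14)

    def test_constant(self):
        assert sens_slope([1.0, 1.0, 1.0]) == 0.0

    def test_enumerated_example(self):
        # pairwise slopes {2, 0.5, 1, -1, 0.5, 2} -> median 0.75
        assert sens_slope([1, 3, 2, 4]) == pytest.approx(0.75, rel=1e-14)

    def test_matches_bruteforce_oracle(self):
        for x in _random_series_battery(seed=7):
            assert sens_slope(x) == pytest.approx(
                sens_slope_bruteforce(x), rel=1e-13, abs=1e-13)

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            sens_slope([1.0, 2.0, 3.0], t=[0, 1, 1])

    def test_too_short(self):
        with pytest.raises(SeriesTooShortError):
            sens_slope([1.0])


class TestTFPW:
    def test_white_noise_below_gate_is_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.standard_normal(60)
            blended, r1, beta = tfpw_transform(x)
            if abs(r1) < 1.645 / np.sqrt(60):
                detrended = x - beta * np.arange(60)
                assert np.array_equal(blended, x)
                assert r1 == pytest.approx(lag1_autocorr(detrended))
                break
        else:
            pytest.fail("no white-noise draw fell below the r1 gate")

    def test_pure_linear_series_identity(self):
        x = 0.3 * np.arange(40)
        blended, r1, beta = tfpw_transform(x)
        assert r1 == 0.0  # degenerate residual treated as uncorrelated
        assert beta == pytest.approx(0.3, rel=1e-12)
        np.testing.assert_array_equal(blended, x)

    def test_recovers_known_rho_and_whitens(self):
        rng = np.random.default_rng(17)
        r1s, resid_r1s = [], []
        for _ in range(50):
            x = 0.05 * np.arange(110) + ar1_series(110, 0.6, 1.0, rng)
            blended, r1, beta = tfpw_transform(x)
            r1s.append(r1)
            resid = blended - beta * np.arange(1, 111)[: blended.size]
            resid_r1s.append(abs(lag1_autocorr(resid)))
        assert np.mean(r1s) == pytest.approx(0.6, abs=0.1)
        # whitened residuals fall below the gate bound on average
        assert np.mean(resid_r1s) < 1.645 / np.sqrt(110)

    def test_short_series_rejected(self):
        with pytest.raises(SeriesTooShortError, match="TFPW"):
            tfpw_transform(np.arange(9.0))

    def test_constant_series_not_significant(self):
        res = tfpw_mk_test(np.full(20, 3.0))
        assert res.p == 1.0 and not res.significant

    def test_sen_slope_reported_from_original_series(self):
        rng = np.random.default_rng(3)
        x = 0.2 * np.arange(110) + ar1_series(110, 0.5, 1.0, rng)
        res = tfpw_mk_test(x)
        assert res.sen_slope == pytest.approx(sens_slope(x), rel=1e-12)
        assert res.method == "tfpw-mk"


class TestMonteCarloInference:
    """The motivating comparison: plain MK inflates type-I under AR(1);
    TFPW restores it near nominal while keeping power for real trends."""

    def test_ar1_null_rates(self):
        rng = np.random.default_rng(606)
        reps = 400
        plain = tfpw = 0
        for _ in range(reps):
            x = ar1_series(110, 0.5, 1.0, rng)
            plain += mk_test(x).significant
            tfpw += tfpw_mk_test(x).significant
        assert plain / reps > 0.15
        assert 0.02 <= tfpw / reps <= 0.09

    def test_power_with_trend(self):
        rng = np.random.default_rng(707)
        reps = 200
        hits = sum(
            tfpw_mk_test(0.1 * np.arange(110) + ar1_series(110, 0.3, 1.0, rng)).significant
            for _ in range(reps)
        )
        assert hits / reps >= 0.95


class TestPercentageChange:
    def test_direct_arithmetic(self):
        assert percentage_change(0.5, 10, 25.0) == pytest.approx(20.0, rel=1e-14)

    def test_zero_slope(self):
        assert percentage_change(0.0, 110, 3.7) == 0.0

    def test_linear_in_slope_and_inverse_mean(self):
        base = percentage_change(0.5, 10, 25.0)
        assert percentage_change(1.5, 10, 25.0) == pytest.approx(3 * base)
        assert percentage_change(0.5, 10, 50.0) == pytest.approx(base / 2)

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError, match="undefined"):
            percentage_change(1.0, 10, 0.0)

    def test_recovers_injected_multiplicative_trend(self):
        # +10 % over 110 years, noiseless: recovered within 0.5 points of 10
        years = np.arange(110)
        x = 2.0 * (1.0 + 0.10 * years / 109.0)
        pct = percentage_change(sens_slope(x), x.size, x.mean())
        assert pct == pytest.approx(10.0, abs=0.5)
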