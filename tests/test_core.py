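"""Disposal-rate transform, Gompertz hazard, and log-linear fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import herdspan as hs
from herdspan.errors import (
    FitDomainError,
    InsufficientDataError,
    InvalidCohortError,
    SingularFitError,
    UndefinedRateError,
)


def ols_oracle(x, y):
    """Normal-equations OLS, independent of the fitting path under test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]  # slope, intercept


class TestDisposalSeries:
    def test_registration_cohort_first_lactation(self, tosno_disposal):
        # 1423 of 5825 first-lactation cows leave the herd
        assert tosno_disposal.y[0] == pytest.approx(0.244, abs=5e-4)
        assert tosno_disposal.dn[0] == pytest.approx(0.244, abs=5e-4)
        assert tosno_disposal.dN[0] == 1423

    @pytest.mark.parametrize(
        "counts, y, dn",
        [
            ([100, 50], [0.5], [0.5]),
            ([1000, 900, 810], [0.1, 0.1], [0.1, 0.09]),
        ],
    )
    def test_simple_cohorts(self, counts, y, dn):
        d = hs.compute_disposal_series(hs.CohortSeries.from_counts(counts))
        assert np.allclose(d.y, y)
        assert np.allclose(d.dn, dn)

    @given(
        n1=st.floats(min_value=10, max_value=1e6),
        rates=st.lists(st.floats(min_value=0, max_value=0.9), min_size=1, max_size=15),
    )
    @settings(deadline=None, max_examples=50)
    def test_cow_conservation(self, n1, rates):
        counts = [n1]
        for r in rates:
            counts.append(counts[-1] * (1 - r))
        d = hs.compute_disposal_series(hs.CohortSeries.from_counts(counts))
        assert d.dN.sum() + counts[-1] == pytest.approx(n1, rel=1e-12)

    def test_zero_count_before_last_is_undefined(self):
        cohort = hs.CohortSeries.from_counts([100, 0, 0])
        with pytest.raises(UndefinedRateError):
            hs.compute_disposal_series(cohort)

    def test_increasing_counts_rejected(self):
        with pytest.raises(InvalidCohortError):
            hs.CohortSeries.from_counts([100, 150, 80])


class TestGompertzHazard:
    def test_baseline_at_t0(self):
        assert hs.gompertz_hazard(hs.GompertzParams(B=0.1, c=0.15), 0) == 0.1

    def test_first_lactation_value(self):
        p = hs.GompertzParams(B=0.1, c=0.15)
        assert hs.gompertz_hazard(p, 1) == pytest.approx(0.11618, abs=5e-6)
        assert p.hazard_at_first == pytest.approx(0.11618, abs=5e-6)

    @given(
        B=st.floats(min_value=0.01, max_value=0.5),
        c=st.floats(min_value=0.01, max_value=0.3),
    )
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing_for_positive_c(self, B, c):
        p = hs.GompertzParams(B=B, c=c)
        t = np.arange(0, 12)
        assert np.all(np.diff(hs.gompertz_hazard(p, t)) > 0)


class TestFitGompertz:
    def _exact_series(self, B, c, n=8):
        t = np.arange(1, n + 1)
        y = B * np.exp(c * t)
        return hs.DisposalSeries(t=t, y=y, dn=y / (10 * n), dN=y)

    def test_noiseless_recovery(self):
        params = hs.fit_gompertz(self._exact_series(0.1, 0.15))
        assert params.B == pytest.approx(0.1, rel=1e-10)
        assert params.c == pytest.approx(0.15, rel=1e-10)
        assert params.r2 == pytest.approx(1.0, abs=1e-12)

    @given(
        B=st.floats(min_value=0.005, max_value=0.5),
        c=st.floats(min_value=0.005, max_value=0.3),
    )
    @settings(deadline=None, max_examples=50)
    def test_noiseless_recovery_over_parameter_space(self, B, c):
        params = hs.fit_gompertz(self._exact_series(B, c))
        assert params.B == pytest.approx(B, rel=1e-9)
        assert params.c == pytest.approx(c, abs=1e-9)
        assert params.r2 == pytest.approx(1.0, abs=1e-9)

    def test_homogeneous_simulated_cohort_recovers_aging_rate(self):
        # expected-value cohort under the hazard 0.1*exp(0.15 t), N1=1000
        cohort = hs.generate_cohort(hs.GompertzParams(B=0.1, c=0.15), 1000)
        params = hs.fit_gompertz(hs.compute_disposal_series(cohort), window=(1, 8))
        assert round(params.c, 2) == 0.15

    def test_registration_series_matches_ols_oracle(self, tosno_disposal):
        params = hs.fit_gompertz(tosno_disposal, window=(1, 10))
        slope, intercept = ols_oracle(tosno_disposal.t, np.log(tosno_disposal.y))
        assert params.c == pytest.approx(slope, rel=1e-10)
        assert params.B == pytest.approx(np.exp(intercept), rel=1e-10)

    def test_nonpositive_rate_in_window_rejected(self):
        d = hs.DisposalSeries(t=[1, 2, 3], y=[0.1, 0.0, 0.2], dn=[0.1, 0.0, 0.2],
                              dN=[10, 0, 20])
        with pytest.raises(FitDomainError):
            hs.fit_gompertz(d, window=(1, 3))

    def test_too_few_points_rejected(self):
        d = hs.DisposalSeries(t=[1, 2], y=[0.1, 0.2], dn=[0.1, 0.2], dN=[10, 20])
        with pytest.raises(InsufficientDataError):
            hs.fit_gompertz(d, window=(1, 1))


class TestViabilityIndex:
    @pytest.mark.parametrize("y1, expected", [(0.244, 4.098), (1.0, 1.0), (0.5, 2.0)])
    def test_reciprocal_first_lactation_rate(self, y1, expected):
        d = hs.DisposalSeries(t=[1], y=[y1], dn=[y1], dN=[y1 * 100])
        assert hs.viability_index(d) == pytest.approx(expected, abs=5e-4)

    def test_zero_rate_undefined(self):
        d = hs.DisposalSeries(t=[1, 2], y=[0.0, 0.5], dn=[0.0, 0.5], dN=[0, 50])
        with pytest.raises(UndefinedRateError):
            hs.viability_index(d)


class TestLinearFit:
    def test_exact_line(self):
        fit = hs.linear_fit([0, 1, 2], [1.2, 1.46, 1.72])
        assert fit.slope == pytest.approx(0.26, rel=1e-12)
        assert fit.intercept == pytest.approx(1.2, rel=1e-12)
        assert fit.r == pytest.approx(1.0, abs=1e-12)

    def test_three_point_example(self):
        fit = hs.linear_fit([1, 2, 3], [1, 2, 4])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-2 / 3)

    def test_flat_response_reports_zero_r(self):
        with pytest.warns(UserWarning):
            fit = hs.linear_fit([1, 2], [5, 5])
        assert fit.slope == 0
        assert fit.r == 0

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(SingularFitError):
            hs.linear_fit([2, 2, 2], [1, 2, 3])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_agrees_with_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        if np.ptp(x) == 0:
            return
        y = rng.normal(size=8)
        fit = hs.linear_fit(x, y)
        slope, intercept = ols_oracle(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
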