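"""Depletion integration, PLS statistics, and turnover profiles."""

import numpy as np
import pytest

import herdspan as hs
from herdspan.datasets import TOSNO_INTEGRATION_RATES
from herdspan.errors import InvalidInputError, SingularFitError

PUBLISHED_INTEGRATION = [1500, 1213, 899, 585, 372, 230, 121, 63, 30, 10]


class TestIntegrateCohort:
    def test_reproduces_published_integration(self):
        """Every published integer count from N1=1500 under the published
        retention factors, destination-hazard convention."""
        result = hs.integrate_cohort(TOSNO_INTEGRATION_RATES, 1500)
        assert list(result.cohort.rounded_counts()) == PUBLISHED_INTEGRATION

    def test_checkpoints_at_lactations_5_and_9(self):
        cohort = hs.integrate_cohort(TOSNO_INTEGRATION_RATES, 1500).cohort
        counts = cohort.rounded_counts()
        assert counts[4] == 372
        assert counts[8] == 30

    def test_origin_convention_fails_published_table(self):
        """Discriminating check: stepping with the origin lactation's hazard
        does NOT reproduce the published worked integration."""
        result = hs.integrate_cohort(TOSNO_INTEGRATION_RATES, 1500,
                                     convention="origin")
        counts = result.cohort.rounded_counts()
        assert counts[1] != 1213  # 1500 * 0.7558 = 1134
        assert counts[1] == 1134

    def test_zero_hazards_constant_series(self):
        result = hs.integrate_cohort([0.0] * 15, 1000, horizon=15)
        assert np.all(result.cohort.N == 1000)
        assert result.t_max == 15
        assert result.horizon_limited

    def test_gompertz_destination_first_step(self):
        result = hs.integrate_cohort(hs.GompertzParams(B=0.1, c=0.15), 1000)
        assert result.cohort.N[1] == pytest.approx(1000 * (1 - 0.1 * np.exp(0.30)),
                                                   abs=0.01)

    def test_stop_on_unit_hazard_depends_on_convention(self):
        # destination: the transition into lactation 2 is driven by the
        # rate at lactation 2 (1.2 >= 1), so integration stops at t=1;
        # origin: the first transition uses 0.5, the second stops.
        dest = hs.integrate_cohort([0.5, 1.2], 1000)
        assert dest.t_max == 1
        assert dest.stop_reason == "hazard_capped"
        orig = hs.integrate_cohort([0.5, 1.2], 1000, convention="origin")
        assert orig.t_max == 2
        assert orig.stop_reason == "hazard_capped"

    def test_invalid_initial_size(self):
        with pytest.raises(InvalidInputError):
            hs.integrate_cohort([0.1], -5)

    def test_roundtrip_recovers_acting_hazards(self):
        """The disposal series of an integrated cohort returns exactly the
        hazards that drove each transition."""
        h = np.array([0.05, 0.08, 0.12, 0.2, 0.3, 0.45])
        result = hs.integrate_cohort(h, 1000)
        d = hs.compute_disposal_series(result.cohort)
        # destination convention: transition t -> t+1 driven by h[t+1]
        assert np.allclose(d.y, h[1:], rtol=1e-10)

    def test_exit_fractions_plus_remnant_conserve(self):
        result = hs.integrate_cohort(hs.GompertzParams(B=0.15, c=0.2), 2000)
        d = hs.compute_disposal_series(result.cohort)
        assert d.dn.sum() + result.remnant_fraction == pytest.approx(1.0, abs=1e-12)


class TestAveragePLS:
    def test_registration_cohort(self, tosno_disposal):
        assert hs.average_pls(tosno_disposal) == pytest.approx(3.5, abs=0.06)

    def test_all_exit_at_first_lactation(self):
        d = hs.compute_disposal_series(hs.CohortSeries.from_counts([100, 0]))
        assert hs.average_pls(d) == 1.0

    def test_half_and_half(self):
        d = hs.compute_disposal_series(hs.CohortSeries.from_counts([100, 50, 0]))
        assert hs.average_pls(d) == pytest.approx(1.5)

    def test_decreasing_in_baseline_hazard(self):
        for c in (0.1, 0.2):
            T = [
                hs.integrate_cohort(hs.GompertzParams(B=B, c=c), 10000).T
                for B in np.arange(0.05, 0.41, 0.05)
            ]
            assert np.all(np.diff(T) < 0)

    def test_never_exceeds_t_max(self):
        for B in (0.05, 0.1, 0.3):
            result = hs.integrate_cohort(hs.GompertzParams(B=B, c=0.15), 1500)
            assert result.T <= result.t_max


class TestMaxPLS:
    def test_published_integration_reaches_lactation_10(self):
        result = hs.integrate_cohort(TOSNO_INTEGRATION_RATES, 1500)
        assert hs.max_pls(result) == 10


class TestPredictT:
    @pytest.mark.parametrize(
        "index, expected", [(0.0, 1.2), (5.0, 2.5), (1 / 0.244, 2.266)]
    )
    def test_published_predictor(self, index, expected):
        T = hs.predict_T(index, hs.datasets.PLS_FROM_VIABILITY)
        assert T == pytest.approx(expected, abs=5e-4)


class TestRegressTOnViability:
    def test_exact_collinear_pairs(self):
        pairs = [(x, 0.26 * x + 1.2) for x in (1.0, 2.5, 4.0, 6.0)]
        pred = hs.regress_T_on_viability(pairs)
        assert pred.fit.slope == pytest.approx(0.26, rel=1e-10)
        assert pred.fit.intercept == pytest.approx(1.2, rel=1e-10)
        assert pred.r2 == pytest.approx(1.0, abs=1e-12)

    def test_simulated_herds_match_ols_oracle(self):
        from .test_core import ols_oracle

        pairs = []
        for B in np.linspace(0.08, 0.35, 15):
            result = hs.integrate_cohort(hs.GompertzParams(B=float(B), c=0.15), 5000)
            d = hs.compute_disposal_series(result.cohort)
            pairs.append((hs.viability_index(d), hs.average_pls(d)))
        pred = hs.regress_T_on_viability(pairs)
        arr = np.asarray(pairs)
        slope, intercept = ols_oracle(arr[:, 0], arr[:, 1])
        assert pred.fit.slope == pytest.approx(slope, rel=1e-10)
        assert pred.fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_repeated_index_is_singular(self):
        with pytest.raises(SingularFitError):
            hs.regress_T_on_viability([(2.0, 1.5), (2.0, 1.7), (2.0, 1.9)])


class TestTurnoverProfiles:
    def test_partial_pls_column_matches_published(self, tosno_disposal):
        profiles = hs.turnover_profiles(tosno_disposal)
        published = [0.24, 0.29, 0.47, 0.63, 0.54, 0.43, 0.38, 0.23, 0.15, 0.10]
        assert np.allclose(np.round(profiles["partial_pls"], 2), published)
        # the column total is the average productive life span
        assert profiles["partial_pls"].sum() == pytest.approx(
            hs.average_pls(tosno_disposal)
        )

    def test_constant_rate_gives_constant_viability(self):
        d = hs.DisposalSeries(t=[1, 2, 3], y=[0.5] * 3, dn=[0.2] * 3, dN=[1] * 3)
        assert np.all(hs.turnover_profiles(d)["viability"] == 2.0)

    def test_homogeneous_viability_decays_exponentially(self):
        cohort = hs.integrate_cohort(hs.GompertzParams(B=0.1, c=0.15), 100000).cohort
        profiles = hs.turnover_profiles(hs.compute_disposal_series(cohort))
        logv = np.log(profiles["viability"].to_numpy())
        slopes = np.diff(logv)
        assert np.allclose(slopes, -0.15, atol=1e-10)

    def test_zero_rate_emitted_as_missing(self):
        d = hs.DisposalSeries(t=[1, 2], y=[0.0, 0.5], dn=[0.0, 0.5], dN=[0, 1])
        assert np.isnan(hs.turnover_profiles(d)["viability"].iloc[0])
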