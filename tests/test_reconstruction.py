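"""Kaplan-Meier pseudo-IPD reconstruction and censored-MLE fitting."""

import numpy as np
import pytest

from mesocea import (
    DigitizedCurve,
    Family,
    ParametricDistribution,
    PseudoIPD,
    fit_all_families,
    fit_parametric,
    guyot_reconstruct,
    km_curve_from_ipd,
    km_estimate,
    select_distribution,
    simulate_ipd,
)
from mesocea.errors import (
    IncomparableFitsError,
    InsufficientDataError,
    ReconstructionInfeasibleError,
)
from mesocea.reconstruct import FitResult
from mesocea.simulate import Censoring, SimulationScenario
from tests.conftest import BASE_DISTS


def make_curve(dist, n, seed, censoring=Censoring(), risk_step=6.0):
    ipd = simulate_ipd(SimulationScenario(dist, n, censoring, seed))
    horizon = float(np.ceil(ipd.time.max()))
    risk_times = np.arange(0.0, horizon + risk_step, risk_step)
    return ipd, km_estimate(ipd, risk_times)


class TestGuyotReconstruction:
    def test_exact_round_trip_uncensored(self):
        """A curve digitized exactly from an uncensored KM fit, with its true
        risk table, reconstructs the original step function exactly."""
        dist = BASE_DISTS["nivo_ipi_os"]
        ipd, curve = make_curve(dist, n=120, seed=21)
        rec = guyot_reconstruct(curve)
        assert rec.n == 120
        assert rec.n_events == 120
        km_in = km_curve_from_ipd(ipd, curve.times)
        km_out = km_curve_from_ipd(rec, curve.times)
        np.testing.assert_allclose(km_out, km_in, atol=1e-12)

    def test_single_interval_exact_halving(self):
        # survival halves with the risk count: five events, no censoring
        curve = DigitizedCurve([1.0], [0.5], [0.0, 2.0], [10, 5])
        rec = guyot_reconstruct(curve)
        assert rec.n_events == 5
        assert np.all(rec.time[rec.event == 1] == 1.0)

    def test_flat_curve_departures_are_censorings(self):
        curve = DigitizedCurve([1.0, 2.0], [1.0, 1.0], [0.0, 3.0], [10, 4])
        rec = guyot_reconstruct(curve)
        assert rec.n_events == 0
        assert rec.n == 10

    @pytest.mark.parametrize("key", list(BASE_DISTS), ids=list(BASE_DISTS))
    def test_round_trip_with_censoring_within_one_over_n(self, key):
        """KM recomputed from the reconstruction matches the digitized input
        within 1/n at every digitized time, censoring included."""
        dist = BASE_DISTS[key]
        n = 300
        _, curve = make_curve(dist, n, seed=31, censoring=Censoring("administrative", 36.0))
        rec = guyot_reconstruct(curve)
        km_out = km_curve_from_ipd(rec, curve.times)
        assert np.max(np.abs(km_out - curve.surv)) <= 1.0 / n + 1e-12

    def test_impossible_event_count_signalled(self):
        # the curve exhausts all 10 patients before the risk table says
        # 8 should remain: infeasible, naming the offending interval
        curve = DigitizedCurve([1.0], [0.0], [0.0, 2.0], [10, 8])
        with pytest.raises(ReconstructionInfeasibleError) as exc:
            guyot_reconstruct(curve)
        assert exc.value.interval == 0

    def test_rising_risk_counts_rejected(self):
        with pytest.raises((ReconstructionInfeasibleError, ValueError)):
            DigitizedCurve([1.0], [0.5], [0.0, 2.0], [10, 12])

    def test_inverted_survival_clipped_isotonic(self):
        # slight digitization inversion is repaired, not fatal
        curve = DigitizedCurve(
            [1.0, 2.0, 3.0], [0.8, 0.82, 0.5], [0.0, 4.0], [20, 9]
        )
        rec = guyot_reconstruct(curve)
        km_out = km_curve_from_ipd(rec, np.array([1.0, 3.0]))
        assert np.all(np.diff(km_out) <= 0)


class TestParametricFitting:
    def test_weibull_parameter_recovery(self):
        true = ParametricDistribution(Family.WEIBULL, 1.2, 25.0)
        ipd = simulate_ipd(SimulationScenario(true, 5000, seed=41))
        fit = fit_parametric(ipd, Family.WEIBULL)
        assert fit.dist.p1 == pytest.approx(1.2, abs=0.05)
        assert fit.dist.p2 == pytest.approx(25.0, abs=1.0)

    def test_exponential_data_gives_unit_weibull_shape(self):
        expo = ParametricDistribution(Family.WEIBULL, 1.0, 14.0)
        ipd = simulate_ipd(SimulationScenario(expo, 5000, seed=42))
        fit = fit_parametric(ipd, Family.WEIBULL)
        assert fit.dist.p1 == pytest.approx(1.0, abs=0.05)

    def test_all_censored_is_insufficient(self):
        ipd = PseudoIPD(np.linspace(1, 10, 20), np.zeros(20, dtype=int))
        with pytest.raises(InsufficientDataError):
            fit_parametric(ipd, Family.WEIBULL)

    @pytest.mark.parametrize("key", list(BASE_DISTS), ids=list(BASE_DISTS))
    def test_published_parameter_sets_self_recover(self, key):
        """Data simulated from each base-case law refits within 5% at n=5000."""
        true = BASE_DISTS[key]
        ipd = simulate_ipd(SimulationScenario(true, 5000, seed=43))
        fit = fit_parametric(ipd, true.family)
        assert fit.dist.p1 == pytest.approx(true.p1, rel=0.05)
        assert fit.dist.p2 == pytest.approx(true.p2, rel=0.05)

    def test_information_criterion_identities(self):
        ipd = simulate_ipd(
            SimulationScenario(BASE_DISTS["chemo_os"], 400, seed=44)
        )
        for fit in fit_all_families(ipd):
            assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik, abs=1e-9)
            assert fit.bic == pytest.approx(
                2 * np.log(fit.n) - 2 * fit.loglik, abs=1e-9
            )

    def test_mle_beats_small_perturbations(self):
        from mesocea.reconstruct import censored_loglik

        ipd = simulate_ipd(
            SimulationScenario(BASE_DISTS["nivo_ipi_os"], 1000, seed=45,
                               censoring=Censoring("administrative", 36.0))
        )
        fit = fit_parametric(ipd, Family.WEIBULL)
        for f1 in (0.95, 1.05):
            for f2 in (0.95, 1.05):
                perturbed = ParametricDistribution(
                    Family.WEIBULL, fit.dist.p1 * f1, fit.dist.p2 * f2
                )
                assert censored_loglik(perturbed, ipd) <= fit.loglik + 1e-6


class TestModelSelection:
    def test_minimum_criterion_wins(self):
        d = ParametricDistribution(Family.WEIBULL, 1.0, 1.0)
        fits = [
            FitResult(d, -50.0, 110.0, 112.0, 100),
            FitResult(d, -48.0, 100.0, 102.0, 100),
        ]
        assert select_distribution(fits, "aic").aic == 100.0

    def test_self_selection_from_loglogistic_data(self):
        true = BASE_DISTS["chemo_os"]
        ipd = simulate_ipd(SimulationScenario(true, 5000, seed=46))
        fits = fit_all_families(ipd)
        for criterion in ("aic", "bic"):
            assert (
                select_distribution(fits, criterion).dist.family
                is Family.LOGLOGISTIC
            )

    def test_tie_prefers_weibull_and_flags(self):
        dw = ParametricDistribution(Family.WEIBULL, 1.0, 1.0)
        dl = ParametricDistribution(Family.LOGLOGISTIC, 1.0, 1.0)
        fits = [
            FitResult(dl, -50.0, 104.0, 106.0, 100),
            FitResult(dw, -50.0, 104.0, 106.0, 100),
        ]
        best = select_distribution(fits, "aic")
        assert best.dist.family is Family.WEIBULL
        assert best.tie

    def test_fits_on_different_data_incomparable(self):
        d = ParametricDistribution(Family.WEIBULL, 1.0, 1.0)
        fits = [
            FitResult(d, -50.0, 104.0, 106.0, 100),
            FitResult(d, -50.0, 104.0, 106.0, 200),
        ]
        with pytest.raises(IncomparableFitsError):
            select_distribution(fits, "aic")
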