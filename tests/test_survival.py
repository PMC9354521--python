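"""Closed-form survival-law identities and the sampling contract."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mesocea import Family, ParametricDistribution
from mesocea.errors import InvalidDistributionError
from tests.conftest import BASE_DISTS

WEIBULL_OS = BASE_DISTS["nivo_ipi_os"]
LOGNORM_PFS = BASE_DISTS["nivo_ipi_pfs"]
LOGLOG_OS = BASE_DISTS["chemo_os"]

families = st.sampled_from(list(Family))
shapes = st.floats(0.3, 5.0)
scales = st.floats(0.5, 60.0)


def make_dist(family, p1, p2):
    if family is Family.LOGNORMAL:
        # reinterpret: meanlog in a sane range, sdlog positive
        return ParametricDistribution(family, math.log(p2), min(p1, 2.5))
    return ParametricDistribution(family, p1, p2)


class TestClosedForms:
    def test_survival_at_known_points(self):
        # log-logistic median equals its scale; Weibull S(scale) = 1/e
        assert LOGLOG_OS.survival(14.1088) == pytest.approx(0.5, abs=1e-12)
        assert WEIBULL_OS.survival(0.0) == 1.0
        assert WEIBULL_OS.survival(25.48855) == pytest.approx(math.exp(-1), abs=1e-9)
        assert LOGNORM_PFS.survival(math.exp(1.88660)) == pytest.approx(0.5, abs=1e-12)

    def test_medians(self):
        # chemo OS median reproduces the trial's 14.1-month median survival
        assert LOGLOG_OS.median() == pytest.approx(14.1088)
        # frozen oracle: high-resolution root of S(t) = 0.5
        assert WEIBULL_OS.median() == pytest.approx(18.757924959328776, abs=1e-9)
        assert LOGNORM_PFS.median() == pytest.approx(6.596901044154062, abs=1e-9)

    @given(families, shapes, scales)
    @settings(max_examples=60, deadline=None)
    def test_survival_invariants(self, family, p1, p2):
        d = make_dist(family, p1, p2)
        assert d.survival(0.0) == pytest.approx(1.0)
        t = np.linspace(0.0, 200.0, 80)
        s = d.survival(t)
        assert np.all(np.diff(s) <= 1e-12)
        assert d.survival(d.median()) == pytest.approx(0.5, abs=1e-9)
        assert d.survival(1e12) < 1e-3  # S -> 0 (slowly for log-logistic)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidDistributionError):
            ParametricDistribution(Family.WEIBULL, -1.0, 10.0)
        with pytest.raises(InvalidDistributionError):
            ParametricDistribution(Family.LOGLOGISTIC, 1.0, 0.0)
        with pytest.raises(InvalidDistributionError):
            WEIBULL_OS.survival(-1.0)
        # meanlog may be negative
        ParametricDistribution(Family.LOGNORMAL, -1.0, 0.5)


class TestTransitionProbability:
    def test_from_zero_is_one_minus_survival(self):
        d = 0.69
        for dist in BASE_DISTS.values():
            assert dist.transition_probability(0.0, d) == pytest.approx(
                1.0 - dist.survival(d), abs=1e-12
            )

    def test_exponential_is_memoryless(self):
        expo = ParametricDistribution(Family.WEIBULL, 1.0, 9.0)
        expected = 1.0 - math.exp(-2.0 / 9.0)
        for t in (0.0, 5.0, 40.0):
            assert expo.transition_probability(t, 2.0) == pytest.approx(
                expected, abs=1e-12
            )

    def test_frozen_oracle_value(self):
        # arbitrary-precision evaluation of 1 - S(12.6901)/S(12)
        assert WEIBULL_OS.transition_probability(12.0, 0.6901) == pytest.approx(
            0.0276988578128865, abs=1e-12
        )

    @given(families, shapes, scales, st.floats(0.0, 50.0), st.floats(0.1, 5.0),
           st.floats(0.1, 5.0))
    @settings(max_examples=60, deadline=None)
    def test_composition_over_adjacent_intervals(self, family, p1, p2, t, a, b):
        d = make_dist(family, p1, p2)
        one_step = d.transition_probability(t, a + b)
        q1 = d.transition_probability(t, a)
        q2 = d.transition_probability(t + a, b)
        assert 1.0 - one_step == pytest.approx((1 - q1) * (1 - q2), abs=1e-9)

    def test_exhausted_state_transitions_with_probability_one(self):
        assert WEIBULL_OS.transition_probability(1e5, 1.0) == 1.0


class TestRestrictedMean:
    def test_vanishes_at_zero_horizon(self):
        assert WEIBULL_OS.restricted_mean(0.0) == 0.0

    def test_exponential_closed_form(self):
        expo = ParametricDistribution(Family.WEIBULL, 1.0, 8.0)
        for h in (1.0, 12.0, 200.0):
            assert expo.restricted_mean(h) == pytest.approx(
                8.0 * (1 - math.exp(-h / 8.0)), rel=1e-9
            )

    def test_chemo_os_against_quadrature_oracle(self):
        # frozen fine-grid trapezoid oracle (2e6 points over [0, 120])
        assert LOGLOG_OS.restricted_mean(120.0) == pytest.approx(
            22.61500277429398, rel=1e-6
        )

    def test_converges_to_unrestricted_mean(self):
        # log-logistic tails are heavy (~H^(1-shape)), so the horizon must be
        # long before the restricted mean closes on the unrestricted one
        assert WEIBULL_OS.restricted_mean(5000.0) == pytest.approx(
            WEIBULL_OS.mean(), rel=1e-6
        )
        assert LOGLOG_OS.restricted_mean(5e4) == pytest.approx(
            LOGLOG_OS.mean(), rel=5e-3
        )

    def test_monotone_and_bounded(self):
        h = np.array([1.0, 10.0, 50.0, 120.0])
        vals = [WEIBULL_OS.restricted_mean(x) for x in h]
        assert np.all(np.diff(vals) > 0)
        assert all(v <= x for v, x in zip(vals, h))


class TestSampling:
    @pytest.mark.parametrize("dist", list(BASE_DISTS.values()), ids=list(BASE_DISTS))
    def test_empirical_survival_at_median(self, dist):
        x = dist.sample(100_000, seed=7)
        assert np.mean(x > dist.median()) == pytest.approx(0.5, abs=0.005)

    def test_same_seed_same_sequence(self):
        a = WEIBULL_OS.sample(100, seed=3)
        b = WEIBULL_OS.sample(100, seed=3)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("dist", list(BASE_DISTS.values()), ids=list(BASE_DISTS))
    def test_ks_distance_below_critical(self, dist):
        x = dist.sample(10_000, seed=5)
        stat = stats.kstest(x, lambda t: 1.0 - np.asarray(dist.survival(t))).statistic
        crit_1pct = 1.628 / math.sqrt(len(x))
        assert stat < crit_1pct


def test_serialisation_round_trip():
    for dist in BASE_DISTS.values():
        again = ParametricDistribution.from_dict(dist.to_dict())
        assert again == dist
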