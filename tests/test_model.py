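"""Closed forms of the two-stage model against independent quadrature oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from pulsechase import (
    INFINITE_PULSE,
    PulseProtocol,
    RateSet,
    abundance,
    age_density_at_pulse_end,
    chase_curve,
    chase_weights,
    half_time,
    hazard_rate,
    lifetime_pdf,
    mean_lifetime,
    occupancies,
    pulse_only_curve,
    pulse_weights,
    survival,
)
from conftest import random_rates

NEARLY_EXP = RateSet(0.005, 1e-15, 0.3)  # one-stage limit within float range


def survival_quadrature(rates: RateSet, t: float) -> float:
    """Brute-force survival: dwell-time convolution integrated numerically."""
    lam1, lam2 = rates.lam1, rates.lam2
    rho1 = lambda x: lam1 * math.exp(-lam1 * x)
    rho2 = lambda x: lam2 * math.exp(-lam2 * x)
    direct = rates.p10 * quad(rho1, 0, t)[0]
    inner = lambda tau: rho1(tau) * quad(rho2, 0, t - tau)[0]
    via_state2 = rates.p12 * quad(inner, 0, t, limit=200)[0]
    return 1.0 - direct - via_state2


def chase_quadrature(rates: RateSet, tp: float, dt: float) -> float:
    """Window-integral definition of the chase curve, by adaptive quadrature."""
    s = lambda u: survival(rates, u)
    return quad(s, dt, dt + tp, limit=400)[0] / quad(s, 0, tp, limit=400)[0]


class TestSurvival:
    def test_starts_at_one(self, reference_rates):
        assert survival(reference_rates, 0.0) == 1.0

    def test_one_stage_limit_is_exponential(self):
        t = np.linspace(0, 800, 9)
        np.testing.assert_allclose(survival(NEARLY_EXP, t), np.exp(-0.005 * t),
                                   rtol=1e-9)

    @pytest.mark.parametrize("t", [1.0, 100.0, 5000.0])
    def test_matches_convolution_quadrature(self, reference_rates, t):
        assert survival(reference_rates, t) == pytest.approx(
            survival_quadrature(reference_rates, t), abs=1e-10)

    def test_degenerate_eigenvalues_match_quadrature(self):
        rates = RateSet(0.004, 0.006, 0.01)  # kappa20 == kappa10 + kappa12
        assert rates.degenerate
        for t in (10.0, 500.0):
            assert survival(rates, t) == pytest.approx(
                survival_quadrature(rates, t), abs=1e-9)

    def test_negative_time_rejected(self, reference_rates):
        with pytest.raises(ValueError):
            survival(reference_rates, -1.0)

    @settings(deadline=None, max_examples=40)
    @given(logk=st.tuples(*[st.floats(-5, 0) for _ in range(3)]),
           logt=st.floats(-1, 5))
    def test_is_valid_survival_function(self, logk, logt):
        """S(0)=1, values in [0,1], non-increasing, -dS/dt equals the pdf."""
        rates = RateSet(*(10.0 ** np.asarray(logk)))
        t = 10.0 ** logt
        grid = np.linspace(0, t, 20)
        s = survival(rates, grid)
        assert np.all((0 <= s) & (s <= 1 + 1e-15))
        assert np.all(np.diff(s) <= 1e-15)
        h = max(1e-6 * t, 1e-9)
        mid = t / 2
        slope = (survival(rates, mid + h) - survival(rates, mid - h)) / (2 * h)
        if lifetime_pdf(rates, mid) > 1e-12:
            assert -slope == pytest.approx(lifetime_pdf(rates, mid), rel=1e-5)


class TestLifetimePdf:
    def test_one_stage_limit(self):
        t = np.linspace(0, 500, 6)
        np.testing.assert_allclose(lifetime_pdf(NEARLY_EXP, t),
                                   0.005 * np.exp(-0.005 * t), rtol=1e-9)

    def test_normalizes_to_one(self, reference_rates):
        total, _ = quad(lambda u: lifetime_pdf(reference_rates, u), 0, np.inf,
                        limit=400)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_consistent_with_hazard_reconstruction(self):
        """f(t) = delta(t) * exp(-int_0^t delta) for random rate sets."""
        rng = np.random.default_rng(1)
        for i in range(20):
            rates = random_rates(rng)
            t = float(10 ** rng.uniform(-1, 2.5))
            cum, _ = quad(lambda a: hazard_rate(rates, a), 0, t, limit=300)
            recon = hazard_rate(rates, t) * math.exp(-cum)
            assert recon == pytest.approx(lifetime_pdf(rates, t), rel=1e-8)


class TestHazard:
    def test_constant_for_one_stage(self):
        for a in (0.0, 50.0, 5000.0):
            assert hazard_rate(NEARLY_EXP, a) == pytest.approx(0.005, rel=1e-9)

    def test_initial_value_is_kappa10(self, reference_rates):
        assert hazard_rate(reference_rates, 0.0) == pytest.approx(0.0109, rel=1e-12)
        # cross-check f(0) against the quadrature-based density
        h = 1e-4
        f0 = (survival_quadrature(reference_rates, 0.0)
              - survival_quadrature(reference_rates, h)) / h
        assert f0 == pytest.approx(0.0109, rel=1e-3)

    def test_late_age_limit_is_kappa20(self, reference_rates):
        assert abs(hazard_rate(reference_rates, 1e4) - 0.0002) < 1e-6

    def test_monotone_decreasing_to_limit(self, reference_rates):
        ages = np.logspace(0, 6, 40)
        d = hazard_rate(reference_rates, ages)
        assert np.all(np.diff(d) <= 0)  # flat only once the limit is reached
        assert d[0] > d[-1]
        assert np.all(d > 0.0002 - 1e-15)

    def test_no_underflow_at_extreme_age(self, reference_rates):
        assert hazard_rate(reference_rates, 1e9) == pytest.approx(0.0002, rel=1e-6)

    def test_survival_reconstructed_from_hazard(self, reference_rates):
        """1 - exp(-int_0^t delta) reproduces F_T within 1e-8."""
        for t in (10.0, 300.0, 4000.0):
            cum, _ = quad(lambda a: hazard_rate(reference_rates, a), 0, t,
                          limit=300)
            assert 1.0 - math.exp(-cum) == pytest.approx(
                1.0 - survival(reference_rates, t), abs=1e-8)


class TestMeanLifetime:
    def test_reference_value_exceeds_53_hours(self, reference_rates):
        tbar = mean_lifetime(reference_rates)
        assert tbar == pytest.approx(3204.698, abs=0.01)
        assert tbar > 53 * 60

    def test_one_stage_limit(self):
        assert mean_lifetime(NEARLY_EXP) == pytest.approx(200.0, rel=1e-9)

    def test_closed_form_equals_quadrature(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            rates = random_rates(rng)
            q, _ = quad(lambda u: survival(rates, u), 0, np.inf, limit=400)
            assert mean_lifetime(rates) == pytest.approx(q, rel=1e-8)


class TestAbundance:
    def test_zero_at_start(self, reference_rates):
        assert abundance(PulseProtocol(), reference_rates, 0.0) == 0.0

    def test_saturates_at_omega_tbar(self, reference_rates):
        proto = PulseProtocol(synthesis_rate=2.5)
        n_inf = abundance(proto, reference_rates, 1e9)
        assert n_inf == pytest.approx(2.5 * mean_lifetime(reference_rates),
                                      rel=1e-8)

    def test_matches_quadrature(self, reference_rates):
        q, _ = quad(lambda u: survival(reference_rates, u), 0, 120, limit=200)
        assert abundance(PulseProtocol(), reference_rates, 120.0) == pytest.approx(
            q, abs=1e-9)

    def test_monotone(self, reference_rates):
        t = np.linspace(0, 5000, 50)
        n = abundance(PulseProtocol(), reference_rates, t)
        assert np.all(np.diff(n) > 0)


class TestChaseWeights:
    def test_infinite_pulse_factors_equal_one(self, reference_rates):
        w = chase_weights(reference_rates, INFINITE_PULSE)
        r = reference_rates
        assert w.a == pytest.approx((r.kappa10 - r.kappa20) / r.lam1, rel=1e-14)
        assert w.b == pytest.approx(r.kappa12 / r.kappa20, rel=1e-14)

    def test_zero_pulse_limit_is_survival_mixture(self, reference_rates):
        """As t_p -> 0 the chase curve tends to the bare survival function."""
        dt = np.array([10.0, 200.0, 2000.0])
        c = chase_curve(reference_rates, 1e-8, dt)
        np.testing.assert_allclose(c, survival(reference_rates, dt), rtol=1e-6)

    def test_normalized_weights_sum_to_one(self, reference_rates):
        w = chase_weights(reference_rates, 30.0)
        wa, wb = w.normalized
        assert wa + wb == 1.0
        assert w.b >= 0


class TestChaseCurve:
    def test_starts_at_one_for_any_pulse(self, reference_rates):
        for tp in (1.0, 30.0, 1200.0, INFINITE_PULSE):
            assert chase_curve(reference_rates, tp, 0.0) == pytest.approx(
                1.0, abs=1e-14)

    def test_strictly_decreasing(self, reference_rates):
        dt = np.linspace(0, 20000, 200)
        c = chase_curve(reference_rates, 30.0, dt)
        assert np.all(np.diff(c) < 0)

    def test_pulse_independent_in_exponential_limit(self):
        """One-stage decay: identical curves for a 1-min and a 1200-min pulse."""
        dt = np.linspace(0, 1000, 21)
        c1 = chase_curve(NEARLY_EXP, 1.0, dt)
        c1200 = chase_curve(NEARLY_EXP, 1200.0, dt)
        np.testing.assert_allclose(c1, c1200, rtol=1e-14, atol=1e-300)
        np.testing.assert_allclose(c1, np.exp(-0.005 * dt), rtol=1e-9)

    def test_closed_form_equals_window_quadrature(self, reference_rates):
        for tp in (1.0, 5.0, 30.0, 120.0, 1200.0):
            for dt in (0.0, 40.0, 480.0, 5000.0):
                assert chase_curve(reference_rates, tp, dt) == pytest.approx(
                    chase_quadrature(reference_rates, tp, dt), abs=1e-9)

    def test_random_triples_including_near_degenerate(self):
        """Closed form vs window quadrature on random (rates, t_p, dt) triples."""
        rng = np.random.default_rng(3)
        for i in range(25):
            rates = random_rates(rng, degenerate_every=3, i=i)
            tp = float(10 ** rng.uniform(0, 3.1))
            dt = float(10 ** rng.uniform(0, math.log10(min(3 / rates.lam2, 1e5))))
            assert chase_curve(rates, tp, dt) == pytest.approx(
                chase_quadrature(rates, tp, dt), abs=1e-9)

    def test_two_exponential_form_with_explicit_weights(self, reference_rates):
        """Spelled-out mixture (A_c, B_c) agrees for separated eigenvalues."""
        w = chase_weights(reference_rates, 30.0)
        wa, wb = w.normalized
        dt = np.array([0.0, 10.0, 100.0, 1000.0])
        plain = (wa * np.exp(-reference_rates.lam1 * dt)
                 + wb * np.exp(-reference_rates.lam2 * dt))
        np.testing.assert_allclose(chase_curve(reference_rates, 30.0, dt), plain,
                                   rtol=1e-12)

    def test_negative_dt_rejected(self, reference_rates):
        with pytest.raises(ValueError):
            chase_curve(reference_rates, 30.0, -5.0)


class TestPulseOnly:
    def test_zero_at_start_and_saturation(self, reference_rates):
        assert pulse_only_curve(reference_rates, 0.0) == 0.0
        assert pulse_only_curve(reference_rates, 1e9) == pytest.approx(1.0,
                                                                       rel=1e-10)

    def test_monotone_increasing(self, reference_rates):
        t = np.linspace(0, 20000, 100)
        p = pulse_only_curve(reference_rates, t)
        assert np.all(np.diff(p) > 0)

    def test_explicit_weights_route_agrees(self, reference_rates):
        """Dual route: A_p/B_p mixture vs integrated-survival ratio, rel 1e-10."""
        w = pulse_weights(reference_rates)
        r = reference_rates
        assert w.a == pytest.approx(r.kappa20 * (r.kappa10 - r.kappa20), rel=1e-14)
        assert w.b == pytest.approx(r.kappa12 * r.lam1, rel=1e-14)
        for dt in (1.0, 10.0, 100.0, 1000.0):
            explicit = (w.a * -math.expm1(-r.lam1 * dt)
                        + w.b * -math.expm1(-r.lam2 * dt)) / (w.a + w.b)
            assert pulse_only_curve(r, dt) == pytest.approx(explicit, rel=1e-10)

    def test_finite_time_normalization_is_abundance_ratio(self, reference_rates):
        proto = PulseProtocol()
        p = pulse_only_curve(reference_rates, 15.0, normalization=60.0)
        ratio = (abundance(proto, reference_rates, 15.0)
                 / abundance(proto, reference_rates, 60.0))
        assert p == pytest.approx(ratio, rel=1e-12)

    def test_zero_normalization_time_rejected(self, reference_rates):
        with pytest.raises(ZeroDivisionError, match="N\\(0\\) = 0"):
            pulse_only_curve(reference_rates, 10.0, normalization=0.0)


class TestHalfTime:
    def test_defining_property(self, reference_rates):
        th = half_time(reference_rates)
        assert chase_curve(reference_rates, INFINITE_PULSE, th) == pytest.approx(
            0.5, abs=1e-9)

    def test_one_stage_limit_pulse_independent(self):
        expected = math.log(2) / 0.005
        for tp in (1.0, 1200.0, INFINITE_PULSE):
            assert half_time(NEARLY_EXP, tp) == pytest.approx(expected, rel=1e-9)

    def test_apparent_half_time_grows_with_pulse(self, reference_rates):
        """Short pulses label a young, fast-decaying cohort."""
        t1 = half_time(reference_rates, 1.0)
        t1200 = half_time(reference_rates, 1200.0)
        tinf = half_time(reference_rates, INFINITE_PULSE)
        assert t1 < t1200 < tinf


class TestOccupancies:
    def test_reference_value(self, reference_rates):
        pi1, pi2 = occupancies(reference_rates)
        assert pi1 == pytest.approx(0.0002 / (0.0189 + 0.0002), rel=1e-14)
        assert pi1 == pytest.approx(0.010471, abs=5e-7)
        assert pi1 + pi2 == 1.0

    def test_one_stage_limit(self):
        pi1, _ = occupancies(NEARLY_EXP)
        assert pi1 == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_rates(self):
        pi1, pi2 = occupancies(RateSet(0.01, 0.003, 0.003))
        assert pi1 == pytest.approx(0.5, rel=1e-14)


class TestAgeDensity:
    def test_zero_beyond_pulse(self, reference_rates):
        assert age_density_at_pulse_end(reference_rates, 30.0, 31.0) == 0.0

    def test_normalized(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            rates = random_rates(rng)
            tp = float(10 ** rng.uniform(0, 3))
            total, _ = quad(lambda a: age_density_at_pulse_end(rates, tp, a),
                            0, tp, limit=300)
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_exponential_limit_long_pulse(self):
        a = np.array([0.0, 100.0, 400.0])
        dens = age_density_at_pulse_end(NEARLY_EXP, 1e7, a)
        np.testing.assert_allclose(dens, 0.005 * np.exp(-0.005 * a), rtol=1e-6)
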