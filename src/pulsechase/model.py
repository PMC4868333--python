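"""Two-stage Markov degradation model: closed-form decay curves and kinetics.

A molecule is synthesized into biochemical state 1, where it dwells an
exponential time with rate ``kappa10 + kappa12``.  It then either degrades
directly (probability ``P10 = kappa10/(kappa10+kappa12)``) or moves to state 2
(probability ``P12``), from which it degrades with rate ``kappa20``.  The
lifetime is the absorption time of this chain — a phase-type (hypoexponential
mixture) distribution whose survival function is a two-exponential mixture
with eigenvalues ``lam1 = kappa10 + kappa12`` and ``lam2 = kappa20``.

Labeling a cohort during a pulse of length ``t_p`` and normalizing the
surviving labeled abundance to 1 at chase start yields the chase decay
pattern ``C(dt)``; measuring *during* the pulse and normalizing by the steady
state yields the pulse-only accumulation ``P(dt)``.  Both are closed-form
two-exponential expressions whose mixture weights depend on ``t_p`` — this
pulse dependence is the entire point: for non-exponential decay, ignoring
the pulse length biases every fitted rate and the apparent half-time.

All evaluations go through divided-difference primitives (see
``_numerics``) so that fitting trajectories can cross the eigenvalue
degeneracy ``kappa20 == kappa10 + kappa12`` without NaNs or cancellation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from ._numerics import exp_dd, int_exp, int_exp_dd, phi, window_int_exp_dd

__all__ = [
    "INFINITE_PULSE",
    "RATE_BOUNDS",
    "RateSet",
    "OneStageRate",
    "PulseProtocol",
    "MixtureWeights",
    "DerivedQuantities",
    "survival",
    "lifetime_pdf",
    "hazard_rate",
    "mean_lifetime",
    "abundance",
    "chase_weights",
    "chase_curve",
    "pulse_weights",
    "pulse_only_curve",
    "half_time",
    "occupancies",
    "derived_quantities",
    "age_density_at_pulse_end",
]

#: Symbolic "infinite pulse" (synthesis shutoff at steady state).
INFINITE_PULSE = math.inf

#: Calibration bounds for every rate, in 1/min.
RATE_BOUNDS = (1e-6, 1.0)

#: Relative eigenvalue gap below which RateSet flags itself degenerate.
DEGENERACY_RTOL = 1e-12


@dataclass(frozen=True)
class RateSet:
    """The three transition rates of the two-stage model, in 1/min."""

    kappa10: float
    kappa12: float
    kappa20: float

    def __post_init__(self):
        for name in ("kappa10", "kappa12", "kappa20"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def lam1(self) -> float:
        """Fast eigenvalue (state-1 exit rate), kappa10 + kappa12."""
        return self.kappa10 + self.kappa12

    @property
    def lam2(self) -> float:
        """Second eigenvalue, kappa20."""
        return self.kappa20

    @property
    def tau1(self) -> float:
        """Mean dwell time in state 1 (min)."""
        return 1.0 / self.lam1

    @property
    def tau2(self) -> float:
        """Mean dwell time in state 2 (min)."""
        return 1.0 / self.kappa20

    @property
    def p10(self) -> float:
        """Probability of direct degradation from state 1."""
        return self.kappa10 / self.lam1

    @property
    def p12(self) -> float:
        """Probability of passing through state 2."""
        return self.kappa12 / self.lam1

    @property
    def degenerate(self) -> bool:
        """True when the eigenvalues coincide to relative gap < 1e-12."""
        return abs(self.lam1 - self.lam2) / self.lam1 < DEGENERACY_RTOL

    def within_bounds(self, bounds=RATE_BOUNDS) -> bool:
        lo, hi = bounds
        return all(lo <= v <= hi for v in (self.kappa10, self.kappa12, self.kappa20))


@dataclass(frozen=True)
class OneStageRate:
    """Single-exponential decay rate (1/min)."""

    kappa_exp: float

    def __post_init__(self):
        if not (self.kappa_exp > 0) or not math.isfinite(self.kappa_exp):
            raise ValueError(f"kappa_exp must be strictly positive, got {self.kappa_exp!r}")


@dataclass(frozen=True)
class PulseProtocol:
    """Labeling protocol: pulse length t_p (min, may be inf) and synthesis rate omega.

    omega only scales absolute abundances; the normalized curves C and P are
    omega-free, hence the default of 1.
    """

    pulse_length: float = INFINITE_PULSE
    synthesis_rate: float = 1.0

    def __post_init__(self):
        if not (self.pulse_length > 0):
            raise ValueError("pulse_length must be > 0 (or math.inf)")
        if not (self.synthesis_rate > 0) or not math.isfinite(self.synthesis_rate):
            raise ValueError("synthesis_rate must be strictly positive and finite")


@dataclass(frozen=True)
class MixtureWeights:
    """Coefficients (a, b) of the fast/slow exponentials of a decay curve.

    ``a`` may be negative (chase context with kappa20 > kappa10); ``b`` is
    non-negative.  ``normalized`` returns weights that sum to 1 exactly.
    """

    a: float
    b: float
    context: Literal["chase", "pulse_only"]

    @property
    def normalized(self) -> tuple[float, float]:
        s = self.a + self.b
        if s == 0.0:
            raise ZeroDivisionError(
                "mixture weights sum to zero (degenerate eigenvalues); "
                "use the curve functions, which handle this limit"
            )
        wa = self.a / s
        return wa, 1.0 - wa


@dataclass(frozen=True)
class DerivedQuantities:
    """Stability summary derived from a RateSet (see ``derived_quantities``)."""

    mean_lifetime: float
    half_time: float
    pi1: float
    pi2: float
    steady_state_abundance: float
    synthesis_rate: float = 1.0


def _check_nonneg(t, name="t"):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"{name} must be non-negative")
    return t


def _check_pulse(pulse_length):
    if not (pulse_length > 0):
        raise ValueError("pulse_length must be > 0 (or math.inf)")
    return float(pulse_length)


def survival(rates: RateSet, t):
    """Survival function S(t) = 1 - F_T(t) of the molecule lifetime.

    Two-exponential mixture ``w1*exp(-lam1 t) + w2*exp(-lam2 t)`` with
    ``w2 = kappa12/(lam1 - lam2)``, evaluated in divided-difference form
    ``exp(-lam1 t) + kappa12 * exp_dd(lam1, lam2, t)`` which is exact in the
    degenerate limit as well.
    """
    t = _check_nonneg(t)
    out = np.exp(-rates.lam1 * t) + rates.kappa12 * exp_dd(rates.lam1, rates.lam2, t)
    return out if np.ndim(out) else float(out)


def lifetime_pdf(rates: RateSet, t):
    """Lifetime probability density f_T(t) = -dS/dt (1/min).

    ``kappa10*exp(-lam1 t) + kappa12*kappa20*exp_dd(lam1, lam2, t)``;
    f_T(0) = kappa10.
    """
    t = _check_nonneg(t)
    out = (rates.kappa10 * np.exp(-rates.lam1 * t)
           + rates.kappa12 * rates.lam2 * exp_dd(rates.lam1, rates.lam2, t))
    return out if np.ndim(out) else float(out)


def hazard_rate(rates: RateSet, a):
    """Age-dependent degradation rate delta(a) = f_T(a) / S(a) (1/min).

    Constant kappa10 in the one-stage limit (kappa12 -> 0); otherwise tends
    monotonically to min(lam1, lam2) at large ages.  Evaluated with both
    numerator and denominator rescaled by exp(min(lam1, lam2)*a) so that it
    never underflows to 0/0.
    """
    a = _check_nonneg(a, "a")
    lam1, lam2, k12 = rates.lam1, rates.lam2, rates.kappa12
    h = lam1 - lam2
    # E = exp(m*a) * exp_dd(lam1, lam2, a) with m = min(lam1, lam2); stable
    # for arbitrarily large a in both orderings of the eigenvalues.
    if h >= 0:  # m = lam2
        E = a * phi(h * a)
        r1 = np.exp(-h * a)  # exp(m*a - lam1*a)
    else:  # m = lam1
        x = h * a  # <= 0
        E = np.where(x != 0.0, np.expm1(x) / h, a)
        r1 = np.ones_like(np.asarray(a, dtype=float))
    num = rates.kappa10 * r1 + k12 * lam2 * E
    den = r1 + k12 * E
    out = num / den
    return out if np.ndim(out) else float(out)


def mean_lifetime(rates: RateSet) -> float:
    """Mean lifetime T-bar = tau1 + P12*tau2 = 1/lam1 + kappa12/(lam1*kappa20) (min)."""
    return 1.0 / rates.lam1 + rates.kappa12 / (rates.lam1 * rates.kappa20)


def _integrated_survival(rates: RateSet, t):
    """I(t) = int_0^t S(u) du; t may be +inf (I(inf) = mean lifetime)."""
    return (int_exp(rates.lam1, t)
            + rates.kappa12 * int_exp_dd(rates.lam1, rates.lam2, t))


def abundance(protocol: PulseProtocol, rates: RateSet, t):
    """Mean labeled abundance N(t) = omega * int_0^t S(u) du during the pulse.

    N(0) = 0, non-decreasing, saturating at omega * mean_lifetime.
    """
    t = _check_nonneg(t)
    out = protocol.synthesis_rate * _integrated_survival(rates, t)
    return out if np.ndim(out) else float(out)


def chase_weights(rates: RateSet, pulse_length) -> MixtureWeights:
    """Pulse-dependent chase coefficients (A_c, B_c).

    ``A_c = (kappa10-kappa20)/(kappa10+kappa12) * [1 - exp(-(kappa10+kappa12)*t_p)]``
    and ``B_c = kappa12/kappa20 * [1 - exp(-kappa20*t_p)]``; the bracketed
    factors equal 1 for an infinite pulse.
    """
    tp = _check_pulse(pulse_length)
    f1 = 1.0 if math.isinf(tp) else -math.expm1(-rates.lam1 * tp)
    f2 = 1.0 if math.isinf(tp) else -math.expm1(-rates.lam2 * tp)
    a = (rates.kappa10 - rates.kappa20) / rates.lam1 * f1
    b = rates.kappa12 / rates.kappa20 * f2
    return MixtureWeights(a=a, b=b, context="chase")


def chase_curve(rates: RateSet, pulse_length, dt):
    """Relative labeled abundance C(dt) during the chase after a pulse of t_p.

    ``C(dt) = [A_c exp(-lam1 dt) + B_c exp(-lam2 dt)] / (A_c + B_c)``,
    equivalently the window integral of survival over [dt, dt + t_p]
    normalized so that C(0) = 1.  Strictly decreasing from 1 to 0; in the
    one-stage limit it is exp(-kappa10*dt) for every pulse length.
    """
    tp = _check_pulse(pulse_length)
    dt = _check_nonneg(dt, "dt")
    num = (np.exp(-rates.lam1 * dt) * int_exp(rates.lam1, tp)
           + rates.kappa12 * window_int_exp_dd(rates.lam1, rates.lam2, dt, tp))
    den = _integrated_survival(rates, tp)
    out = num / den
    return out if np.ndim(out) else float(out)


def pulse_weights(rates: RateSet) -> MixtureWeights:
    """Steady-state pulse-only coefficients A_p = kappa20*(kappa10-kappa20),
    B_p = kappa12*(kappa10+kappa12)."""
    a = rates.kappa20 * (rates.kappa10 - rates.kappa20)
    b = rates.kappa12 * rates.lam1
    return MixtureWeights(a=a, b=b, context="pulse_only")


def pulse_only_curve(rates: RateSet, dt, normalization="steady_state"):
    """Relative labeled abundance P(dt) measured *during* the pulse.

    With steady-state normalization (the default), ``P(dt) = N(dt)/N(st)``:
    the saturating two-term mixture
    ``[A_p(1-exp(-lam1 dt)) + B_p(1-exp(-lam2 dt))]/(A_p+B_p)``, computed as
    I(dt)/T-bar which is the same expression in a degeneracy-safe form.
    P(0) = 0, increasing, P(inf) = 1.

    ``normalization`` may instead be a finite time t_norm > 0, giving the
    abundance ratio N(dt)/N(t_norm).
    """
    dt = _check_nonneg(dt, "dt")
    if normalization == "steady_state":
        den = mean_lifetime(rates)
    else:
        t_norm = float(normalization)
        if t_norm == 0.0:
            raise ZeroDivisionError(
                "normalization time must be > 0: N(0) = 0 cannot normalize"
            )
        if t_norm < 0:
            raise ValueError("normalization time must be > 0")
        den = _integrated_survival(rates, t_norm)
    out = _integrated_survival(rates, dt) / den
    return out if np.ndim(out) else float(out)


def half_time(rates: RateSet, pulse_length=INFINITE_PULSE) -> float:
    """Time at which the chase curve crosses 1/2 (min).

    Default pulse length is infinite — the molecule's true t_1/2 defined from
    the synthesis-shutoff curve.  For finite pulses this is the *apparent*
    half-time, which depends on the pulse length whenever kappa12 > 0.
    Solved by bracketed root finding to 1e-12 relative tolerance.
    """
    tp = _check_pulse(pulse_length)
    f = lambda t: chase_curve(rates, tp, t) - 0.5
    hi = mean_lifetime(rates)
    while f(hi) > 0:
        hi *= 2.0
    return float(brentq(f, 0.0, hi, rtol=1e-12, xtol=1e-30, maxiter=200))


def occupancies(rates: RateSet) -> tuple[float, float]:
    """Steady-state fractions (pi1, pi2) of molecules in states 1 and 2.

    pi1 = kappa20/(kappa12 + kappa20), pi2 = 1 - pi1.
    """
    pi1 = rates.kappa20 / (rates.kappa12 + rates.kappa20)
    return pi1, 1.0 - pi1


def derived_quantities(rates: RateSet, protocol: PulseProtocol | None = None) -> DerivedQuantities:
    """Bundle the standard stability read-outs for a fitted RateSet."""
    if protocol is None:
        protocol = PulseProtocol()
    tbar = mean_lifetime(rates)
    pi1, pi2 = occupancies(rates)
    return DerivedQuantities(
        mean_lifetime=tbar,
        half_time=half_time(rates, protocol.pulse_length),
        pi1=pi1,
        pi2=pi2,
        steady_state_abundance=protocol.synthesis_rate * tbar,
        synthesis_rate=protocol.synthesis_rate,
    )


def age_density_at_pulse_end(rates: RateSet, pulse_length, a):
    """Age distribution of the labeled cohort at chase start.

    Proportional to S(a) on [0, t_p], zero for ages beyond the pulse,
    normalized to integrate to 1.
    """
    tp = _check_pulse(pulse_length)
    a = _check_nonneg(a, "a")
    dens = survival(rates, a) / _integrated_survival(rates, tp)
    out = np.where(np.asarray(a) <= tp, dens, 0.0)
    return out if out.ndim else float(out)
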