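"""Fabricated decay patterns, measurement noise, and a single-molecule simulator.

Three generators, all pure functions of (parameters, seed):

* :func:`fabricate_pattern` — noiseless curves straight from the closed
  forms, on a default grid of 0, 40, ..., 480 min that spans both the fast
  (1/lam1 ~ 34 min at the reference rates) and slow (1/kappa20 = 5000 min)
  timescales.
* :func:`add_noise` — one-sided multiplicative noise
  ``C -> C * exp(eps * zeta)`` with ``zeta ~ U[0, 1)`` drawn independently
  per time point (t > 0 only); ``eps`` defaults to 0.01.  The factor is
  deliberately >= 1 — the noise model is kept exactly as defined, not
  symmetrized.
* :func:`simulate_single_molecules` — an independent Monte-Carlo oracle:
  molecules born uniformly over the pulse window draw phase-type lifetimes
  (exponential dwell in state 1, branch to state 2 with probability P12,
  exponential dwell there) and are censused at each sample time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .fitting import DecayPattern
from .model import RateSet, chase_curve, mean_lifetime, pulse_only_curve

__all__ = [
    "NoiseSpec",
    "SimConfig",
    "SimulationError",
    "DEFAULT_CHASE_GRID",
    "PULSE_PRESETS",
    "fabricate_pattern",
    "fabricate_pulse_set",
    "add_noise",
    "simulate_single_molecules",
]

#: Default chase sampling grid (min): 13 points, 0..480 in steps of 40.
DEFAULT_CHASE_GRID = np.arange(0.0, 481.0, 40.0)

#: The five reference pulse lengths (min), keyed by preset name.
PULSE_PRESETS = {"p1": 1.0, "p5": 5.0, "p30": 30.0, "p120": 120.0, "p1200": 1200.0}


class SimulationError(RuntimeError):
    """Raised when a stochastic census cannot be normalized."""


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitude and seed of the multiplicative measurement noise."""

    epsilon: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the single-molecule simulator."""

    n_molecules: int
    pulse_length: float
    sample_times: np.ndarray
    seed: int = 0
    design: Literal["chase", "pulse_only"] = "chase"

    def __post_init__(self):
        object.__setattr__(self, "sample_times",
                           np.asarray(self.sample_times, dtype=float))
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not (self.pulse_length > 0) or math.isinf(self.pulse_length):
            raise ValueError("simulator needs a finite pulse_length > 0")
        if np.any(self.sample_times < 0) or np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be non-negative and increasing")


def fabricate_pattern(rates: RateSet,
                      pulse_length: float,
                      times: Sequence[float] | None = None,
                      design: Literal["chase", "pulse_only"] = "chase") -> DecayPattern:
    """Noiseless pattern computed from the closed-form curves."""
    if times is None:
        times = DEFAULT_CHASE_GRID
    times = np.asarray(times, dtype=float)
    if design == "chase":
        values = np.asarray(chase_curve(rates, pulse_length, times))
    elif design == "pulse_only":
        values = np.asarray(pulse_only_curve(rates, times))
    else:
        raise ValueError(f"unknown design {design!r}")
    return DecayPattern(
        pulse_length=pulse_length,
        times=times,
        values=values,
        design=design,
        label=f"fabricated_{design}_tp={pulse_length:g}",
        metadata={
            "source": "fabricate_pattern",
            "kappa10": rates.kappa10,
            "kappa12": rates.kappa12,
            "kappa20": rates.kappa20,
            "pulse_length": pulse_length,
            "design": design,
        },
    )


def fabricate_pulse_set(rates: RateSet,
                        pulse_lengths: Sequence[float] = tuple(PULSE_PRESETS.values()),
                        times: Sequence[float] | None = None) -> list[DecayPattern]:
    """The standard fixture family: one chase pattern per pulse length."""
    return [fabricate_pattern(rates, tp, times=times) for tp in pulse_lengths]


def add_noise(pattern: DecayPattern, noise: NoiseSpec) -> DecayPattern:
    """Corrupt a pattern with one-sided multiplicative noise.

    Each value at t > 0 is multiplied by ``exp(epsilon * zeta)``,
    ``zeta ~ U[0, 1)`` independent per point; a t = 0 point (the
    normalization anchor) is left untouched.
    """
    rng = np.random.default_rng(noise.seed)
    zeta = rng.random(pattern.n_points)
    factor = np.where(pattern.times > 0, np.exp(noise.epsilon * zeta), 1.0)
    return DecayPattern(
        pulse_length=pattern.pulse_length,
        times=pattern.times.copy(),
        values=pattern.values * factor,
        design=pattern.design,
        label=pattern.label + "+noise" if pattern.label else "noisy",
        metadata={**pattern.metadata, "noise_epsilon": noise.epsilon,
                  "noise_seed": noise.seed},
    )


def _sample_lifetimes(rates: RateSet, n: int, rng: np.random.Generator) -> np.ndarray:
    dwell1 = rng.exponential(scale=1.0 / rates.lam1, size=n)
    to_state2 = rng.random(n) < rates.p12
    dwell2 = rng.exponential(scale=1.0 / rates.kappa20, size=n)
    return dwell1 + np.where(to_state2, dwell2, 0.0), to_state2


def simulate_single_molecules(rates: RateSet, config: SimConfig) -> DecayPattern:
    """Monte-Carlo decay pattern from explicit single-molecule trajectories.

    ``n_molecules`` labeled molecules are born uniformly over the pulse
    window (conditioning on the number of births rather than simulating
    Poisson arrivals — the normalized pattern has the same distribution).
    Chase design: census at ``pulse_length + sample_times``, normalized by
    the count surviving at pulse end.  Pulse-only design: births are spread
    over [0, max(sample_times)], censused during labeling and normalized by
    the long-run mean count ``n * mean_lifetime / window``.

    The fraction of molecules that ever reach state 2 is recorded in the
    metadata (``fraction_state2``) for branching-probability checks.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    if config.design == "chase":
        window = config.pulse_length
    else:
        window = float(config.sample_times.max())
        if window <= 0:
            raise ValueError("pulse_only simulation needs a positive census time")
    births = rng.uniform(0.0, window, size=n)
    lifetimes, to_state2 = _sample_lifetimes(rates, n, rng)
    deaths = births + lifetimes

    if config.design == "chase":
        census = config.pulse_length + config.sample_times
        counts = (deaths[None, :] > census[:, None]).sum(axis=1)
        n0 = int((deaths > config.pulse_length).sum())
        if n0 == 0:
            raise SimulationError(
                "no labeled molecule survived to the end of the pulse; "
                "increase n_molecules"
            )
        if np.any(counts == 0):
            raise SimulationError(
                "a census time has zero surviving molecules; increase "
                "n_molecules or shorten the census grid"
            )
        values = counts / n0
    else:
        census = config.sample_times
        alive = (births[None, :] <= census[:, None]) & (deaths[None, :] > census[:, None])
        counts = alive.sum(axis=1)
        norm = n * mean_lifetime(rates) / window
        values = counts / norm

    return DecayPattern(
        pulse_length=config.pulse_length,
        times=config.sample_times.copy(),
        values=values,
        design=config.design,
        label=f"simulated_{config.design}_n={n}",
        metadata={
            "source": "simulate_single_molecules",
            "n_molecules": n,
            "seed": config.seed,
            "fraction_state2": float(to_state2.mean()),
            "survivors_at_normalization": int(n0) if config.design == "chase" else n,
        },
    )
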