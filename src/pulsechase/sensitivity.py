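"""Local sensitivity of the pulse-only output P(t) to each transition rate.

``v_k(t) = dP(t)/dk`` for k in {kappa10, kappa12, kappa20}, holding the
other rates fixed.  P is the steady-state-normalized accumulation curve

    P(t) = [Ap*(1 - exp(-lam1 t)) + Bp*(1 - exp(-lam2 t))] / (Ap + Bp),
    Ap = kappa20*(kappa10 - kappa20),  Bp = kappa12*(kappa10 + kappa12),

and the closed-form derivatives below follow from the chain rule through
(Ap, Bp, lam1, lam2); they were derived symbolically once and are validated
against a central finite-difference oracle in the test suite.  Because P
saturates at 1, every sensitivity vanishes at late times — late samples
carry no parameter information, which is why adding measurements beyond a
few multiples of 1/lam1 does not improve a pulse-only fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .model import RateSet, pulse_only_curve

__all__ = [
    "PARAMETERS",
    "SensitivityProfile",
    "sensitivity_closed_form",
    "sensitivity_finite_difference",
    "sensitivity_profile",
]

PARAMETERS = ("kappa10", "kappa12", "kappa20")

#: Relative eigenvalue gap below which the closed form is refused.
_DEGENERACY_GAP = 1e-9


@dataclass(frozen=True)
class SensitivityProfile:
    """dP/dkappa over a time grid (and optionally a kappa grid)."""

    parameter: str
    times: np.ndarray
    values: np.ndarray  # shape (len(times),) or (len(kappa_grid), len(times))
    method: Literal["closed_form", "finite_difference"]
    kappa_grid: np.ndarray | None = None


def _check(rates: RateSet, parameter: str):
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {PARAMETERS}, got {parameter!r}")
    gap = abs(rates.lam1 - rates.lam2) / rates.lam1
    if gap < _DEGENERACY_GAP:
        raise ValueError(
            "closed-form sensitivity is not supported at (near-)degenerate "
            "eigenvalues (kappa20 ~= kappa10 + kappa12); use "
            "sensitivity_finite_difference"
        )


def sensitivity_closed_form(rates: RateSet, parameter: str, t):
    """Analytic dP(t)/dkappa_i at the given rates (units: min)."""
    _check(rates, parameter)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    k10, k12, k20 = rates.kappa10, rates.kappa12, rates.kappa20
    lam1, lam2 = rates.lam1, rates.lam2
    e1, e2 = np.exp(-lam1 * t), np.exp(-lam2 * t)
    u1, u2 = -np.expm1(-lam1 * t), -np.expm1(-lam2 * t)
    ap = k20 * (k10 - k20)
    bp = k12 * lam1
    d = ap + bp
    numer = ap * u1 + bp * u2

    if parameter == "kappa10":
        dap, dbp = k20, k12
        du1, du2 = t * e1, np.zeros_like(t)
    elif parameter == "kappa12":
        dap, dbp = 0.0, k10 + 2.0 * k12
        du1, du2 = t * e1, np.zeros_like(t)
    else:  # kappa20
        dap, dbp = k10 - 2.0 * k20, 0.0
        du1, du2 = np.zeros_like(t), t * e2
    dnumer = dap * u1 + ap * du1 + dbp * u2 + bp * du2
    out = (dnumer * d - numer * (dap + dbp)) / d**2
    return out if np.ndim(out) else float(out)


def sensitivity_finite_difference(rates: RateSet, parameter: str, t,
                                  rel_step: float = 1e-6):
    """Central finite-difference oracle for dP(t)/dkappa_i.

    The step is relative (default 1e-6), balancing truncation and rounding
    for rates spanning 1e-6..1.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {PARAMETERS}, got {parameter!r}")
    t = np.asarray(t, dtype=float)
    k = {p: getattr(rates, p) for p in PARAMETERS}
    h = rel_step * k[parameter]
    up = dict(k); up[parameter] += h
    dn = dict(k); dn[parameter] -= h
    p_up = np.asarray(pulse_only_curve(RateSet(**up), t))
    p_dn = np.asarray(pulse_only_curve(RateSet(**dn), t))
    out = (p_up - p_dn) / (2.0 * h)
    return out if np.ndim(out) else float(out)


def sensitivity_profile(rates: RateSet, parameter: str,
                        times: Sequence[float],
                        kappa_range: Sequence[float] | None = None,
                        method: Literal["closed_form", "finite_difference"] = "closed_form",
                        ) -> SensitivityProfile:
    """Evaluate v_kappa over a time grid, optionally sweeping kappa_i itself.

    With ``kappa_range``, the named rate is swept over the grid while the
    other rates stay pinned at their values in ``rates``; the result is a
    (len(kappa_range), len(times)) surface for reporting or plotting.
    """
    times = np.asarray(times, dtype=float)
    fun = (sensitivity_closed_form if method == "closed_form"
           else sensitivity_finite_difference)
    if kappa_range is None:
        return SensitivityProfile(parameter=parameter, times=times,
                                  values=np.asarray(fun(rates, parameter, times)),
                                  method=method)
    kappa_range = np.asarray(kappa_range, dtype=float)
    base = {p: getattr(rates, p) for p in PARAMETERS}
    rows = []
    for kv in kappa_range:
        r = RateSet(**{**base, parameter: float(kv)})
        rows.append(np.asarray(fun(r, parameter, times)))
    return SensitivityProfile(parameter=parameter, times=times,
                              values=np.vstack(rows), method=method,
                              kappa_grid=kappa_range)
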