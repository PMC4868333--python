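"""Stable two-exponential primitives.

All closed forms of the two-stage model are linear combinations of
``exp(-lam1*t)`` and ``exp(-lam2*t)`` whose coefficients carry a
``1/(lam1 - lam2)`` factor.  Evaluated naively these are 0/0 forms at the
eigenvalue degeneracy ``lam1 == lam2`` and lose precision catastrophically
nearby.  Everything here is written as divided differences built on
``expm1``, which are accurate for any eigenvalue gap, including the exact
degenerate limit (where ``t*exp(-lam*t)`` secular terms appear).
"""

from __future__ import annotations

import numpy as np

# |gap * t| above which the naive difference quotient is already safe
# (the two exponentials then differ by a factor >= e^50).
_SERIES_CUTOFF = 50.0


def expg(x):
    """``expm1(x)/x`` with the removable singularity at 0 filled in."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0.0
    out[nz] = np.expm1(x[nz]) / x[nz]
    return out if out.ndim else float(out)


def phi(x):
    """``(1 - exp(-x))/x`` with phi(0) = 1; equals expg(-x) up to sign bookkeeping."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0.0
    out[nz] = -np.expm1(-x[nz]) / x[nz]
    return out if out.ndim else float(out)


def exp_dd(lam1: float, lam2: float, t):
    """Divided difference ``(exp(-lam2*t) - exp(-lam1*t)) / (lam1 - lam2)``.

    Degenerate limit: ``t * exp(-lam*t)``.  Non-negative for t >= 0.
    """
    t = np.asarray(t, dtype=float)
    h = lam1 - lam2
    ht = h * t
    small = np.abs(ht) <= _SERIES_CUTOFF
    out = np.empty_like(t)
    # series-stable branch: t * exp(-lam1 t) * expg(h t)
    ts = t[small]
    out[small] = ts * np.exp(-lam1 * ts) * expg(ht[small])
    big = ~small
    if np.any(big):
        tb = t[big]
        out[big] = (np.exp(-lam2 * tb) - np.exp(-lam1 * tb)) / h
    return out if out.ndim else float(out)


def int_exp(lam: float, t):
    """``int_0^t exp(-lam*u) du = (1 - exp(-lam*t))/lam``; t may be +inf."""
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    fin = np.isfinite(t)
    out[fin] = t[fin] * phi(lam * t[fin])
    out[~fin] = 1.0 / lam
    return out if out.ndim else float(out)


def int_exp_dd(lam1: float, lam2: float, t):
    """Divided difference of :func:`int_exp` in the rate argument.

    ``(int_exp(lam2, t) - int_exp(lam1, t)) / (lam1 - lam2)``, i.e. the
    integral of :func:`exp_dd` from 0 to t.  Positive; t may be +inf
    (limit ``1/(lam1*lam2)``).
    """
    t = np.asarray(t, dtype=float)
    h = lam1 - lam2
    out = np.empty_like(t)
    inf = ~np.isfinite(t)
    out[inf] = 1.0 / (lam1 * lam2)
    fin = ~inf
    tf = t[fin]
    ht = h * tf
    small = np.abs(ht) <= _SERIES_CUTOFF
    res = np.empty_like(tf)
    # [-expm1(-lam1 t) - lam1 t exp(-lam1 t) expg(h t)] / (lam1 lam2)
    ts = tf[small]
    res[small] = (-np.expm1(-lam1 * ts)
                  - lam1 * ts * np.exp(-lam1 * ts) * expg(ht[small])) / (lam1 * lam2)
    big = ~small
    if np.any(big):
        tb = tf[big]
        res[big] = ((1.0 - np.exp(-lam2 * tb)) / lam2
                    - (1.0 - np.exp(-lam1 * tb)) / lam1) / h
    out[fin] = res
    return out if out.ndim else float(out)


def window_int_exp_dd(lam1: float, lam2: float, start, width):
    """Window integral of :func:`exp_dd` over ``[start, start + width]``.

    ``(exp(-lam2*start)*int_exp(lam2,width) - exp(-lam1*start)*int_exp(lam1,width))
    / (lam1 - lam2)``; ``width`` may be +inf.
    """
    start = np.asarray(start, dtype=float)
    h = lam1 - lam2
    hs = h * start
    small = np.abs(hs) <= _SERIES_CUTOFF
    out = np.empty_like(start)
    p2 = int_exp(lam2, width)
    ss = start[small]
    out[small] = np.exp(-lam1 * ss) * (
        ss * expg(hs[small]) * p2 + int_exp_dd(lam1, lam2, width)
    )
    big = ~small
    if np.any(big):
        sb = start[big]
        out[big] = (np.exp(-lam2 * sb) * p2
                    - np.exp(-lam1 * sb) * int_exp(lam1, width)) / h
    return out if out.ndim else float(out)
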