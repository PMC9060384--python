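"""Ribosome flow with extended footprints and drop-off (the q = r = 1 case).

Without nearest-neighbour forces the model describes mRNA translation: the
lattice is the codon chain, particles are ribosomes with footprint ``ell``
codons, ``lam`` are initiation/elongation/termination rates and ``alpha``
are premature-termination (drop-off) rates.  The output rate
``R = (lam_n + alpha_n) x_n`` is the protein production rate.

This module implements the dynamics directly from their specialised form —
independently of the general evaluator, so the two serve as cross-checks —
plus a shooting solver on the steady-state flux recursion, closed forms for
the fully homogeneous full-footprint chain, and the positive-feedback closed
loop in which ribosomes leaving the chain (completed or dropped off) are
recycled into the initiation rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.optimize import brentq

from .core import LatticeParams, coverage, output_rate
from .steady_state import (
    SteadyState,
    SteadyStateError,
    converge_to_equilibrium,
)

__all__ = [
    "FeedbackParams",
    "rfmeod_rhs",
    "solve_steady_state_shooting",
    "homogeneous_full_footprint",
    "feedback_rhs",
    "feedback_steady_state",
]


def _require_no_interactions(p: LatticeParams):
    if p.q != 1.0 or p.r != 1.0:
        raise ValueError(
            f"this evaluator requires q = r = 1 (no interactions), "
            f"got q={p.q}, r={p.r}")


@dataclass(frozen=True)
class FeedbackParams:
    """Positive-feedback (ribosome recycling) parameters.

    ``k1`` (> 0, 1/time) is the constant initiation source from freely
    diffusing ribosomes; ``k2`` (>= 0, dimensionless) is the recycling gain
    multiplying the total ribosome outflow ``lam_n x_n + sum_i alpha_i x_i``.
    """

    k1: float
    k2: float = 0.0

    def __post_init__(self):
        if self.k1 <= 0:
            raise ValueError(f"k1 must be > 0, got {self.k1}")
        if self.k2 < 0:
            raise ValueError(f"k2 must be >= 0, got {self.k2}")


def _rhs_with_initiation(x, p: LatticeParams, lam0):
    """Specialised field with a (possibly state-dependent) initiation rate.

    dx_1 = lam0 (1 - y_ell) - lam_1 x_1 (1 - y_{ell+1}) - alpha_1 x_1 and
    dx_i = lam_{i-1} x_{i-1} (1 - y_{i+ell-1}) - lam_i x_i (1 - y_{i+ell})
           - alpha_i x_i, with y_k = 0 for k > n.  The last ``ell`` sites'
    equations are linear: a ribosome reading the final codons has no one
    ahead of it.
    """
    n, ell = p.n, p.ell
    y = coverage(x, ell)
    yext = np.concatenate([y, np.zeros(ell + 1)])  # y_k = 0 beyond the chain

    f = np.empty(n + 1)
    f[0] = lam0 * (1.0 - yext[ell - 1])
    # f_i = lam_i x_i (1 - y_{i+ell}), the factor collapsing to 1 for i > n-ell
    f[1:] = p.lam[1:] * x * (1.0 - yext[ell:ell + n])
    return f[:-1] - f[1:] - p.alpha * x


def rfmeod_rhs(x, p: LatticeParams, t=0.0):
    """Time derivative of the translation model (q = r = 1)."""
    _require_no_interactions(p)
    x = np.asarray(x, dtype=float)
    if x.shape != (p.n,):
        raise ValueError(f"state must have shape ({p.n},), got {x.shape}")
    return _rhs_with_initiation(x, p, p.lam[0])


def feedback_rhs(x, p: LatticeParams, fb: FeedbackParams, t=0.0):
    """Closed-loop field: initiation rate ``k1 + k2 (lam_n x_n + sum alpha_i x_i)``.

    With ``k2 = 0`` this is the open loop with ``lam_0 = k1``.
    """
    _require_no_interactions(p)
    x = np.asarray(x, dtype=float)
    if x.shape != (p.n,):
        raise ValueError(f"state must have shape ({p.n},), got {x.shape}")
    lam0 = fb.k1 + fb.k2 * (p.lam[p.n] * x[-1] + float(np.dot(p.alpha, x)))
    return _rhs_with_initiation(x, p, lam0)


def _back_substitute(R, p: LatticeParams):
    """Back-substitution of the steady-state flux recursion for a trial R.

    Starting from ``e_n = R / (lam_n + alpha_n)`` (so that the exit rate
    ``(lam_n + alpha_n) e_n`` equals R), each upstream density follows from
    flux balance:

        e_i = (R + sum_{k=i+1}^{n-1} alpha_k e_k) / (lam_i (1 - y_{i+ell}))

    where the coverage ``y_{i+ell}`` is assembled from the already-computed
    downstream densities (zero beyond the chain).  Returns None if a trial R
    is infeasible (some ``1 - y_{i+ell} <= 0`` or a density leaves [0, 1]).
    """
    n, ell = p.n, p.ell
    e = np.zeros(n)
    e[n - 1] = R / (p.lam[n] + p.alpha[n - 1])
    if not 0.0 <= e[n - 1] <= 1.0:
        return None
    drop_sum = 0.0  # sum_{k=i+1}^{n-1} alpha_k e_k, built as i decreases
    for i in range(n - 1, 0, -1):  # sites n-1 .. 1
        # y_{i+ell} = sum of e_j over the window j in [i+1, i+ell] inside 1..n
        if i + ell <= n:
            cov = float(np.sum(e[i:min(i + ell, n)]))
            free = 1.0 - cov
            if free <= 0.0:
                return None
        else:
            free = 1.0
        if i < n - 1:  # the drop-off sum runs k = i+1 .. n-1 only
            drop_sum += p.alpha[i] * e[i]
        ei = (R + drop_sum) / (p.lam[i] * free)
        if not 0.0 <= ei <= 1.0:
            return None
        e[i - 1] = ei
    return e


def _consistency_residual(R, p: LatticeParams):
    """Residual of the initiation-site flux balance for a trial R.

    The recursion fixes ``e_1..e_n`` from R; consistency then demands the
    coverage of the first window equal
    ``(lam_0 - R - sum_{k=1}^{n-1} alpha_k e_k) / lam_0``.  Infeasible
    trials count as +inf so bisection keeps a usable sign.
    """
    e = _back_substitute(R, p)
    if e is None:
        return np.inf
    y_ell = float(np.sum(e[:p.ell]))
    target = (p.lam[0] - R - float(np.dot(p.alpha[:p.n - 1], e[:p.n - 1]))) / p.lam[0]
    return y_ell - target


def solve_steady_state_shooting(p: LatticeParams, tol=1e-12):
    """Steady state via a scalar shoot on the output rate R.

    R is bracketed in ``(0, lam_0)``: at R -> 0 every density vanishes and
    the residual is -1; as R grows the recursion either overflows
    (+inf by convention) or the residual turns positive.  Bisection locates
    the sign change, Brent refines it.  Agrees with the ODE route to the
    solver tolerance; exists as an independent second route to the same
    equilibrium.
    """
    _require_no_interactions(p)
    eps = 1e-10
    lo, hi = eps * p.lam[0], (1.0 - eps) * p.lam[0]
    flo = _consistency_residual(lo, p)
    if not flo < 0:
        raise SteadyStateError("no feasible flux bracket at R ~ 0")
    # shrink the upper end until the residual is defined-positive
    fhi = _consistency_residual(hi, p)
    for _ in range(200):
        if np.isfinite(fhi) and fhi > 0:
            break
        if np.isinf(fhi):
            # bisect toward the feasible region keeping +inf convention
            mid = 0.5 * (lo + hi)
            fmid = _consistency_residual(mid, p)
            if fmid < 0:
                lo, flo = mid, fmid
            else:
                hi, fhi = mid, fmid
        else:
            break
    else:
        raise SteadyStateError("could not bracket the output rate")
    if not (np.isfinite(fhi) and fhi > 0):
        # the residual jumps from negative straight to +inf: tighten by pure
        # bisection on the feasibility boundary
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            fmid = _consistency_residual(mid, p)
            if fmid < 0:
                lo, flo = mid, fmid
            else:
                hi, fhi = mid, fmid
            if np.isfinite(fhi) and fhi > 0:
                break
        if not (np.isfinite(fhi) and fhi > 0):
            raise SteadyStateError("no root of the flux recursion in (0, lam_0)")
    R = brentq(lambda v: min(_consistency_residual(v, p), 1e9), lo, hi,
               xtol=1e-15, rtol=8.9e-16, maxiter=200)
    e = _back_substitute(R, p)
    if e is None:
        raise SteadyStateError("root landed on an infeasible trial flux")
    res = float(np.max(np.abs(rfmeod_rhs(e, p))))
    return SteadyState(e=e, R=float(output_rate(e, p)), rho=float(np.mean(e)),
                       y=coverage(e, p.ell), residual=res)


def homogeneous_full_footprint(n, lam, alpha):
    """Closed-form steady state for ``ell = n`` with uniform rates.

    When the particle spans the whole chain at most one particle is present
    and the flux recursion telescopes into binomial sums:

        D = 1 + lam/(lam+alpha)
            + ((lam+alpha)/lam) * sum_{i=1}^{n-1} sum_{j=0}^{n-i-1}
              C(n-i-1, j) (alpha/lam)^j
        R = lam / D,   e_i = sum_{j=0}^{n-i-1} C(n-i-1, j) (alpha/lam)^j / D

    (inner sums equal ``(1 + alpha/lam)^{n-i-1}``).  For ``alpha = lam`` this
    collapses to ``R = 2 lam / (2^{n+1} - 1)`` and
    ``e_i = 2^{n-i} / (2^{n+1} - 1)``.  Returns a
    :class:`~efeiod.steady_state.SteadyState`.
    """
    n = int(n)
    lam = float(lam)
    alpha = float(alpha)
    if n < 1 or lam <= 0 or alpha < 0:
        raise ValueError("need n >= 1, lam > 0, alpha >= 0")
    ratio = alpha / lam
    inner = [sum(comb(n - i - 1, j) * ratio ** j for j in range(n - i))
             for i in range(1, n)]  # i = 1..n-1
    D = 1.0 + lam / (lam + alpha) + ((lam + alpha) / lam) * sum(inner)
    R = lam / D
    e = np.empty(n)
    for i in range(1, n):
        e[i - 1] = inner[i - 1] / D
    e[n - 1] = R / (lam + alpha)
    p = LatticeParams.homogeneous(n, n, lam=lam, alpha=alpha)
    res = float(np.max(np.abs(rfmeod_rhs(e, p))))
    return SteadyState(e=e, R=R, rho=float(np.mean(e)), y=coverage(e, n),
                       residual=res)


def feedback_steady_state(p: LatticeParams, fb: FeedbackParams, tol=1e-12,
                          x0=None):
    """Unique equilibrium of the recycling closed loop.

    The state-dependent initiation rate is uniformly bounded and separated
    from zero (``k1 > 0``), so the contraction argument of the open loop
    carries over and integrate-then-Newton converges from any feasible start.
    """
    def rhs(x, params, t=0.0):
        return feedback_rhs(x, params, fb, t)

    e, res = converge_to_equilibrium(rhs, p, x0=x0, tol=tol)
    return SteadyState(e=e, R=float(output_rate(e, p)), rho=float(np.mean(e)),
                       y=coverage(e, p.ell), residual=float(res))
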