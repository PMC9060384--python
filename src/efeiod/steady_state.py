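"""Steady-state computation for the general interacting model.

For ``q, r > 0`` the dynamics are contractive (after an arbitrarily short
transient) on the invariant set ``H``, so a unique globally asymptotically
stable equilibrium ``e`` exists in the interior of ``H``.  The solver
exploits this: integrate the ODE from a feasible interior point until the
vector field is small, then polish with a damped Newton iteration on the
field itself.  Uniqueness for ``q = 0`` or ``r = 0`` fails (a continuum of
equilibria can exist), so those regimes are rejected here while remaining
simulatable through :func:`simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import LatticeParams, coverage, efeiod_rhs, in_state_space, output_rate

__all__ = [
    "SteadyState",
    "Trajectory",
    "simulate",
    "find_steady_state",
    "scale_parameters",
    "sensitivity",
    "SensitivityResult",
    "DegenerateInteractionError",
    "SteadyStateError",
]


class SteadyStateError(RuntimeError):
    """Raised when the equilibrium solver fails to converge."""


class DegenerateInteractionError(ValueError):
    """Raised for q = 0 or r = 0, where the equilibrium is not unique."""


@dataclass(frozen=True)
class SteadyState:
    """Equilibrium of one parameter set.

    Attributes
    ----------
    e : array (n,)
        Equilibrium reader densities.
    R : float
        Steady-state output (exit) rate, 1/time.
    rho : float
        Mean reader density ``(1/n) sum_i e_i``.
    y : array (n,)
        Equilibrium coverage densities.
    residual : float
        Max-norm of the vector field at ``e``.
    """

    e: np.ndarray
    R: float
    rho: float
    y: np.ndarray
    residual: float


@dataclass(frozen=True)
class Trajectory:
    """Sampled solution of an initial-value problem."""

    t: np.ndarray
    x: np.ndarray  # shape (len(t), n)

    def final(self):
        return self.x[-1]


def simulate(p: LatticeParams, x0, t_end, t_eval=None, rhs=None,
             rtol=1e-9, atol=1e-11, require_feasible=True):
    """Integrate the model from ``x0`` over ``[0, t_end]``.

    Parameters
    ----------
    p : LatticeParams
    x0 : array (n,)
        Initial reader densities; must lie in ``H`` unless
        ``require_feasible=False`` (used e.g. to demonstrate that the unit
        cube alone is *not* invariant).
    t_end : float
    t_eval : array, optional
        Output sample times; defaults to 200 evenly spaced points.
    rhs : callable ``(x, p, t) -> dx/dt``, optional
        Alternative vector field sharing the signature of
        :func:`~efeiod.core.efeiod_rhs`.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (p.n,):
        raise ValueError(f"x0 must have shape ({p.n},), got {x0.shape}")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if require_feasible and not in_state_space(x0, p.ell, tol=1e-9):
        raise ValueError("x0 is not in the state space H")
    if rhs is None:
        rhs = efeiod_rhs
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 200)
    sol = solve_ivp(lambda t, x: rhs(x, p, t), (0.0, float(t_end)), x0,
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise SteadyStateError(
            f"integration failed ({sol.message}) for params n={p.n}, "
            f"ell={p.ell}, q={p.q}, r={p.r}")
    return Trajectory(t=sol.t, x=sol.y.T)


def _fd_jacobian(fun, x, h=1e-7):
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        step = h * max(1.0, abs(x[j]))
        xp = x.copy()
        xm = x.copy()
        xp[j] += step
        xm[j] -= step
        J[:, j] = (fun(xp) - fun(xm)) / (2.0 * step)
    return J


def _newton_polish(fun, x, tol, max_iter=50):
    """Damped Newton on ``fun(x) = 0``; returns (x, residual)."""
    fx = fun(x)
    res = np.max(np.abs(fx))
    for _ in range(max_iter):
        if res <= tol:
            break
        J = _fd_jacobian(fun, x)
        try:
            dx = np.linalg.solve(J, -fx)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        while lam > 1e-6:
            xn = x + lam * dx
            fn = fun(xn)
            rn = np.max(np.abs(fn))
            if rn < res:
                x, fx, res = xn, fn, rn
                break
            lam /= 2.0
        else:
            break
    return x, res


def converge_to_equilibrium(rhs, p: LatticeParams, x0=None, tol=1e-12,
                            ode_tol=1e-6, max_time=2e5):
    """Generic integrate-then-polish equilibrium finder for a contractive field.

    Integrates ``rhs`` in chunks until the field's max-norm drops below
    ``ode_tol``, then Newton-polishes to ``tol``.  Used by both the general
    solver and the closed-loop (feedback) variant.
    """
    warm = x0 is not None
    if x0 is None:
        x0 = np.full(p.n, 1.0 / (2.0 * p.ell))
    x = np.asarray(x0, dtype=float).copy()

    def field(v):
        return rhs(v, p, 0.0)

    if warm:
        # a warm start near the equilibrium lets Newton finish immediately;
        # uniqueness in H makes any converged interior point THE equilibrium
        xn, res = _newton_polish(field, x, tol)
        if res <= tol and in_state_space(xn, p.ell, tol=1e-9):
            return xn, res

    # chunk length scaled to the fastest rate so stiff instances still step
    rate_scale = max(float(np.max(p.lam)), float(np.max(p.alpha, initial=0.0)), 1e-6)
    t_chunk = max(50.0, 50.0 / float(np.min(p.lam)))
    elapsed = 0.0
    while elapsed < max_time:
        sol = solve_ivp(lambda t, v: field(v), (0.0, t_chunk), x,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise SteadyStateError(f"integration failed: {sol.message}")
        x = sol.y[:, -1]
        elapsed += t_chunk
        if np.max(np.abs(field(x))) < ode_tol * rate_scale:
            break
    x, res = _newton_polish(field, x, tol)
    if res > max(tol, 1e-9):
        raise SteadyStateError(
            f"equilibrium residual {res:.3e} above tolerance {tol:.1e}")
    return x, res


def find_steady_state(p: LatticeParams, tol=1e-12, x0=None):
    """Globally asymptotically stable equilibrium of the model.

    Requires ``q > 0`` and ``r > 0``; otherwise the equilibrium need not be
    unique (e.g. ``[1, 1, v]`` for every ``v`` in a 3-site chain with
    ``q = r = 0``) and a :class:`DegenerateInteractionError` is raised.
    """
    if p.q <= 0 or p.r <= 0:
        raise DegenerateInteractionError(
            "steady state is unique only for q > 0 and r > 0; this instance "
            "admits a continuum of equilibria (use simulate() for dynamics)")
    strength = max(abs(np.log(p.q)), abs(np.log(p.r)))
    if x0 is None and strength > 3.0:
        # strong interactions make the field stiff; walk a geometric homotopy
        # from the non-interacting instance, warm-starting Newton at each step
        steps = int(np.ceil(strength / 1.5))
        x = None
        for k in range(1, steps + 1):
            s = k / steps
            pk = p.with_rates(q=p.q ** s, r=p.r ** s)
            x, res = converge_to_equilibrium(efeiod_rhs, pk, x0=x, tol=tol)
        e = x
    else:
        e, res = converge_to_equilibrium(efeiod_rhs, p, x0=x0, tol=tol)
    return SteadyState(e=e, R=output_rate(e, p), rho=float(np.mean(e)),
                       y=coverage(e, p.ell), residual=float(res))


def scale_parameters(p: LatticeParams, c):
    """Multiply every ``lam`` and ``alpha`` by ``c > 0`` (q, r unchanged).

    The equilibrium is invariant under this scaling while the output rate is
    homogeneous of order one: ``e(c*p) = e(p)`` and ``R(c*p) = c*R(p)``.
    """
    c = float(c)
    if c <= 0:
        raise ValueError(f"scale factor must be > 0, got {c}")
    return p.with_rates(lam=c * p.lam, alpha=c * p.alpha)


@dataclass(frozen=True)
class SensitivityResult:
    """Finite-difference steady-state sensitivities.

    ``names[j]`` labels parameter ``gamma_j``; ``de[j, i]`` approximates
    ``d e_i / d gamma_j`` and ``dR[j]`` approximates ``d R / d gamma_j``.
    """

    names: list
    de: np.ndarray
    dR: np.ndarray

    def dR_by(self, name):
        return float(self.dR[self.names.index(name)])


def sensitivity(p: LatticeParams, h=1e-5, tol=1e-12):
    """Central finite-difference sensitivities of ``e`` and ``R``.

    The parameter vector is ``gamma = (lam_0..lam_n, alpha_1..alpha_n, r, q)``.
    Steps are relative, ``h * max(1, |gamma_j|)``; a step that would push a
    rate nonpositive is shrunk until feasible.  The equilibrium map is
    differentiable in every parameter, so central differences converge.
    """
    names = ([f"lambda_{i}" for i in range(p.n + 1)]
             + [f"alpha_{i}" for i in range(1, p.n + 1)]
             + ["r", "q"])
    gamma = np.concatenate([p.lam, p.alpha, [p.r, p.q]])

    def build(vec):
        return LatticeParams(n=p.n, ell=p.ell, lam=vec[:p.n + 1],
                             alpha=vec[p.n + 1:2 * p.n + 1],
                             q=vec[-1], r=vec[-2])

    base = find_steady_state(p, tol=tol)
    de = np.empty((gamma.size, p.n))
    dR = np.empty(gamma.size)
    for j in range(gamma.size):
        step = h * max(1.0, abs(gamma[j]))
        # alphas may sit at 0: shrink until the minus-perturbation is legal
        is_alpha = p.n + 1 <= j < 2 * p.n + 1
        floor = 0.0 if is_alpha else 1e-12
        while gamma[j] - step < floor and step > 1e-12:
            step /= 2.0
        gp = gamma.copy()
        gm = gamma.copy()
        gp[j] += step
        gm[j] -= step
        sp = find_steady_state(build(gp), tol=tol, x0=base.e)
        sm = find_steady_state(build(gm), tol=tol, x0=base.e)
        de[j] = (sp.e - sm.e) / (2.0 * step)
        dR[j] = (sp.R - sm.R) / (2.0 * step)
    return SensitivityResult(names=names, de=de, dR=dR)
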