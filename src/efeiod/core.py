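"""Core model definition: parameters, coverage operator, vector field.

The model describes unidirectional transport of extended particles on a 1-D
lattice of ``n`` sites.  Each particle covers ``ell`` consecutive sites; its
position is identified with the site under its left edge (the *reader*).
The state is the vector of reader densities ``x_1..x_n``, each a probability.
The *coverage* density ``y_i`` is the probability that site ``i`` is covered
by any part of a particle, i.e. a trailing window sum of width ``ell`` over
the reader densities.

Transitions from site ``i`` to ``i+1`` occur at rate ``lam[i]``, modulated by
a soft exclusion factor ``1 - y_{i+ell}`` and by nearest-neighbour
interaction factors: ``q`` scales the rate when a *new* bond with a particle
at distance ``ell+1`` ahead would be created, ``r`` scales rates involving an
*existing* bond with a particle exactly ``ell`` sites away.  Whole particles
detach (drop off) from site ``i`` at rate ``alpha[i]``, also modulated by
``r``-factors.  Thermodynamic consistency couples the two factors through the
interaction energy: ``q*r = exp(E)`` (k_B*T normalised to 1), split equally
as ``q = exp(E/2)``, ``r = exp(-E/2)``.

The dynamics are the ``n`` coupled ODEs

    dx_i/dt = f_{i-1}(x) - f_i(x) - g_i(x)

with the flux and detachment terms defined in :func:`efeiod_rhs`.  The
invariant state space is ``H = {x : x in [0,1]^n and Px in [0,1]^n}`` where
``P`` is the banded coverage matrix (:func:`coverage_matrix`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LatticeParams",
    "coverage",
    "coverage_matrix",
    "efeiod_rhs",
    "output_rate",
    "in_state_space",
]


@dataclass(frozen=True)
class LatticeParams:
    """Full parameter set of one lattice-transport instance.

    Parameters
    ----------
    n : int
        Number of lattice sites (>= 1).
    ell : int
        Particle footprint in sites, ``1 <= ell <= n``.
    lam : array of shape (n+1,)
        Transition rates ``lam[0]..lam[n]`` (1/time), all strictly positive.
        ``lam[0]`` is the initiation (entry) rate, ``lam[n]`` the exit rate.
    alpha : array of shape (n,)
        Detachment rates ``alpha[1]..alpha[n]`` (1/time, stored 0-based),
        all nonnegative.
    q : float
        New-bond interaction factor (>= 0); ``q > 1`` attracts, ``q < 1``
        repels.
    r : float
        Existing-bond interaction factor (>= 0).
    entry_interaction : bool
        Whether the entry flux carries the new-bond factor
        ``1 + (q-1) z_{ell+1}`` for a neighbour whose reader sits at site
        ``ell + 1`` (default True).  With ``False`` the entering particle is
        treated as interaction-free until it is on the lattice, i.e.
        ``f_0 = lam_0 (1 - w_ell)``.  The two conventions coincide whenever
        ``q = 1`` or no neighbour can occupy site ``ell + 1``; published
        steady-state curves for strongly interacting lattices exist under
        both, so the choice is exposed explicitly.
    """

    n: int
    ell: int
    lam: np.ndarray
    alpha: np.ndarray
    q: float = 1.0
    r: float = 1.0
    entry_interaction: bool = True

    def __post_init__(self):
        n = int(self.n)
        ell = int(self.ell)
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        if not 1 <= ell <= n:
            raise ValueError(f"ell must satisfy 1 <= ell <= n, got ell={ell}, n={n}")
        lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if lam.shape != (n + 1,):
            raise ValueError(f"lam must have length n+1={n + 1}, got {lam.shape}")
        if alpha.shape != (n,):
            raise ValueError(f"alpha must have length n={n}, got {alpha.shape}")
        if not np.all(lam > 0):
            raise ValueError("all transition rates lam must be > 0")
        if not np.all(alpha >= 0):
            raise ValueError("all detachment rates alpha must be >= 0")
        if self.q < 0 or self.r < 0:
            raise ValueError("interaction factors q, r must be >= 0")
        lam.setflags(write=False)
        alpha.setflags(write=False)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "ell", ell)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "q", float(self.q))
        object.__setattr__(self, "r", float(self.r))

    @classmethod
    def from_energy(cls, n, ell, lam, alpha, E, entry_interaction=True):
        """Build parameters from an interaction energy ``E`` (k_B*T = 1).

        The energy is split equally between bond creation and breaking:
        ``q = exp(E/2)``, ``r = exp(-E/2)``, so ``q*r = 1`` exactly.
        ``E > 0`` means attraction, ``E < 0`` repulsion, ``E = 0`` none.
        """
        E = float(E)
        return cls(n=n, ell=ell, lam=lam, alpha=alpha,
                   q=float(np.exp(E / 2.0)), r=float(np.exp(-E / 2.0)),
                   entry_interaction=entry_interaction)

    @classmethod
    def homogeneous(cls, n, ell, lam=1.0, alpha=0.0, q=1.0, r=1.0, lam0=None,
                    entry_interaction=True):
        """Uniform rates; ``lam0`` optionally overrides the entry rate."""
        lam_vec = np.full(n + 1, float(lam))
        if lam0 is not None:
            lam_vec[0] = float(lam0)
        return cls(n=n, ell=ell, lam=lam_vec, alpha=np.full(n, float(alpha)),
                   q=q, r=r, entry_interaction=entry_interaction)

    @property
    def energy(self) -> float:
        """Interaction energy implied by the equal-split convention.

        Under ``q = exp(E/2)``, ``r = exp(-E/2)`` the energy is recovered as
        ``E = log(q/r)``; for independently chosen factors this is the
        energy of the nearest equal-split pair.
        """
        return float(np.log(self.q / self.r))

    def with_rates(self, lam=None, alpha=None, q=None, r=None):
        """Copy with some rates replaced (shape-checked by the constructor)."""
        kw = {}
        if lam is not None:
            kw["lam"] = np.asarray(lam, dtype=float)
        if alpha is not None:
            kw["alpha"] = np.asarray(alpha, dtype=float)
        if q is not None:
            kw["q"] = q
        if r is not None:
            kw["r"] = r
        return replace(self, **kw)


def coverage(x, ell):
    """Coverage densities ``y_i = sum_{j=max(1,i-ell+1)}^{i} x_j``.

    A particle whose reader sits at site ``j`` covers sites
    ``j..j+ell-1``; ``y_i`` sums the readers of the ``ell`` windows that
    reach site ``i``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a 1-D state vector")
    n = x.shape[0]
    ell = int(ell)
    if not 1 <= ell <= n:
        raise ValueError(f"ell must satisfy 1 <= ell <= n, got ell={ell}, n={n}")
    if ell == 1:
        return x.copy()
    return np.convolve(x, np.ones(ell))[:n]


def coverage_matrix(n, ell):
    """The banded 0/1 matrix ``P`` with ``y = P @ x``.

    Lower triangular with ones on the main diagonal and the ``ell-1``
    diagonals below it.
    """
    if not 1 <= ell <= n:
        raise ValueError(f"ell must satisfy 1 <= ell <= n, got ell={ell}, n={n}")
    P = np.zeros((n, n))
    for d in range(ell):
        P += np.diag(np.ones(n - d), -d)
    return P


def _padded(x, y, n, ell):
    """Zero-padded reader/coverage arrays.

    Site ``i`` (1-based, any ``i`` in ``[1-ell-1, n+ell+1]``) maps to index
    ``pad + i - 1`` with ``pad = ell + 1``; out-of-lattice sites read 0.
    """
    pad = ell + 1
    z = np.zeros(n + 2 * pad)
    z[pad:pad + n] = x
    w = np.zeros(n + 2 * pad)
    w[pad:pad + n] = y
    return z, w, pad


def _fluxes(x, p: LatticeParams):
    """Site fluxes ``f_0..f_n`` and detachment terms ``g_1..g_n``."""
    n, ell, q, r = p.n, p.ell, p.q, p.r
    y = coverage(x, ell)
    z, w, pad = _padded(x, y, n, ell)
    # slices over i = 1..n; site i+k lives at index pad + i + k - 1
    z_ahead_new = z[pad + ell: pad + ell + n + 1][1:]      # z_{i+ell+1}
    z_ahead = z[pad + ell - 1: pad + ell - 1 + n + 1][1:]  # z_{i+ell}
    z_behind = z[pad - ell - 1: pad - ell - 1 + n + 1][1:]  # z_{i-ell}
    w_ahead = w[pad + ell - 1: pad + ell - 1 + n + 1][1:]  # w_{i+ell}

    f = np.empty(n + 1)
    f[0] = p.lam[0] * (1.0 - w[pad + ell - 1])
    if p.entry_interaction:
        f[0] *= 1.0 + (q - 1.0) * z[pad + ell]
    f[1:] = (p.lam[1:] * x
             * (1.0 - w_ahead)
             * (1.0 + (q - 1.0) * z_ahead_new)
             * (1.0 + (r - 1.0) * z_behind))
    g = (p.alpha * x
         * (1.0 + (r - 1.0) * z_ahead)
         * (1.0 + (r - 1.0) * z_behind))
    return f, g


def efeiod_rhs(x, p: LatticeParams, t=0.0):
    """Time derivative of the reader densities.

    ``dx_i/dt = f_{i-1}(x) - f_i(x) - g_i(x)`` with

    - entry flux    ``f_0 = lam_0 (1 - w_ell)(1 + (q-1) z_{ell+1})``,
    - site fluxes   ``f_i = lam_i x_i (1 - w_{i+ell})
      (1 + (q-1) z_{i+ell+1})(1 + (r-1) z_{i-ell})``,
    - drop-off      ``g_i = alpha_i x_i (1 + (r-1) z_{i+ell})
      (1 + (r-1) z_{i-ell})``,

    where ``z``/``w`` equal the reader/coverage densities on the lattice and
    0 outside it.  ``t`` is accepted (and ignored) so the same evaluator
    serves constant and time-varying parameter schedules.

    With ``q = r = 1``, ``ell = 1`` and ``alpha = 0`` this reduces to the
    classical ribosome flow model field
    ``lam_{i-1} x_{i-1} (1 - x_i) - lam_i x_i (1 - x_{i+1})``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (p.n,):
        raise ValueError(f"state must have shape ({p.n},), got {x.shape}")
    f, g = _fluxes(x, p)
    return f[:-1] - f[1:] - g


def output_rate(x, p: LatticeParams):
    """Instantaneous exit flux ``R = (lam_n + alpha_n) x_n (1 + (r-1) x_{n-ell})``.

    For ``ell = n`` the trailing-neighbour index ``n - ell`` falls off the
    lattice and the interaction factor is 1.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (p.n,):
        raise ValueError(f"state must have shape ({p.n},), got {x.shape}")
    behind = x[p.n - p.ell - 1] if p.n - p.ell >= 1 else 0.0
    return float((p.lam[p.n] + p.alpha[p.n - 1]) * x[p.n - 1]
                 * (1.0 + (p.r - 1.0) * behind))


def in_state_space(x, ell, tol=1e-12):
    """Membership in the invariant set ``H``.

    True iff every reader density and every coverage density lies in
    ``[0, 1]`` (up to ``tol``, which absorbs integrator round-off).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a 1-D state vector")
    lo, hi = -tol, 1.0 + tol
    if x.min(initial=0.0) < lo or x.max(initial=0.0) > hi:
        return False
    y = coverage(x, ell)
    return bool(y.min(initial=0.0) >= lo and y.max(initial=0.0) <= hi)
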