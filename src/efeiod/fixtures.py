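"""Reproducible random instances for property tests and demos.

Rates are drawn from documented distributions — ``lam ~ U[0.1, 2]``,
``alpha ~ U[0, 0.2]``, interaction energy ``E ~ U[-3, 3]`` — and feasible
initial states are built constructively so that every reader *and* coverage
density lands in [0, 1].
"""

from __future__ import annotations

import numpy as np

from .core import LatticeParams, in_state_space

__all__ = ["generate_fixture", "random_feasible_state"]


def random_feasible_state(n, ell, rng):
    """A random point of the state space H, built site by site.

    Site ``i`` can take at most ``1 - max(coverage over the windows that
    contain i)``; sampling uniformly below that slack keeps every coverage
    sum within [0, 1] by construction.
    """
    x = np.zeros(n)
    for i in range(n):
        # every coverage window that will contain site i+1 gains x[i];
        # cap it by the fullest of those windows so far
        worst = max(np.sum(x[max(0, j - ell + 1):i])
                    for j in range(i, min(i + ell, n)))
        x[i] = rng.uniform(0.0, max(0.0, 1.0 - worst))
    return x


def generate_fixture(n, ell, seed, regime="random"):
    """A (parameters, feasible initial state) pair.

    ``regime``:

    - ``random``: heterogeneous rates, moderate interaction energy;
    - ``bottleneck``: one interior transition rate two orders of magnitude
      below the rest (traffic-jam scenario);
    - ``homogeneous``: all transition rates equal, all drop-off rates equal,
      no interactions.
    """
    if not 1 <= ell <= n:
        raise ValueError(f"ell must satisfy 1 <= ell <= n, got ell={ell}, n={n}")
    rng = np.random.default_rng(seed)
    if regime == "random":
        lam = rng.uniform(0.1, 2.0, n + 1)
        alpha = rng.uniform(0.0, 0.2, n)
        E = rng.uniform(-3.0, 3.0)
        p = LatticeParams.from_energy(n, ell, lam, alpha, E)
    elif regime == "bottleneck":
        lam = np.ones(n + 1)
        lam[int(rng.integers(1, n))] = 0.01
        p = LatticeParams(n, ell, lam, np.zeros(n),
                          q=float(rng.uniform(1.0, 10.0)))
        p = p.with_rates(r=1.0 / p.q)
    elif regime == "homogeneous":
        p = LatticeParams.homogeneous(
            n, ell, lam=float(rng.uniform(0.5, 1.5)),
            alpha=float(rng.uniform(0.0, 0.2)))
    else:
        raise ValueError(f"unknown regime {regime!r}")
    x0 = random_feasible_state(n, ell, rng)
    assert in_state_space(x0, ell)
    return p, x0
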