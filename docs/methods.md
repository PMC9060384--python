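# Methods

## Model

The package implements a deterministic, nonlinear compartmental model of
unidirectional transport of extended, interacting, detachable particles on a
one-dimensional lattice of `n` sites — ribosomes translating an mRNA,
molecular motors walking a filament.  A particle covers `ell` consecutive
sites and is tracked by its *reader*, the leftmost covered site.  The state
is the vector of reader densities `x_1..x_n in [0,1]`; the coverage density
`y_i = sum_{j=max(1,i-ell+1)}^{i} x_j` is the probability that site `i` is
covered by any part of a particle.

The dynamics are `dx_i/dt = f_{i-1} - f_i - g_i` with

```
f_0 = lam_0 (1 - w_ell) (1 + (q-1) z_{ell+1})
f_i = lam_i x_i (1 - w_{i+ell}) (1 + (q-1) z_{i+ell+1}) (1 + (r-1) z_{i-ell})
g_i = alpha_i x_i (1 + (r-1) z_{i+ell}) (1 + (r-1) z_{i-ell})
```

where `z`/`w` equal `x`/`y` on the lattice and zero outside it.  `lam_i > 0`
are transition rates, `alpha_i >= 0` site-specific drop-off rates, and the
dimensionless factors `q` (new bond, at distance `ell+1` ahead) and `r`
(existing bond, at distance `ell`) encode nearest-neighbour attraction
(`>1`) or repulsion (`<1`).  Thermodynamic consistency ties the two to an
interaction energy split equally between bond creation and breaking:
`q = exp(E/2)`, `r = exp(-E/2)` (k_B T = 1), so `r = 1/q`.  The exit flux is
`R = (lam_n + alpha_n) x_n (1 + (r-1) x_{n-ell})`, read as the protein
production rate in the translation interpretation.

The invariant state space is `H = {x : x in [0,1]^n, Px in [0,1]^n}` with
`P` the banded coverage matrix: box feasibility alone is *not* invariant
(a feasible-box start with coverage above 1 can push densities above 1,
which the tests demonstrate), while `H` is forward invariant with a
repelling boundary.  For `q, r > 0` the flow is contractive in L1 after an
arbitrarily short transient, which gives a unique globally asymptotically
stable equilibrium and, for T-periodic rates with transition rates uniformly
bounded in `[delta1, delta2]`, a unique attracting T-periodic orbit.

## Solvers and numerical choices

* **Equilibrium** (`find_steady_state`): integrate from the interior point
  `x_i = 1/(2 ell)` with LSODA (rtol 1e-10, atol 1e-12) in chunks until the
  field's max-norm is small, then polish with a damped Newton iteration on
  the vector field using a central finite-difference Jacobian, to residual
  1e-12 by default.  Global convergence of the integration phase is
  guaranteed by contraction; Newton supplies the final digits cheaply.
  `q = 0` or `r = 0` is refused (a continuum of equilibria exists there,
  e.g. `[1, 1, v]` on a 3-site chain) while `simulate` still integrates
  those dynamics.
* **Strong interactions**: when `max(|log q|, |log r|) > 3` the solver walks
  a geometric homotopy `(q^s, r^s)`, `s: 0 -> 1`, warm-starting Newton at
  each step.  This keeps energies up to `E = 25` (q ~ 2.7e5) fast and
  stable; saturation claims are verified by comparing `E = 20` against
  `E = 25`.  Energies are capped at 25 by convention to avoid overflow.
* **Shooting solver** (q = r = 1 only): the steady state satisfies
  `e_n = R/(lam_n + alpha_n)` and, upstream,
  `e_i = (R + sum_{k=i+1}^{n-1} alpha_k e_k) / (lam_i (1 - y_{i+ell}))`,
  with the initiation-site consistency condition
  `y_ell = (lam_0 - R - sum_{k<n} alpha_k e_k)/lam_0`.  A scalar root-find
  on `R in (0, lam_0)` (bisection to bracket, Brent to refine, infeasible
  trials counted as +inf residual) solves the chain.  This is an
  independent second route to the equilibrium and agrees with the ODE route
  to 1e-6 on random instances.
* **Sensitivities**: central finite differences with relative step
  `1e-5 * max(1, |gamma_j|)`, shrunk automatically when a rate would go
  nonpositive; the equilibrium map is differentiable in every rate, so this
  is adequate without Richardson refinement.
* **Periodic schedules**: constant-plus-single-sinusoid per parameter (the
  serialisable grammar); orbits are sampled 64 points per period and the
  entrainment diagnostic is the sup-norm gap between the last two periods.
  Integrator steps are independent of the sampling grid.
* **Indexing**: sites are 1-based in all I/O; out-of-lattice densities are
  implemented by guarded zero-padding internal to the evaluator.

## The entry-interaction convention

For the entry flux there are two defensible conventions: the entering
particle either feels the new-bond factor `(1 + (q-1) z_{ell+1})` toward a
neighbour parked immediately downstream of its landing footprint
(`entry_interaction=True`, the default, matching the displayed equations
above) or it enters interaction-free (`entry_interaction=False`).  The two
coincide unless `q != 1` *and* a neighbour can sit at site `ell+1`.  The
choice matters in strongly attracting short chains: with the factor, the
3-site, footprint-2 chain's output rate decays to zero as `E -> inf`; with
interaction-free entry it saturates at 0.1910 (drop-off 0), 0.1720 (0.5),
0.1267 (1).  Published steady-state curves for such lattices exist under
both conventions, so the flag is exposed on `LatticeParams` and each
computation states which it uses.  With `q = 1` (the whole translation
specialisation) the flag is irrelevant.

## Stochastic validator

The q = r = 1 model is a mean-field approximation of a continuous-time
exclusion process with extended particles and site-wise detachment.  The
validator simulates that process exactly with the Gillespie direct method
(statistically equivalent to per-site exponential clocks): entry at rate
`lam_0` gated on sites `1..ell` all vacant, reader hops at `lam_i` gated on
site `i+ell` vacant (unconditional in the last `ell` sites, whose tail is
off-lattice), exit when the reader hops from site `n`, and whole-particle
detachment at `alpha_i` with no exclusion constraint.  Occupancy is
integrated over inter-event waiting times (not per-event sampling), with a
configurable burn-in discarded.  Replicates use independent child streams
of one seed, so runs are bit-reproducible.

Correctness is pinned by an exact oracle: for footprint 1, 5 sites and unit
rates the simulated flux reproduces the known combinatorial stationary
current `C_5/C_6 = 42/132 = 0.3182` of the finite open chain within Monte
Carlo error.

**What agreement with mean-field does and does not show.**  Mean-field
treats reader densities as independent.  For extended particles this
overstates blocking near the entry: conditional on a reader at site 1
(covering sites `1..ell`), readers at sites `2..ell` are impossible, so the
true conditional coverage ahead is far below the product approximation.  At
a 15-site, footprint-3 chain with slow entry the stochastic profile is
therefore systematically flatter (~0.083 versus 0.090–0.100 upstream) even
though both profiles share every qualitative feature (drop-off dip,
pre-exit dip, exit pile-up) and agree within 0.017 per site.  Because the
profiles are nearly flat, the Pearson correlation between them is an
unforgiving statistic (~0.6) dominated by this structural offset rather
than by Monte Carlo noise (per-site SE ~ 2e-4 at 10^6 events x 4
replicates).  A high correlation should not be expected from a faithful
extended-object exclusion simulation in this regime; the per-site deviation
band is the meaningful agreement measure.  Desk-scale defaults (10^6
events, 10^4 burn-in, 4 replicates) were chosen to resolve a 15-site
profile to a few per mille; longer production runs only shrink the noise,
not the structural offset.

## Synthetic fixtures

Random instances draw `lam ~ U[0.1, 2]`, `alpha ~ U[0, 0.2]` and
`E ~ U[-3, 3]` — heterogeneous but moderate rates of the kind the model is
meant for; `bottleneck` instances plant one transition rate at 0.01 to
emulate a slow codon/defect site, and `homogeneous` instances have uniform
rates.  Feasible initial states are built site-by-site, capping each reader
density by the fullest coverage window it joins, which guarantees
membership in `H` by construction.  These fixtures exercise the solvers
across regimes but are not calibrated to any organism's measured rates;
passing tests demonstrate the mathematical properties (invariance,
contraction, monotonicity), not biological accuracy of specific rate
values.

## Known limitations

* The general interacting model has no closed-form steady state; all
  general-`(q, r)` results are numerical.
* Thermodynamic-limit phase formulas for the extended-object exclusion
  process are not implemented; only the finite-chain monotone decay of flux
  and density with footprint is tested.
* The stochastic validator covers q = r = 1 only; no stochastic counterpart
  of the interacting model is provided.
* Minimality of a declared schedule period is not verified.
* One published reference value (9 sites, footprint 1, q = 13: 0.0808)
  could not be reproduced from the displayed equations under any convention
  tried (computed: 0.0696, stable across both solver routes); the
  footprint-2 and footprint-3 values from the same figure reproduce to all
  printed digits.
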