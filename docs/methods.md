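# Methods

This note documents the model, the sharp-switch decomposition algorithm,
the finite-Hill numerical pipeline, and the numerical and design choices
behind them.  Nothing here is asserted beyond what the test suite and
`scripts/acceptance.py` actually compute.

## Model

Two cells exchange free mRNA and protein of an autoregulatory factor; the
protein switches on (i) the immobilization of its own mRNA (threshold
`theta1`, Hill exponent `n`) and (ii) its own translation (threshold
`theta2`, exponent `nu`).  The package carries three equivalent levels:

* a six-variable dimensional system (unbound mRNA, bound mRNA, protein per
  cell), used only as a consistency oracle;
* its four-variable reduction under a rapid-equilibrium approximation of
  binding/unbinding, valid when `k_plus, k_minus` are fast — tested by
  integrating the full system with binding rates scaled up a thousandfold;
* the nondimensionalized four-variable system `(M1, M2, P1, P2)` with the
  eight groups `theta1, theta2, mu, gamma, eta, kappa, pi, epsilon`, on
  which all analysis operates.  Time is measured in units of the maximal
  intercellular mRNA transport rate.

Exchange symmetry (swapping the cells permutes the equations) holds at
every level; at any steady state of the scaled system `M1 + M2 = 2/mu`,
and the two cells hold equal mRNA iff they hold equal protein.

**Parameter domain.**  The eight groups are positive and, because `kappa =
K/(1+K0)` and `eta = K/K0` are ratios of the same induced-binding constant
`K` with `K0 > 0`, every physically realizable set satisfies `eta >
kappa`.  The sharp-switch catalog is therefore computed over the open cone
`{eta > kappa}` of the positive orthant.  This constraint matters: over
eight fully independent coordinates the decomposition would also contain
an empty configuration and purely asymmetric configurations, while over
the physical cone every realizable configuration contains at least one
symmetric attractor, and the counts come out at 40 configurations and 70
regions.  The finite-Hill sampling studies, by contrast, treat the box
`[0.01, 3]^8` with all coordinates independent (the benchmark parameter
set itself has `eta < kappa`); the two steps of the framework intentionally
use these two domains.

## Sharp-switch decomposition

With Heaviside switches the positive `(P1, P2)` quadrant splits into 9
domains (3 threshold intervals per coordinate, indexed `3*c2 + c1`; the
toy model has 2).  Substituting the 0/1 switch values into the equations
gives an affine system `x' = Ax + c` per domain whose matrix is provably
Hurwitz for all positive parameters (block-triangular: mRNA dynamics relax
independently of protein), with closed-form fixed point `f = -A^{-1}c`
computed symbolically.  A domain is *attracting* iff the protein
coordinates of `f` lie inside the domain's threshold intervals — a
conjunction of strict inequalities between rational functions of the six
non-threshold parameters (the *wall values*, 9 distinct expressions) and
the thresholds.

The set of attracting domains is hence constant on each cell of the
arrangement obtained by classifying every wall value as below `theta_low`,
between the thresholds, or above `theta_high`.  The decomposition then
proceeds:

1. **Provable wall orderings.**  For every ordered wall pair the package
   tries to prove `w_i < w_j` over the parameter cone by substituting
   `eta = kappa + delta` (`delta > 0`) and checking that the difference is
   a ratio of polynomials with positive coefficients.  24 of the 72 pairs
   are provable for `theta2 < theta1`; they prune the 3^9 candidate bin
   assignments to 224.
2. **Sampling certification.**  400,000 log-uniform parameter samples over
   `[e^-9, e^9]^6` (with `eta = kappa + delta` to cover the cone) are
   reduced to their distinct wall orderings; each ordering certifies every
   threshold placement in its gaps as a feasible cell, and every placement
   with one threshold pinned at a wall as a realizable codimension-1
   boundary between two cells.  Every hit stores a constructive witness
   point with its log-scale slack.
3. **Slack maximization.**  Candidates not certified by sampling are
   decided by maximizing the minimum log-slack of their defining
   inequalities over log-parameters (SLSQP, multi-start, deterministic
   seeds); slack above `1e-6` certifies feasibility, convergence to
   nonpositive slack from all starts declares infeasibility, anything in
   between is flagged inconclusive (the catalog refuses to silently drop
   it; at the default settings nothing is flagged).
4. **Configurations and regions.**  Feasible cells map to attractor sets
   through the derived conditions; a configuration's connected components
   are the components of its cell graph under certified boundaries.
   Region labels are `<config>:<component>` with configurations ordered by
   attractor bitmask and components by their lexicographically smallest
   cell; single-component configurations drop the suffix.

The procedure is one-sidedly rigorous: every feasibility claim and every
edge carries an explicit witness, while infeasibility and non-adjacency
rest on the budgeted numerical search (no cylindrical algebraic
decomposition is attempted).  The acceptance checks — 40 configurations,
70 regions, graph diameter 9 — validate the search end to end, and the
partition property test confirms on 10^5 random cone points that the
catalog's cells cover parameter space.

**Region adjacency.**  Since thresholds are free coordinates, a pinned
threshold-wall coincidence with all other constraints slack is a
transversal codimension-1 interface; an edge joins the two regions on its
sides.  Graph distance counts edges (adjacent regions are at distance 1).

**The benchmark region.**  The reference inequality chain used for density
studies (`Cl < theta2 < 1/(mu*pi)`, `1 < g2 < mu*pi*theta1 < Ch`, with
`g2` the all-on production gain and `Ch/Cl` the high/low protein
coordinates of the mixed high-low domain) is, over the physical cone,
exactly the union of two catalog regions that differ in whether the
high-middle attractor pair is present: the position of one wall (the
middle-cell protein coordinate of the high-middle domain) relative to
`theta2` is not fixed by the chain.  The package proves this equivalence
order-theoretically from the provable wall relations
(`verify_region16_equivalence`); density studies over "the benchmark
region" sample the chain itself, matching its stated definition.

## Finite-Hill exploration

Stable steady states of the finite-`n` system are enumerated per parameter
set by:

* **Initial conditions** — 34 starts: a 5x5 grid over `(P1, P2) in
  {0.2*theta2, theta2, (theta1+theta2)/2, theta1, 2*theta1}^2` with
  `M1 = M2 = 1/mu`, plus the nine sharp-switch domain fixed points, which
  place a start near every possible attractor location.
* **Relaxation** — a compiled Dormand-Prince 4(5) integrator with
  per-trajectory adaptive steps, horizon `1e4` time units, stopping when
  `max |dx/dt| < 1e-8`; trajectories that fail to settle are counted and
  skipped (rare).  Hill factors are evaluated as `1/(1 + (theta/x)^n)`,
  which neither overflows at large states and exponents nor loses the
  exact half-activation value at threshold.
* **Certification** — endpoints are deduplicated, polished with a
  Newton-type solver to residual `1e-9` (relative to state scale), tested
  for stability through the analytic Jacobian's spectral abscissa
  (strictly negative required), and deduplicated at relative `1e-4`.
* **Classification** — a state is asymmetric when `|P1 - P2| >
  1e-3 * max(P1, P2, theta2)` (scale-aware, far below the separation of
  genuinely symmetry-broken branches); a parameter set is
  `asymmetric_only` / `symmetric_only` / `mixed` according to its stable
  set.  Asymmetric states always appear in swap pairs (asserted).

Density studies draw uniform samples from `[0.01, 3]^8` (rejection
sampling against region inequalities where requested) with a recorded
seed, and report the proportion of `asymmetric_only` sets.  Problem sizes
follow the reference protocol: 1000 accepted sets for the benchmark
region; the box-wide study runs at 2000 samples in the test suite (the
full 10^4-sample rate is about 6 in 10^4, so the scaled run expects about
1.2 hits and asserts a Poisson-consistent bound).

**Toy model.**  The one-variable autocatalytic model `X' = b + h(X;
theta, n) - gamma*X` has regions D1 (`b > gamma*theta`, high state only),
D2 (bistable) and D3 (low state only) in the sharp limit.  Finite-`n`
stable states come from a sign-change scan plus bisection (400-point
grid; results are grid-independent against a 4000-point control), with
stability from the derivative sign, cross-checked by an independent
LSODA-integration route.  Preservation proportions evaluate the same 1000
sampled sets per region at `n = 5, 10, 20`; the bistable region's
preservation grows with `n` (monotone sharpening), the monostable regions
are always preserved.

## Known limitations

* Infeasibility/non-adjacency decisions are search-based; a pathologically
  thin cell could in principle be missed (mitigated by the 18-decade
  sampling range, the multi-start optimizer and the end-to-end count
  checks).
* Attractors of the Heaviside limit that live *on* threshold lines
  (sliding states) are outside the catalog's notion of configuration; at
  finite `n` their descendants are found by the numerical explorer but are
  not predicted by the sharp-switch step.
* The explorer certifies only stable equilibria; limit cycles, if any
  existed, would be reported as non-convergent starts (none are observed
  at the study settings).
* Trajectory-level behavior (basin sizes, selection times) is out of
  scope; classification asks only which stable states exist.
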