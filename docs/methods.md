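# Methods

## Model

A population structure is a connected, undirected, weighted graph with no
self-loops and strictly positive weights; every node hosts exactly one
individual, resident (fitness 1) or mutant (fitness `r > 0`). One
replacement happens per discrete time step:

- **Bd**: reproducer `u` drawn with probability `f(u)/F`; offspring
  replaces neighbour `v` with probability `w(u,v)/deg(u)`.
- **dB**: `v` dies with probability `1/N`; neighbour `u` fills the
  vacancy with probability `f(u)w(u,v) / Σ_{u'} f(u')w(u',v)`.

Fitness acts only in the birth step. Replacements that copy a type onto
itself are counted as steps; absorption is reached at the all-resident or
all-mutant configuration. The uniform-initialization fixation probability
is the mean of the `N` single-mutant probabilities.

## Exact solvers

**Full state.** Configurations are N-bit integers. For each transient
configuration the per-node flip probabilities are read off the one-step
event matrix; the absorption system `(D − Q)x = b` (D the row sums of the
flip transitions, b the one-step mass into the all-mutant state) is solved
with `scipy.sparse.linalg.spsolve`. Self-loop mass cancels out of the
system, so no-change steps need no special handling. The backend is
capped at `N ≤ 20` (≈10⁶ states); beyond that a `CapacityError` points to
the lumped and Monte Carlo backends. Solver tolerance is that of the
sparse LU direct solve, recorded as 1e−12 in result metadata; observed
agreement with closed forms is ~1e−15.

**Symmetry-lumped.** Family constructors attach a `SymmetrySpec`
partitioning the nodes into individually tracked nodes, exchangeable
singles (only the mutant count matters), and exchangeable two-node blades
(only the multiset of per-blade counts matters). Orbit classes are
discovered by breadth-first search from the initial configurations, with
transitions computed on one stored representative per class; the same
linear absorption solve then runs on the class space. Exact lumpability
is a property of the declared automorphisms and is *verified*, not
assumed: `verify_lumpability` exhaustively checks, on instances small
enough to enumerate, that every configuration in a class has the same
class-transition distribution. The suite runs this for all four families
(complete, star, fan, composite) under both rules, and additionally
checks lumped ≡ full-state to 1e−10 on every family at `N ≤ 12`.

Class counts: star `S_N` has `2(N−1)` classes; the 26-node composite
instance has 8 820 reachable classes against 2²⁶ ≈ 6.7e7 raw
configurations (solve time ~10 s).

**Monte Carlo.** Seeded independent trajectories with per-replicate
seeds derived from the master seed; an optional numba kernel (NumPy
fallback implements the identical process) samples the O(N) categorical
birth/death choices per step. Truncated replicates (hitting `max_steps`,
default unlimited) are reported separately and excluded from the
estimate. Standard errors are binomial normal-approximation;
Clopper–Pearson 95% intervals are available via `ci_method`.

## Closed forms and first-step quantities

`rho_complete` evaluates the complete-graph formulas through `expm1` for
stability near `r = 1`; the `r = 1` singularity is resolved analytically
to `1/N`, never by perturbation.

The neutral (r = 1) single-start formulas — Bd:
`(1/deg v)/Σ(1/deg u)`, dB: `deg v/Σ deg u` — follow from a martingale
argument (weights `1/deg` resp. `deg` make the mutant mass a martingale
under the respective rule). Because they are reconstructed rather than
taken from a printed source, they are gated behind an oracle-equivalence
test against the full-state solver on 200 seeded random weighted graphs
(max |error| observed ~1e−14) before anything else relies on them.

First-step survival `γ(G, u)` is computed generically by conditioning the
one-step event distribution on configuration-changing events. The Bd
closed form `r/(r + T(u))` and the dB form `S/(1+S)` with
`S = Σ_{v∼u} r·w(u,v)/(deg v + (r−1)w(u,v))` are cross-checked fast
paths. Note the isothermal extension holds for Bd only: on a k-regular
graph `γ_dB = kr/(kr + k + r − 1)` depends on k, so e.g. cycles sit
strictly below the complete graph on the dB side — the trichotomy checker
reports `dB-below` there, which is the correct branch.

Trichotomy checks use absolute tolerance 1e−12 on closed-form quantities;
amplifier verdicts from exact/lumped backends use 1e−9 (far below any
real amplification effect, far above solver noise); Monte Carlo verdicts
use a 99% confidence rule and return `inconclusive` when the interval
straddles the baseline.

## Graph families

`make_complete`, `make_star` are unweighted. `make_fan(m, c)` builds the
weighted fan: m two-node blades with internal weight 1, each blade node
tied to the center with small coupling `c` (default 0.01, which at
`N = 11` reproduces the fan's dB-amplification across `r = 1.01..1.10`).

`make_amplifier_AN(ANParams(a, b, f, t))` builds the composite graph on
`N = a + 2b + f` nodes: a Bd chunk (hub clique of `a` nodes, `b` blades,
blade–hub coupling defaulting to `1/t`) and a fan chunk with `f = 2m+1`
nodes, joined by a single edge `u–v` of weight `t⁻³`. Design choices made
where the construction was genuinely open:

- the fan's hub coupling is fixed at `1/(2m)`, which makes the total
  weight of `v`'s other edges exactly 1 with no rescaling;
- the Bd chunk is scaled *uniformly* so the total weight of `u`'s other
  edges is `t⁻¹` — uniform scaling leaves within-chunk dynamics
  untouched and keeps the non-`u` hub nodes exchangeable, which the
  lumped solver requires;
- `u` is a hub node (`hub-0`); hub nodes interconnect as a unit-weight
  clique and every blade node couples to every hub node, the same
  rare-interaction motif as the fan;
- default `t = 100`: well inside the "large separation" regime while all
  weights (`t⁻³ = 1e−6`) remain comfortably above float noise.

These interior weights are a faithful parametrized reconstruction of the
two-chunk design, not a verbatim copy of any published weight table; the
weight contract at the connecting edge (`w(u,v) = t⁻³`, totals `t⁻¹` and
1 at the two endpoints) is tested to 1e−12.

## Chunk-coupling model of the composite amplifier

Because the chunks interact only at order `t⁻²` relative to within-chunk
dynamics, the process is well approximated by a four-state absorbing
chain: all-resident, Bd-chunk fixed ("half done"), fan fixed, all-mutant.
Inputs are computed, never fitted: chunk fixation and invasion
probabilities from exact lumped solves on the isolated chunks (the lone
invader enters at `u` resp. `v`; resident re-invasion is one minus mutant
re-fixation from the complement), and migration rates from the exact
one-step event matrix of the full graph at the two half-done
configurations. From a half-done state the decisive event is a race
between successful invasions in each direction, so the coarse chain's
jump probabilities are the normalized products `migration × invasion
success`.

The model exposes the paper-level mechanism directly: at the half-done
configurations the computed migration rates satisfy `p_{u→v} ≈ r·t·
p_{v→u}` under Bd and `p_{v→u} ≈ (t/r²)·p_{u→v}` under dB — the offspring
flow across the connecting edge reverses with the update rule, so
whichever chunk has fixed is effectively upstream and consolidates. On
the 26-node instance (`a = b = 5, f = 11, t = 100`) at `r = 1.1` the model
matches the exact lumped solution to ~1e−5 relative; the test asserts a
pre-stated factor-2 slack appropriate for a coarse-grained approximation.

## Synthetic data

`random_connected_weighted_graph(N, density, weight_range, seed)` grows a
uniform random attachment tree (guaranteeing connectivity) and adds each
remaining pair independently with the given density; weights are
log-uniform on `(0.2, 5.0)` by default so heavy and light interactions
both occur. These fixtures emulate arbitrary small structured
populations for the cross-validation and trichotomy sweeps; they do not
emulate any particular empirical contact network, degree distribution or
scale — passing sweeps show the identities and impossibility statements
hold across random weighted topologies at `N ≤ 8`, not that any specific
real population amplifies.

## Problem sizes

The default suite and the acceptance script run at desk scale: full-state
solves at `N ≤ 12` (the `N = 11` star/fan sweeps are 2¹¹-state solves),
lumped solves up to the 26-node composite instance, 200-graph
closed-form cross-validations, 500-graph trichotomy sweeps, and Monte
Carlo at 10³–10⁵ replicates. The composite construction at the
published-scale `N = 1001` (where simultaneous amplification appears) is
out of desk range for these backends: the full chain is astronomically
large and the product-orbit lumped space still has ~1e13 classes. The
package constructs the graph at any size; verifying amplification there
would need a coarser aggregation or very long simulation campaigns, which
we deliberately leave out.

## Known limitations

- Undirected graphs only; no self-loops, no time-varying structure.
- The lumped backend requires a declared symmetry; arbitrary graphs fall
  back to full-state (`N ≤ 20`) or Monte Carlo.
- Monte Carlo trajectory *sequences* are backend-specific (numba vs
  NumPy RNG streams differ); estimates, seeds and reproducibility
  contracts hold within a backend.
- Fixation-time statistics and multi-mutant (`k ≥ 2`) initial conditions
  are out of scope.
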