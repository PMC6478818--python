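# Methods

## The process

`moranet` studies the discrete-time Moran birth–death process on a weighted
graph. A population of `N` individuals occupies the vertices of a connected
graph `G`; residents have fitness 1 and a single invading mutant lineage has
relative fitness `r > 0`. At every step:

1. an individual `u` is chosen to reproduce with probability proportional to
   its fitness, `f(u)/F` with `f(u) = r` for mutants and `1` for residents;
2. its offspring is placed on vertex `v` with probability `w(u, v)`, the
   per-source normalisation of the edge weights (the *replacement kernel*),
   and `v` adopts `u`'s type.

Every such event counts as one Moran step, including events that change
nothing — an offspring replacing an individual of its own type, and
self-loop replacements (`v = u`). This convention matters: on the
self-loop-heavy α-weighted bipartite graphs most steps are self-replacements,
and all reported times count them. `N` steps correspond to one generation.

The mutant lineage eventually either fixes (occupies all of `G`) or goes
extinct. The package computes, per starting vertex `v`:

- the fixation probability `ρ_v`,
- the absorption time `a_v` (expected steps until homogeneity),
- the conditional fixation time `τ_v` (expected steps over trajectories that
  fix) and its extinction-conditioned mirror, which satisfy the exact
  decomposition `a_v = ρ_v τ_v + (1 − ρ_v) τ̄_v`.

Initial placement is either **uniform** (`π(v) = 1/N`; spontaneous mutation)
or by **temperature** (`π(v) = t(v) = (1/N) Σ_u w(u, v)`; mutation during
reproduction, proportional to a vertex's replacement rate). Temperatures
include the self-loop term `w(v, v)` — a self-replacement is a replacement
event, and the sum over *all* reproducers `u` includes `u = v`. A switch
(`include_self_loops=False`) exposes the alternative convention, which
renormalises cross-vertex turnover only; it is not the default and changes
results materially on self-loop graphs.

Aggregated quantities are `ρ = Σ_v π(v) ρ_v` and `a = Σ_v π(v) a_v`. For the
conditional fixation time the package defaults to the fixation-weighted
mixture `τ = Σ_v π(v) ρ_v τ_v / Σ_v π(v) ρ_v`, which is the true conditional
expectation of the step count given fixation when the start vertex is itself
random; the plain mixture `Σ_v π(v) τ_v` is available as `tau_mode="plain"`.
The two differ whenever `ρ_v` varies across vertices (tested against a
trajectory-propagation oracle on a 3-vertex path).

## Solvers

**Full-state engine** (`exact`). The process is an absorbing Markov chain on
the `2^N` mutant configurations. The engine assembles the sparse one-step
matrix (vectorised over configurations), restricts to transient states and
solves three linear systems per graph — fixation probabilities, absorption
times, and `z = ρ·τ` for the conditional times — by dense LU below 2,048
states and sparse LU above. Self-transitions are retained so that times count
every step. Default cap: 14 vertices.

**Lumped solvers** (`lumped`). Within-part vertices of complete bipartite
graphs (and the trivial one-part complete graph) are automorphic by
construction, so the chain projects exactly onto mutant *counts*:

- complete graph → a 1-D birth–death chain on `k = 0..N`. Fixation
  probabilities use the γ-product formula in log space (robust for `r < 1`
  at large `N`); times solve the exact tridiagonal systems with a banded
  LAPACK solver. Neutral `r = 1` needs no special-casing in the linear
  systems; the closed-form `ρ` uses the `1/N` limit.
- complete bipartite with per-large-vertex self-loop weight ℓ → a 2-D chain
  on `(i, j)` mutant counts with `(m+1)(s+1)` states, solved by sparse LU.
  The star is the special case `(m, s, ℓ) = (N−1, 1, 0)`.

Lumped and full-state results agree to ~1e−12 on every family small enough
to solve both ways (asserted at 1e−8 in the tests). The 2-D chain reaches
populations of a few thousand (≈10⁶ states ~ 10 s, the practical ceiling on
one CPU with a direct factorisation).

**Monte Carlo** (`simulate`). For arbitrary graphs beyond exact reach.
Reproducer choice is two-level — mutant vs resident pool by aggregate
fitness, then uniform within the pool — which is distributionally identical
to per-individual sampling and O(1) per step; offspring placement inverts the
kernel-row CDF. The inner loop is numba-compiled. Optional *fast-forward*
samples the number of consecutive no-change steps from the geometric
distribution of the current configuration's hold probability (exact in
distribution; validated by a two-sample test against plain stepping) — it
pays off precisely on self-loop graphs. Per-run seeds derive from the master
seed by a counter scheme, so estimates are exactly reproducible given
`(graph, r, init, seed, n_runs)`. Standard errors come from run-level
variance; conditional fixation times are over fixing runs only. Defaults:
10⁵ runs for probabilities, 10⁴ when time estimates at larger `N` dominate
the budget.

## Graph families and enumeration

Constructors cover the structures used in the tradeoff analyses: complete
`K_N`, star `S_N`, complete bipartite with optional large-part self-loops,
the α-balanced bipartite family `B_{N,α}` (parts `N` and `round(N^{1−α})`),
the α-weighted family `W_{N,α}` (adds self-loops of exact weight
`N^{1−α/2} − N^{1−α}` to each large-part vertex), cycles, uniform random
labeled trees (Prüfer), connectivity-conditioned Erdős–Rényi graphs
(rejection sampling, 10,000-retry cap), and stars/cycles with extra random
edges. Part sizes round to the nearest integer (min 1) — the asymptotic
definitions never prescribe rounding — while self-loop weights stay exact
reals. For experiments at a fixed total population (e.g. `N = 100`), part
sizes are chosen by scanning `m` for `m + round(m^{1−α})` closest to the
total; a `large-part` convention (the asymptotic reading, `m = N`) is a
flag away.

`enumerate_connected_graphs(n)` generates one representative per isomorphism
class by vertex augmentation — every class on `k` vertices arises from a
class on `k−1` by attaching the new vertex to some subset — deduplicated by
BLISS canonical form (igraph) and emitted in sorted canonical-edge-encoding
order (deterministic; chosen over a lexicographically minimal bitstring for
speed). `count_connected_graphs(n)` is the analytic cross-check: a Burnside
cycle-index count of all unlabeled graphs followed by the inverse Euler
transform, in exact rational arithmetic. Both give 11,117 connected graphs
on 8 vertices (and 261,080 on 9).

## Numerical choices

- Linear systems: direct factorisations only (dense LU, sparse LU, banded
  tridiagonal); no iterative solvers, no tolerances to tune. Kernel rows are
  validated to sum to 1 within 1e−12.
- Classification ties (amplifier/accelerator vs the complete graph) within
  1e−10 yield no flag; Pareto dominance uses a 1e−12 tie tolerance.
- "log" in every timescale statement is the natural logarithm.
- Degenerate inputs raise `GraphError`: disconnected graphs (weak/strong
  connectivity checked at construction), absorbing start configurations,
  non-positive fitness, zero-weight edges, `n_runs = 1` flags undefined
  standard errors rather than raising.

## What the tests certify — and what they do not

The exhaustive `N = 8` sweep (11,117 exact solves, ~30 s) certifies the
finite-size tradeoff statements exactly: under uniform initialization the
complete graph minimises the conditional fixation time and the star
maximises `ρ`; under temperature initialization the complete graph attains
both extremes and all 17 regular graphs match its `ρ` to 1e−8 (isothermal
theorem). The absorption-time lower bound `(ρ/r) N ln N` is verified on
every connected graph of sizes 6 and 7.

Asymptotic statements are certified as *order-of-growth bands* at desk
scale, not as limits: `B_{N,0.5}`'s uniform-init `ρ` is within 0.02 of
`1 − 1/r²` by `N = 800` and its fixation time tracks `N^{1.5} ln N` within a
factor-2 band over `N ∈ {100..800}`. For `W_{N,0.5}` under temperature
initialization the time-scaling band holds identically, but the
fixation-probability limit is approached only at rate `≈ N^{−α/2}`
(`N^{−1/4}`): the measured gap is 0.047 at `N = 800` and still 0.0285 at
`N = 10,000`, the largest population the 2-D chain factorises directly.
Extrapolation puts the 0.02 mark near `N ≈ 4·10⁴`, beyond a direct sparse
factorisation's memory; the corresponding test asserts the 0.02 band at
`N = 10,000` and currently fails, intentionally — the gap, its decay rate
and its monotone approach are the quantitative content at reachable sizes.

The synthetic graph generators emulate the *structures* of the analyses, not
biological data: no spatial embedding, no heterogeneous fitness, no clonal
interference (the effective-rate measure assumes at most one segregating
mutant lineage — its `1/(t₁ + t₂)` form, `t₁ = 1/(Nμρ)`, `t₂ = τ/N`
generations, is meaningful only when `μ` is small enough that fixation
completes between mutant arrivals). Passing tests therefore validate the
process mathematics on those structures, not predictions about any
particular biological population.

Monte Carlo agreement tests use 3-standard-error bands per comparison at
fixed seeds; with 24 comparisons in the backend-agreement suite a ~3-SE
excursion is expected occasionally under the null, so the suite's seed is
fixed and the per-quantity unbiasedness was additionally checked across
independent seeds.

## Known limitations

- Full-state solves are capped at 14 vertices (2^N growth); lumped solvers
  exist only for families whose parts are automorphic by construction.
- Directed graphs are supported by the containers, kernel, full-state engine
  and simulator, but enumeration and the family constructors are undirected.
- Birth–death updating with constant fitness only: no death–birth rule, no
  frequency dependence, no multiple mutant types.
- The effective-rate measure ignores clonal interference by construction.
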