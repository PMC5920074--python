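# Methods

This note records the models, conventions, numerical choices and problem
sizes behind `sirpaths`, in the order a reader meets them.

## The process and its mapping

We consider generalized SIR dynamics on an undirected simple contact
network: an infected node attempts transmission along each incident edge
after a waiting time drawn from ψ, and recovers after a waiting time
drawn from φ; a transmission succeeds only if it precedes the
transmitter's recovery and the target is still susceptible. The
Poissonian (Markovian) case has exponential ψ, φ with rates β, γ.

The package's core transformation replaces forward simulation by
sampling a *weighted network realization*: edge i→j gets weight
Ψ⁻¹(x) when Ψ⁻¹(x) ≤ Φ⁻¹(y) and the infinity sentinel otherwise. The
shortest-path distance from a source then equals the first-infection
time of every node in that realization. Two variants:

- **exact** — one recovery variate y_i per node, one transmission
  variate per *directed* arc. All out-weights of node i share Φ⁻¹(y_i),
  which makes them conditionally independent given y_i and reproduces
  the process law exactly (validated against Gillespie simulation at
  Kolmogorov–Smirnov distance < 0.03 on 10⁴ samples, per target node).
- **meanfield** — an independent (x, y) pair per undirected edge,
  symmetric weights. Exact for SI (γ = 0) and for deterministic
  recovery; elsewhere it drops the shared-recovery correlation, and the
  toy-network study quantifies the resulting bias at β = γ (≈ 0.08 on a
  reach probability of 0.64).

**Tie rule.** Equality Ψ⁻¹(x) = Φ⁻¹(y) counts as transmission. This is
measure-zero in continuous time but material in discrete time, where it
makes the geometric-weight mapping exactly consistent with the
synchronous infect-then-recover chain below.

**Conventions.** Uniform variates live on (0, 1] (u = 0 would map to an
infinite waiting time); inverse sampling uses the survival-inverse form,
so the exponential case is −ln(u)/β literally, and the round-trip
identity is sf(inverse_cdf(u)) = u. Draw order is fixed — nodes in
canonical (natural-sorted) id order, then arcs in sorted (src, dst)
order — so realizations are bit-reproducible given a seed. Infinity is a
first-class sentinel, never a large number; the shortest-path kernels
skip infinite arcs, so unreachable targets come out exactly infinite.
Self-loops and duplicate edges are rejected on input.

## Waiting-time families

| family | params | time | role notes |
|---|---|---|---|
| exponential | rate ≥ 0 | continuous | rate 0 = "never" (SI recovery) |
| lognormal | μ, σ > 0 | continuous | heavy-tailed non-Markovian law |
| deterministic | delay ≥ 0 | either | point mass; fixed recovery time |
| geometric | p ∈ [0, 1] | discrete | support {1, 2, …}; p per step |

Discrete time is realized by geometric laws: the standard synchronous
SIR chain (each step: every infected node attempts each susceptible
neighbour with probability β, then recovers with probability γ) has
geometric waiting times on {1, 2, …} — a node can still transmit during
its recovery step, matching the "≤" tie rule. A transmission can never
take zero steps.

## Ensembles and samplers

Expectations are Monte Carlo averages over realizations. Independent
sampling has the usual O(n^{-1/2}) error; the standard error is the
sample SD over √n. The rejection-free Gibbs chain resamples, per step,
one uniformly chosen node's recovery draw plus all its out-weights
(exact mode) or one uniformly chosen edge's weight (mean-field). The
redrawn block's conditional given the rest equals its marginal, so every
move is accepted and the stationary law is the ensemble itself. Defaults:
burn-in 10·N steps, thinning N steps (one sweep-scale refresh between
retained states), standard errors by batch means with up to 30 batches.
The chain and independent sampling are cross-checked on three statistics
at 3 combined standard errors.

Shortest paths are recomputed per source with a compiled linear-scan
Dijkstra (O(N² + E) per source). At this package's sizes (N ≤ ~10³,
with 10⁴–10⁵ realizations) recomputation is faster and simpler than
incremental all-pairs updates after each local Gibbs move, and produces
identical outputs; an optional `limit` truncates the search at a time
horizon, which the snapshot and survival computations exploit.

## Observables

- **Temporal distances**: single-source shortest paths over finite
  weights; directed in exact mode.
- **Node states at t**: S while d > t; I when d ≤ t < d + r; R from the
  recovery instant t = d + r onward (closed boundary on both
  transitions; measure-zero in continuous time). The source carries its
  own recovery draw. Mean-field realizations with γ > 0 have no per-node
  recovery draw, so the I/R split is refused rather than invented.
- **Expected propagation time D_ij**: with recovery present the raw
  expectation diverges (unreachable with positive probability), so the
  matrix stores the conditional-on-finite mean plus the per-pair finite
  fraction and a divergence flag — infinities are never silently
  averaged.
- **Characteristic timescale τ_i**: the N̄-th smallest finite entry of
  row i (reaching counts at equality), infinite when fewer than N̄
  entries are finite.

## Percolation limit

The infinite-time reached set equals the finite-weight reachable
component. The scalar transmissibility p = ∫φ(τ)Ψ(τ)dτ is computed by
adaptive quadrature on [0, ∞) (scipy's infinite-interval transform;
absolute tolerance 10⁻⁹ enforced, failures raise). A substitution that
maps [0, ∞) to (0, 1) multiplies the integrand by e^τ and diverges for
subexponential recovery tails (lognormal), so it is not used. Point-mass
laws are integrated analytically; discrete laws by summation with the
geometric tail truncated below 10⁻¹² mass. The Poissonian closed form
for p_{n,k} is evaluated in log-gamma space (Γ ratios overflow for
n ≳ 20); quadrature and closed form agree to 10⁻⁸ over the tested grid.

The parallel-chains toy network (source and destination joined by n_c
disjoint chains of l intermediate nodes) admits the closed form
P(s→d) = 1 − Σ_j p_{n_c,j}(1 − p^l)^j: the source's first neighbourhood
follows p_{n,k}, and each activated chain delivers independently with
p^l because its interior nodes' forward edges involve distinct recovery
draws. This is the package's end-to-end analytic anchor.

## Source detection

Given an observed S/I/R snapshot at t₀, candidates (by default the
infected-or-recovered nodes — a source must have been infected) are
scored three ways: temporal kernel (ensemble average of
exp(−(φ−1)²/a²), φ the fraction of matching states, one shared
realization stream scoring all candidates), direct Monte Carlo (exact
snapshot matches over forward runs), and the topological baseline
(inverse mean hop distance to the other infected nodes, the candidate
excluded from its own average; disconnected candidates score zero).
Matching uses the full three-state vector. Default bandwidth
a = 0.1·(1 + 1/N): a snapshot mismatching on ten percent of the nodes is
down-weighted by about a factor e. Rankings break ties by a secondary
estimator and then by node id, deterministically.

## Time-critical vaccination

p̃_i is the fraction of realizations with d(source, i) ≥ t₀ + Δt
(infinite distances count as survival). Selection strategies: "temporal"
samples m vaccinees without replacement with weights p̃ (an exponential
race; zero-weight nodes fill leftover slots only), with a deterministic
top-m variant off by default; "random" is uniform; "hubs" is
degree-weighted. The simulator draws the plan per run from that run's
susceptible set at t₀; vaccinees still susceptible at t₀ + Δt become
permanently immune, vaccinees infected inside the window transmit
normally and count as wasted doses. The source is assumed known,
matching the observed-outbreak scenario.

## Synthetic networks and what passing tests show

Generators: 4-connected non-periodic lattices, Erdős–Rényi G(n, p) at a
target mean degree (largest component on request), preferential
attachment for scale-free graphs, and the toy chain network. All are
seed-deterministic. The scale-free graph in the vaccination study uses
attachment 7 (mean degree ≈ 14) to match the degree scale of the
online-social friendship networks it stands in for: at that density the
epidemic is far above threshold and the strategies separate through
wasted doses (hubs are infected early), which is the regime of interest;
on a much sparser graph (mean degree ~6), degree-targeted removal of 20%
of nodes instead fragments the network and wins structurally. Synthetic
graphs lack clustering, degree correlations and community structure, so
passing studies demonstrate correctness of the machinery and the
qualitative regime orderings, not quantitative predictions for any
particular empirical network.

## Validation studies and problem sizes

The `validation` module fixes the study protocols (sizes chosen so the
full battery runs in ~2 minutes on one core): toy network at 10⁵
realizations; Gillespie equivalence on a 3-path, 4-star and 8-node ER
graph at 10⁴ samples per setting (γ ∈ {0, 0.5, 1}); bond-percolation
limit on the 11×11 lattice at 10³ realizations (γ = 0.001,
β ∈ {0.3, 0.003}); sampler consistency on a 20-node ER graph (the
pairwise-distance statistic is truncated at 20 time units because its
raw expectation diverges under recovery); source detection on a 10×10
lattice, discrete time, β = 0.7, γ = 0.3, snapshots at T = 5, 30
replicates with 10⁴ mapping samples and 10⁴ direct-MC runs per
candidate; vaccination on a 1000-node scale-free graph, discrete
β = 0.03, γ = 0.01, t₀ = 3, Δt = 10, m = 0.2N, 200 runs per strategy, a
horizon of 800 steps (≈ 8 mean infectious periods, by which runs are
essentially extinct); disorder scaling on ER graphs of N ∈
{50, 100, 200, 400} at mean degree 6, averaging 8 graph instances × 5
weight realizations per size.

On disorder scaling: with exponential weights the mean pairwise SI
propagation time grows logarithmically in N (weak disorder). Under a
broad lognormal (σ = 3) the pairwise *mean* is dominated by single
extreme edge weights (per-edge variance ~ e^{18}), so the study also
reports the median ("typical") distance; at these scaled-down sizes the
system sits in the weak/strong-disorder crossover, and the power-law
versus logarithmic contrast on the mean is visible but statistically
marginal.

## Known limitations

- Static networks only; no temporal contact networks or per-edge rates.
- Single-source epidemics; no multi-source detection.
- The Gibbs sampler recomputes shortest paths rather than maintaining
  them incrementally — the right trade-off at these sizes, not at
  N ≫ 10⁴.
- Discrete and continuous laws cannot be mixed within one process.
- The direct-MC source baseline is exact-match counting and needs
  exponentially many runs as snapshots grow unlikely; it is a baseline,
  not a recommended estimator.
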