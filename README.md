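# sirpaths

Simulate generalized SIR spreading on contact networks by mapping the
dynamics to **weighted shortest paths**.

## The idea

A stochastic SIR epidemic on a network G is specified by two waiting-time
laws: ψ(t), the time from a node's infection to a transmission attempt
along a link, and φ(t), the time to its recovery (exponential with rates
β and γ in the Markovian case; arbitrary laws — lognormal, deterministic,
geometric — in the non-Markovian case). One *realization* of the process
is encoded as a weighted network: each edge i→j receives the propagation
delay

    ρ_ij = Ψ⁻¹(x)   if Ψ⁻¹(x) ≤ Φ⁻¹(y),   else ∞,

where x, y are uniform variates and Ψ⁻¹, Φ⁻¹ are the survival-inverses
of the cumulative waiting-time distributions (for the Poissonian case,
−ln(x)/β and −ln(y)/γ). The weighted shortest-path distance d(i, j) in
such a realization **equals the first-infection time** of j for an
epidemic seeded at i, so a single sampled network encodes one outcome
from *every* potential source at once.

Everything else follows from ensembles {G_k} of these realizations:

- **Exact mapping** — one recovery draw per node shared by all its
  out-edges (directed weights); reproduces all dynamical correlations of
  SIR. **Mean-field mapping** — independent draws per edge (symmetric
  weights); exact for SI (γ = 0) and for fixed recovery times.
- **Samplers** — independent draws, or a rejection-free Gibbs chain that
  resamples one node's block (or one edge) at a time.
- **Observables** — outbreak-size curves, the expected propagation-time
  matrix D_ij, and the characteristic spreading timescale τ_i (time for
  node i to reach N̄ others), an influence ranking.
- **Percolation limit** — as t → ∞ the reached set is a bond-percolation
  component with transmissibility p = ∫φ(τ)Ψ(τ)dτ; the
  first-neighbourhood generalization p_{n,k} (probability that k of n
  links activate) captures the shared-recovery correlation, with a
  gamma-function closed form in the Poissonian case.
- **Applications** — snapshot source detection via a Gaussian similarity
  kernel over the ensemble, and time-critical vaccination guided by each
  node's probability of still being uninfected when the vaccine becomes
  effective.

Who is this for: anyone studying spreading on networks who needs exact
(not mean-field) finite-time statistics for Markovian *and* non-Markovian
SIR — e.g. for source inference, influence ranking or intervention
planning — without writing a bespoke event-driven simulator per question.

## Worked example

```python
import numpy as np
import sirpaths as sp

rng = np.random.default_rng(42)
psi, phi = sp.Exponential(1.0), sp.Exponential(1.0)   # Poissonian SIR, beta = gamma = 1

p = sp.transmissibility(psi, phi)
print(f"per-link transmissibility p = {p:.4f}")

# 20 disjoint chains of 3 nodes between a source s and destination d:
# the reach probability has a closed form, which the exact mapping recovers
p_analytic = sp.toy_network_probability(20, 3, psi, phi)
net = sp.build_toy_network(20, 3)
reach = lambda r: float(np.isfinite(sp.temporal_distances(r, "s")["d"]))
est = sp.sample_independent(net, psi, phi, "exact", 20_000, rng, reach, name="reach")
print(f"P(s->d): analytic {p_analytic:.4f}, exact-mapping MC {est.mean:.4f} +- {est.std_error:.4f}")

D = sp.expected_propagation_matrix(net, psi, sp.si_recovery(), "meanfield", 400, rng)
tau = sp.characteristic_timescale(D, Nbar=31)
print(f"characteristic timescale tau_s = {tau['s']:.3f} (time for s to reach half the network, SI case)")
```

prints

```
per-link transmissibility p = 0.5000
P(s->d): analytic 0.6421, exact-mapping MC 0.6419 +- 0.0034
characteristic timescale tau_s = 1.680 (time for s to reach half the network, SI case)
```

The transmissibility 0.5 is β/(β+γ); the Monte Carlo reach probability
agrees with the analytic formula within one standard error, while the
mean-field mapping would land near 0.727 — the visible cost of ignoring
the shared-recovery correlation at β ≈ γ.

A command-line interface exposes the same machinery
(`sirpaths generate | map | estimate | distances | percolation |
simulate | source-detect | vaccinate`); every subcommand logs its
resolved configuration and seed.

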