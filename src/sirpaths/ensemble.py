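"""Ensemble construction and traversal: independent sampling and the
rejection-free Gibbs Markov chain over weighted networks.

Any expectation over the process is a Monte Carlo average of a statistic
``f`` over sampled weighted networks.  Independent sampling draws fresh
realizations (O(n^-1/2) convergence); the Gibbs chain instead resamples
one local block — a node's recovery draw together with all of its
out-weights (exact mode), or a single edge (mean-field mode) — from its
exact conditional given the rest, so every move is accepted and the
stationary law is the realization ensemble itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mapping
from ._paths import dijkstra
from .mapping import EXACT, MEANFIELD, WeightedRealization

__all__ = [
    "EnsembleEstimate",
    "sample_independent",
    "gibbs_step",
    "run_gibbs",
    "finite_fraction_statistic",
    "make_distance_statistic",
    "make_outbreak_statistic",
]


@dataclass
class EnsembleEstimate:
    """Monte Carlo mean of a statistic with its standard error.

    For independent sampling ``std_error`` is sample-sd / sqrt(n); chain
    output uses batch means to absorb autocorrelation.
    """

    statistic_name: str
    mean: float | np.ndarray
    std_error: float | np.ndarray
    n_samples: int
    sampler: str
    burn_in: int = 0
    thinning: int = 0
    meta: dict = field(default_factory=dict)


def _finalize(values: np.ndarray, name, sampler, n, **kw) -> EnsembleEstimate:
    mean = values.mean(axis=0)
    if values.shape[0] > 1:
        se = values.std(axis=0, ddof=1) / np.sqrt(values.shape[0])
    else:
        se = np.zeros_like(np.asarray(mean, dtype=float))
    if np.ndim(mean) == 0:
        mean, se = float(mean), float(se)
    return EnsembleEstimate(name, mean, se, n, sampler, **kw)


def sample_independent(network, psi, phi, mode, n, rng, statistic,
                       name="statistic") -> EnsembleEstimate:
    """Estimate ``E[statistic]`` from ``n`` independently sampled realizations.

    ``statistic`` is any pure function of a :class:`WeightedRealization`
    returning a float or a fixed-shape vector.  Realizations are streamed,
    not retained.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = (mapping.generate_realization_exact if mode == EXACT
           else mapping.generate_realization_meanfield)
    if mode not in (EXACT, MEANFIELD):
        raise ValueError(f"unknown mode {mode!r}")
    values = np.asarray([statistic(gen(network, psi, phi, rng)) for _ in range(n)],
                        dtype=float)
    return _finalize(values, name, "independent", n)


def gibbs_step(realization: WeightedRealization, rng: np.random.Generator):
    """One rejection-free Gibbs transition, in place.

    Exact mode: pick a node uniformly, redraw its recovery variate and the
    transmission variates of all its out-arcs, and recompute those
    out-weights only.  Mean-field mode: pick an undirected edge uniformly
    and redraw its weight.  The redrawn block's conditional given the rest
    equals its marginal, so the move is always accepted.  Returns the same
    (mutated) realization.
    """
    net = realization.network
    psi, phi = realization.psi, realization.phi
    if realization.mode == EXACT:
        i = int(rng.integers(net.n_nodes))
        y = 1.0 - rng.random()
        r = float(phi.inverse_cdf(y))
        realization.node_recovery[i] = r
        lo, hi = int(net.indptr[i]), int(net.indptr[i + 1])
        if hi > lo:
            x = 1.0 - rng.random(hi - lo)
            t = np.asarray(psi.inverse_cdf(x), dtype=float).reshape(hi - lo)
            realization.weights[lo:hi] = np.where(t <= r, t, np.inf)
    elif realization.mode == MEANFIELD:
        e = int(rng.integers(net.n_edges))
        x = 1.0 - rng.random()
        y = 1.0 - rng.random()
        realization.weights[e] = mapping.sample_edge_weight(psi, phi, x, y)
    else:  # pragma: no cover - constructor enforces the mode
        raise ValueError(f"unknown mode {realization.mode!r}")
    return realization


def run_gibbs(network, psi, phi, mode, n_steps, rng, statistic,
              burn_in=None, thinning=None, name="statistic") -> EnsembleEstimate:
    """Estimate ``E[statistic]`` along the Gibbs chain.

    Defaults: ``burn_in = 10 N`` steps and ``thinning = N`` steps, i.e. the
    chain refreshes on the order of one sweep between retained states.  The
    standard error uses batch means with up to 30 batches, the usual recipe
    for autocorrelated chain output.
    """
    n = network.n_nodes
    if burn_in is None:
        burn_in = 10 * n
    if thinning is None:
        thinning = n
    if thinning < 1:
        raise ValueError("thinning must be a positive integer")
    if n_steps <= burn_in:
        raise ValueError("n_steps must exceed burn_in")
    gen = (mapping.generate_realization_exact if mode == EXACT
           else mapping.generate_realization_meanfield)
    if mode not in (EXACT, MEANFIELD):
        raise ValueError(f"unknown mode {mode!r}")
    state = gen(network, psi, phi, rng)
    retained = []
    for step in range(n_steps):
        gibbs_step(state, rng)
        if step >= burn_in and (step - burn_in) % thinning == 0:
            retained.append(statistic(state))
    values = np.asarray(retained, dtype=float)
    m = values.shape[0]
    mean = values.mean(axis=0)
    n_batches = min(30, m)
    if n_batches >= 2:
        edges = np.linspace(0, m, n_batches + 1).astype(int)
        bm = np.asarray([values[a:b].mean(axis=0) for a, b in zip(edges[:-1], edges[1:])])
        se = bm.std(axis=0, ddof=1) / np.sqrt(n_batches)
    else:
        se = np.zeros_like(np.asarray(mean, dtype=float))
    if np.ndim(mean) == 0:
        mean, se = float(mean), float(se)
    return EnsembleEstimate(name, mean, se, m, "gibbs",
                            burn_in=burn_in, thinning=thinning)


# -- canned statistics ---------------------------------------------------

def finite_fraction_statistic(realization: WeightedRealization) -> float:
    """Fraction of sampled weights that are finite (active links)."""
    return realization.finite_fraction()


def make_distance_statistic(source, target, truncate=np.inf):
    """Temporal distance d(source, target), optionally truncated.

    With recovery present the raw expectation diverges (infinite samples
    occur), so a finite ``truncate`` gives the bounded surrogate
    ``min(d, truncate)`` whose expectation is well defined.
    """

    def stat(realization: WeightedRealization) -> float:
        net = realization.network
        dist = dijkstra(net.indptr, net.arc_dst, realization.arc_weights,
                        net.index(source), np.inf)
        return float(min(dist[net.index(target)], truncate))

    return stat


def make_outbreak_statistic(source, t):
    """Number of nodes reached within time t from ``source`` (incl. itself)."""

    def stat(realization: WeightedRealization) -> float:
        net = realization.network
        dist = dijkstra(net.indptr, net.arc_dst, realization.arc_weights,
                        net.index(source), float(t))
        return float(np.sum(dist <= t))

    return stat
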