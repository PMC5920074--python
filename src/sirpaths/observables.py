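"""Epidemic observables computed from weighted realizations.

The temporal distance d(i, j) of a realization — the weighted shortest
path from i to j — equals that realization's first-infection time of j
when the epidemic starts at i.  Everything here derives from it: node
states at an observation time, outbreak-size curves, the expected
propagation-time matrix D_ij, and the characteristic spreading timescale
tau_i (the time for a node to reach a prescribed number of others).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _paths
from .ensemble import EnsembleEstimate
from .mapping import EXACT, MEANFIELD, WeightedRealization, sample_weights_batch
from .netio import ContactNetwork

__all__ = [
    "NodeStateVector",
    "DistanceMatrix",
    "temporal_distances",
    "node_states_at",
    "outbreak_size_curve",
    "expected_propagation_matrix",
    "characteristic_timescale",
]

S, I, R = "S", "I", "R"


@dataclass
class NodeStateVector:
    """S/I/R assignment for every node at an observation time."""

    states: dict
    time: float

    def codes(self, network: ContactNetwork) -> np.ndarray:
        """Integer encoding (0=S, 1=I, 2=R) in canonical node order."""
        lut = {S: 0, I: 1, R: 2}
        return np.array([lut[self.states[v]] for v in network.node_ids], dtype=np.int8)


@dataclass
class DistanceMatrix:
    """Monte Carlo average of temporal distances between all node pairs.

    With recovery present some sampled distances are infinite and the raw
    expectation diverges; ``values`` therefore holds the mean conditional
    on reaching, ``finite_fraction`` the per-pair probability of reaching,
    and ``divergence_flag`` marks entries where any sample was infinite.
    """

    node_order: tuple
    values: np.ndarray
    n_samples: int
    divergence_flag: np.ndarray
    finite_fraction: np.ndarray
    meta: dict = field(default_factory=dict)

    def row(self, node_id, network: ContactNetwork | None = None) -> np.ndarray:
        return self.values[self.node_order.index(str(node_id))]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("," + ",".join(self.node_order) + "\n")
            for vid, row in zip(self.node_order, self.values):
                fh.write(vid + "," + ",".join(str(x) for x in row) + "\n")


def temporal_distances(realization: WeightedRealization, source) -> dict:
    """Single-source weighted shortest paths: map node-id -> propagation time.

    Directed in exact mode, symmetric in mean-field mode; unreachable nodes
    get ``inf``.
    """
    net = realization.network
    dist = _paths.dijkstra(net.indptr, net.arc_dst, realization.arc_weights,
                           net.index(source), np.inf)
    return dict(zip(net.node_ids, dist.tolist()))


def node_states_at(realization: WeightedRealization, source, t) -> NodeStateVector:
    """S/I/R states at time ``t`` for the epidemic seeded at ``source``.

    A node at temporal distance d is S while d > t, infected at d (so I
    when d <= t), and R from its recovery instant d + r onward, where r is
    the realization's recovery draw.  The source is infected at time 0 and
    carries its own recovery draw.  Mean-field realizations have no
    per-node draws, so the I/R split is undefined unless recovery never
    occurs.
    """
    if t < 0:
        raise ValueError("observation time must be non-negative")
    net = realization.network
    if realization.node_recovery is not None:
        r = realization.node_recovery
    elif realization.phi.never:
        r = np.full(net.n_nodes, np.inf)
    else:
        raise ValueError(
            "mean-field realizations with recovery carry no per-node recovery "
            "draws; use exact mode for snapshot-based workflows"
        )
    dist = _paths.dijkstra(net.indptr, net.arc_dst, realization.arc_weights,
                           net.index(source), float(t))
    states = {}
    for i, vid in enumerate(net.node_ids):
        d = dist[i]
        if d > t:
            states[vid] = S
        elif t < d + r[i]:
            states[vid] = I
        else:
            states[vid] = R
    return NodeStateVector(states, float(t))


def outbreak_size_curve(network, psi, phi, mode, source, times, n, rng) -> EnsembleEstimate:
    """Mean number of nodes reached within each time in ``times``.

    Counts |{j : d(source, j) <= t}| per realization (monotone in t within
    each realization) and averages over ``n`` realizations.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    src = network.index(source)
    limit = float(times[-1])
    counts = np.empty((n, times.size))
    chunk = max(1, min(n, 4_000_000 // max(network.n_arcs, 1)))
    done = 0
    while done < n:
        b = min(chunk, n - done)
        W, _ = sample_weights_batch(network, psi, phi, mode, b, rng)
        dist = _paths.distance_rows(network.indptr, network.arc_dst, W, src, limit)
        for k, t in enumerate(times):
            counts[done:done + b, k] = (dist <= t).sum(axis=1)
        done += b
    mean = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return EnsembleEstimate("outbreak_size", mean, se, n, "independent",
                            meta={"times": times, "source": str(source), "mode": mode})


def expected_propagation_matrix(network, psi, phi, mode, n, rng) -> DistanceMatrix:
    """All-pairs expected propagation time from ``n`` sampled realizations.

    For SI dynamics every entry is finite on a connected graph.  With
    recovery, entries are conditional-on-finite means and the divergence
    flag records pairs where any sample was infinite.
    """
    N = network.n_nodes
    total = np.zeros((N, N))
    n_finite = np.zeros((N, N), dtype=np.int64)
    for _ in range(n):
        W, _ = sample_weights_batch(network, psi, phi, mode, 1, rng)
        d = _paths.all_pairs(network.indptr, network.arc_dst, W[0], np.inf)
        finite = np.isfinite(d)
        total[finite] += d[finite]
        n_finite += finite
    with np.errstate(invalid="ignore"):
        values = np.where(n_finite > 0, total / np.maximum(n_finite, 1), np.inf)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(
        node_order=network.node_ids,
        values=values,
        n_samples=n,
        divergence_flag=n_finite < n,
        finite_fraction=n_finite / n,
        meta={"mode": mode, "psi": psi.spec(), "phi": phi.spec()},
    )


def characteristic_timescale(D: DistanceMatrix, Nbar: int) -> dict:
    """Characteristic spreading timescale per node.

    tau_i is the earliest t at which node i has reached ``Nbar`` other
    nodes, i.e. the Nbar-th smallest off-diagonal expected propagation time
    of row i (reaching counts at equality, t >= D_ij).  Rows with fewer
    than ``Nbar`` finite entries get ``inf``.
    """
    if Nbar < 1:
        raise ValueError("Nbar must be >= 1")
    N = len(D.node_order)
    if Nbar > N - 1:
        raise ValueError("Nbar must be at most N - 1")
    out = {}
    for i, vid in enumerate(D.node_order):
        row = np.delete(D.values[i], i)
        finite = np.sort(row[np.isfinite(row)])
        out[vid] = float(finite[Nbar - 1]) if finite.size >= Nbar else np.inf
    return out
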