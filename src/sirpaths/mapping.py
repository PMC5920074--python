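"""Mapping generalized SIR dynamics to weighted time-respecting networks.

One sampled *realization* assigns to every edge a propagation delay: the
transmission waiting time if it precedes the transmitter's recovery, and
the infinity sentinel otherwise.  Shortest-path lengths over those weights
equal the first-infection times of the stochastic process, so a single
weighted network encodes one outcome of the epidemic from every potential
source at once.

Two variants are provided:

* **exact** — one recovery variate per node, one transmission variate per
  *directed* arc.  All out-weights of a node share its recovery draw, which
  reproduces the dynamical correlations of SIR exactly; the result is a
  directed weighted network.
* **meanfield** — one (transmission, recovery) pair per undirected edge,
  drawn independently; weights are symmetric.  Valid when transmission is
  much faster than recovery (the SI limit is exact), and the regime in
  which the process reduces to i.i.d. disordered weights.

Ties ``transmission time == recovery time`` count as a successful
transmission; this is immaterial in continuous time but material in
discrete time, where it makes the mapping consistent with a synchronous
infect-then-recover update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import InterEventDistribution
from .netio import ContactNetwork

__all__ = [
    "WeightedRealization",
    "sample_edge_weight",
    "generate_realization_exact",
    "generate_realization_meanfield",
    "sample_weights_batch",
    "write_realization",
]

EXACT = "exact"
MEANFIELD = "meanfield"


def _check_inputs(network: ContactNetwork, psi, phi) -> None:
    if network.n_nodes == 0:
        raise ValueError("network has no nodes")
    if psi.time_mode != phi.time_mode:
        raise ValueError(
            f"mixed time modes: psi is {psi.time_mode}, phi is {phi.time_mode}"
        )


def sample_edge_weight(psi: InterEventDistribution, phi: InterEventDistribution, x, y):
    """Propagation delay for one edge given uniform variates x, y in (0,1].

    Returns the transmission draw ``Psi^{-1}(x)`` when it does not exceed
    the recovery draw ``Phi^{-1}(y)``, and ``inf`` otherwise (the node
    recovered before transmitting).
    """
    t = psi.inverse_cdf(x)
    r = phi.inverse_cdf(y)
    out = np.where(np.asarray(t) <= np.asarray(r), t, np.inf)
    return float(out) if out.ndim == 0 else out


@dataclass
class WeightedRealization:
    """One sampled weighted network.

    ``weights`` is arc-aligned (sorted (src, dst) order) in exact mode and
    edge-aligned (sorted (i, j), i<j order) in mean-field mode; ``inf``
    marks edges with no transmission.  ``node_recovery`` holds the per-node
    recovery draws and is populated only in exact mode.
    """

    network: ContactNetwork
    mode: str
    weights: np.ndarray
    psi: InterEventDistribution
    phi: InterEventDistribution
    node_recovery: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def arc_weights(self) -> np.ndarray:
        """Weights aligned with the network's directed-arc CSR order."""
        if self.mode == EXACT:
            return self.weights
        return self.weights[self.network.arc_edge]

    def weight(self, u, v) -> float:
        """Weight of the directed edge u -> v (by node id)."""
        net = self.network
        ui, vi = net.index(u), net.index(v)
        lo, hi = net.indptr[ui], net.indptr[ui + 1]
        pos = np.searchsorted(net.arc_dst[lo:hi], vi)
        if pos == hi - lo or net.arc_dst[lo + pos] != vi:
            raise KeyError(f"no edge {u!r} -> {v!r}")
        return float(self.arc_weights[lo + pos])

    def recovery(self, u) -> float:
        if self.node_recovery is None:
            raise ValueError("mean-field realizations carry no per-node recovery draws")
        return float(self.node_recovery[self.network.index(u)])

    def finite_fraction(self) -> float:
        """Fraction of stored weights that are finite (active links)."""
        return float(np.mean(np.isfinite(self.weights)))

    def copy(self) -> "WeightedRealization":
        return WeightedRealization(
            network=self.network,
            mode=self.mode,
            weights=self.weights.copy(),
            psi=self.psi,
            phi=self.phi,
            node_recovery=None if self.node_recovery is None else self.node_recovery.copy(),
            meta=dict(self.meta),
        )


def generate_realization_exact(
    network: ContactNetwork,
    psi: InterEventDistribution,
    phi: InterEventDistribution,
    rng: np.random.Generator,
) -> WeightedRealization:
    """Sample one exact-mode realization.

    Draw order (fixed for reproducibility): one recovery variate per node
    in canonical node order, then one transmission variate per directed arc
    in sorted (src, dst) order.  The weight of arc i->j is the transmission
    draw when it does not exceed node i's recovery draw, else ``inf``.
    """
    _check_inputs(network, psi, phi)
    y = 1.0 - rng.random(network.n_nodes)
    r = np.atleast_1d(np.asarray(phi.inverse_cdf(y), dtype=float))
    x = 1.0 - rng.random(network.n_arcs)
    t = np.asarray(psi.inverse_cdf(x), dtype=float).reshape(network.n_arcs)
    w = np.where(t <= r[network.arc_src], t, np.inf)
    return WeightedRealization(network, EXACT, w, psi, phi, node_recovery=r)


def generate_realization_meanfield(
    network: ContactNetwork,
    psi: InterEventDistribution,
    phi: InterEventDistribution,
    rng: np.random.Generator,
) -> WeightedRealization:
    """Sample one mean-field realization: an independent (x, y) pair per
    undirected edge, giving symmetric weights and no node recovery draws.

    Draw order: all transmission variates in edge order, then all recovery
    variates in edge order.
    """
    _check_inputs(network, psi, phi)
    x = 1.0 - rng.random(network.n_edges)
    y = 1.0 - rng.random(network.n_edges)
    t = np.asarray(psi.inverse_cdf(x), dtype=float).reshape(network.n_edges)
    r = np.asarray(phi.inverse_cdf(y), dtype=float).reshape(network.n_edges)
    w = np.where(t <= r, t, np.inf)
    return WeightedRealization(network, MEANFIELD, w, psi, phi)


def sample_weights_batch(
    network: ContactNetwork,
    psi: InterEventDistribution,
    phi: InterEventDistribution,
    mode: str,
    n: int,
    rng: np.random.Generator,
):
    """Vectorized sampler for ``n`` realizations at once.

    Returns ``(W, R)``: in exact mode ``W`` has shape (n, n_arcs) in arc
    order and ``R`` (n, n_nodes); in mean-field mode ``W`` has shape
    (n, n_arcs) with symmetric weights and ``R`` is None.  Used by the
    Monte Carlo observables, where sampling cost would otherwise dominate.
    """
    _check_inputs(network, psi, phi)
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode == EXACT:
        y = 1.0 - rng.random((n, network.n_nodes))
        r = np.asarray(phi.inverse_cdf(y), dtype=float).reshape(n, network.n_nodes)
        x = 1.0 - rng.random((n, network.n_arcs))
        t = np.asarray(psi.inverse_cdf(x), dtype=float).reshape(n, network.n_arcs)
        w = np.where(t <= r[:, network.arc_src], t, np.inf)
        return w, r
    if mode == MEANFIELD:
        x = 1.0 - rng.random((n, network.n_edges))
        y = 1.0 - rng.random((n, network.n_edges))
        t = np.asarray(psi.inverse_cdf(x), dtype=float).reshape(n, network.n_edges)
        re = np.asarray(phi.inverse_cdf(y), dtype=float).reshape(n, network.n_edges)
        w = np.where(t <= re, t, np.inf)
        return w[:, network.arc_edge], None
    raise ValueError(f"unknown mode {mode!r}")


def write_realization(realization: WeightedRealization, edge_path, recovery_path=None):
    """Serialize to a 3-column directed weighted edge list (src, dst, weight,
    with ``inf`` for the infinity sentinel) and, in exact mode, a 2-column
    node recovery file."""
    net = realization.network
    w = realization.arc_weights
    with open(edge_path, "w") as fh:
        fh.write("src,dst,weight\n")
        for k in range(net.n_arcs):
            fh.write(
                f"{net.node_ids[net.arc_src[k]]},{net.node_ids[net.arc_dst[k]]},{w[k]}\n"
            )
    if realization.node_recovery is not None and recovery_path is not None:
        with open(recovery_path, "w") as fh:
            fh.write("node,recovery\n")
            for i, vid in enumerate(net.node_ids):
                fh.write(f"{vid},{realization.node_recovery[i]}\n")
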