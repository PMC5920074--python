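"""Infinite-time theory: transmissibility and bond percolation.

As the process time goes to infinity, the set of ever-infected nodes in a
realization equals the component reachable through finite-weight edges, so
the epidemic final state is a bond percolation problem.  The scalar
transmissibility

    p = int_0^inf dtau phi(tau) int_0^tau dtau' psi(tau')

is the probability that an infected node transmits along one link before
recovering (``beta/(beta+gamma)`` in the Poissonian case).  Because a
node's links share its recovery time, activation events of the links of
one node are not independent: the first-neighbourhood transmissibility

    p_{n,k} = int_0^inf phi(tau) C(n,k) (1-Psi(tau))^{n-k} Psi(tau)^k dtau

gives the probability that exactly k of a node's n links are active, and
only factorizes into a binomial when recovery is deterministic or absent.
For the Poissonian process p_{n,k} has a closed gamma-function form,
evaluated here in log-gamma space.

The module also provides the analytic source-to-destination reachability
probability for the parallel-chains toy network used to validate the
mapping end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import gammaln

from . import _paths
from .distributions import (
    CONTINUOUS,
    DISCRETE,
    Deterministic,
    InterEventDistribution,
)
from .mapping import WeightedRealization
from .netio import ContactNetwork

__all__ = [
    "TransmissibilityTable",
    "transmissibility",
    "transmissibility_nk",
    "transmissibility_nk_poisson",
    "transmissibility_table",
    "percolation_component_size",
    "bond_percolation_component_sizes",
    "build_toy_network",
    "toy_network_probability",
]

_QUAD_TOL = 1e-9


class IntegrationError(RuntimeError):
    pass


def _integrate_against_recovery(phi, f):
    """Compute  int phi(tau) f(tau) dtau  (sum in discrete mode).

    ``f`` must be bounded in [0, 1].  Point-mass recovery evaluates f at
    the fixed delay; the "never" law takes the tau -> inf limit of f.
    """
    if phi.never:
        return float(f(np.inf))
    if isinstance(phi, Deterministic):
        return float(f(phi.delay))
    if phi.time_mode == DISCRETE:
        # truncate the geometric support once the remaining tail mass is
        # negligible (< 1e-12)
        r_max = int(min(10**7, math.ceil(math.log(1e-12) / math.log1p(-phi.p)))) if phi.p < 1 else 1
        r = np.arange(1, r_max + 1, dtype=float)
        return float(np.sum(phi.pmf(r) * f(r)))
    val, err = integrate.quad(lambda t: phi.pdf(t) * f(t), 0.0, np.inf,
                              epsabs=1e-12, epsrel=1e-12, limit=400)
    if err > _QUAD_TOL:
        raise IntegrationError(
            f"quadrature error {err:.2e} exceeds tolerance {_QUAD_TOL:.0e} "
            f"for phi={phi.spec()}"
        )
    return float(val)


def _cdf_with_limit(psi, tau):
    """Psi(tau) accepting tau = inf (limit 1 unless psi never fires)."""
    tau = np.asarray(tau, dtype=float)
    out = np.where(np.isinf(tau),
                   0.0 if psi.never else 1.0,
                   psi.cdf(np.where(np.isinf(tau), 0.0, tau)))
    return out


def transmissibility(psi: InterEventDistribution, phi: InterEventDistribution) -> float:
    """Probability p that transmission precedes recovery on one link.

    Ties count as transmission, consistent with the edge-weight rule; this
    only matters in discrete time, where p = sum_r phi(r) Psi(r) with
    Psi(r) = P(transmission step <= r).
    """
    if psi.time_mode != phi.time_mode:
        raise ValueError("psi and phi must share a time mode")
    if isinstance(psi, Deterministic) and phi.time_mode == CONTINUOUS and not phi.never \
            and not isinstance(phi, Deterministic):
        # point-mass transmission at delay T: active iff recovery >= T
        return float(phi.sf(psi.delay))
    return min(1.0, _integrate_against_recovery(phi, lambda tau: _cdf_with_limit(psi, tau)))


def transmissibility_nk(n: int, k: int, psi, phi) -> float:
    """Probability that exactly k of a node's n links are active."""
    if k < 0 or k > n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if n == 0:
        return 1.0 if k == 0 else 0.0
    if isinstance(psi, Deterministic) and phi.time_mode == CONTINUOUS and not phi.never \
            and not isinstance(phi, Deterministic):
        # all links fire together at the fixed delay: k is either 0 or n
        if k == n:
            return float(phi.sf(psi.delay))
        if k == 0:
            return float(phi.cdf(psi.delay))
        return 0.0
    binom = math.comb(n, k)

    def f(tau):
        q = _cdf_with_limit(psi, tau)
        return binom * (1.0 - q) ** (n - k) * q**k

    return float(np.clip(_integrate_against_recovery(phi, f), 0.0, 1.0))


def transmissibility_nk_poisson(n: int, k: int, beta: float, gamma: float) -> float:
    """Closed form of p_{n,k} for exponential psi (rate beta) and phi (rate
    gamma), evaluated via log-gamma differences for numerical stability."""
    if beta <= 0 or gamma <= 0:
        raise ValueError("beta and gamma must be positive")
    if k < 0 or k > n:
        raise ValueError("k must satisfy 0 <= k <= n")
    a = (gamma + beta * (n - k)) / beta
    log_val = (
        math.log(math.comb(n, k))
        + math.log(gamma / beta)
        + gammaln(k + 1)
        + gammaln(a)
        - gammaln(k + 1 + a)
    )
    return float(math.exp(log_val))


@dataclass
class TransmissibilityTable:
    """p_{n,k} for all 0 <= k <= n up to a maximum neighbourhood size."""

    n_max: int
    values: dict
    psi_spec: str
    phi_spec: str

    def __getitem__(self, nk):
        return self.values[nk]

    def row(self, n: int) -> np.ndarray:
        return np.array([self.values[(n, k)] for k in range(n + 1)])


def transmissibility_table(n_max: int, psi, phi) -> TransmissibilityTable:
    values = {
        (n, k): transmissibility_nk(n, k, psi, phi)
        for n in range(1, n_max + 1)
        for k in range(n + 1)
    }
    return TransmissibilityTable(n_max, values, psi.spec(), phi.spec())


# -- percolation components ---------------------------------------------

def percolation_component_size(realization: WeightedRealization, source) -> int:
    """Number of nodes reachable from ``source`` through finite-weight
    edges — the infinite-time outbreak size of this realization."""
    net = realization.network
    mask = _paths.finite_reach_mask(net.indptr, net.arc_dst,
                                    realization.arc_weights, net.index(source))
    return int(mask.sum())


def bond_percolation_component_sizes(network: ContactNetwork, p: float, source,
                                     n: int, rng: np.random.Generator) -> np.ndarray:
    """Component-size samples of plain independent bond percolation.

    Each undirected edge is open with probability ``p`` independently; the
    returned array holds the size of the open component of ``source`` for
    ``n`` independent bond configurations.  Serves as the infinite-time
    reference for the mean-field mapping.
    """
    src = network.index(source)
    sizes = np.empty(n, dtype=np.int64)
    for i in range(n):
        open_edge = rng.random(network.n_edges) < p
        w = np.where(open_edge[network.arc_edge], 1.0, np.inf)
        sizes[i] = _paths.finite_reach_mask(network.indptr, network.arc_dst,
                                            w, src).sum()
    return sizes


# -- parallel-chains toy network -----------------------------------------

def build_toy_network(n_chains: int, chain_length: int) -> ContactNetwork:
    """Source and destination joined by ``n_chains`` disjoint paths of
    ``chain_length`` intermediate nodes each (N = 2 + n_chains*chain_length)."""
    if n_chains < 1 or chain_length < 0:
        raise ValueError("need n_chains >= 1 and chain_length >= 0")
    pairs = []
    for c in range(n_chains):
        prev = "s"
        for j in range(chain_length):
            node = f"c{c}_{j}"
            pairs.append((prev, node))
            prev = node
        pairs.append((prev, "d"))
    return ContactNetwork.from_edge_ids(
        pairs, name=f"toy_{n_chains}x{chain_length}",
        meta={"n_chains": n_chains, "chain_length": chain_length},
    )


def toy_network_probability(n_chains: int, chain_length: int, psi, phi) -> float:
    """Analytic probability that the source ever infects the destination.

    The source's first neighbourhood has ``n_chains`` links whose joint
    activation law is p_{n,j}; an activated chain then delivers the
    infection through its remaining ``chain_length`` hops independently
    with probability p^l, p being the scalar transmissibility.  Hence

        P(s -> d) = 1 - sum_j p_{n,j} (1 - p^l)^j.
    """
    p = transmissibility(psi, phi)
    fail_chain = 1.0 - p**chain_length
    total = 0.0
    for j in range(n_chains + 1):
        total += transmissibility_nk(n_chains, j, psi, phi) * fail_chain**j
    return float(1.0 - total)
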