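"""Reference dynamic Monte Carlo simulators.

These simulate the SIR process forward in time, event by event, and are
entirely independent of the weighted-network mapping: a continuous-time
Gillespie algorithm for the Poissonian case, an event-queue (next
reaction) simulator for arbitrary inter-event laws, and a synchronous
discrete-time chain.  They validate the mapping's first-infection-time and
final-size laws, and power the direct Monte Carlo source-detection
baseline and the vaccination experiments.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from . import _paths
from .distributions import CONTINUOUS, InterEventDistribution
from .netio import ContactNetwork

__all__ = [
    "EventTrace",
    "gillespie_sir",
    "nonmarkovian_sir",
    "discrete_time_sir",
    "discrete_match_counts",
]


@dataclass
class EventTrace:
    """Infection and recovery times of one simulated epidemic.

    Times are ``inf`` for events that never happened; ``final_size`` counts
    every node that was ever infected (including the source).
    """

    infection_time: dict
    recovery_time: dict
    source: str
    final_size: int

    @classmethod
    def _from_arrays(cls, network, inf_t, rec_t, source):
        return cls(
            infection_time=dict(zip(network.node_ids, inf_t.tolist())),
            recovery_time=dict(zip(network.node_ids, rec_t.tolist())),
            source=str(source),
            final_size=int(np.isfinite(inf_t).sum()),
        )

    def states_at(self, t: float) -> dict:
        """S/I/R states at time ``t`` (R from the recovery instant onward)."""
        out = {}
        for v, ti in self.infection_time.items():
            tr = self.recovery_time[v]
            if ti > t:
                out[v] = "S"
            elif t < tr:
                out[v] = "I"
            else:
                out[v] = "R"
        return out


def gillespie_sir(network: ContactNetwork, beta: float, gamma: float, source,
                  rng: np.random.Generator) -> EventTrace:
    """Exact stochastic simulation of the Poissonian SIR process.

    At total rate beta * (#S-I contact arcs) + gamma * (#infected) the next
    event time is exponential; the event is an infection of a uniformly
    chosen S-I arc or a recovery of a uniformly chosen infected node.  With
    gamma = 0 the run terminates when the reachable set is exhausted.
    """
    if beta <= 0 or gamma < 0:
        raise ValueError("need beta > 0 and gamma >= 0")
    n = network.n_nodes
    src = network.index(source)
    indptr, dst = network.indptr, network.arc_dst
    status = np.zeros(n, dtype=np.int8)  # 0 S, 1 I, 2 R
    inf_t = np.full(n, np.inf)
    rec_t = np.full(n, np.inf)
    status[src] = 1
    inf_t[src] = 0.0
    infected = [src]
    # per infected node, its currently susceptible neighbours
    sus_nbrs = {src: [int(u) for u in dst[indptr[src]:indptr[src + 1]] if status[u] == 0]}
    t = 0.0
    while infected:
        n_arcs = sum(len(sus_nbrs[v]) for v in infected)
        rate_inf = beta * n_arcs
        rate_rec = gamma * len(infected)
        total = rate_inf + rate_rec
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if rng.random() * total < rate_inf:
            # uniform choice among S-I arcs
            pick = int(rng.integers(n_arcs))
            for v in infected:
                if pick < len(sus_nbrs[v]):
                    u = sus_nbrs[v][pick]
                    break
                pick -= len(sus_nbrs[v])
            status[u] = 1
            inf_t[u] = t
            infected.append(u)
            sus_nbrs[u] = [int(w) for w in dst[indptr[u]:indptr[u + 1]] if status[w] == 0]
            for v in infected:
                lst = sus_nbrs[v]
                if u in lst:
                    lst.remove(u)
        else:
            pick = int(rng.integers(len(infected)))
            v = infected.pop(pick)
            status[v] = 2
            rec_t[v] = t
            del sus_nbrs[v]
    return EventTrace._from_arrays(network, inf_t, rec_t, source)


def nonmarkovian_sir(network: ContactNetwork, psi: InterEventDistribution,
                     phi: InterEventDistribution, source,
                     rng: np.random.Generator) -> EventTrace:
    """Event-queue simulation for arbitrary continuous inter-event laws.

    On infection of a node at time t its recovery is drawn from phi, and
    for each neighbour a transmission delay from psi whose clock starts at
    t (the renewal convention).  A transmission is scheduled only when the
    delay does not exceed the transmitter's infectious period, and takes
    effect only if the target is still susceptible.
    """
    if psi.time_mode != CONTINUOUS or phi.time_mode != CONTINUOUS:
        raise ValueError("event-queue simulator requires continuous-time laws")
    n = network.n_nodes
    src = network.index(source)
    indptr, dst = network.indptr, network.arc_dst
    inf_t = np.full(n, np.inf)
    rec_t = np.full(n, np.inf)
    queue: list[tuple[float, int]] = []

    def infect(v: int, t: float) -> None:
        inf_t[v] = t
        r = float(phi.inverse_cdf(1.0 - rng.random()))
        rec_t[v] = t + r
        for k in range(indptr[v], indptr[v + 1]):
            u = int(dst[k])
            if np.isfinite(inf_t[u]):
                continue
            delay = float(psi.inverse_cdf(1.0 - rng.random()))
            if delay <= r:  # transmission before (or at) recovery
                heapq.heappush(queue, (t + delay, u))

    infect(src, 0.0)
    while queue:
        t, u = heapq.heappop(queue)
        if not np.isfinite(inf_t[u]):
            infect(u, t)
    return EventTrace._from_arrays(network, inf_t, rec_t, source)


def discrete_time_sir(network: ContactNetwork, beta_prob: float, gamma_prob: float,
                      source, rng: np.random.Generator,
                      vaccination_hook=None, t_max: int = 10**6) -> EventTrace:
    """Synchronous discrete-time SIR chain.

    Each step, every infected node first attempts to infect each
    susceptible neighbour independently with probability ``beta_prob``,
    then recovers with probability ``gamma_prob`` — so a node can still
    transmit during its recovery step and all waiting times are geometric
    on {1, 2, ...}.

    ``vaccination_hook(t, states)`` is invoked at every step boundary
    (including t=0) with the current S/I/R state dict and may return node
    ids to immunize; immunized nodes can never be infected afterwards.
    """
    if not (0.0 <= beta_prob <= 1.0 and 0.0 <= gamma_prob <= 1.0):
        raise ValueError("per-step probabilities must lie in [0, 1]")
    src = network.index(source)
    if vaccination_hook is None:
        seed = int(rng.integers(2**31))
        status, inf_t, rec_t = _paths.discrete_sir_trace(
            network.indptr, network.arc_dst, beta_prob, gamma_prob, src, t_max, seed
        )
        return EventTrace._from_arrays(network, inf_t, rec_t, source)
    # hook-capable pure-Python path (small instances / intervention studies)
    n = network.n_nodes
    indptr, dst = network.indptr, network.arc_dst
    status = np.zeros(n, dtype=np.int8)  # 0 S, 1 I, 2 R, 3 immune
    inf_t = np.full(n, np.inf)
    rec_t = np.full(n, np.inf)
    status[src] = 1
    inf_t[src] = 0.0

    def call_hook(t):
        names = {0: "S", 1: "I", 2: "R", 3: "V"}
        states = {vid: names[int(s)] for vid, s in zip(network.node_ids, status)}
        for vid in vaccination_hook(t, states) or ():
            i = network.index(vid)
            if status[i] == 0:
                status[i] = 3

    call_hook(0)
    t = 0
    while np.any(status == 1) and t < t_max:
        t += 1
        infected = np.flatnonzero(status == 1)
        newly = []
        for v in infected:
            for k in range(indptr[v], indptr[v + 1]):
                u = int(dst[k])
                if status[u] == 0 and rng.random() < beta_prob:
                    status[u] = 4
                    newly.append(u)
        recover = infected[rng.random(infected.size) < gamma_prob]
        status[recover] = 2
        rec_t[recover] = t
        for u in newly:
            status[u] = 1
            inf_t[u] = t
        call_hook(t)
    return EventTrace._from_arrays(network, inf_t, rec_t, source)


def discrete_match_counts(network: ContactNetwork, beta_prob: float,
                          gamma_prob: float, source, t_obs: int,
                          snapshot_codes: np.ndarray, n_runs: int,
                          rng: np.random.Generator) -> int:
    """Count, over ``n_runs`` discrete-time forward simulations seeded at
    ``source``, how many reproduce ``snapshot_codes`` (0=S,1=I,2=R) exactly
    at time ``t_obs``.  This is the direct Monte Carlo matching primitive
    of the source-detection baseline."""
    seed = int(rng.integers(2**31))
    return int(_paths.discrete_sir_match_count(
        network.indptr, network.arc_dst, beta_prob, gamma_prob,
        network.index(source), int(t_obs), snapshot_codes, int(n_runs), seed
    ))
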