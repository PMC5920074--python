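"""Compiled shortest-path and simulation kernels.

All kernels operate on the CSR arc arrays of a :class:`ContactNetwork`
(``indptr``, ``arc_dst``) plus a per-arc weight vector in which ``inf`` is
the first-class "no transmission" sentinel: an infinite weight is never
relaxed, so unreachable targets come out at ``inf`` exactly.

Graphs in this package are small-to-medium (10^2 .. 10^3 nodes) while the
number of sampled realizations is large (10^4 .. 10^5), so the kernels use
a simple linear-scan Dijkstra, O(N^2 + E) per source: for these sizes the
scan beats heap bookkeeping and compiles to tight machine code.  An
optional ``limit`` truncates the search: every node whose true distance is
<= limit is settled exactly; all others are reported as ``inf``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.inf


@njit(cache=False)
def dijkstra(indptr, arc_dst, w, source, limit):
    """Single-source shortest path over finite-weight arcs.

    Returns the distance array; entries whose true distance exceeds
    ``limit`` are ``inf``.
    """
    n = indptr.size - 1
    dist = np.full(n, INF)
    done = np.zeros(n, np.bool_)
    dist[source] = 0.0
    for _ in range(n):
        best = -1
        bd = INF
        for v in range(n):
            if not done[v] and dist[v] < bd:
                bd = dist[v]
                best = v
        if best < 0 or bd > limit:
            break
        done[best] = True
        for k in range(indptr[best], indptr[best + 1]):
            wt = w[k]
            if wt != INF:
                nd = bd + wt
                u = arc_dst[k]
                if nd < dist[u]:
                    dist[u] = nd
    for v in range(n):
        if not done[v]:
            dist[v] = INF
    return dist


@njit(cache=False)
def distance_rows(indptr, arc_dst, W, source, limit):
    """Distances from ``source`` for a batch of realizations.

    ``W`` has shape (n_realizations, n_arcs); returns (n_realizations, N).
    """
    B = W.shape[0]
    n = indptr.size - 1
    out = np.empty((B, n))
    for b in range(B):
        out[b] = dijkstra(indptr, arc_dst, W[b], source, limit)
    return out


@njit(cache=False)
def all_pairs(indptr, arc_dst, w, limit):
    n = indptr.size - 1
    out = np.empty((n, n))
    for s in range(n):
        out[s] = dijkstra(indptr, arc_dst, w, s, limit)
    return out


@njit(cache=False)
def finite_reach_mask(indptr, arc_dst, w, source):
    """Nodes reachable from ``source`` through finite-weight arcs (BFS)."""
    n = indptr.size - 1
    seen = np.zeros(n, np.bool_)
    stack = np.empty(n, np.int64)
    seen[source] = True
    stack[0] = source
    top = 1
    while top > 0:
        top -= 1
        v = stack[top]
        for k in range(indptr[v], indptr[v + 1]):
            if w[k] != INF:
                u = arc_dst[k]
                if not seen[u]:
                    seen[u] = True
                    stack[top] = u
                    top += 1
    return seen


@njit(cache=False)
def component_sizes(indptr, arc_dst, W, source):
    B = W.shape[0]
    out = np.empty(B, np.int64)
    for b in range(B):
        out[b] = finite_reach_mask(indptr, arc_dst, W[b], source).sum()
    return out


@njit(cache=False)
def reach_indicator(indptr, arc_dst, W, source, target):
    B = W.shape[0]
    out = np.empty(B, np.float64)
    for b in range(B):
        out[b] = 1.0 if finite_reach_mask(indptr, arc_dst, W[b], source)[target] else 0.0
    return out


@njit(cache=False)
def snapshot_match_counts(indptr, arc_dst, W, R, candidates, snapshot, t0):
    """Per-(realization, candidate) count of nodes whose predicted S/I/R
    state at time ``t0`` matches the observed snapshot.

    State convention: a node with temporal distance d from the candidate is
    S when d > t0, I when d <= t0 < d + r, and R when t0 >= d + r, where r
    is the realization's recovery draw for that node.  Snapshot codes are
    0=S, 1=I, 2=R.
    """
    B = W.shape[0]
    C = candidates.size
    n = indptr.size - 1
    out = np.zeros((B, C), np.int64)
    for b in range(B):
        for ci in range(C):
            dist = dijkstra(indptr, arc_dst, W[b], candidates[ci], t0)
            m = 0
            for v in range(n):
                d = dist[v]
                if d <= t0:
                    pred = 1 if t0 < d + R[b, v] else 2
                else:
                    pred = 0
                if pred == snapshot[v]:
                    m += 1
            out[b, ci] = m
    return out


# -- discrete-time SIR kernels ------------------------------------------


@njit(cache=False)
def discrete_sir_run(indptr, arc_dst, beta, gamma, source, t_max,
                     status, inf_time, rec_time):
    """Synchronous discrete-time SIR, one run, in-place on state arrays.

    Update order within a step: every infected node attempts to infect each
    susceptible neighbour with probability ``beta``, then recovers with
    probability ``gamma`` — so a node can still transmit during its
    recovery step, and waiting times are geometric on {1, 2, ...}.

    Status codes: 0=S, 1=I, 2=R, 3=immune (vaccinated).  Runs until no
    infected remain or ``t_max`` steps have elapsed; returns the stop time.
    """
    n = indptr.size - 1
    newly = np.empty(n, np.int64)
    status[source] = 1
    inf_time[source] = 0.0
    n_inf = 1
    t = 0
    while n_inf > 0 and t < t_max:
        t += 1
        n_new = 0
        for v in range(n):
            if status[v] == 1:
                for k in range(indptr[v], indptr[v + 1]):
                    u = arc_dst[k]
                    if status[u] == 0 and np.random.random() < beta:
                        status[u] = 4  # mark: infected this step, not yet active
                        newly[n_new] = u
                        n_new += 1
        for v in range(n):
            if status[v] == 1 and np.random.random() < gamma:
                status[v] = 2
                rec_time[v] = t
                n_inf -= 1
        for i in range(n_new):
            u = newly[i]
            status[u] = 1
            inf_time[u] = t
        n_inf += n_new
    return t


@njit(cache=False)
def discrete_sir_match_count(indptr, arc_dst, beta, gamma, source, t_obs,
                             snapshot, n_runs, seed):
    """Number of forward simulations whose S/I/R state at ``t_obs`` exactly
    matches ``snapshot`` (codes 0/1/2), out of ``n_runs`` from ``source``."""
    np.random.seed(seed)
    n = indptr.size - 1
    status = np.empty(n, np.int8)
    inf_time = np.empty(n)
    rec_time = np.empty(n)
    matches = 0
    for _ in range(n_runs):
        status[:] = 0
        inf_time[:] = INF
        rec_time[:] = INF
        discrete_sir_run(indptr, arc_dst, beta, gamma, source, t_obs,
                         status, inf_time, rec_time)
        ok = True
        for v in range(n):
            s = status[v]
            if s == 2 and rec_time[v] > t_obs:
                s = 1  # recovered after the observation instant
            if s != snapshot[v]:
                ok = False
                break
        if ok:
            matches += 1
    return matches


@njit(cache=False)
def discrete_sir_trace(indptr, arc_dst, beta, gamma, source, t_max, seed):
    """Seeded single discrete-time SIR run; returns (status, inf_time, rec_time)."""
    np.random.seed(seed)
    n = indptr.size - 1
    status = np.zeros(n, np.int8)
    inf_time = np.full(n, INF)
    rec_time = np.full(n, INF)
    discrete_sir_run(indptr, arc_dst, beta, gamma, source, t_max,
                     status, inf_time, rec_time)
    return status, inf_time, rec_time


@njit(cache=False)
def discrete_sir_span(indptr, arc_dst, beta, gamma, status, t_start, t_end,
                      t_imm, vacc, cum, seed):
    """Advance a discrete-time SIR state from ``t_start`` to ``t_end``.

    ``cum`` is the cumulative ever-infected count per integer time, with
    entries up to ``t_start`` already filled by the caller.  Nodes listed
    in ``vacc`` that are still susceptible at time ``t_imm`` become immune
    (status 3) at that instant; pass ``t_imm < t_start`` with an empty
    ``vacc`` for an unvaccinated run.
    """
    np.random.seed(seed)
    n = indptr.size - 1
    newly = np.empty(n, np.int64)
    n_inf = 0
    for v in range(n):
        if status[v] == 1:
            n_inf += 1
    if t_imm == t_start:
        for i in range(vacc.size):
            if status[vacc[i]] == 0:
                status[vacc[i]] = 3
    for t in range(t_start + 1, t_end + 1):
        n_new = 0
        if n_inf > 0:
            for v in range(n):
                if status[v] == 1:
                    for k in range(indptr[v], indptr[v + 1]):
                        u = arc_dst[k]
                        if status[u] == 0 and np.random.random() < beta:
                            status[u] = 4
                            newly[n_new] = u
                            n_new += 1
            for v in range(n):
                if status[v] == 1 and np.random.random() < gamma:
                    status[v] = 2
                    n_inf -= 1
            for i in range(n_new):
                status[newly[i]] = 1
            n_inf += n_new
        cum[t] = cum[t - 1] + n_new
        if t == t_imm:
            for i in range(vacc.size):
                if status[vacc[i]] == 0:
                    status[vacc[i]] = 3
    return n_inf
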