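"""End-to-end validation protocols.

Each function runs one self-contained study — analytic toy-network
agreement, equivalence with dynamic Monte Carlo, the bond-percolation
limit, the identity between quadrature and closed-form neighbourhood
transmissibility, Gibbs/independent sampler consistency, source-detection
ranking, vaccination-strategy comparison, and the weak/strong-disorder
scaling of propagation times — and returns plain numbers.  The test suite
asserts on them and the reporting script writes them to JSON.

Problem sizes are chosen so a full pass completes in minutes on one core;
they are stated in the package documentation.
"""

from __future__ import annotations

import numpy as np

from . import _paths, mapping, oracle, percolation, source_detection, vaccination
from .distributions import Exponential, Geometric, LogNormal, si_recovery
from .ensemble import run_gibbs, sample_independent
from .netio import ContactNetwork, generate_er, generate_lattice, generate_scale_free

__all__ = [
    "ks_distance",
    "tv_distance",
    "toy_network_agreement",
    "gillespie_equivalence",
    "lattice_percolation_limit",
    "neighbourhood_transmissibility_identity",
    "sampler_consistency",
    "source_detection_experiment",
    "vaccination_experiment",
    "disorder_scaling",
]


# -- small statistical helpers ------------------------------------------

def ks_distance(x, y) -> float:
    """Two-sample Kolmogorov–Smirnov distance, tolerating masses at +inf.

    The supremum is taken over the finite support; a differing probability
    of the infinite outcome shows up at the largest finite point.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pts = np.concatenate([x[np.isfinite(x)], y[np.isfinite(y)]])
    if pts.size == 0:
        return 0.0
    fx = np.searchsorted(x, pts, side="right") / x.size
    fy = np.searchsorted(y, pts, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))


def tv_distance(x, y) -> float:
    """Total-variation distance between two empirical discrete laws."""
    x = np.asarray(x)
    y = np.asarray(y)
    support = np.union1d(x, y)
    px = np.array([(x == v).mean() for v in support])
    py = np.array([(y == v).mean() for v in support])
    return float(0.5 * np.abs(px - py).sum())


def _linfit_r2(xs, ys) -> float:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    coef = np.polyfit(xs, ys, 1)
    resid = ys - np.polyval(coef, xs)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


# -- 1. toy-network analytic agreement ----------------------------------

def toy_network_agreement(seed: int, n_realizations: int = 100_000,
                          n_chains: int = 20, chain_length: int = 3,
                          beta: float = 1.0, gamma: float = 1.0) -> dict:
    """Source-to-destination reach probability on the parallel-chains toy
    network: analytic formula vs exact-mapping and mean-field Monte Carlo."""
    rng = np.random.default_rng(seed)
    psi, phi = Exponential(beta), Exponential(gamma)
    net = percolation.build_toy_network(n_chains, chain_length)
    analytic = percolation.toy_network_probability(n_chains, chain_length, psi, phi)
    s, d = net.index("s"), net.index("d")
    out = {"analytic": analytic, "n": n_realizations}
    for mode in ("exact", "meanfield"):
        hits = np.empty(n_realizations)
        done = 0
        while done < n_realizations:
            b = min(20_000, n_realizations - done)
            W, _ = mapping.sample_weights_batch(net, psi, phi, mode, b, rng)
            hits[done:done + b] = _paths.reach_indicator(net.indptr, net.arc_dst, W, s, d)
            done += b
        out[mode] = float(hits.mean())
        out[mode + "_se"] = float(hits.std(ddof=1) / np.sqrt(n_realizations))
    return out


# -- 2. equivalence with the Gillespie oracle ---------------------------

def _benchmark_graphs(seed: int):
    rng = np.random.default_rng(seed)
    path3 = ContactNetwork.from_edge_ids([("a", "b"), ("b", "c")], name="path3")
    star4 = ContactNetwork.from_edge_ids(
        [("c", "l1"), ("c", "l2"), ("c", "l3")], name="star4")
    er8 = generate_er(8, 3.0, rng)
    return [(path3, "a"), (star4, "c"), (er8, er8.node_ids[0])]


def gillespie_equivalence(seed: int, n_samples: int = 10_000,
                          gammas=(0.0, 0.5, 1.0), beta: float = 1.0) -> dict:
    """First-infection-time and final-size laws: exact mapping vs Gillespie.

    For every benchmark graph and recovery rate, compares per-target
    first-infection-time samples (KS) and final-size samples (TV).
    """
    rng = np.random.default_rng(seed)
    max_ks, max_tv = 0.0, 0.0
    for net, source in _benchmark_graphs(seed + 1):
        src = net.index(source)
        for gamma in gammas:
            psi = Exponential(beta)
            phi = Exponential(gamma) if gamma > 0 else si_recovery()
            W, _ = mapping.sample_weights_batch(net, psi, phi, "exact", n_samples, rng)
            dist = _paths.distance_rows(net.indptr, net.arc_dst, W, src, np.inf)
            sizes_map = np.isfinite(dist).sum(axis=1)
            inf_times = np.full((n_samples, net.n_nodes), np.inf)
            sizes_gil = np.empty(n_samples)
            for k in range(n_samples):
                trace = oracle.gillespie_sir(net, beta, gamma, source, rng)
                inf_times[k] = [trace.infection_time[v] for v in net.node_ids]
                sizes_gil[k] = trace.final_size
            for j in range(net.n_nodes):
                if j == src:
                    continue
                max_ks = max(max_ks, ks_distance(dist[:, j], inf_times[:, j]))
            max_tv = max(max_tv, tv_distance(sizes_map, sizes_gil))
    return {"max_ks": max_ks, "max_tv": max_tv, "n": n_samples}


# -- 3. bond-percolation limit on the lattice ---------------------------

def lattice_percolation_limit(seed: int, betas=(0.3, 0.003),
                              gamma: float = 0.001,
                              n_realizations: int = 1000) -> dict:
    """Late-time mean outbreak of the mean-field mapping vs plain bond
    percolation at p = beta/(beta+gamma) on an 11x11 lattice."""
    rng = np.random.default_rng(seed)
    net = generate_lattice(11, 11)
    source = "5_5"
    src = net.index(source)
    out = {"n": n_realizations}
    for beta in betas:
        psi, phi = Exponential(beta), Exponential(gamma)
        W, _ = mapping.sample_weights_batch(net, psi, phi, "meanfield",
                                            n_realizations, rng)
        sizes_map = _paths.component_sizes(net.indptr, net.arc_dst, W, src)
        p = beta / (beta + gamma)
        sizes_bond = percolation.bond_percolation_component_sizes(
            net, p, source, n_realizations, rng)
        key = f"beta_{beta:g}"
        out[key] = {
            "mapping_mean": float(sizes_map.mean()),
            "mapping_se": float(sizes_map.std(ddof=1) / np.sqrt(n_realizations)),
            "bond_mean": float(sizes_bond.mean()),
            "bond_se": float(sizes_bond.std(ddof=1) / np.sqrt(n_realizations)),
            "p": p,
        }
    return out


# -- 4. neighbourhood transmissibility: quadrature vs closed form -------

def neighbourhood_transmissibility_identity(n_max: int = 5) -> dict:
    """Agreement of the p_{n,k} quadrature with the Poissonian closed form,
    row normalization, and the p_{1,1} = beta/(beta+gamma) identity."""
    rates = [(1.0, 1.0), (1.0, 0.5), (2.0, 0.7)]
    max_err = 0.0
    max_norm_err = 0.0
    max_p11_err = 0.0
    for beta, gamma in rates:
        psi, phi = Exponential(beta), Exponential(gamma)
        for n in range(1, n_max + 1):
            row = np.array([percolation.transmissibility_nk(n, k, psi, phi)
                            for k in range(n + 1)])
            closed = np.array([percolation.transmissibility_nk_poisson(n, k, beta, gamma)
                               for k in range(n + 1)])
            max_err = max(max_err, float(np.max(np.abs(row - closed))))
            max_norm_err = max(max_norm_err, abs(float(row.sum()) - 1.0))
        p11 = percolation.transmissibility(psi, phi)
        max_p11_err = max(max_p11_err, abs(p11 - beta / (beta + gamma)))
    return {"max_abs_error": max_err, "max_norm_error": max_norm_err,
            "max_p11_error": max_p11_err, "n_max": n_max}


# -- 5. Gibbs vs independent sampling -----------------------------------

def sampler_consistency(seed: int, n_independent: int = 2000,
                        n_retained: int = 600) -> dict:
    """Three statistics (finite-edge fraction, outbreak size at t=1,
    truncated pairwise distance) estimated by both samplers on a 20-node
    Erdős–Rényi graph; reports the discrepancy in combined SE units."""
    rng = np.random.default_rng(seed)
    net = generate_er(20, 4.0, rng, connected=True)
    psi, phi = Exponential(1.0), Exponential(0.5)
    a, b = net.node_ids[0], net.node_ids[-1]
    src = net.index(a)
    trunc = 20.0

    def stats(re):
        dist = _paths.dijkstra(net.indptr, net.arc_dst, re.arc_weights, src, np.inf)
        return np.array([
            re.finite_fraction(),
            float(np.sum(dist <= 1.0)),
            min(float(dist[net.index(b)]), trunc),
        ])

    est_ind = sample_independent(net, psi, phi, "exact", n_independent, rng, stats)
    burn = 10 * net.n_nodes
    thin = net.n_nodes
    est_gibbs = run_gibbs(net, psi, phi, "exact",
                          burn + thin * n_retained, rng, stats,
                          burn_in=burn, thinning=thin)
    z = np.abs(np.asarray(est_ind.mean) - np.asarray(est_gibbs.mean)) / np.sqrt(
        np.asarray(est_ind.std_error) ** 2 + np.asarray(est_gibbs.std_error) ** 2
    )
    names = ["finite_fraction", "outbreak_size_t1", "pair_distance"]
    return {
        "z": dict(zip(names, z.tolist())),
        "independent": dict(zip(names, np.asarray(est_ind.mean).tolist())),
        "gibbs": dict(zip(names, np.asarray(est_gibbs.mean).tolist())),
        "n_independent": n_independent,
        "n_retained": est_gibbs.n_samples,
    }


# -- 6. source detection on the lattice ---------------------------------

def source_detection_experiment(seed: int, n_replicates: int = 30,
                                m_samples: int = 10_000, n_mc: int = 10_000,
                                rows: int = 10, cols: int = 10,
                                beta: float = 0.7, gamma: float = 0.3,
                                t_obs: int = 5) -> dict:
    """Discrete-time snapshot source detection on a 4-connected lattice.

    For each replicate an epidemic is simulated to the observation time,
    the three estimators score the infected-or-recovered candidates, and
    the direct-MC top candidate (temporal tie-break) is located in the
    temporal and topological rankings.  Reports the mean rank under each.
    """
    rng = np.random.default_rng(seed)
    net = generate_lattice(rows, cols)
    psi, phi = Geometric(beta), Geometric(gamma)
    ranks_temporal, ranks_topo, agree_direct = [], [], []
    for _ in range(n_replicates):
        true_source = net.node_ids[int(rng.integers(net.n_nodes))]
        trace = oracle.discrete_time_sir(net, beta, gamma, true_source, rng,
                                         t_max=t_obs)
        snap = source_detection.Snapshot(trace.states_at(t_obs), float(t_obs))
        temporal = source_detection.estimate_source_temporal(
            net, psi, phi, snap, t_obs, m_samples, rng)
        direct = source_detection.estimate_source_direct_mc(
            net, psi, phi, snap, t_obs, n_mc, rng)
        topo = source_detection.estimate_source_topological(net, snap)
        top = direct.rank(tie_breaker=temporal)[0]
        ranks_temporal.append(temporal.rank().index(top) + 1)
        ranks_topo.append(topo.rank().index(top) + 1)
        agree_direct.append(top == temporal.rank()[0])
    return {
        "mean_rank_temporal": float(np.mean(ranks_temporal)),
        "mean_rank_topological": float(np.mean(ranks_topo)),
        "top1_agreement_fraction": float(np.mean(agree_direct)),
        "n_replicates": n_replicates,
        "m_samples": m_samples,
        "n_mc": n_mc,
    }


# -- 7. time-critical vaccination ---------------------------------------

def vaccination_experiment(seed: int, n_nodes: int = 1000, n_runs: int = 200,
                           beta: float = 0.03, gamma: float = 0.01,
                           t0: int = 3, delta_t: int = 10,
                           vaccine_fraction: float = 0.2,
                           horizon: int = 800, attachment: int = 7,
                           n_survival: int = 1000) -> dict:
    """Vaccination-strategy comparison on a scale-free network.

    Discrete-time SIR from a fixed source; m = 0.2 N doses administered at
    t0, effective at t0 + dt.  Compares mean final epidemic sizes of the
    survival-probability-guided, uniformly random and degree-targeted
    strategies, with 95% confidence intervals and mean wasted doses.

    The preferential-attachment network stands in for an online-social
    contact graph; ``attachment=7`` matches that class's mean degree
    (~13.5).  At this density the epidemic is far above threshold, so the
    strategies separate through wasted doses: hubs are infected early, so
    degree-targeted doses are disproportionately wasted.
    """
    rng = np.random.default_rng(seed)
    net = generate_scale_free(n_nodes, attachment, rng)
    psi, phi = Geometric(beta), Geometric(gamma)
    source = "10"
    m = int(round(vaccine_fraction * net.n_nodes))
    p_tilde = vaccination.survival_probability(
        net, psi, phi, "exact", source, t0, delta_t, n_survival, rng)
    out = {"m": m, "n_runs": n_runs, "source": source}
    for strategy in ("temporal", "random", "hubs"):
        res = vaccination.simulate_with_vaccination(
            net, psi, phi, source, strategy, m, t0, delta_t, horizon,
            n_runs, rng, p_tilde=p_tilde)
        half = 1.96 * res.se_final_size
        out[strategy] = {
            "final_mean": res.mean_final_size,
            "final_se": res.se_final_size,
            "ci95": [res.mean_final_size - half, res.mean_final_size + half],
            "wasted_mean": float(res.wasted.mean()),
        }
    return out


# -- 8. weak vs strong disorder -----------------------------------------

def disorder_scaling(seed: int, sizes=(50, 100, 200, 400),
                     n_graphs: int = 8, n_realizations: int = 5,
                     mean_degree: float = 6.0, sigma: float = 3.0) -> dict:
    """Scaling of the mean SI propagation time with system size on
    Erdős–Rényi graphs: logarithmic for exponential waiting times (weak
    disorder), closer to a power law for broad lognormal ones (strong
    disorder).  Reports R^2 of a linear fit in log N and in log-log.

    Each size is averaged over several independent graph instances
    (graph-to-graph variability dominates the weight noise at these sizes)
    with several weight realizations each.
    """
    rng = np.random.default_rng(seed)
    phi = si_recovery()
    families = {"exponential": Exponential(1.0),
                "lognormal": LogNormal(0.0, sigma)}
    mean_d = {name: [] for name in families}
    median_d = {name: [] for name in families}
    actual_sizes = []
    for n in sizes:
        nets = [generate_er(n, mean_degree, rng, connected=True)
                for _ in range(n_graphs)]
        actual_sizes.append(float(np.mean([g.n_nodes for g in nets])))
        for name, psi in families.items():
            means, medians = [], []
            for net in nets:
                offdiag = ~np.eye(net.n_nodes, dtype=bool)
                for _ in range(n_realizations):
                    W, _ = mapping.sample_weights_batch(net, psi, phi,
                                                        "meanfield", 1, rng)
                    d = _paths.all_pairs(net.indptr, net.arc_dst, W[0], np.inf)
                    means.append(d[offdiag].mean())
                    medians.append(np.median(d[offdiag]))
            mean_d[name].append(float(np.mean(means)))
            median_d[name].append(float(np.mean(medians)))
    logn = np.log(actual_sizes)
    out = {"sizes": actual_sizes, "mean_distance": mean_d,
           "median_distance": median_d, "n_graphs": n_graphs,
           "n_realizations": n_realizations}
    # Mean-based fits implement the disorder contrast directly; the median
    # (typical distance) is reported alongside because the pairwise mean
    # under a broad lognormal is dominated by single extreme edge weights.
    for name in families:
        out[f"r2_logN_{name}"] = _linfit_r2(logn, mean_d[name])
        out[f"r2_loglog_{name}"] = _linfit_r2(logn, np.log(mean_d[name]))
        ys = np.asarray(median_d[name])
        out[f"r2_logN_{name}_median"] = _linfit_r2(logn, ys)
        out[f"r2_loglog_{name}_median"] = _linfit_r2(logn, np.log(ys))
    return out
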