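import numpy as np
import pytest

from sirpaths import _paths, oracle
from sirpaths.distributions import Exponential, si_recovery
from sirpaths.mapping import (
    WeightedRealization,
    generate_realization_exact,
    generate_realization_meanfield,
    sample_weights_batch,
)
from sirpaths.netio import ContactNetwork, generate_er
from sirpaths.observables import (
    DistanceMatrix,
    characteristic_timescale,
    expected_propagation_matrix,
    node_states_at,
    outbreak_size_curve,
    temporal_distances,
)
from sirpaths.validation import ks_distance


def _fixed_realization(net, arc_weight_map, psi=None, phi=None, recovery=None):
    """Build a realization with hand-set directed weights."""
    w = np.full(net.n_arcs, np.inf)
    for (a, b), val in arc_weight_map.items():
        ai, bi = net.index(a), net.index(b)
        lo, hi = net.indptr[ai], net.indptr[ai + 1]
        k = lo + int(np.searchsorted(net.arc_dst[lo:hi], bi))
        w[k] = val
    return WeightedRealization(net, "exact", w, psi or Exponential(1.0),
                               phi or Exponential(1.0), node_recovery=recovery)


class TestTemporalDistances:
    def test_source_distance_zero(self, path3, rng):
        re = generate_realization_exact(path3, Exponential(1.0), si_recovery(), rng)
        assert temporal_distances(re, "a")["a"] == 0.0

    def test_chain_distances_sum(self, path3):
        re = _fixed_realization(path3, {("a", "b"): 1.2, ("b", "c"): 0.7})
        d = temporal_distances(re, "a")
        assert d["b"] == pytest.approx(1.2)
        assert d["c"] == pytest.approx(1.9)

    def test_unreachable_is_infinite(self, path3):
        re = _fixed_realization(path3, {("a", "b"): 1.0})
        assert np.isinf(temporal_distances(re, "a")["c"])

    def test_unknown_source_rejected(self, path3, rng):
        re = generate_realization_exact(path3, Exponential(1.0), si_recovery(), rng)
        with pytest.raises(KeyError):
            temporal_distances(re, "zz")

    def test_matches_scipy_dijkstra(self, rng):
        """Cross-check the compiled kernel against an independent solver."""
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import dijkstra as scipy_dijkstra
        net = generate_er(40, 4.0, rng)
        re = generate_realization_exact(net, Exponential(1.0), Exponential(0.5), rng)
        w = re.arc_weights
        finite = np.isfinite(w)
        mat = csr_matrix(
            (w[finite],
             (net.arc_src[finite], net.arc_dst[finite])),
            shape=(net.n_nodes, net.n_nodes),
        )
        ref = scipy_dijkstra(mat, indices=0)
        mine = _paths.dijkstra(net.indptr, net.arc_dst, w, 0, np.inf)
        assert np.allclose(ref, mine, equal_nan=False)

    def test_triangle_inequality(self, rng):
        net = generate_er(15, 4.0, rng)
        re = generate_realization_meanfield(net, Exponential(1.0), Exponential(1.0), rng)
        d = _paths.all_pairs(net.indptr, net.arc_dst, re.arc_weights, np.inf)
        finite = np.isfinite(d)
        for i in range(net.n_nodes):
            for j in range(net.n_nodes):
                if not finite[i, j]:
                    continue
                via = d[i] + d[:, j]
                assert d[i, j] <= np.min(via) + 1e-9

    def test_first_infection_law_matches_gillespie(self, path3, rng):
        """Joint first-infection-time law: exact mapping vs dynamic simulation."""
        beta, gamma, n = 1.0, 0.7, 4000
        W, _ = sample_weights_batch(path3, Exponential(beta), Exponential(gamma),
                                    "exact", n, rng)
        src = path3.index("a")
        dist = _paths.distance_rows(path3.indptr, path3.arc_dst, W, src, np.inf)
        gil = np.empty((n, path3.n_nodes))
        for k in range(n):
            tr = oracle.gillespie_sir(path3, beta, gamma, "a", rng)
            gil[k] = [tr.infection_time[v] for v in path3.node_ids]
        for j in range(path3.n_nodes):
            if j == src:
                continue
            assert ks_distance(dist[:, j], gil[:, j]) < 0.04


class TestNodeStates:
    def test_time_zero_only_source_infected(self, path3, rng):
        re = generate_realization_exact(path3, Exponential(1.0), Exponential(1.0), rng)
        sv = node_states_at(re, "a", 0.0)
        assert sv.states["a"] == "I"
        assert sv.states["b"] == sv.states["c"] == "S"

    def test_infinite_time_reached_nodes_recover(self, path3, rng):
        re = generate_realization_exact(path3, Exponential(1.0), Exponential(1.0), rng)
        d = temporal_distances(re, "a")
        sv = node_states_at(re, "a", 1e12)
        for v, s in sv.states.items():
            assert s == ("R" if np.isfinite(d[v]) else "S")

    def test_recovery_boundary_convention(self, single_edge):
        rec = np.array([5.0, 2.0])  # order: a, b
        re = _fixed_realization(single_edge, {("a", "b"): 1.0, ("b", "a"): 1.0},
                                recovery=rec)
        assert node_states_at(re, "a", 2.5).states["b"] == "I"
        assert node_states_at(re, "a", 3.0).states["b"] == "R"

    def test_meanfield_with_recovery_refuses(self, single_edge, rng):
        re = generate_realization_meanfield(single_edge, Exponential(1.0),
                                            Exponential(1.0), rng)
        with pytest.raises(ValueError, match="exact mode"):
            node_states_at(re, "a", 1.0)

    def test_meanfield_si_is_fine(self, single_edge, rng):
        re = generate_realization_meanfield(single_edge, Exponential(1.0),
                                            si_recovery(), rng)
        sv = node_states_at(re, "a", 1e9)
        assert sv.states["b"] == "I"


class TestOutbreakCurve:
    def test_starts_at_source_and_monotone(self, path3, rng):
        est = outbreak_size_curve(path3, Exponential(1.0), Exponential(1.0),
                                  "exact", "a", [0.0, 0.5, 1.0, 2.0], 500, rng)
        assert est.mean[0] == 1.0
        assert np.all(np.diff(est.mean) >= 0)

    def test_empty_times_rejected(self, path3, rng):
        with pytest.raises(ValueError):
            outbreak_size_curve(path3, Exponential(1.0), Exponential(1.0),
                                "exact", "a", [], 10, rng)


class TestPropagationMatrix:
    def test_si_edge_mean_is_inverse_rate(self, single_edge, rng):
        D = expected_propagation_matrix(single_edge, Exponential(1.0), si_recovery(),
                                        "meanfield", 4000, rng)
        i, j = 0, 1
        assert D.values[i, i] == 0.0
        assert not D.divergence_flag[i, j]
        assert D.values[i, j] == pytest.approx(1.0, abs=0.06)

    def test_si_connected_never_diverges(self, rng):
        net = generate_er(12, 4.0, rng, connected=True)
        D = expected_propagation_matrix(net, Exponential(1.0), si_recovery(),
                                        "meanfield", 50, rng)
        assert not D.divergence_flag.any()

    def test_divergence_flagged_with_recovery(self, single_edge, rng):
        D = expected_propagation_matrix(single_edge, Exponential(1.0),
                                        Exponential(5.0), "exact", 300, rng)
        assert D.divergence_flag[0, 1]
        assert D.finite_fraction[0, 1] == pytest.approx(1 / 6, abs=0.1)

    def test_csv_round_trip_header(self, single_edge, rng, tmp_path):
        D = expected_propagation_matrix(single_edge, Exponential(1.0), si_recovery(),
                                        "meanfield", 10, rng)
        p = tmp_path / "d.csv"
        D.to_csv(p)
        header = p.read_text().splitlines()[0]
        assert header == "," + ",".join(single_edge.node_ids)


class TestCharacteristicTimescale:
    def _matrix(self, rows):
        n = len(rows)
        return DistanceMatrix(tuple(str(i) for i in range(n)), np.asarray(rows),
                              1, np.zeros((n, n), bool), np.ones((n, n)))

    def test_star_center(self):
        D = self._matrix([[0, 2.0, 2.0, 2.0], [2, 0, 4, 4], [2, 4, 0, 4], [2, 4, 4, 0]])
        assert characteristic_timescale(D, 3)["0"] == 2.0

    def test_order_statistic_with_infinities(self):
        D = self._matrix([[0, 1, 2, 3, np.inf]] + [[1, 0, 9, 9, 9]] * 4)
        assert characteristic_timescale(D, 3)["0"] == 3.0
        assert np.isinf(characteristic_timescale(D, 4)["0"])

    def test_monotone_in_nbar(self):
        D = self._matrix(np.abs(np.subtract.outer(np.arange(6.0), np.arange(6.0))))
        taus = [characteristic_timescale(D, nb)["2"] for nb in range(1, 6)]
        assert np.all(np.diff(taus) >= 0)

    def test_validation(self):
        D = self._matrix([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            characteristic_timescale(D, 0)
        with pytest.raises(ValueError):
            characteristic_timescale(D, 2)
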