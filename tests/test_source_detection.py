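import numpy as np
import pytest

from sirpaths import oracle
from sirpaths.distributions import Geometric
from sirpaths.netio import ContactNetwork, generate_lattice
from sirpaths.observables import NodeStateVector
from sirpaths.source_detection import (
    Snapshot,
    SourceScores,
    estimate_source_direct_mc,
    estimate_source_temporal,
    estimate_source_topological,
    kernel_score,
    rank_sources,
    similarity,
)


def _snapshot(states, t0=2.0):
    return Snapshot(dict(states), t0)


class TestSimilarity:
    def test_identical_is_one(self):
        sv = NodeStateVector({"a": "I", "b": "S"}, 1.0)
        assert similarity(sv, _snapshot({"a": "I", "b": "S"})) == 1.0

    def test_disjoint_is_zero(self):
        sv = NodeStateVector({str(i): "S" for i in range(10)}, 1.0)
        snap = _snapshot({str(i): "I" for i in range(10)})
        assert similarity(sv, snap) == 0.0

    def test_counting(self):
        n = 12
        sv = NodeStateVector({str(i): "I" for i in range(n)}, 1.0)
        states = {str(i): ("I" if i < 9 else "R") for i in range(n)}
        assert similarity(sv, _snapshot(states)) == 0.75

    def test_node_set_mismatch(self):
        sv = NodeStateVector({"a": "I"}, 1.0)
        with pytest.raises(ValueError):
            similarity(sv, _snapshot({"a": "I", "b": "S"}))


class TestKernel:
    def test_exact_match_scores_one(self):
        assert kernel_score(1.0, 0.5) == 1.0

    def test_plug_in(self):
        assert kernel_score(0.0, 1.0) == pytest.approx(np.exp(-1))

    def test_monotone_in_similarity(self):
        vals = [kernel_score(p, 0.3) for p in np.linspace(0, 1, 20)]
        assert np.all(np.diff(vals) > 0)

    def test_bandwidth_validation(self):
        with pytest.raises(ValueError):
            kernel_score(0.5, 0.0)


class TestTemporalEstimator:
    def test_two_node_symmetry_breaking(self, single_edge, rng):
        snap = _snapshot({"a": "I", "b": "S"}, t0=1.0)
        scores = estimate_source_temporal(single_edge, Geometric(0.5), Geometric(0.3),
                                          snap, 1, 2000, rng, candidates=["a", "b"])
        assert scores.scores["a"] > scores.scores["b"]
        assert sum(scores.scores.values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_signal_rejected(self, single_edge, rng):
        snap = _snapshot({"a": "S", "b": "S"})
        with pytest.raises(ValueError, match="no infected"):
            estimate_source_temporal(single_edge, Geometric(0.5), Geometric(0.3),
                                     snap, 2, 100, rng)

    def test_symmetric_candidates_score_equally(self, rng):
        """On a path with a symmetric snapshot the two ends are exchangeable."""
        net = ContactNetwork.from_edge_ids([("a", "b"), ("b", "c")])
        snap = _snapshot({"a": "I", "b": "I", "c": "I"}, t0=2.0)
        scores = estimate_source_temporal(net, Geometric(0.5), Geometric(0.3),
                                          snap, 2, 40_000, rng)
        assert scores.scores["a"] == pytest.approx(scores.scores["c"], abs=0.02)

    def test_se_shrinks_with_samples(self, single_edge):
        """Score estimates tighten as O(m^-1/2): spread across repeats."""
        def spread(m):
            vals = [
                estimate_source_temporal(
                    single_edge, Geometric(0.5), Geometric(0.3),
                    _snapshot({"a": "I", "b": "S"}, 1.0), 1, m,
                    np.random.default_rng(100 + k), candidates=["a", "b"],
                ).scores["a"]
                for k in range(12)
            ]
            return np.std(vals)

        assert spread(4000) < spread(40) * 0.5


class TestDirectMC:
    def test_deterministic_dynamics_identify_source(self, rng):
        net = ContactNetwork.from_edge_ids([("a", "b"), ("b", "c"), ("c", "d")])
        tr = oracle.discrete_time_sir(net, 1.0, 1.0, "a", rng)
        snap = _snapshot(tr.states_at(2), t0=2.0)
        scores = estimate_source_direct_mc(net, Geometric(1.0), Geometric(1.0),
                                           snap, 2, 200, rng,
                                           candidates=list(net.node_ids))
        assert scores.scores["a"] == 1.0
        assert all(scores.scores[v] == 0.0 for v in "bcd")

    def test_scores_normalize(self, rng):
        net = generate_lattice(4, 4)
        tr = oracle.discrete_time_sir(net, 0.7, 0.3, "1_1", rng, t_max=3)
        snap = _snapshot(tr.states_at(3), t0=3.0)
        scores = estimate_source_direct_mc(net, Geometric(0.7), Geometric(0.3),
                                           snap, 3, 2000, rng)
        if scores.normalized:
            assert sum(scores.scores.values()) == pytest.approx(1.0, abs=1e-12)
        counts = scores.meta["match_counts"]
        assert all(isinstance(c, int) and c >= 0 for c in counts.values())


class TestTopological:
    def test_single_infected_node_wins(self, path3):
        snap = _snapshot({"a": "I", "b": "S", "c": "S"})
        scores = estimate_source_topological(path3, snap)
        assert scores.top() == "a"

    def test_center_of_symmetric_ball(self):
        net = generate_lattice(5, 5)
        states = {v: "S" for v in net.node_ids}
        for v in ("2_2", "1_2", "3_2", "2_1", "2_3"):
            states[v] = "I"
        scores = estimate_source_topological(net, _snapshot(states))
        assert scores.top() == "2_2"

    def test_relabeling_invariance(self):
        """Scores follow the structure, not the labels (path reversal)."""
        n1 = ContactNetwork.from_edge_ids([("a", "b"), ("b", "c"), ("c", "d")])
        n2 = ContactNetwork.from_edge_ids([("d", "c"), ("c", "b"), ("b", "a")])
        snap1 = _snapshot({"a": "I", "b": "I", "c": "R", "d": "S"})
        snap2 = _snapshot({"d": "I", "c": "I", "b": "R", "a": "S"})
        s1 = estimate_source_topological(n1, snap1).scores
        s2 = estimate_source_topological(n2, snap2).scores
        for x, y in [("a", "d"), ("b", "c"), ("c", "b")]:
            assert s1[x] == pytest.approx(s2[y], abs=1e-12)


class TestRanking:
    def test_plain_sort(self):
        s = SourceScores({"a": 0.2, "b": 0.5, "c": 0.3}, "m", True)
        assert rank_sources(s) == ["b", "c", "a"]

    def test_tie_broken_by_secondary_estimator(self):
        s = SourceScores({"a": 0.5, "b": 0.5}, "m", True)
        tb = SourceScores({"a": 0.1, "b": 0.9}, "m2", True)
        assert rank_sources(s, tb) == ["b", "a"]
        assert rank_sources(s) == ["a", "b"]  # id fallback is deterministic

    def test_output_is_permutation(self):
        s = SourceScores({str(i): 0.125 for i in range(8)}, "m", True)
        assert sorted(rank_sources(s)) == sorted(s.scores)


class TestSnapshotIO:
    def test_csv_round_trip(self, tmp_path):
        snap = _snapshot({"a": "I", "b": "S", "c": "R"}, t0=4.0)
        p = tmp_path / "snap.csv"
        snap.write_csv(p)
        back = Snapshot.read_csv(p, 4.0)
        assert back.states == snap.states

    def test_invalid_state_rejected(self, tmp_path):
        p = tmp_path / "snap.csv"
        p.write_text("node_id,state\na,X\n")
        with pytest.raises(ValueError, match="invalid state"):
            Snapshot.read_csv(p, 1.0)
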