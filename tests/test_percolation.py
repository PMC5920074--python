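import math

import numpy as np
import pytest

from sirpaths.distributions import (
    Deterministic,
    Exponential,
    Geometric,
    LogNormal,
    si_recovery,
)
from sirpaths.mapping import generate_realization_meanfield, sample_weights_batch
from sirpaths.netio import generate_lattice
from sirpaths.percolation import (
    bond_percolation_component_sizes,
    build_toy_network,
    percolation_component_size,
    toy_network_probability,
    transmissibility,
    transmissibility_nk,
    transmissibility_nk_poisson,
    transmissibility_table,
)


class TestTransmissibility:
    def test_poisson_closed_form(self):
        assert transmissibility(Exponential(1.0), Exponential(1.0)) == pytest.approx(0.5, abs=1e-9)
        assert transmissibility(Exponential(3.0), Exponential(1.0)) == pytest.approx(0.75, abs=1e-9)

    def test_si_limit_is_one(self):
        assert transmissibility(Exponential(0.2), si_recovery()) == 1.0
        assert transmissibility(Geometric(0.2), si_recovery("discrete")) == 1.0

    def test_deterministic_recovery_closed_form(self):
        beta, T = 0.5, 2.0
        val = transmissibility(Exponential(beta), Deterministic(T))
        assert val == pytest.approx(1 - math.exp(-beta * T), abs=1e-12)

    def test_deterministic_transmission(self):
        # point-mass transmission at T succeeds iff recovery lasts past T
        gamma, T = 0.8, 1.5
        val = transmissibility(Deterministic(T), Exponential(gamma))
        assert val == pytest.approx(math.exp(-gamma * T), abs=1e-12)

    def test_discrete_geometric_sum(self):
        # sum_t gamma (1-gamma)^(t-1) (1 - (1-beta)^t)
        beta, gamma = 0.7, 0.3
        expected = sum(gamma * (1 - gamma) ** (t - 1) * (1 - (1 - beta) ** t)
                       for t in range(1, 500))
        val = transmissibility(Geometric(beta), Geometric(gamma))
        assert val == pytest.approx(expected, abs=1e-10)

    def test_lognormal_recovery_quadrature_vs_mc(self, rng):
        psi, phi = Exponential(1.0), LogNormal(0.0, 1.0)
        p = transmissibility(psi, phi)
        r = phi.sample(rng, 200_000)
        t = psi.sample(rng, 200_000)
        mc = (t <= r).mean()
        assert abs(p - mc) < 3 * np.sqrt(mc * (1 - mc) / 200_000) + 1e-3

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            transmissibility(Exponential(1.0), Geometric(0.5))


class TestNeighbourhoodTransmissibility:
    def test_reduces_to_scalar_at_n1(self):
        psi, phi = Exponential(1.3), Exponential(0.6)
        assert transmissibility_nk(1, 1, psi, phi) == pytest.approx(
            transmissibility(psi, phi), abs=1e-9)

    @pytest.mark.parametrize("psi,phi", [
        (Exponential(1.0), Exponential(1.0)),
        (Exponential(2.0), LogNormal(0.0, 1.0)),
        (Exponential(1.0), Deterministic(2.0)),
        (Geometric(0.4), Geometric(0.2)),
    ], ids=["poisson", "lognormal-recovery", "fixed-recovery", "discrete"])
    def test_rows_normalize(self, psi, phi):
        for n in range(1, 7):
            row = sum(transmissibility_nk(n, k, psi, phi) for k in range(n + 1))
            assert row == pytest.approx(1.0, abs=1e-10)

    def test_poisson_closed_form_simple_value(self):
        # C(1,1)*(g/b)*Gamma(2)Gamma(1)/Gamma(3) = 1/2
        assert transmissibility_nk_poisson(1, 1, 1.0, 1.0) == pytest.approx(0.5)

    def test_closed_form_normalization(self):
        s = sum(transmissibility_nk_poisson(4, k, 2.0, 0.7) for k in range(5))
        assert s == pytest.approx(1.0, abs=1e-10)

    def test_quadrature_matches_closed_form_on_grid(self):
        for beta, gamma in [(1.0, 1.0), (1.0, 0.5), (2.0, 0.7)]:
            psi, phi = Exponential(beta), Exponential(gamma)
            for n in range(1, 6):
                for k in range(n + 1):
                    quad = transmissibility_nk(n, k, psi, phi)
                    closed = transmissibility_nk_poisson(n, k, beta, gamma)
                    assert abs(quad - closed) < 1e-8

    def test_large_n_stability(self):
        # log-gamma evaluation must not overflow for wide neighbourhoods
        vals = [transmissibility_nk_poisson(60, k, 1.0, 1.0) for k in range(61)]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert sum(vals) == pytest.approx(1.0, abs=1e-9)

    def test_table_invariants(self):
        table = transmissibility_table(5, Exponential(1.0), Exponential(1.0))
        assert table[(1, 1)] == pytest.approx(0.5, abs=1e-8)
        for n in range(1, 6):
            assert table.row(n).sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all((table.row(n) >= 0) & (table.row(n) <= 1))

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            transmissibility_nk(2, 3, Exponential(1.0), Exponential(1.0))

    def test_shared_recovery_overdispersion(self):
        """p_{2,2} > p^2: both-links activation is more likely than under
        independence because the links share the recovery time."""
        psi, phi = Exponential(1.0), Exponential(1.0)
        p = transmissibility(psi, phi)
        assert transmissibility_nk(2, 2, psi, phi) == pytest.approx(1 / 3, abs=1e-9)
        assert transmissibility_nk(2, 2, psi, phi) - p**2 == pytest.approx(1 / 12, abs=1e-8)


class TestComponents:
    def test_all_infinite_gives_singleton(self, path3):
        from sirpaths.mapping import WeightedRealization
        re = WeightedRealization(path3, "exact", np.full(path3.n_arcs, np.inf),
                                 Exponential(1.0), Exponential(1.0),
                                 node_recovery=np.ones(3))
        assert percolation_component_size(re, "a") == 1

    def test_si_reaches_whole_component(self, path3, rng):
        re = generate_realization_meanfield(path3, Exponential(1.0), si_recovery(), rng)
        assert percolation_component_size(re, "b") == 3

    def test_meanfield_matches_independent_bond_percolation(self, rng):
        """Late-time outbreak of the mean-field mapping vs a plain bond
        sampler at p = beta/(beta+gamma), on the 11x11 lattice."""
        net = generate_lattice(11, 11)
        beta, gamma = 0.003, 0.001
        n = 600
        W, _ = sample_weights_batch(net, Exponential(beta), Exponential(gamma),
                                    "meanfield", n, rng)
        from sirpaths import _paths
        sizes_map = _paths.component_sizes(net.indptr, net.arc_dst, W, net.index("5_5"))
        sizes_bond = bond_percolation_component_sizes(net, beta / (beta + gamma),
                                                      "5_5", n, rng)
        z = abs(sizes_map.mean() - sizes_bond.mean()) / np.hypot(
            sizes_map.std(ddof=1) / np.sqrt(n), sizes_bond.std(ddof=1) / np.sqrt(n))
        assert z < 3


class TestToyNetwork:
    def test_structure(self):
        net = build_toy_network(20, 3)
        assert net.n_nodes == 62
        assert net.degrees()[net.index("s")] == 20
        net2 = build_toy_network(1, 0)
        assert net2.n_nodes == 2 and net2.n_edges == 1
        net3 = build_toy_network(2, 1)
        assert net3.n_nodes == 4 and net3.n_edges == 4

    def test_si_certain_delivery(self):
        assert toy_network_probability(1, 1, Exponential(1.0), si_recovery()) == pytest.approx(1.0)

    def test_closed_form_poisson_value(self):
        """Independent derivation: for beta=gamma=1 each chain fails with
        prob 7/8 and sum_j p_{20,j} x^j = int_0^1 ((7+s)/8)^20 ds, giving
        P = 1 - (8/21)(1 - (7/8)^21)."""
        val = toy_network_probability(20, 3, Exponential(1.0), Exponential(1.0))
        assert val == pytest.approx(1 - (8 / 21) * (1 - (7 / 8) ** 21), abs=1e-9)

    def test_monotone_in_chain_count(self):
        psi, phi = Exponential(1.0), Exponential(1.0)
        vals = [toy_network_probability(nc, 3, psi, phi) for nc in (1, 5, 10, 20)]
        assert np.all(np.diff(vals) > 0)
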