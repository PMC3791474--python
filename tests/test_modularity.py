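import networkx as nx
import numpy as np
import pytest

from codistmod.incidence import IncidenceMatrix, to_bipartite_graph
from codistmod.modularity import (
    ModularityResult, Partition, PartitionCoverageError, SAParams, anneal,
    exhaustive_best_partition, modularity, participation_coefficient,
    within_module_degree,
)
from conftest import random_connected_graph


class TestModularityValue:
    def test_two_block_partition_is_half(self, two_block_graph,
                                         two_block_partition):
        # 2 modules, each l_s=4, d_s=8, L=8: 2*(4/8 - (8/16)^2) = 0.5
        assert modularity(two_block_graph, two_block_partition) == pytest.approx(0.5)

    def test_all_in_one_module_is_zero(self, two_block_graph):
        p = Partition({v: 0 for v in two_block_graph.nodes()})
        assert modularity(two_block_graph, p) == pytest.approx(0.0, abs=1e-12)

    def test_splitting_blocks_lowers_m(self, two_block_graph,
                                       two_block_partition):
        quarters = {}
        for v in two_block_graph.nodes():
            base = two_block_partition.assignment[v]
            quarters[v] = base * 2 + (1 if v.startswith("sp:") else 0)
        assert modularity(two_block_graph, Partition(quarters)) < 0.5

    def test_invariant_under_relabeling(self, two_block_graph,
                                        two_block_partition):
        relabeled = Partition({v: 7 - m for v, m in
                               two_block_partition.assignment.items()})
        assert modularity(two_block_graph, relabeled) == pytest.approx(
            modularity(two_block_graph, two_block_partition))

    def test_missing_node_rejected(self, two_block_graph):
        p = Partition({v: 0 for v in list(two_block_graph.nodes())[:-1]})
        with pytest.raises(PartitionCoverageError):
            modularity(two_block_graph, p)


class TestExhaustiveOracle:
    def test_two_disjoint_edges(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        res = exhaustive_best_partition(g)
        assert res.M == pytest.approx(0.5)
        mods = res.partition.modules()
        assert sorted(map(sorted, mods.values())) == [["a", "b"], ["c", "d"]]

    def test_single_edge_best_is_zero(self):
        res = exhaustive_best_partition(nx.Graph([("a", "b")]))
        assert res.M == pytest.approx(0.0, abs=1e-12)
        assert res.partition.K == 1  # tie broken to the single module

    def test_size_limit(self):
        with pytest.raises(ValueError, match="enumeration limit"):
            exhaustive_best_partition(nx.path_graph(13))

    def test_star_matches_annealer(self):
        g = nx.star_graph(3)
        o = exhaustive_best_partition(g)
        a = anneal(g, SAParams(seed=0))
        assert a.M == pytest.approx(o.M, abs=1e-12)


class TestAnneal:
    def test_recovers_two_block_optimum(self, two_block_graph):
        res = anneal(two_block_graph, SAParams(seed=3))
        assert res.M == pytest.approx(0.5)
        assert res.partition.K == 2

    def test_seed_determinism(self, two_block_graph):
        a = anneal(two_block_graph, SAParams(seed=11))
        b = anneal(two_block_graph, SAParams(seed=11))
        assert a.M == b.M
        assert a.partition.assignment == b.partition.assignment

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SAParams(cooling=1.5)
        with pytest.raises(ValueError):
            SAParams(moves_factor=0.01)
        with pytest.raises(ValueError):
            SAParams(T0=-1.0)

    def test_planted_partition_recovery(self):
        """Planted 4-module bipartite structure is recovered with high NMI."""
        from sklearn.metrics import normalized_mutual_info_score
        from codistmod.synth import gen_planted_incidence
        hits = 0
        for seed in range(5):
            m, planted = gen_planted_incidence(
                K=4, species_per_module=10, sites_per_module=10,
                p_in=0.9, p_out=0.05, seed=seed)
            g = to_bipartite_graph(m)
            res = anneal(g, SAParams(seed=seed, restarts=2))
            nodes = list(g.nodes())
            nmi = normalized_mutual_info_score(
                [planted.assignment[v] for v in nodes],
                [res.partition.assignment[v] for v in nodes])
            hits += nmi >= 0.9
        assert hits >= 4

    def test_matches_oracle_on_small_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            g = random_connected_graph(rng)
            o = exhaustive_best_partition(g)
            a = anneal(g, SAParams(seed=trial, restarts=3))
            assert a.M == pytest.approx(o.M, abs=1e-9), \
                f"annealer below optimum on trial {trial}"


class TestRoles:
    def test_equal_kappa_gives_zero_z(self, two_block_graph,
                                      two_block_partition):
        z = within_module_degree(two_block_graph, two_block_partition)
        assert all(v == 0.0 for v in z.values())

    def test_z_hand_computed_population_sd(self):
        # module kappa = (3,1,1,1): z(hub) = (3-1.5)/0.866 ~ 1.732
        g = nx.star_graph(3)  # node 0 is the hub
        p = Partition({v: 0 for v in g.nodes()})
        z = within_module_degree(g, p)
        assert z[0] == pytest.approx(1.7320508, abs=1e-6)
        assert z[1] == pytest.approx(-0.5773503, abs=1e-6)

    def test_singleton_module_z_zero(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        p = Partition({"a": 0, "b": 1, "c": 2})
        z = within_module_degree(g, p)
        assert z["b"] == 0.0

    def test_p_all_links_inside(self, two_block_graph, two_block_partition):
        P = participation_coefficient(two_block_graph, two_block_partition)
        assert all(v == pytest.approx(0.0) for v in P.values())

    def test_p_split_links(self):
        # degree-2 node bridging two modules: P = 1 - 2*(1/2)^2 = 0.5
        g = nx.Graph([("x", "a"), ("x", "b"), ("a", "a2"), ("b", "b2")])
        p = Partition({"x": 0, "a": 1, "a2": 1, "b": 2, "b2": 2})
        P = participation_coefficient(g, p)
        assert P["x"] == pytest.approx(0.5)

    def test_p_four_modules(self):
        g = nx.star_graph(4)
        p = Partition({0: 0, 1: 1, 2: 2, 3: 3, 4: 4})
        P = participation_coefficient(g, p)
        # hub: 4 links spread 1 per module: 1 - 4*(1/4)^2 = 0.75
        assert P[0] == pytest.approx(0.75)

    def test_p_bounded_by_module_count(self, two_block_graph):
        rng = np.random.default_rng(0)
        p = Partition({v: int(rng.integers(0, 3))
                       for v in two_block_graph.nodes()})
        K = p.K
        P = participation_coefficient(two_block_graph, p)
        for v in P.values():
            assert -1e-12 <= v <= 1 - 1 / K + 1e-12

    def test_result_roles_table(self, two_block_graph):
        res = anneal(two_block_graph, SAParams(seed=0))
        assert set(res.roles.columns) == {"z", "P", "module"}
        assert len(res.roles) == two_block_graph.number_of_nodes()


def test_partition_csv_round_trip(tmp_path, two_block_partition):
    p = tmp_path / "part.csv"
    two_block_partition.to_csv(p)
    back = Partition.from_csv(p)
    assert back.compact().assignment == two_block_partition.compact().assignment
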