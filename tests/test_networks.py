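"""networks: induced subgraphs, correlation thresholding, cores, rankings."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from saltrend.io_formats import RelationTable
from saltrend.networks import (
    build_coexpression,
    build_gene_act,
    core_factors,
    degree_centrality,
    k_core,
    pearson_p_value,
)


def _relations(rows):
    return RelationTable(
        pd.DataFrame(rows, columns=["source", "target", "kind", "directed", "indirect"])
    )


def kcore_by_hand(graph: nx.Graph) -> dict:
    """Oracle: iterative pruning. Remove nodes of degree < k until stable;
    a node's core number is the largest k at which it survives."""
    core = {n: 0 for n in graph.nodes()}
    k = 1
    g = nx.Graph(graph)
    g.remove_edges_from(nx.selfloop_edges(g))
    while g.number_of_nodes():
        changed = True
        while changed:
            drop = [n for n, d in g.degree() if d < k]
            changed = bool(drop)
            g.remove_nodes_from(drop)
        for n in g.nodes():
            core[n] = k
        k += 1
    return core


class TestGeneAct:
    def test_single_edge_induced(self):
        rt = _relations([("a", "b", "activation", True, False)])
        net = build_gene_act(rt, ["a", "b"], {"a": "up", "b": "down"})
        assert net.number_of_edges() == 1
        assert net.graph["n_up"] == 1 and net.graph["n_down"] == 1

    def test_disjoint_de_genes_give_empty_network(self):
        rt = _relations([("a", "b", "binding", True, False)])
        net = build_gene_act(rt, ["x", "y"], {"x": "up", "y": "up"})
        assert net.number_of_edges() == 0
        assert set(net.nodes()) == {"x", "y"}

    def test_matches_bruteforce_induced_subgraph(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(40)]
        rows = []
        for _ in range(150):
            u, v = rng.choice(genes, size=2, replace=False)
            rows.append((u, v, "activation", True, False))
        rt = _relations(rows)
        de = list(rng.choice(genes, size=15, replace=False))
        signs = {g: "up" for g in de}
        net = build_gene_act(rt, de, signs)
        de_set = set(de)
        brute = {(u, v) for u, v, *_ in rows if u in de_set and v in de_set}
        assert {(u, v) for u, v in net.edges()} == brute

    def test_monotone_under_gene_addition(self):
        rt = _relations(
            [("a", "b", "activation", True, False), ("b", "c", "inhibition", True, False)]
        )
        signs = {g: "up" for g in "abc"}
        small = build_gene_act(rt, ["a", "b"], signs)
        big = build_gene_act(rt, ["a", "b", "c"], signs)
        assert set(small.edges()) <= set(big.edges())

    def test_indirect_flag_preserved(self):
        rt = _relations([("a", "b", "compound", True, True)])
        net = build_gene_act(rt, ["a", "b"], {"a": "up", "b": "up"})
        assert all(d["indirect"] for _, _, d in net.edges(data=True))


class TestCoexpression:
    def test_identical_vectors_link_with_r_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        expr = pd.DataFrame([x, x, [5, 1, 4, 2, 3]], index=["a", "b", "c"])
        net = build_coexpression(expr)
        assert net.has_edge("a", "b")
        assert net["a"]["b"]["weight"] == pytest.approx(1.0)
        assert not net.has_edge("a", "c")

    def test_independent_vectors_unlinked(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(30, 8)), index=[f"g{i}" for i in range(30)])
        assert build_coexpression(expr).number_of_edges() == 0

    def test_fewer_than_three_samples_rejected(self):
        from saltrend.io_formats import ValidationError

        with pytest.raises(ValidationError):
            build_coexpression(pd.DataFrame([[1, 2], [3, 4]]))

    def test_affine_sample_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(10, 6)), index=[f"g{i}" for i in range(10)])
        expr.iloc[1] = 2 * expr.iloc[0] + 3  # force one near-perfect pair
        base = build_coexpression(expr)
        rescaled = expr * 1.7 - 0.4
        again = build_coexpression(rescaled)
        assert set(base.edges()) == set(again.edges())
        assert base.has_edge("g0", "g1")

    def test_planted_block_recovered_as_component(self):
        """Genes sharing a planted profile at high depth and zero dispersion
        form one connected co-expression component with no flat members."""
        from saltrend import de_screen
        from saltrend.synthetic_data import SimulationConfig, simulate_counts

        cfg = SimulationConfig(
            seed=11, n_genes=200, profile_fractions={0: 0.1, 4: 0.1},
            nb_dispersion=0.0, baseline_log_mean=14.0, baseline_log_sd=0.0,
        )
        counts, truth = simulate_counts(cfg)
        expr = np.log2(de_screen.normalize_cpm(counts))
        net = build_coexpression(expr)
        components = list(nx.connected_components(net))
        flat = {g for g, p in truth.items() if p == -1}
        for prof in (0, 4):
            block = {g for g, p in truth.items() if p == prof}
            containing = [c for c in components if block <= c]
            assert len(containing) == 1
            assert not {g for g in containing[0] & flat if net.degree(g) > 0}

    def test_pearson_p_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 12))
        r, p_ref = stats.pearsonr(x, y)
        assert pearson_p_value(np.array([r]), 12)[0] == pytest.approx(p_ref, rel=1e-9)


class TestDegreeAndCore:
    def test_star_center_degree(self):
        g = nx.star_graph(6)
        assert degree_centrality(g)[0] == 6

    def test_empty_graph_all_zero(self):
        g = nx.empty_graph(5)
        assert set(degree_centrality(g).values()) == {0}
        assert set(k_core(g).values()) == {0}

    def test_degree_matches_bruteforce_on_random_graph(self):
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        deg = degree_centrality(g)
        for n in g.nodes():
            assert deg[n] == sum(1 for u, v in g.edges() if n in (u, v))

    def test_complete_graph_core(self):
        assert set(k_core(nx.complete_graph(4)).values()) == {3}

    def test_triangle_plus_pendant(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3)])
        assert k_core(g) == {0: 2, 1: 2, 2: 2, 3: 1}

    @pytest.mark.parametrize("seed", range(6))
    def test_core_matches_hand_pruning_and_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.4)), seed=seed)
        core = k_core(g)
        assert core == kcore_by_hand(g)
        deg = degree_centrality(g)
        assert all(core[v] <= deg[v] for v in g.nodes())
        # nestedness: the (k+1)-core is a subgraph of the k-core
        for k in range(1, max(core.values(), default=0) + 1):
            upper = {v for v, c in core.items() if c >= k + 1}
            lower = {v for v, c in core.items() if c >= k}
            assert upper <= lower


class TestCoreFactors:
    def test_largest_degree_difference_ranks_first(self):
        a = nx.star_graph(5)  # node 0 has degree 5
        b = nx.Graph([(0, 1)])
        res = core_factors(a, b)
        assert res[0].gene == 0
        assert res[0].degree_difference == 4
        assert res[0].rank == 1

    def test_identical_networks_all_zero(self):
        g = nx.gnp_random_graph(12, 0.3, seed=1)
        assert all(r.degree_difference == 0 for r in core_factors(g, g))

    def test_matches_bruteforce_sort(self):
        a = nx.gnp_random_graph(25, 0.2, seed=2)
        b = nx.gnp_random_graph(25, 0.2, seed=3)
        res = core_factors(a, b)
        brute = sorted(
            set(a.nodes()) | set(b.nodes()),
            key=lambda n: (-abs((a.degree(n) if n in a else 0) - (b.degree(n) if n in b else 0)), n),
        )
        assert [r.gene for r in res] == brute
        assert [r.rank for r in res] == list(range(1, len(brute) + 1))
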