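"""Top-ASV selection, Spearman screening, FDR, network build, modularity, signs."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from clpp.errors import ClppError, NetworkError, TableError
from clpp.network import (
    CoocNetwork,
    adjust_p_matrix,
    bh_fdr,
    build_network,
    cooccurrence_network,
    edge_sign_summary,
    modularity,
    select_top_asvs,
    spearman_matrix,
)


def table(arr, asvs=None):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"S{i}" for i in range(arr.shape[0])],
        columns=asvs or [f"A{j:02d}" for j in range(arr.shape[1])],
    )


def taxonomy_for(asvs, domain="Bacteria", phylum="Proteobacteria", cls="Alphaproteobacteria"):
    return pd.DataFrame(
        {"domain": domain, "phylum": phylum, "class": cls}, index=pd.Index(asvs, name="asv")
    )


def set_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def exhaustive_max_modularity(g):
    return max(
        nx.community.modularity(g, [set(b) for b in p]) for p in set_partitions(list(g.nodes))
    )


class TestSelectTopAsvs:
    def test_k_exceeding_pool_keeps_all_with_warning(self):
        t = table(np.ones((4, 10), dtype=int))
        with pytest.warns(UserWarning, match="keeping all"):
            out = select_top_asvs(t, k=200)
        assert out.shape[1] == 10

    def test_known_ranking(self):
        t = table([[10, 1, 5], [10, 1, 5], [10, 1, 5], [10, 1, 5]], asvs=["x", "y", "z"])
        out = select_top_asvs(t, k=2)
        assert list(out.columns) == ["x", "z"]

    def test_tie_broken_lexicographically(self):
        t = table([[5, 5, 1]] * 4, asvs=["b", "a", "c"])
        out = select_top_asvs(t, k=1)
        assert list(out.columns) == ["a"]

    def test_empty_table_rejected(self):
        with pytest.raises(TableError):
            select_top_asvs(pd.DataFrame(index=["S0"], columns=[], dtype=int), k=5)


class TestSpearman:
    def test_monotone_and_reversed_pairs(self):
        a = np.array([1, 2, 3, 4, 5])
        t = table(np.column_stack([a, a**2, a[::-1]]))
        rho, p = spearman_matrix(t)
        assert rho.iloc[0, 1] == pytest.approx(1.0)
        assert rho.iloc[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0) and np.allclose(np.diag(p), 0.0)

    def test_tied_pair_matches_rank_covariance_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0])  # one tie
        y = np.array([3.0, 1.0, 4.0, 4.0, 5.0])
        t = table(np.column_stack([x, y, np.arange(5) + 1.0]))
        rho, _ = spearman_matrix(t)
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho.iloc[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_constant_asv_excluded(self):
        base = np.column_stack([np.arange(5) + 1.0, (np.arange(5) + 1.0) ** 2])
        t = table(np.column_stack([base, np.full(5, 7.0)]))  # constant third ASV
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_matrix(t)
        assert rho.shape == (2, 2)
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_relative_basis_option(self):
        # on proportions a pair with constant row sums keeps its ranks
        a = np.arange(5) + 1.0
        t = table(np.column_stack([a, 2 * a, 100 - 3 * a]))
        rho, _ = spearman_matrix(t, basis="relative")
        assert rho.iloc[0, 1] == pytest.approx(1.0)
        with pytest.raises(ClppError):
            spearman_matrix(t, basis="clr")

    def test_too_few_samples(self):
        with pytest.raises(ClppError):
            spearman_matrix(table(np.ones((3, 5))))

    def test_exact_p_agrees_with_t_approx_in_direction(self):
        rng = np.random.default_rng(2)
        t = table(rng.integers(1, 50, size=(6, 4)))
        rho, p_t = spearman_matrix(t)
        _, p_exact = spearman_matrix(t, exact_p=True)
        assert ((p_exact.to_numpy() >= 0) & (p_exact.to_numpy() <= 1)).all()
        np.testing.assert_allclose(p_exact, p_exact.T)
        # strong correlations get small p under both routes
        strong = np.abs(rho.to_numpy()) > 0.9
        np.fill_diagonal(strong, False)
        assert (p_exact.to_numpy()[strong] <= 0.2).all()


class TestBhFdr:
    def test_hand_cases(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_step_up_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 25)
        # hand step-up: sort, p*(m/i), enforce monotone from the largest down
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / (np.arange(m) + 1)
        adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ClppError):
            bh_fdr([0.5, 1.2])

    def test_matrix_adjustment_uses_upper_triangle(self):
        p = pd.DataFrame(
            [[0.0, 0.01, 0.02], [0.01, 0.0, 0.03], [0.02, 0.03, 0.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        adj = adjust_p_matrix(p)
        np.testing.assert_allclose(adj.to_numpy(), adj.to_numpy().T)
        np.testing.assert_allclose(np.sort(adj.to_numpy()[np.triu_indices(3, 1)]), [0.03, 0.03, 0.03])


class TestBuildNetwork:
    def _matrices(self, rho_vals, p_vals, ids=("a", "b", "c", "d")):
        n = len(ids)
        rho = np.eye(n)
        p = np.zeros((n, n))
        for (i, j), r in rho_vals.items():
            rho[i, j] = rho[j, i] = r
        for (i, j), v in p_vals.items():
            p[i, j] = p[j, i] = v
        idx = pd.Index(ids)
        return pd.DataFrame(rho, idx, idx), pd.DataFrame(p, idx, idx)

    def test_weak_correlations_give_no_edges(self):
        rho, p = self._matrices({(0, 1): 0.5, (2, 3): -0.6}, {})
        net = build_network(rho, p, taxonomy_for(rho.index))
        assert net.graph.number_of_edges() == 0
        assert set(net.isolated_nodes) == set(rho.index)

    def test_significance_gate_is_conjunctive(self):
        rho, p = self._matrices({(0, 1): 0.9}, {(0, 1): 0.2})
        net = build_network(rho, p, taxonomy_for(rho.index))
        assert net.graph.number_of_edges() == 0

    def test_exactly_the_qualifying_pairs(self):
        rho, p = self._matrices(
            {(0, 1): 0.9, (2, 3): -0.8, (0, 2): 0.7}, {(0, 1): 0.001, (2, 3): 0.01, (0, 2): 0.2}
        )
        net = build_network(rho, p, taxonomy_for(rho.index))
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        assert edges == {("a", "b"), ("c", "d")}
        assert net.graph.edges["c", "d"]["sign"] == -1

    def test_missing_taxonomy_rejected(self):
        rho, p = self._matrices({(0, 1): 0.9}, {(0, 1): 0.001})
        with pytest.raises(NetworkError, match="taxonomy"):
            build_network(rho, p, taxonomy_for(["a", "b"]))

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(9)
        n = 8
        r = rng.uniform(-1, 1, (n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        idx = pd.Index([f"A{i}" for i in range(n)])
        rho = pd.DataFrame(r, idx, idx)
        p = pd.DataFrame(np.full((n, n), 0.001), idx, idx)
        tax = taxonomy_for(idx)
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            edges = {tuple(sorted(e)) for e in build_network(rho, p, tax, r_threshold=thr).graph.edges}
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestModularity:
    def test_single_clique_is_one_module(self):
        g = nx.complete_graph(5)
        part, q = modularity(g, seed=0)
        assert len(set(part.values())) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_q_half(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part, q = modularity(g, seed=0)
        assert q == pytest.approx(0.5, abs=1e-9)
        assert len(set(part.values())) == 2

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_louvain_bounded_by_exhaustive_maximum(self, seed):
        g = nx.gnp_random_graph(8, 0.4, seed=seed)
        if g.number_of_edges() == 0:
            pytest.skip("empty random draw")
        _, q = modularity(g, seed=0)
        assert q <= exhaustive_max_modularity(g) + 1e-9

    def test_edgeless_graph_undefined(self):
        g = nx.empty_graph(4)
        part, q = modularity(g, seed=0)
        assert part == {} and q is None

    def test_seeded_reproducibility(self):
        g = nx.gnp_random_graph(30, 0.15, seed=2)
        runs = [modularity(g, seed=11) for _ in range(3)]
        assert all(r == runs[0] for r in runs)

    def test_louvain_seed_stability_on_planted_network(self):
        # on one planted-guild network, Q across 20 Louvain seeds stays
        # modular (> 0.4) and varies by < 0.05
        from clpp.simulate import CommunitySimConfig, simulate_asv_table

        t, tax, _ = simulate_asv_table(CommunitySimConfig(seed=6))
        net = cooccurrence_network(t, tax, top_k=80, seed=0)
        qs = [modularity(net.graph, seed=s)[1] for s in range(20)]
        assert min(qs) > 0.4
        assert max(qs) - min(qs) < 0.05


class TestEdgeSignSummary:
    def _net(self, edges, domains):
        g = nx.Graph()
        for node, dom in domains.items():
            g.add_node(node, domain=dom, phylum=f"phy_{dom}", **{"class": "c"})
        for u, v, sign in edges:
            g.add_edge(u, v, rho=0.9 * sign, sign=sign, p_adj=0.001)
        return CoocNetwork(g, 0.6, 0.05)

    def test_all_positive(self):
        net = self._net(
            [("a", "b", 1), ("b", "c", 1)],
            {"a": "Archaea", "b": "Bacteria", "c": "Bacteria"},
        )
        s = edge_sign_summary(net)
        assert (s["positive_fraction"] == 1.0).all()

    def test_counting(self):
        net = self._net(
            [("a", "b", 1), ("a", "c", 1), ("b", "c", 1), ("c", "d", -1)],
            {k: "Bacteria" for k in "abcd"},
        )
        s = edge_sign_summary(net).set_index("stratum")
        assert s.loc["overall", "positive_fraction"] == pytest.approx(0.75)
        assert s.loc["overall", "negative_fraction"] == pytest.approx(0.25)

    def test_empty_archaeal_strata_omitted(self):
        net = self._net([("a", "b", 1)], {"a": "Bacteria", "b": "Bacteria"})
        strata = set(edge_sign_summary(net)["stratum"])
        assert "archaea-archaea" not in strata and "archaea-bacteria" not in strata
        assert {"overall", "bacteria-bacteria"} <= strata


class TestSampleOrderInvariance:
    def test_permuting_samples_leaves_network_unchanged(self):
        from clpp.simulate import CommunitySimConfig, simulate_asv_table

        t, tax, _ = simulate_asv_table(CommunitySimConfig(n_samples=12, n_asvs=30, seed=5))
        net1 = cooccurrence_network(t, tax, top_k=30, seed=0)
        shuffled = t.sample(frac=1.0, random_state=4)
        net2 = cooccurrence_network(shuffled, tax, top_k=30, seed=0)
        e1 = {tuple(sorted(e)) for e in net1.graph.edges}
        e2 = {tuple(sorted(e)) for e in net2.graph.edges}
        assert e1 == e2
        assert net1.modularity_q == pytest.approx(net2.modularity_q, abs=1e-12)
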