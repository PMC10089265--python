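import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from invanet import network
from invanet.io import FeatureTable, ValidationError
from invanet.network import (
    NetworkConfig,
    build_network,
    correlation_matrix,
    keystone_taxa,
    prevalence_filter,
    topology,
)

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive re-implementations)
# ---------------------------------------------------------------------------

def bh_adjust_oracle(pvals: np.ndarray) -> np.ndarray:
    """Textbook step-up BH with the running-minimum enforcement."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        prev = min(prev, pvals[idx] * m / k)
        adjusted[idx] = prev
    return adjusted


def edge_set_oracle(features: pd.DataFrame, r_min: float, alpha: float) -> set:
    """All-pairs filter built directly on scipy.spearmanr + oracle BH."""
    cols = list(features.columns)
    pairs = list(itertools.combinations(cols, 2))
    rhos, ps = [], []
    for a, b in pairs:
        rho, p = scipy.stats.spearmanr(features[a], features[b])
        rhos.append(rho)
        ps.append(p)
    qs = bh_adjust_oracle(np.array(ps))
    return {
        frozenset((a, b))
        for (a, b), rho, q in zip(pairs, rhos, qs)
        if abs(rho) > r_min and q < alpha
    }


def floyd_warshall_oracle(g: nx.Graph):
    """Brute-force distances, triangles and clustering on a small graph."""
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    inf = float("inf")
    d = np.full((n, n), inf)
    np.fill_diagonal(d, 0.0)
    for u, v in g.edges:
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    triangles = 0
    triads = 0
    for v in nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        triads += k * (k - 1) // 2
        triangles += sum(
            1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
        )
    local = []
    for v in nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            local.append(0.0)
        else:
            links = sum(
                1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
            )
            local.append(2 * links / (k * (k - 1)))
    transitivity = triangles / triads if triads else 0.0
    return d, transitivity, float(np.mean(local))


# ---------------------------------------------------------------------------
# prevalence filter
# ---------------------------------------------------------------------------

class TestPrevalenceFilter:
    def _table(self, presence_counts, n_samples=10):
        data = {}
        for j, k in enumerate(presence_counts):
            col = np.zeros(n_samples)
            col[:k] = 1.0
            data[f"f{j}"] = col
        return FeatureTable(
            pd.DataFrame(data, index=[f"s{i}" for i in range(n_samples)]),
            kind="otu", units="relative",
        )

    def test_strictly_more_than_threshold(self):
        t = self._table([7, 8, 9, 10])
        out = prevalence_filter(t, 0.8)
        # "more than 80% of 10" keeps 9/10 and 10/10 only
        assert out.feature_ids == ["f2", "f3"]

    def test_zero_threshold_keeps_any_presence(self):
        t = self._table([1, 5, 0])
        out = prevalence_filter(t, 0.0)
        assert out.feature_ids == ["f0", "f1"]

    def test_empty_result_raises_with_advice(self):
        t = self._table([1, 2])
        with pytest.raises(ValidationError, match="lower"):
            prevalence_filter(t, 0.9)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

class TestCorrelationMatrix:
    def test_perfect_monotone(self):
        x = np.arange(1.0, 9.0)
        f = pd.DataFrame({"x": x, "y": 2 * x, "z": -x})
        rho, p = correlation_matrix(f)
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        assert rho.loc["x", "z"] == pytest.approx(-1.0)

    def test_five_point_hand_value(self):
        # ranks differ by d = (1,1,1,1,0): rho = 1 - 6·4/(5·24) = 0.8
        f = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        rho, p = correlation_matrix(f)
        assert rho.loc["x", "y"] == pytest.approx(0.8, abs=1e-12)

    def test_matches_scipy_p_values(self):
        rng = np.random.default_rng(0)
        f = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        rho, p = correlation_matrix(f)
        for a, b in itertools.combinations("abcd", 2):
            r_ref, p_ref = scipy.stats.spearmanr(f[a], f[b])
            assert rho.loc[a, b] == pytest.approx(r_ref, abs=1e-12)
            assert p.loc[a, b] == pytest.approx(p_ref, rel=1e-9)

    def test_zero_variance_feature_excluded(self):
        f = pd.DataFrame({"x": np.arange(6.0), "c": np.ones(6)})
        with pytest.warns(UserWarning, match="zero-variance"):
            rho, _ = correlation_matrix(f)
        assert "c" not in rho.columns


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_edges_match_brute_force_filter(self, small_dataset):
        ds, _ = small_dataset
        samples = ds.metadata.groups.index[ds.metadata.groups == "AP"]
        otus = prevalence_filter(
            ds.otus.relative_abundance().subset_samples(samples), 0.8
        )
        cfg = NetworkConfig(prevalence_min=0.8, r_min=0.6)
        net = build_network(
            FeatureTable(otus.data, kind="otu", units="relative"), cfg=cfg
        )
        got = {frozenset(e) for e in net.edges}
        expected = edge_set_oracle(otus.data, r_min=0.6, alpha=0.05)
        assert got == expected

    def test_thresholds_are_strict(self):
        # engineered pair with rho exactly 0.6 must NOT form an edge
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([3, 1, 2, 5, 4.0])  # Σd² = 8 → rho = 1 − 48/120 = 0.6
        assert scipy.stats.spearmanr(x, y).statistic == pytest.approx(0.6)
        f = pd.DataFrame(
            {"a": x, "b": y},
            index=[f"s{i}" for i in range(5)],
        )
        net = build_network(
            FeatureTable(f, kind="otu", units="relative"),
            cfg=NetworkConfig(prevalence_min=0.0, r_min=0.6, p_adjust="none", alpha=0.999),
        )
        assert net.number_of_edges() == 0

    def test_negative_edge_retained_with_sign(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        f = pd.DataFrame(
            {"a": np.exp(x), "b": np.exp(-x) + 0.01 * rng.normal(size=20)},
            index=[f"s{i}" for i in range(20)],
        )
        net = build_network(
            FeatureTable(f, kind="otu", units="relative"),
            cfg=NetworkConfig(prevalence_min=0.0, r_min=0.6),
        )
        assert net.edges["a", "b"]["sign"] == "negative"
        assert net.edges["a", "b"]["rho"] < -0.6

    def test_sample_mismatch_rejected(self, small_dataset):
        ds, _ = small_dataset
        genes = FeatureTable(
            pd.DataFrame(
                np.ones((3, 2)), index=["x1", "x2", "x3"], columns=["g1", "g2"]
            ),
            kind="gene", units="copies_per_gram",
        )
        with pytest.raises(ValidationError, match="sample"):
            build_network(ds.otus, genes)

    def test_degree_sum_is_twice_edges(self, small_dataset):
        ds, _ = small_dataset
        net = build_network(ds.otus, cfg=NetworkConfig(prevalence_min=0.5))
        assert sum(d for _, d in net.degree) == 2 * net.number_of_edges()


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

class TestTopology:
    def test_triangle_graph(self):
        g = nx.complete_graph(3)
        t = topology(g)
        assert t.average_degree == 2.0
        assert t.transitivity == 1.0
        assert t.diameter == 1
        assert t.average_distance == 1.0
        assert t.n_edges == t.n_positive + t.n_negative

    def test_path_graph(self):
        t = topology(nx.path_graph(4))
        assert t.average_degree == pytest.approx(1.5)
        assert t.transitivity == 0.0
        assert t.diameter == 3

    def test_random_graphs_match_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(3, 11))
            g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.8), seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            t = topology(g)
            d, trans, avg_clust = floyd_warshall_oracle(g)
            assert t.transitivity == pytest.approx(trans, abs=1e-12)
            assert t.average_clustering == pytest.approx(avg_clust, abs=1e-12)
            giant = g.subgraph(max(nx.connected_components(g), key=len))
            gi = [list(g.nodes).index(v) for v in giant.nodes]
            sub = d[np.ix_(gi, gi)]
            if len(gi) > 1:
                off = sub[~np.eye(len(gi), dtype=bool)]
                assert t.diameter == int(off.max())
                assert t.average_distance == pytest.approx(off.mean(), abs=1e-12)

    def test_edgeless_network_reports_null_distances(self):
        g = nx.empty_graph(3)
        t = topology(g)
        assert t.average_distance is None and t.diameter is None
        assert t.component_count == 3

    def test_modularity_matches_partition(self):
        g = nx.barbell_graph(5, 0)
        t = topology(g)
        comms = nx.algorithms.community.greedy_modularity_communities(g)
        assert t.modularity == pytest.approx(
            nx.algorithms.community.modularity(g, comms), abs=1e-12
        )


# ---------------------------------------------------------------------------
# keystones
# ---------------------------------------------------------------------------

def _net_with(nodes, edges):
    g = nx.Graph()
    for n, kind, ab in nodes:
        g.add_node(n, kind=kind, mean_abundance=ab)
    g.add_edges_from(edges)
    return g


class TestKeystones:
    def test_hub_ranked_first(self):
        nodes = [("hub", "otu", 0.1)] + [(f"g{i}", "gene", 0.1) for i in range(5)]
        g = _net_with(nodes, [("hub", f"g{i}") for i in range(5)])
        ks = keystone_taxa(g, k=5)
        assert ks.index[0] == "hub"
        assert ks.iloc[0]["degree"] == 5

    def test_tie_broken_by_abundance_then_id(self):
        nodes = [
            ("a_low", "otu", 0.01), ("b_high", "otu", 0.02), ("c_same", "otu", 0.02),
            ("g1", "gene", 0.1), ("g2", "gene", 0.1), ("g3", "gene", 0.1),
        ]
        edges = [(o, g) for o in ("a_low", "b_high", "c_same") for g in ("g1", "g2", "g3")]
        ks = keystone_taxa(_net_with(nodes, edges), k=3)
        assert list(ks.index) == ["b_high", "c_same", "a_low"]

    def test_truncation_with_warning(self):
        nodes = [(f"o{i}", "otu", 0.1) for i in range(3)] + [("g", "gene", 0.1)]
        g = _net_with(nodes, [(f"o{i}", "g") for i in range(3)])
        with pytest.warns(UserWarning, match="only 3"):
            ks = keystone_taxa(g, k=5)
        assert len(ks) == 3

    def test_gene_nodes_never_selected(self):
        nodes = [("o1", "otu", 0.1), ("g_hub", "gene", 0.9), ("g2", "gene", 0.1)]
        g = _net_with(nodes, [("g_hub", "g2"), ("g_hub", "o1")])
        ks = keystone_taxa(g, k=2)
        assert set(ks.index) == {"o1"}

    def test_no_otu_nodes_rejected(self):
        g = _net_with([("g1", "gene", 0.1)], [])
        with pytest.raises(ValidationError):
            keystone_taxa(g)


def test_bh_adjustment_matches_oracle():
    """statsmodels' BH must agree with a from-scratch step-up implementation."""
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(3, 60)))
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], bh_adjust_oracle(p), rtol=1e-12
        )
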