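"""Edge statistics, cutoff calibration, PCN construction, graph metrics."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pcnkit.comorbidity import ComorbidityMatrix
from pcnkit.network import (
    build_pcn,
    calibrate_cosine_cutoff,
    classify_edges_by_chapter,
    edge_list_frame,
    network_metrics,
    node_removal_impact,
    pairwise_stats,
)


def _matrix_from_columns(cols: dict[str, list[int]]) -> ComorbidityMatrix:
    df = pd.DataFrame(cols)
    df.index = [f"p{i}" for i in range(len(df))]
    return ComorbidityMatrix(df)


def _stats_row(df, a, b):
    sel = df[(df["disease_a"] == a) & (df["disease_b"] == b)]
    if sel.empty:
        sel = df[(df["disease_a"] == b) & (df["disease_b"] == a)]
    return sel.iloc[0]


class TestPairwiseStats:
    def test_cosine_from_counts(self):
        # n_a=4, n_b=9, n_ab=3 -> 3/sqrt(36) = 0.5
        a = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        b = [1, 1, 1, 0, 1, 1, 1, 1, 1, 1, 0, 0]
        m = _matrix_from_columns({"A": a, "B": b})
        row = _stats_row(pairwise_stats(m), "A", "B")
        assert row["cosine"] == pytest.approx(0.5)
        assert row["n_ab"] == 3

    def test_perfect_overlap_phi_one_p_zero(self):
        col = [1] * 10 + [0] * 90
        m = _matrix_from_columns({"A": col, "B": col})
        row = _stats_row(pairwise_stats(m), "A", "B")
        assert row["phi"] == pytest.approx(1.0)
        assert row["p"] == 0.0

    def test_exact_independence_phi_zero(self):
        # n_a = n_b = 10, N = 100, n_ab = 1 = n_a*n_b/N
        a = [1] * 10 + [0] * 90
        b = [1] + [0] * 9 + [1] * 9 + [0] * 81
        m = _matrix_from_columns({"A": a, "B": b})
        row = _stats_row(pairwise_stats(m), "A", "B")
        assert row["phi"] == pytest.approx(0.0, abs=1e-12)
        assert row["t"] == pytest.approx(0.0, abs=1e-12)

    def test_phi_matches_pearson_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.binomial(1, 0.3, size=(200, 12))
        m = ComorbidityMatrix(pd.DataFrame(
            X, columns=[f"D{j:02d}" for j in range(12)],
            index=[f"p{i}" for i in range(200)],
        ))
        df = pairwise_stats(m)
        corr = np.corrcoef(X.T)
        names = list(m.diseases)
        for row in df.itertuples(index=False):
            i, j = names.index(row.disease_a), names.index(row.disease_b)
            assert abs(row.phi - corr[i, j]) < 1e-12

    def test_too_few_patients_rejected(self):
        m = _matrix_from_columns({"A": [1, 0], "B": [0, 1]})
        with pytest.raises(ValueError):
            pairwise_stats(m)

    def test_empty_columns_dropped(self):
        m = _matrix_from_columns({
            "A": [1, 1, 0, 0], "B": [0, 0, 0, 0], "C": [1, 0, 1, 0],
        })
        df = pairwise_stats(m)
        assert set(df["disease_a"]) | set(df["disease_b"]) == {"A", "C"}


class TestCutoffCalibration:
    def test_no_significant_pairs_empty_network(self):
        df = pd.DataFrame({
            "disease_a": ["A"], "disease_b": ["B"],
            "cosine": [0.4], "phi": [0.01], "p": [0.8],
        })
        assert calibrate_cosine_cutoff(df) == float("inf")

    def test_all_significant_keeps_all(self):
        df = pd.DataFrame({
            "disease_a": ["A", "A", "B"], "disease_b": ["B", "C", "C"],
            "cosine": [0.5, 0.3, 0.7], "phi": [0.2, 0.2, 0.2],
            "p": [0.001, 0.001, 0.001],
        })
        assert calibrate_cosine_cutoff(df) == pytest.approx(0.3)

    def test_edge_count_equals_significant_count_tie_free(self):
        # synthetic matrix with planted strong pairs among null pairs
        rng = np.random.default_rng(7)
        n = 4000
        cols = {}
        for j in range(10):
            cols[f"D{j}"] = rng.binomial(1, 0.15, size=n)
        # plant five strong vertex-disjoint pairs by copying with noise
        for j in range(5):
            base = np.asarray(cols[f"D{j}"])
            flip = rng.random(n) < 0.05
            cols[f"E{j}"] = np.where(flip, 1 - base, base)
        m = ComorbidityMatrix(pd.DataFrame(
            cols, index=[f"p{i}" for i in range(n)]
        ))
        df = pairwise_stats(m)
        assert df["cosine"].nunique() == len(df)  # tie-free instance
        cutoff = calibrate_cosine_cutoff(df, phi_alpha=0.05)
        m_sig = int(((df["phi"] > 0) & (df["p"] < 0.05)).sum())
        n_edges = int((df["cosine"] >= cutoff).sum())
        assert n_edges == m_sig


class TestBuildPCN:
    def test_infinite_cutoff_edgeless_nodes_retained(self):
        df = pd.DataFrame({
            "disease_a": ["A"], "disease_b": ["B"],
            "cosine": [0.4], "phi": [0.1], "p": [0.2],
        })
        g = build_pcn(df, float("inf"))
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 0

    def test_path_degrees(self):
        df = pd.DataFrame({
            "disease_a": ["A10", "B10"], "disease_b": ["B10", "C10"],
            "cosine": [0.5, 0.6], "phi": [0.2, 0.3], "p": [0.01, 0.01],
        })
        g = build_pcn(df, 0.4)
        assert dict(g.degree()) == {"A10": 1, "B10": 2, "C10": 1}

    def test_graphml_roundtrip(self, tmp_path):
        df = pd.DataFrame({
            "disease_a": ["A10", "B10"], "disease_b": ["B10", "C10"],
            "cosine": [0.5, 0.6], "phi": [0.2, 0.3], "p": [0.01, 0.01],
        })
        node_table = pd.DataFrame(
            {"prevalence": [0.1, 0.2, 0.3]}, index=["A10", "B10", "C10"]
        )
        g = build_pcn(df, 0.4, node_table=node_table)
        path = tmp_path / "g.graphml"
        nx.write_graphml(g, path)
        h = nx.read_graphml(path)
        assert set(h.nodes) == set(g.nodes)
        assert set(frozenset(e) for e in h.edges) == \
            set(frozenset(e) for e in g.edges)
        assert h.nodes["A10"]["prevalence"] == pytest.approx(0.1)


class TestMetrics:
    def test_complete_graph_symmetric(self):
        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(5)})
        nx.set_edge_attributes(g, 1.0, "weight")
        nx.set_node_attributes(g, "IX", "chapter")
        m = network_metrics(g)
        assert m.density == pytest.approx(1.0)
        assert all(b == pytest.approx(0.0) for b in m.betweenness)
        assert all(pr == pytest.approx(0.2) for pr in m.pagerank)

    def test_path_betweenness_center(self):
        g = nx.path_graph(["a", "b", "c"])
        nx.set_edge_attributes(g, 1.0, "weight")
        m = network_metrics(g)
        assert m.betweenness["b"] == pytest.approx(1.0)
        assert m.betweenness["a"] == 0.0

    def test_star_pagerank_hub_dominates(self):
        g = nx.star_graph(4)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(5)})
        nx.set_edge_attributes(g, 1.0, "weight")
        m = network_metrics(g)
        leaves = [m.pagerank[f"N{i}"] for i in range(1, 5)]
        assert m.pagerank["N0"] > max(leaves)
        assert max(leaves) == pytest.approx(min(leaves))
        assert m.pagerank.sum() == pytest.approx(1.0, abs=1e-9)

    def test_betweenness_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            p = float(rng.uniform(0.3, 0.8))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            m = network_metrics(nx.relabel_nodes(
                g, {i: str(i) for i in g.nodes}
            ))
            oracle = _brute_force_betweenness(g)
            for node in g.nodes:
                assert m.betweenness[str(node)] == \
                    pytest.approx(oracle[node], abs=1e-12)

    def test_pagerank_matches_power_iteration(self):
        rng = np.random.default_rng(13)
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        g = nx.relabel_nodes(g, {i: str(i) for i in g.nodes})
        m = network_metrics(g)
        oracle = _power_iteration_pagerank(g, damping=0.85)
        for node in g.nodes:
            assert m.pagerank[node] == pytest.approx(oracle[node], abs=1e-8)

    def test_empty_graph_zeroes(self):
        m = network_metrics(nx.Graph())
        assert m.density == 0.0 and len(m.degree) == 0

    def test_degree_tail_fit_on_exponential_degrees(self):
        # sampled from the fitted model class, the bootstrap KS test should
        # not reject
        rng = np.random.default_rng(2)
        degrees = 12 + rng.exponential(4.0, size=60)
        from pcnkit.network import _exponential_tail_fit

        fit = _exponential_tail_fit(degrees.astype(float), 12, 200, seed=0)
        assert fit.n_tail == 60
        assert fit.p > 0.05  # exponential data should not be rejected


def _brute_force_betweenness(g: nx.Graph) -> dict:
    """Textbook definition: for each pair (s, t), the fraction of shortest
    paths through v, summed, normalized by (n-1)(n-2)/2."""
    nodes = list(g.nodes)
    n = len(nodes)
    bet = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bet[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: b / norm for v, b in bet.items()}


def _power_iteration_pagerank(g: nx.Graph, damping: float) -> dict:
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1.0)
        W[idx[u], idx[v]] = w
        W[idx[v], idx[u]] = w
    out = W.sum(axis=1)
    P = np.zeros((n, n))
    for i in range(n):
        if out[i] > 0:
            P[i] = W[i] / out[i]
        else:
            P[i] = 1.0 / n  # dangling: uniform
    r = np.full(n, 1.0 / n)
    for _ in range(10_000):
        r_new = (1 - damping) / n + damping * P.T @ r
        if np.abs(r_new - r).sum() < 1e-14:
            r = r_new
            break
        r = r_new
    return {v: r[idx[v]] for v in nodes}


class TestRemovalAndChapters:
    def _toy_pcn(self):
        df = pd.DataFrame({
            "disease_a": ["I10", "I10", "I25", "I10", "E11"],
            "disease_b": ["I25", "I50", "I50", "E11", "E78"],
            "cosine": [0.9, 0.8, 0.7, 0.6, 0.5],
            "phi": [0.5] * 5, "p": [0.001] * 5,
        })
        return build_pcn(df, 0.0)

    def test_remove_isolated_node_no_impact(self):
        g = self._toy_pcn()
        g.add_node("Z99x"[:3], chapter="XXI")
        assert node_removal_impact(g, ["Z99"]) == 0.0

    def test_remove_star_hub_loses_all(self):
        g = nx.star_graph(4)
        assert node_removal_impact(g, [0]) == 1.0

    def test_remove_triangle_endpoint(self):
        g = nx.complete_graph(3)
        assert node_removal_impact(g, [0]) == pytest.approx(2 / 3)

    def test_edgeless_guarded(self):
        g = nx.Graph()
        g.add_node("A")
        assert node_removal_impact(g, ["A"]) == 0.0

    def test_chapter_classification_counts(self):
        g = self._toy_pcn()
        # chapters: I10/I25/I50 -> IX; E11/E78 -> IV
        same, cross = classify_edges_by_chapter(g, top_k=5)
        assert (same, cross) == (4, 1)
        same3, cross3 = classify_edges_by_chapter(g, top_k=3)
        assert (same3, cross3) == (3, 0)

    def test_top_k_beyond_edges_uses_all(self):
        g = self._toy_pcn()
        assert sum(classify_edges_by_chapter(g, top_k=100)) == 5

    def test_edge_list_sorted_by_weight(self):
        g = self._toy_pcn()
        df = edge_list_frame(g)
        assert df["cosine"].is_monotonic_decreasing
        assert len(df) == 5


class TestCosineSampleSizeStability:
    def test_cosine_invariant_to_cohort_size(self):
        # the cosine index estimates n_ab/sqrt(n_a n_b), a function of the
        # underlying joint distribution only; subsampling shifts it within
        # Monte-Carlo error
        rng = np.random.default_rng(17)
        n_big = 20_000
        a = rng.binomial(1, 0.2, size=n_big)
        flip = rng.random(n_big) < 0.15
        b = np.where(flip, rng.binomial(1, 0.2, size=n_big), a)

        def cosine(x, y):
            return (x & y).sum() / np.sqrt(x.sum() * y.sum())

        big = cosine(a.astype(bool), b.astype(bool))
        sub = rng.choice(n_big, size=2000, replace=False)
        small = cosine(a[sub].astype(bool), b[sub].astype(bool))
        assert abs(big - small) < 0.05
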