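"""Phenotypic comorbidity network (PCN) construction and structure metrics.

For every unordered disease pair (a, b) in the incidence matrix the comorbid
strength is the cosine index

    cos_ab = n_ab / sqrt(n_a * n_b),

and the phi coefficient is the Pearson correlation of the two binary
indicator columns,

    phi_ab = (N n_ab - n_a n_b) /
             sqrt(n_a n_b (N - n_a) (N - n_b)),

whose significance is a t test with ``t = phi sqrt(N-2) / sqrt(1-phi^2)``
on N-2 degrees of freedom.  The cosine cutoff is *calibrated* against the
phi network: with M pairs showing significantly positive phi, the cutoff is
the M-th largest cosine value, so both networks retain the same number of
edges (ties at the cutoff are all kept).

Structure metrics: density, degree median (IQR), average neighbor degree,
betweenness centrality on the unweighted graph, cosine-weighted PageRank
(damping 0.85) with the top-10-percentile nodes marked *important*, and an
exponential fit to the upper degree tail checked by a parametric-bootstrap
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import icd
from .comorbidity import ComorbidityMatrix

__all__ = [
    "pairwise_stats",
    "calibrate_cosine_cutoff",
    "build_pcn",
    "network_metrics",
    "node_removal_impact",
    "classify_edges_by_chapter",
    "NetworkMetrics",
    "TailFit",
]


def pairwise_stats(matrix: ComorbidityMatrix) -> pd.DataFrame:
    """Edge statistics for every unordered disease pair with n_a, n_b > 0.

    Returns a frame with columns disease_a, disease_b, n_a, n_b, n_ab, N,
    cosine, phi, t, p (two-sided, t distribution with N-2 df; |phi| = 1
    maps to p = 0 by convention).
    """
    N = matrix.n
    if N < 3:
        raise ValueError("need at least 3 patients (df = N - 2 > 0)")
    counts = matrix.column_counts()
    keep = [c for c in matrix.diseases if counts[c] > 0]
    X = matrix.data[keep].to_numpy(dtype=float)
    n = X.sum(axis=0)
    co = X.T @ X  # n_ab on the off-diagonal

    ia, ib = np.triu_indices(len(keep), k=1)
    n_a, n_b, n_ab = n[ia], n[ib], co[ia, ib]
    cosine = n_ab / np.sqrt(n_a * n_b)
    denom = np.sqrt(n_a * n_b * (N - n_a) * (N - n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, (N * n_ab - n_a * n_b) / denom, 0.0)
    phi = np.clip(phi, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = phi * np.sqrt(N - 2) / np.sqrt(1 - phi**2)
    p = np.where(
        np.isclose(np.abs(phi), 1.0),
        0.0,
        2 * stats.t.sf(np.abs(t), df=N - 2),
    )
    t = np.where(np.isfinite(t), t, np.copysign(np.inf, phi))
    codes = np.array(keep)
    return pd.DataFrame({
        "disease_a": codes[ia],
        "disease_b": codes[ib],
        "n_a": n_a.astype(int),
        "n_b": n_b.astype(int),
        "n_ab": n_ab.astype(int),
        "N": N,
        "cosine": cosine,
        "phi": phi,
        "t": t,
        "p": p,
    })


def calibrate_cosine_cutoff(
    stats_df: pd.DataFrame, phi_alpha: float = 0.05
) -> float:
    """Cosine cutoff matching the edge count of the significant-phi network.

    M = number of pairs with phi > 0 and p < alpha; the cutoff is the M-th
    largest cosine value.  M = 0 yields +inf (empty network).
    """
    if len(stats_df) == 0:
        raise ValueError("no pair statistics supplied")
    m = int(((stats_df["phi"] > 0) & (stats_df["p"] < phi_alpha)).sum())
    if m == 0:
        return float("inf")
    return float(np.sort(stats_df["cosine"].to_numpy())[-m])


def build_pcn(
    stats_df: pd.DataFrame,
    cutoff: float,
    node_table: pd.DataFrame | None = None,
    metadata: Mapping[str, object] | None = None,
) -> nx.Graph:
    """Weighted undirected PCN: edges are pairs with cosine >= cutoff.

    ``node_table`` (index = disease code, optional columns ``prevalence``
    etc.) seeds node attributes; isolated nodes are retained.  Every node
    gets its ICD-10 chapter.
    """
    g = nx.Graph()
    g.graph["cutoff"] = cutoff
    for k, v in (metadata or {}).items():
        g.graph[k] = v

    codes: set[str] = set(stats_df["disease_a"]) | set(stats_df["disease_b"])
    if node_table is not None:
        codes |= set(node_table.index)
    for code in sorted(codes):
        try:
            attrs = {"chapter": icd.chapter(code)}
        except ValueError:
            attrs = {"chapter": "?"}  # non-ICD node label
        if node_table is not None and code in node_table.index:
            attrs.update({
                k: (v.item() if hasattr(v, "item") else v)
                for k, v in node_table.loc[code].items()
            })
        g.add_node(code, **attrs)

    kept = stats_df[stats_df["cosine"] >= cutoff]
    for row in kept.itertuples(index=False):
        g.add_edge(row.disease_a, row.disease_b, weight=float(row.cosine),
                   phi=float(row.phi), p=float(row.p))
    return g


@dataclass
class TailFit:
    min_degree: int
    n_tail: int
    rate: float  # exponential rate of the fitted tail (1 / mean excess)
    ks_stat: float
    p: float


@dataclass
class NetworkMetrics:
    density: float
    degree: pd.Series
    degree_median: float
    degree_iqr: tuple[float, float]
    avg_neighbor_degree: pd.Series  # over nodes with degree > 0
    betweenness: pd.Series
    pagerank: pd.Series
    important_nodes: list[str]
    tail_fit: TailFit | None = None


def network_metrics(
    g: nx.Graph,
    damping: float = 0.85,
    important_percentile: float = 90.0,
    tail_min_degree: int | None = None,
    tail_bootstrap: int = 200,
    seed: int = 0,
) -> NetworkMetrics:
    """Structural indices of a PCN; see module docstring for definitions."""
    nodes = sorted(g.nodes)
    if not nodes:
        return NetworkMetrics(
            density=0.0, degree=pd.Series(dtype=float), degree_median=0.0,
            degree_iqr=(0.0, 0.0),
            avg_neighbor_degree=pd.Series(dtype=float),
            betweenness=pd.Series(dtype=float),
            pagerank=pd.Series(dtype=float), important_nodes=[],
        )
    degree = pd.Series({n: d for n, d in g.degree()}).loc[nodes].astype(float)
    connected = [n for n in nodes if degree[n] > 0]
    avg_nbr = pd.Series(nx.average_neighbor_degree(g, nodes=connected)) \
        if connected else pd.Series(dtype=float)
    betweenness = pd.Series(nx.betweenness_centrality(g, normalized=True,
                                                      weight=None))
    if g.number_of_edges() > 0:
        pagerank = pd.Series(nx.pagerank(g, alpha=damping, weight="weight",
                                         tol=1e-12, max_iter=1000))
    else:
        pagerank = pd.Series({n: 1.0 / len(nodes) for n in nodes})
    thr = np.percentile(pagerank.to_numpy(), important_percentile)
    important = sorted(
        (n for n in nodes if pagerank[n] >= thr),
        key=lambda n: (-pagerank[n], n),
    )
    q1, q3 = np.percentile(degree.to_numpy(), [25, 75])
    tail = None
    if tail_min_degree is not None:
        tail = _exponential_tail_fit(degree.to_numpy(), tail_min_degree,
                                     tail_bootstrap, seed)
    return NetworkMetrics(
        density=float(nx.density(g)),
        degree=degree,
        degree_median=float(np.median(degree)),
        degree_iqr=(float(q1), float(q3)),
        avg_neighbor_degree=avg_nbr.sort_index(),
        betweenness=betweenness.loc[nodes],
        pagerank=pagerank.loc[nodes],
        important_nodes=important,
        tail_fit=tail,
    )


def _exponential_tail_fit(degrees: np.ndarray, min_degree: int,
                          n_bootstrap: int, seed: int) -> TailFit:
    """Maximum-likelihood exponential fit to the degree tail >= min_degree,
    with a parametric-bootstrap Kolmogorov-Smirnov goodness-of-fit p."""
    tail = degrees[degrees >= min_degree] - min_degree
    if len(tail) < 3 or tail.mean() == 0:
        return TailFit(min_degree, len(tail), np.nan, np.nan, np.nan)
    scale = tail.mean()
    ks = stats.kstest(tail, "expon", args=(0, scale)).statistic
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_bootstrap):
        sim = rng.exponential(scale, size=len(tail))
        sim_ks = stats.kstest(sim, "expon", args=(0, sim.mean())).statistic
        if sim_ks >= ks:
            hits += 1
    return TailFit(min_degree, len(tail), 1.0 / scale, float(ks),
                   hits / n_bootstrap)


def node_removal_impact(g: nx.Graph, nodes: Iterable[str]) -> float:
    """Fraction of edges lost when the given nodes (and incident edges) go."""
    before = g.number_of_edges()
    if before == 0:
        return 0.0
    h = g.copy()
    h.remove_nodes_from(list(nodes))
    return 1.0 - h.number_of_edges() / before


def classify_edges_by_chapter(
    g: nx.Graph, top_k: int = 100
) -> tuple[int, int]:
    """Among the top_k edges by cosine weight: (same-chapter, cross-chapter).

    Ties at rank ``top_k`` are broken deterministically by code order; if
    the graph has fewer edges, all are used.
    """
    edges = sorted(
        g.edges(data="weight"),
        key=lambda e: (-e[2], min(e[0], e[1]), max(e[0], e[1])),
    )[:top_k]
    same = sum(
        1 for a, b, _ in edges
        if g.nodes[a]["chapter"] == g.nodes[b]["chapter"]
    )
    return same, len(edges) - same


def edge_list_frame(g: nx.Graph) -> pd.DataFrame:
    """Edge list (code_a, code_b, cosine, phi, p) sorted by weight desc."""
    rows = [
        {
            "code_a": min(a, b), "code_b": max(a, b),
            "cosine": d.get("weight", np.nan),
            "phi": d.get("phi", np.nan), "p": d.get("p", np.nan),
        }
        for a, b, d in g.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["code_a", "code_b", "cosine", "phi", "p"])
    return df.sort_values(
        ["cosine", "code_a", "code_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
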