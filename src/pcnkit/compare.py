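"""Subgroup PCNs, abundant connections, and network-structure comparison.

Per-subgroup PCNs are built independently: the >1% prevalence screen, edge
statistics and cosine-cutoff calibration are all recomputed within the
subgroup.  Two PCNs are then compared by partitioning the union of their
edge sets into *shared* (present in both with |cosine difference| below the
threshold), *enriched* in one side (present in both, difference >= 0.05 by
default), and *unique* to one side.  Sex-axis comparisons drop sex-specific
diseases first.  Structure comparison reports density, degree and
neighbor-degree summaries and one-sided two-sample t-tests on the per-node
degree vectors (alpha = .025).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .comorbidity import ComorbidityMatrix
from .network import (
    build_pcn,
    calibrate_cosine_cutoff,
    network_metrics,
    pairwise_stats,
)
from .prevalence import screen_above_1pct

__all__ = [
    "SEX_SPECIFIC_CODES",
    "build_subgroup_pcns",
    "abundant_connections",
    "compare_structure",
    "AbundantPartition",
    "StructureComparison",
]

#: 3-digit stems only meaningful for one sex, dropped from sex-axis
#: comparisons (male genital organs + prostate; female genital tract,
#: gynecological neoplasms, breast disorders).
SEX_SPECIFIC_CODES = frozenset(
    [f"N{i}" for i in range(40, 52)]
    + [f"N{i}" for i in range(70, 99)]
    + [f"C{i}" for i in range(51, 59)]
    + [f"C{i}" for i in range(60, 64)]
    + ["D25", "D26", "D27", "D28", "E28", "E29", "N60", "N61", "N62",
       "N63", "N64"]
)

Edge = tuple[str, str]


def _edge_key(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


def build_subgroup_pcns(
    matrix: ComorbidityMatrix,
    labels: pd.Series,
    phi_alpha: float = 0.05,
    min_size: int = 3,
    screen: bool = True,
) -> dict[str, nx.Graph]:
    """Independent PCN per subgroup level of ``labels`` (patient -> level).

    Each subgroup re-applies the >1% prevalence screen on its own patients,
    recomputes pair statistics and calibrates its own cosine cutoff.
    Levels below ``min_size`` patients are skipped.
    """
    out: dict[str, nx.Graph] = {}
    aligned = labels.reindex(matrix.data.index)
    for level in sorted(aligned.dropna().unique()):
        sub = matrix.data.loc[aligned == level]
        if len(sub) < min_size:
            continue
        sub_matrix = ComorbidityMatrix(sub)
        if screen:
            counts = {str(level): (sub.sum(axis=0), len(sub))}
            panel = screen_above_1pct(
                {k: (dict(v[0]), v[1]) for k, v in counts.items()}
            )
            if not panel:
                out[str(level)] = nx.Graph(cutoff=float("inf"),
                                           subgroup=str(level), N=len(sub))
                continue
            sub_matrix = ComorbidityMatrix(sub[panel])
        st = pairwise_stats(sub_matrix)
        cutoff = calibrate_cosine_cutoff(st, phi_alpha=phi_alpha)
        prev = (sub_matrix.column_counts() / len(sub)).rename("prevalence")
        out[str(level)] = build_pcn(
            st, cutoff, node_table=prev.to_frame(),
            metadata={"subgroup": str(level), "N": len(sub)},
        )
    return out


@dataclass
class AbundantPartition:
    """Partition of the union of two PCNs' edge sets.

    ``delta`` is signed as weight(group 1) - weight(group 2); an edge is
    enriched in the group whose weight is higher by at least the threshold.
    """

    group1: str
    group2: str
    threshold: float
    shared: dict[Edge, float]  # edge -> delta, |delta| < threshold
    enriched_1: dict[Edge, float]
    enriched_2: dict[Edge, float]
    unique_1: set[Edge]
    unique_2: set[Edge]

    @property
    def union_size(self) -> int:
        return (len(self.shared) + len(self.enriched_1)
                + len(self.enriched_2) + len(self.unique_1)
                + len(self.unique_2))

    @property
    def shared_fraction(self) -> float:
        return len(self.shared) / self.union_size if self.union_size else 0.0

    @property
    def abundant_1(self) -> set[Edge]:
        return set(self.enriched_1) | self.unique_1

    @property
    def abundant_2(self) -> set[Edge]:
        return set(self.enriched_2) | self.unique_2

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for edge, delta in sorted(self.shared.items()):
            rows.append((*edge, "shared", "", delta))
        for edge, delta in sorted(self.enriched_1.items()):
            rows.append((*edge, "enriched", self.group1, delta))
        for edge, delta in sorted(self.enriched_2.items()):
            rows.append((*edge, "enriched", self.group2, delta))
        for edge in sorted(self.unique_1):
            rows.append((*edge, "unique", self.group1, np.nan))
        for edge in sorted(self.unique_2):
            rows.append((*edge, "unique", self.group2, np.nan))
        return pd.DataFrame(
            rows, columns=["code_a", "code_b", "kind", "favored", "delta"]
        )


def abundant_connections(
    pcn1: nx.Graph,
    pcn2: nx.Graph,
    group1: str = "group_1",
    group2: str = "group_2",
    delta_threshold: float = 0.05,
    exclude_nodes: Iterable[str] = (),
) -> AbundantPartition:
    """Partition the union of edges into shared / enriched / unique sets.

    ``exclude_nodes`` removes edges touching those diseases before the
    comparison (used to drop sex-specific diseases on the sex axis).
    """
    excl = set(exclude_nodes)

    def edges(g: nx.Graph) -> dict[Edge, float]:
        return {
            _edge_key(a, b): float(d.get("weight", np.nan))
            for a, b, d in g.edges(data=True)
            if a not in excl and b not in excl
        }

    e1, e2 = edges(pcn1), edges(pcn2)
    shared: dict[Edge, float] = {}
    enriched_1: dict[Edge, float] = {}
    enriched_2: dict[Edge, float] = {}
    for edge in e1.keys() & e2.keys():
        delta = e1[edge] - e2[edge]
        if delta >= delta_threshold:
            enriched_1[edge] = delta
        elif delta <= -delta_threshold:
            enriched_2[edge] = delta
        else:
            shared[edge] = delta
    return AbundantPartition(
        group1=group1, group2=group2, threshold=delta_threshold,
        shared=shared, enriched_1=enriched_1, enriched_2=enriched_2,
        unique_1=set(e1) - set(e2), unique_2=set(e2) - set(e1),
    )


@dataclass
class StructureComparison:
    """Per-subgroup descriptive network stats plus pairwise degree tests."""

    stats: pd.DataFrame  # one row per subgroup
    tests: dict[tuple[str, str], dict[str, tuple[float, float]]]
    alpha: float = 0.025


def compare_structure(
    pcns: Mapping[str, nx.Graph],
    alpha: float = 0.025,
    connected_only: bool = False,
) -> StructureComparison:
    """Describe and test the degree structure of >= 2 PCNs on one axis.

    One-sided two-sample t-tests compare per-node degree and neighbor-degree
    vectors for every ordered pair (g1 > g2 alternative); degenerate
    (edgeless) PCNs are described but skipped in tests.
    """
    if len(pcns) < 2:
        raise ValueError("need at least two PCNs to compare")
    rows = {}
    degree_vectors: dict[str, np.ndarray] = {}
    nbr_vectors: dict[str, np.ndarray] = {}
    for name in sorted(pcns):
        g = pcns[name]
        m = network_metrics(g)
        deg = m.degree.to_numpy()
        if connected_only:
            deg = deg[deg > 0]
        degree_vectors[name] = deg
        nbr_vectors[name] = m.avg_neighbor_degree.to_numpy()
        nbr_med, nbr_q1, nbr_q3 = (
            (float(np.median(v)), *map(float, np.percentile(v, [25, 75])))
            if (v := m.avg_neighbor_degree.to_numpy()).size
            else (0.0, 0.0, 0.0)
        )
        rows[name] = {
            "subgroup": name,
            "nodes": g.number_of_nodes(),
            "edges": g.number_of_edges(),
            "density": m.density,
            "degree_median": m.degree_median,
            "degree_q1": m.degree_iqr[0],
            "degree_q3": m.degree_iqr[1],
            "neighbor_degree_median": nbr_med,
            "neighbor_degree_q1": nbr_q1,
            "neighbor_degree_q3": nbr_q3,
            "important_nodes": ",".join(m.important_nodes),
        }
    tests: dict[tuple[str, str], dict[str, tuple[float, float]]] = {}
    names = sorted(pcns)
    for g1 in names:
        for g2 in names:
            if g1 == g2:
                continue
            if pcns[g1].number_of_edges() == 0 or \
                    pcns[g2].number_of_edges() == 0:
                continue
            entry: dict[str, tuple[float, float]] = {}
            for label, vecs in (("degree", degree_vectors),
                                ("neighbor_degree", nbr_vectors)):
                v1, v2 = vecs[g1], vecs[g2]
                if len(v1) < 2 or len(v2) < 2:
                    continue
                if np.var(v1) == 0 and np.var(v2) == 0:
                    # degenerate: all degrees identical within each group
                    if v1.mean() == v2.mean():
                        entry[label] = (0.0, 0.5)
                    else:
                        gt = v1.mean() > v2.mean()
                        entry[label] = (np.inf if gt else -np.inf,
                                        0.0 if gt else 1.0)
                    continue
                t, p = stats.ttest_ind(v1, v2, alternative="greater",
                                       equal_var=False)
                entry[label] = (float(t), float(p))
            tests[(g1, g2)] = entry
    return StructureComparison(
        stats=pd.DataFrame(list(rows.values())).set_index("subgroup"),
        tests=tests,
        alpha=alpha,
    )
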