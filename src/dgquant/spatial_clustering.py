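"""Spatial clustering of labelled cells via proximity graphs and
Girvan-Newman community detection.

Newborn cells migrate only a short distance from the progenitor that
produced them, so spatial clusters of labelled nuclei are read as clonal
groups. The statistic works per histological section: every cell is a
node; two cells closer than a distance threshold (25 um by default) are
joined by an edge whose weight grows as the cells get closer
(w = 1 - d/threshold, so w is in (0, 1] and vanishes at the cutoff). The
graph is partitioned by the Girvan-Newman procedure — iterative removal of
the highest-betweenness edge, keeping the partition along the removal
sequence that maximises weighted Newman modularity Q. Communities are then
reported as clusters, with groups larger than the biologically plausible
clone size (5 cells) split by continuing the edge removal until every
component is small enough.

Betweenness is computed on the weighted graph with edge *length* 1/w, so
stronger (closer) edges are shorter paths. Edge-removal ties break on the
lowest (i, j) node-index pair; nodes are canonically ordered by
(section, x, y) so results are independent of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import CellMap

__all__ = [
    "ProximityGraph", "ClusterResult", "build_proximity_graph",
    "girvan_newman_partition", "cluster_stats", "weighted_modularity",
]

DEFAULT_THRESHOLD_UM = 25.0
MAX_CLUSTER_SIZE = 5


@dataclass
class ProximityGraph:
    """Distance-thresholded weighted graph over the cells of one CellMap.

    Nodes are canonical cell indices (row order after sorting by
    section, x, y); cells from different sections are never connected.
    """

    graph: nx.Graph
    threshold_um: float
    cells: pd.DataFrame  # canonical ordering, index = node id


@dataclass
class ClusterResult:
    labels: np.ndarray  # cluster id per canonical cell index
    per_section: pd.DataFrame  # section, n_clusters, mean_cells_per_cluster
    mean_clusters_per_section: float
    mean_cells_per_cluster: float


def _canonical_cells(cells: CellMap) -> pd.DataFrame:
    df = cells.df.sort_values(["section", "x_um", "y_um"], kind="mergesort")
    return df.reset_index(drop=True)


def build_proximity_graph(
    cells: CellMap, threshold_um: float = DEFAULT_THRESHOLD_UM
) -> ProximityGraph:
    """Edges join within-section cell pairs strictly closer than the
    threshold; weight w = 1 - d/threshold."""
    if threshold_um <= 0:
        raise ValueError("threshold must be positive")
    df = _canonical_cells(cells)
    g = nx.Graph()
    g.add_nodes_from(df.index)
    for _, sec_df in df.groupby("section", sort=True):
        idx = sec_df.index.to_numpy()
        if idx.size < 2:
            continue
        dmat = squareform(pdist(sec_df[["x_um", "y_um"]].to_numpy()))
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                d = dmat[a, b]
                if d < threshold_um:
                    w = 1.0 - d / threshold_um
                    g.add_edge(int(idx[a]), int(idx[b]), weight=w, length=1.0 / w)
    return ProximityGraph(g, threshold_um, df)


def weighted_modularity(graph: nx.Graph, communities) -> float:
    """Weighted Newman modularity Q of a node partition.

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / (2m)] delta(c_i, c_j), with
    weighted adjacency and strengths. Edgeless graphs return 0 by
    convention.
    """
    m2 = 2.0 * graph.size(weight="weight")
    if m2 == 0:
        return 0.0
    strength = dict(graph.degree(weight="weight"))
    q = 0.0
    for comm in communities:
        comm = set(comm)
        internal = sum(
            d.get("weight", 1.0)
            for u, v, d in graph.edges(comm, data=True)
            if u in comm and v in comm
        )
        s = sum(strength[n] for n in comm)
        q += 2.0 * internal / m2 - (s / m2) ** 2
    return q


def _max_betweenness_edge(g: nx.Graph):
    """Highest-betweenness edge, ties broken on lowest sorted (i, j)."""
    bet = nx.edge_betweenness_centrality(g, weight="length", normalized=False)
    best_edge, best_val = None, -np.inf
    for (u, v), val in bet.items():
        key = tuple(sorted((u, v)))
        if val > best_val + 1e-12 or (
            abs(val - best_val) <= 1e-12
            and (best_edge is None or key < best_edge)
        ):
            best_edge, best_val = key, max(val, best_val)
    return best_edge


def _gn_removal_sequence(g: nx.Graph):
    """Yield the partition (list of frozensets) after each edge removal,
    starting with the intact graph."""
    work = g.copy()
    yield [frozenset(c) for c in nx.connected_components(work)]
    while work.number_of_edges():
        u, v = _max_betweenness_edge(work)
        work.remove_edge(u, v)
        yield [frozenset(c) for c in nx.connected_components(work)]


def girvan_newman_partition(graph: ProximityGraph | nx.Graph) -> list[frozenset]:
    """Best-modularity partition along the Girvan-Newman removal sequence.

    Returns the partition (list of frozensets of node ids) with maximal
    weighted modularity; on Q ties the earliest (fewest removals) partition
    wins. The empty graph yields an empty partition.
    """
    g = graph.graph if isinstance(graph, ProximityGraph) else graph
    if g.number_of_nodes() == 0:
        return []
    best, best_q = None, -np.inf
    for partition in _gn_removal_sequence(g):
        q = weighted_modularity(g, partition)
        if q > best_q + 1e-12:
            best, best_q = partition, q
    return best


def _split_oversized(g: nx.Graph, community: frozenset, max_size: int):
    """Continue GN edge removal inside an oversized community until every
    component has <= max_size members."""
    sub = g.subgraph(community).copy()
    while True:
        comps = [frozenset(c) for c in nx.connected_components(sub)]
        oversized = [c for c in comps if len(c) > max_size]
        if not oversized:
            return comps
        target = sub.subgraph(max(oversized, key=len))
        u, v = _max_betweenness_edge(target)
        sub.remove_edge(u, v)


def cluster_stats(
    graph: ProximityGraph,
    partition: list[frozenset] | None = None,
    max_cluster_size: int = MAX_CLUSTER_SIZE,
) -> ClusterResult:
    """Per-section cluster counts and mean cells per cluster.

    Communities larger than ``max_cluster_size`` are split by continued
    edge removal (no cell is ever discarded). Every cell receives exactly
    one cluster label.
    """
    if partition is None:
        partition = girvan_newman_partition(graph)
    df = graph.cells
    n = len(df)
    labels = np.full(n, -1, dtype=int)
    clusters: list[frozenset] = []
    for comm in partition:
        if len(comm) > max_cluster_size:
            clusters.extend(_split_oversized(graph.graph, comm, max_cluster_size))
        else:
            clusters.append(comm)
    for cid, comm in enumerate(sorted(clusters, key=min)):
        for node in comm:
            labels[node] = cid
    if np.any(labels < 0):
        raise ValueError("partition does not cover every cell")

    rows = []
    for sec, sec_df in df.groupby("section", sort=True):
        ids, counts = np.unique(labels[sec_df.index.to_numpy()], return_counts=True)
        rows.append(
            {
                "section": sec,
                "n_clusters": ids.size,
                "mean_cells_per_cluster": float(counts.mean()),
            }
        )
    per_section = pd.DataFrame(rows)
    return ClusterResult(
        labels=labels,
        per_section=per_section,
        mean_clusters_per_section=float(per_section["n_clusters"].mean()),
        mean_cells_per_cluster=float(per_section["mean_cells_per_cluster"].mean()),
    )
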