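"""Per-node topological features of an undirected PPI graph.

Pain genes sit disproportionately on network hubs, so node centralities
carry signal for the classifier. Eleven features are computed per
protein: degree, undirected edge count, average shortest-path length,
betweenness, closeness, clustering coefficient, eccentricity,
neighborhood connectivity, radiality, stress and topological
coefficient — the feature set popularised by Cytoscape's
NetworkAnalyzer, whose conventions are followed for the less standard
ones (stress, radiality, topological coefficient).

Path-based quantities are computed within connected components
(unreachable pairs are simply excluded, the "noninfinite" convention),
and betweenness is normalized by the component's pair count so values
stay in [0, 1] on disconnected graphs.

The heavy lifting (all-pairs hop distances, geodesic counts, and the
Brandes-style dependency accumulation behind stress and betweenness) is
vectorized over BFS levels with sparse adjacency products, so graphs of
a few thousand proteins are processed in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import csgraph

__all__ = [
    "TOPOLOGY_FEATURES",
    "TopologyProfile",
    "read_edge_list",
    "build_graph",
    "compute_topology",
    "stress_centrality",
    "radiality",
    "topological_coefficient",
    "compare_topology_by_label",
    "write_profiles",
]

# Fixed column order for every writer/consumer of topology profiles.
TOPOLOGY_FEATURES = [
    "degree",
    "undirected_edges",
    "avg_shortest_path",
    "betweenness",
    "closeness",
    "clustering_coefficient",
    "eccentricity",
    "neighborhood_connectivity",
    "radiality",
    "stress",
    "topological_coefficient",
]


@dataclass(frozen=True)
class TopologyProfile:
    degree: int
    undirected_edges: int
    avg_shortest_path: float
    betweenness: float
    closeness: float
    clustering_coefficient: float
    eccentricity: int
    neighborhood_connectivity: float
    radiality: float
    stress: int
    topological_coefficient: float


def read_edge_list(path: str | Path, min_score: float | None = None) -> nx.Graph:
    """Read a STRING-style TSV edge list into a simple undirected graph.

    Columns: ``protein1, protein2[, combined_score]``; a header row is
    detected by the literal column names. ``min_score`` drops edges
    whose score is below the cutoff (edges without a score column are
    kept regardless).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"edge list {path} needs at least two columns")
    if str(df.iloc[0, 0]).lower() in {"protein1", "node1", "source"}:
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] >= 3 and min_score is not None:
        score = pd.to_numeric(df[2], errors="coerce")
        df = df[score >= min_score]
    g = nx.Graph()
    for a, b in zip(df[0], df[1]):
        if a != b:  # self-loops dropped: the graph is simple
            g.add_edge(str(a), str(b))
    return g


def build_graph(edges, nodes=None) -> nx.Graph:
    """Build a simple undirected graph from an iterable of gene pairs."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for a, b in edges:
        if a != b:
            g.add_edge(a, b)
    return g


def _geodesic_sweep(adj: sparse.csr_matrix):
    """Distances, geodesic counts, and stress/betweenness dependencies
    for one connected component.

    Returns ``(dist, stress, betweenness_raw)`` where ``dist`` is the
    dense hop-distance matrix, ``stress[v]`` counts shortest paths
    through ``v`` (each unordered pair once) and ``betweenness_raw`` is
    the unnormalized undirected betweenness.
    """
    n = adj.shape[0]
    dist = csgraph.shortest_path(adj, method="D", unweighted=True)
    maxd = int(dist.max())
    # dist (and hence every level mask) and sigma are symmetric, which
    # lets every product below run as a plain csr @ dense with no copies
    masks = [dist == level for level in range(maxd + 2)]

    # geodesic counts, filled level by level: sigma[s, t] over d(s, t)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    for level in range(1, maxd + 1):
        reached = adj @ (sigma * masks[level - 1])
        np.copyto(sigma, reached, where=masks[level])

    # dependency accumulation (deepest level first), vectorized over
    # sources; dep[v, s] holds the source-s dependency of node v
    dep_stress = np.zeros((n, n))
    dep_btw = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_sigma = np.where(sigma > 0, 1.0 / sigma, 0.0)
    for level in range(maxd - 1, 0, -1):
        below = masks[level + 1]
        here = masks[level]
        acc = adj @ (below * (1.0 + dep_stress * inv_sigma))
        np.copyto(dep_stress, sigma * acc, where=here)
        acc = adj @ (below * ((1.0 + dep_btw) * inv_sigma))
        np.copyto(dep_btw, sigma * acc, where=here)

    stress = dep_stress.sum(axis=1) / 2.0
    btw_raw = dep_btw.sum(axis=1) / 2.0
    return dist, stress, btw_raw


def compute_topology(g: nx.Graph) -> pd.DataFrame:
    """Compute all eleven features for every node.

    Returns a DataFrame indexed by node with ``TOPOLOGY_FEATURES``
    columns. Isolated nodes get 0 for every path-based feature.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = list(g.nodes)
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=np.float64)
    adj = sparse.csr_matrix(adj)

    deg = np.asarray(adj.sum(axis=1)).ravel()
    out = pd.DataFrame(0.0, index=nodes, columns=TOPOLOGY_FEATURES)
    out["degree"] = deg
    out["undirected_edges"] = deg

    clustering = nx.clustering(g)
    out["clustering_coefficient"] = [clustering[v] for v in nodes]

    with np.errstate(divide="ignore", invalid="ignore"):
        nbr_conn = np.where(deg > 0, (adj @ deg) / np.maximum(deg, 1), 0.0)
    out["neighborhood_connectivity"] = nbr_conn

    out["topological_coefficient"] = _topological_coefficients(adj, deg)

    n_comp, comp_label = csgraph.connected_components(adj, directed=False)
    for c in range(n_comp):
        members = np.where(comp_label == c)[0]
        if members.size < 2:
            continue
        sub = adj[np.ix_(members, members)].tocsr()
        dist, stress, btw_raw = _geodesic_sweep(sub)
        m = members.size
        dsum = dist.sum(axis=1)
        ecc = dist.max(axis=1)
        diameter = ecc.max()
        rows = [nodes[i] for i in members]
        out.loc[rows, "avg_shortest_path"] = dsum / (m - 1)
        out.loc[rows, "eccentricity"] = ecc
        out.loc[rows, "closeness"] = (m - 1) / dsum
        out.loc[rows, "radiality"] = (diameter + 1) - dsum / (m - 1)
        out.loc[rows, "stress"] = stress
        norm = (m - 1) * (m - 2) / 2.0 if m > 2 else 1.0
        out.loc[rows, "betweenness"] = btw_raw / norm

    for col in ("degree", "undirected_edges", "eccentricity", "stress"):
        out[col] = np.rint(out[col].to_numpy()).astype(np.int64)
    return out


def _topological_coefficients(adj: sparse.csr_matrix, deg: np.ndarray) -> np.ndarray:
    """Vectorized topological coefficient for every node."""
    shared = (adj @ adj).tocsr()  # shared[v, w] = # common neighbors
    shared.setdiag(0)
    shared.eliminate_zeros()
    # J adds 1 for adjacent pairs, but only where >= 1 neighbor is shared
    mask = shared.copy()
    mask.data = np.ones_like(mask.data)
    j = shared + adj.multiply(mask)
    partners = np.asarray(mask.sum(axis=1)).ravel()
    jsum = np.asarray(j.sum(axis=1)).ravel()
    tc = np.zeros(adj.shape[0])
    ok = (deg >= 2) & (partners > 0)
    tc[ok] = jsum[ok] / (partners[ok] * deg[ok])
    return tc


def _component_of(g: nx.Graph, v):
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    return sorted(nx.node_connected_component(g, v))


def stress_centrality(g: nx.Graph, v) -> int:
    """Number of shortest paths through ``v`` (endpoints excluded, each
    unordered source-target pair counted once)."""
    comp = _component_of(g, v)
    if len(comp) < 3:
        return 0
    adj = sparse.csr_matrix(
        nx.to_scipy_sparse_array(g.subgraph(comp), nodelist=comp, dtype=np.float64)
    )
    _, stress, _ = _geodesic_sweep(adj)
    return int(round(stress[comp.index(v)]))


def radiality(g: nx.Graph, v) -> float:
    """Diameter-shifted closeness: mean of (diam + 1 - d(v, w)) over the
    rest of the component; 0 for isolated nodes."""
    comp = _component_of(g, v)
    if len(comp) < 2:
        return 0.0
    sub = g.subgraph(comp)
    dist = dict(nx.single_source_shortest_path_length(sub, v))
    diameter = nx.diameter(sub)
    total = sum(diameter + 1 - d for w, d in dist.items() if w != v)
    return total / (len(comp) - 1)


def topological_coefficient(g: nx.Graph, v) -> float:
    """Normalized shared-neighbor measure; 0 for nodes of degree < 2.

    TC(v) averages J(v, w) / degree(v) over nodes w sharing at least one
    neighbor with v, where J counts shared neighbors plus 1 when v and w
    are adjacent.
    """
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    kv = g.degree(v)
    if kv < 2:
        return 0.0
    nv = set(g[v])
    scores = []
    for w in g.nodes:
        if w == v:
            continue
        j = len(nv & set(g[w]))
        if j >= 1:
            scores.append((j + (1 if g.has_edge(v, w) else 0)) / kv)
    return float(np.mean(scores)) if scores else 0.0


def compare_topology_by_label(profiles: pd.DataFrame, labels) -> pd.DataFrame:
    """Two-group (P vs NP) summary per topological feature.

    Returns one row per feature with group means/medians and a
    Mann-Whitney rank-sum p-value; used to check that planted pain
    labels really sit on hubs.
    """
    lab = pd.Series(labels)
    missing = lab.index.difference(profiles.index)
    if len(missing):
        raise KeyError(
            f"{len(missing)} labelled genes missing from profiles, e.g. {missing[0]!r}"
        )
    pos = profiles.loc[lab.index[lab == 1]]
    neg = profiles.loc[lab.index[lab == 0]]
    if pos.empty or neg.empty:
        raise ValueError("both label groups must be non-empty")
    rows = []
    for feat in profiles.columns:
        a, b = pos[feat].to_numpy(float), neg[feat].to_numpy(float)
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0  # constant feature: no evidence either way
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "feature": feat,
                "mean_P": a.mean(),
                "mean_NP": b.mean(),
                "median_P": float(np.median(a)),
                "median_NP": float(np.median(b)),
                "p_ranksum": p,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write one row per gene, 11 feature columns, fixed order."""
    profiles[TOPOLOGY_FEATURES].to_csv(path, sep="\t", index_label="gene_id")
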