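"""Graph-theoretic network measures under proportional thresholding.

Node strength is computed on the full weighted connectivity matrix; the
clustering coefficient, characteristic path length (CPL) and betweenness
centrality are computed on the binarized graph obtained by keeping the top
fraction p of edges by weight (p = 0.30 by default).  The printed-formula
convention is binary: C_i = 2 t_i / (K_i (K_i - 1)) with C_i = 0 for
K_i < 2, and L is the node-mean of each node's average shortest-path
distance to the other nodes (finite distances only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import CoherenceMatrix


@dataclass
class ThresholdedGraph:
    """Binary adjacency from proportional thresholding of a weight matrix."""

    adjacency: np.ndarray
    retained_fraction: float
    labels: list[str]
    source_band: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class NodeMetrics:
    labels: list[str]
    strength: np.ndarray | None = None
    degree: np.ndarray | None = None
    clustering: np.ndarray | None = None
    triangles: np.ndarray | None = None
    betweenness: np.ndarray | None = None


@dataclass
class GlobalMetrics:
    cpl: float
    global_clustering: float
    per_node_path_length: np.ndarray
    n_nodes: int
    isolated_nodes: list[str] = field(default_factory=list)


def _as_weights(W: CoherenceMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(W, CoherenceMatrix):
        return W.values, list(W.labels)
    W = np.asarray(W, dtype=float)
    return W, [f"n{i}" for i in range(W.shape[0])]


def proportional_threshold(
    W: CoherenceMatrix | np.ndarray, p: float = 0.30
) -> ThresholdedGraph:
    """Keep the ``round(p * E)`` largest-weight edges and binarize.

    E = K(K-1)/2 is the number of possible undirected edges.  Ties at the
    cutoff weight are broken deterministically by ascending (row, column)
    index, so equal-weight inputs still yield a reproducible graph.
    """
    if not 0 < p <= 1:
        raise ValueError(f"retained fraction must be in (0, 1], got {p}")
    values, labels = _as_weights(W)
    if not np.allclose(values, values.T):
        raise ValueError("weight matrix must be symmetric")
    k = values.shape[0]
    iu = np.triu_indices(k, 1)
    weights = values[iu]
    n_keep = int(math.floor(p * len(weights) + 0.5))
    # sort by (-weight, row, col): stable deterministic tie-break
    order = np.lexsort((iu[1], iu[0], -weights))
    keep = order[:n_keep]
    adj = np.zeros_like(values, dtype=int)
    adj[iu[0][keep], iu[1][keep]] = 1
    adj = adj + adj.T
    band = W.band if isinstance(W, CoherenceMatrix) else None
    return ThresholdedGraph(
        adjacency=adj, retained_fraction=p, labels=labels, source_band=band
    )


def node_strength(W: CoherenceMatrix | np.ndarray) -> NodeMetrics:
    """Per-node sum of incident edge weights on the full weighted matrix."""
    values, labels = _as_weights(W)
    if (values < 0).any():
        raise ValueError("negative weights are not valid connectivity values")
    if not np.allclose(values, values.T):
        raise ValueError("weight matrix must be symmetric")
    off = values.copy()
    np.fill_diagonal(off, 0.0)
    return NodeMetrics(labels=labels, strength=off.sum(axis=1))


def clustering(graph: ThresholdedGraph) -> tuple[NodeMetrics, float]:
    """Binary clustering coefficients and their node-mean (global C).

    C_i is the fraction of a node's neighbour pairs that are themselves
    connected, i.e. 2 t_i / (K_i (K_i - 1)) with t_i the triangle count;
    nodes of degree < 2 contribute C_i = 0.
    """
    A = graph.adjacency
    deg = A.sum(axis=1)
    tri = np.diag(A @ A @ A) / 2.0  # closed walks of length 3 per node
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    metrics = NodeMetrics(
        labels=list(graph.labels), degree=deg, triangles=tri, clustering=ci
    )
    return metrics, float(ci.mean())


def characteristic_path_length(graph: ThresholdedGraph) -> GlobalMetrics:
    """CPL: mean over nodes of the average finite shortest-path distance.

    Distances are unweighted hop counts.  In a disconnected graph each
    node's l_i averages only the finite distances to its own component;
    fully isolated nodes contribute l_i = 0 and are reported in
    ``isolated_nodes`` so the convention is auditable.

    Raises
    ------
    ValueError
        If the graph has no edges at all (CPL undefined).
    """
    A = graph.adjacency
    if A.sum() == 0:
        raise ValueError("characteristic path length undefined on an empty graph")
    dist = shortest_path(A.astype(float), method="D", unweighted=True)
    np.fill_diagonal(dist, np.inf)  # exclude self-distance from the average
    finite = np.isfinite(dist)
    counts = finite.sum(axis=1)
    li = np.zeros(A.shape[0])
    has = counts > 0
    li[has] = np.where(finite, dist, 0.0)[has].sum(axis=1) / counts[has]
    isolated = [graph.labels[i] for i in np.nonzero(~has)[0]]
    _, global_c = clustering(graph)
    return GlobalMetrics(
        cpl=float(li.mean()),
        global_clustering=global_c,
        per_node_path_length=li,
        n_nodes=A.shape[0],
        isolated_nodes=isolated,
    )


def betweenness(graph: ThresholdedGraph, normalized: bool = False) -> NodeMetrics:
    """Shortest-path betweenness centrality on the binary graph.

    Unnormalized by default: for each unordered pair (s, t) the node v
    accrues sigma_st(v) / sigma_st (equivalently, half the sum over
    ordered pairs).  With ``normalized=True`` values are divided by
    (n-1)(n-2)/2.
    """
    g = nx.from_numpy_array(graph.adjacency)
    bc = nx.betweenness_centrality(g, normalized=normalized)
    values = np.array([bc[i] for i in range(graph.n_nodes)], dtype=float)
    return NodeMetrics(labels=list(graph.labels), betweenness=values)
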