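"""Global network indicators and per-node centrality measures.

Conventions for disconnected graphs:

* average path length is the mean shortest-path distance over *connected*
  ordered pairs only (undefined when no pair is connected);
* closeness applies the classical substitution rule — an unreachable pair
  contributes the total number of vertices ``|V|`` instead of a distance —
  so an isolated node in a graph of ``|V|`` nodes has closeness ``1/|V|``;
* eigenvector centrality is computed on the full adjacency matrix, where
  power iteration localises on the component with the largest spectral
  radius; the result is flagged when the graph is disconnected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph_io import Network

__all__ = [
    "NetworkSummary",
    "NodeMetrics",
    "connected_components",
    "shortest_path_lengths",
    "summarize",
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "eigenvector_centrality",
    "node_metrics",
    "metrics_table",
    "EigenvectorConvergenceError",
]


@dataclass(frozen=True)
class NetworkSummary:
    """Global topological indicators of one network state.

    ``density = 2|E| / (|V|(|V|-1))`` for two or more nodes (0 below);
    ``avg_degree = 2|E| / |V|``; ``avg_path_length`` averages shortest-path
    distances over connected ordered pairs and is NaN when none exist;
    ``diameter`` is the largest finite distance.
    """

    size: int
    edge_count: int
    density: float
    avg_degree: float
    avg_path_length: float
    n_components: int
    component_sizes: tuple[int, ...]
    diameter: int

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["component_sizes"] = list(self.component_sizes)
        return d


@dataclass(frozen=True)
class NodeMetrics:
    degree: int
    betweenness: float
    closeness: float
    eigenvector: float


def connected_components(net: Network) -> dict[str, int]:
    """Partition nodes into connected components.

    Ids run 1..n_components, assigned in decreasing component size with
    ties broken by the smallest member label — a deterministic ordering
    used for component colouring.
    """
    comps = [sorted(c) for c in nx.connected_components(net.to_networkx())]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return {node: cid for cid, comp in enumerate(comps, start=1) for node in comp}


def shortest_path_lengths(net: Network, source: str) -> dict[str, int | None]:
    """BFS distances from ``source``; unreachable nodes map to ``None``
    (distance infinity).  The distance from a node to itself is 0."""
    if source not in net.nodes:
        raise KeyError(f"unknown source node {source!r}")
    dist = nx.single_source_shortest_path_length(net.to_networkx(), source)
    return {n: dist.get(n) for n in net.nodes}


def _all_pairs_stats(g: nx.Graph) -> tuple[float, int]:
    """(mean distance over connected ordered pairs, max finite distance)."""
    total = 0
    pairs = 0
    diameter = 0
    for _, dist in nx.all_pairs_shortest_path_length(g):
        for d in dist.values():
            if d > 0:
                total += d
                pairs += 1
                if d > diameter:
                    diameter = d
    return (total / pairs if pairs else math.nan), diameter


def summarize(net: Network, include_paths: bool = True) -> NetworkSummary:
    """Compute all global indicators for a network.

    ``include_paths=False`` skips the all-pairs distance pass (average
    path length and diameter become NaN/0) — useful inside long cascades
    where only size and connectivity are traced.
    """
    n = net.size
    m = net.edge_count
    density = 2.0 * m / (n * (n - 1)) if n >= 2 else 0.0
    avg_degree = 2.0 * m / n if n >= 1 else 0.0
    g = net.to_networkx()
    sizes = tuple(sorted((len(c) for c in nx.connected_components(g)), reverse=True))
    if include_paths and n >= 1:
        apl, diam = _all_pairs_stats(g)
    else:
        apl, diam = math.nan, 0
    return NetworkSummary(
        size=n,
        edge_count=m,
        density=density,
        avg_degree=avg_degree,
        avg_path_length=apl,
        n_components=len(sizes),
        component_sizes=sizes,
        diameter=diam,
    )


def degree_centrality(net: Network) -> dict[str, int]:
    """Raw degree k(i) = |N(i)| per node."""
    return net.degrees()


def betweenness_centrality(net: Network) -> dict[str, float]:
    """Unnormalised betweenness: for each vertex v, the sum over unordered
    pairs {i, j} (i != v != j) of the fraction of i-j geodesics passing
    through v.  Pairs with no connecting path contribute 0."""
    return dict(nx.betweenness_centrality(net.to_networkx(), normalized=False))


def closeness_centrality(net: Network) -> dict[str, float]:
    """Closeness (|V|-1) / sum_i d'(v, i) with the substitution rule:
    d'(v, i) = d(v, i) when a path exists, else |V|.

    Raises ``ValueError`` on a single-node network, where closeness is
    undefined.
    """
    n = net.size
    if n < 2:
        raise ValueError("closeness undefined for networks with fewer than 2 nodes")
    g = net.to_networkx()
    out: dict[str, float] = {}
    for v in net.nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        total = sum(dist.get(i, n) for i in net.nodes if i != v)
        out[v] = (n - 1) / total
    return out


class EigenvectorConvergenceError(RuntimeError):
    """Power iteration failed to converge; carries the last iterate."""

    def __init__(self, iterate: dict[str, float], max_iter: int):
        super().__init__(f"eigenvector centrality did not converge in {max_iter} iterations")
        self.iterate = iterate


def eigenvector_centrality(
    net: Network, tol: float = 1e-10, max_iter: int = 10000
) -> dict[str, float]:
    """Principal eigenvector of the 0/1 adjacency matrix by power iteration.

    Starts from the uniform positive vector, rescales every iterate so the
    maximum entry is 1, and stops when successive rescaled iterates differ
    by less than ``tol`` in max norm.  Requires at least one edge.

    Iteration actually uses the shifted matrix A + I: it shares A's
    principal eigenvector (eigenvalues are shifted by +1, so their order
    is preserved) but converges on bipartite graphs, where plain power
    iteration on A oscillates with period 2.
    """
    if net.edge_count == 0:
        raise ValueError("eigenvector centrality requires at least one edge")
    labels = sorted(net.nodes)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    a = np.zeros((n, n))
    for u, v in net.edges:
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    shifted = a + np.eye(n)
    x = np.ones(n)
    x /= x.max()
    for _ in range(max_iter):
        y = shifted @ x
        m = y.max()
        if m <= 0:  # pragma: no cover - impossible with an edge present
            raise ValueError("adjacency iteration vanished")
        y /= m
        if np.abs(y - x).max() < tol:
            return {lab: float(y[index[lab]]) for lab in labels}
        x = y
    raise EigenvectorConvergenceError(
        {lab: float(x[index[lab]]) for lab in labels}, max_iter
    )


def node_metrics(
    net: Network, tol: float = 1e-10, max_iter: int = 10000
) -> dict[str, NodeMetrics]:
    """All four centrality measures per node."""
    deg = degree_centrality(net)
    btw = betweenness_centrality(net)
    clo = closeness_centrality(net)
    eig = eigenvector_centrality(net, tol=tol, max_iter=max_iter)
    return {
        n: NodeMetrics(
            degree=deg[n], betweenness=btw[n], closeness=clo[n], eigenvector=eig[n]
        )
        for n in net.nodes
    }


def sorted_listing(values: dict[str, float]) -> list[tuple[str, float]]:
    """Descending by value, ties broken lexicographically by label."""
    return sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))


def metrics_table(net: Network) -> pd.DataFrame:
    """Per-node metrics as a DataFrame: node, degree, betweenness,
    closeness, eigenvector, component_id; rows sorted by descending degree
    then label, matching the sorted listings a user browses."""
    metrics = node_metrics(net)
    comp = connected_components(net)
    rows = [
        {
            "node": n,
            "degree": m.degree,
            "betweenness": m.betweenness,
            "closeness": m.closeness,
            "eigenvector": m.eigenvector,
            "component_id": comp[n],
        }
        for n, m in metrics.items()
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["degree", "node"], ascending=[False, True], ignore_index=True
    )
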