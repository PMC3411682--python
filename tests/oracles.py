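"""Independent brute-force oracles used only by the test suite.

Everything here is computed from the dense adjacency matrix with plain
linear algebra — Floyd–Warshall distances, shortest-path counts via
matrix powers (walks of minimal length are exactly the geodesics), and
eigen-decomposition — deliberately sharing no code path with the package
under test.
"""

from __future__ import annotations

import itertools

import numpy as np

INF = np.inf


def adjacency(labels: list[str], edges) -> np.ndarray:
    idx = {lab: i for i, lab in enumerate(labels)}
    a = np.zeros((len(labels), len(labels)))
    for u, v in edges:
        a[idx[u], idx[v]] = 1.0
        a[idx[v], idx[u]] = 1.0
    return a


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.where(a > 0, 1.0, INF)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def geodesic_counts(a: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[i, j] = number of shortest i-j paths.

    The number of walks of length d(i, j) equals the number of shortest
    paths, because a minimal-length walk cannot revisit a vertex.
    """
    n = a.shape[0]
    sigma = np.zeros((n, n))
    power = np.eye(n)
    for length in range(n):
        mask = dist == length
        sigma[mask] = power[mask]
        power = power @ a
    return sigma


def brute_betweenness(a: np.ndarray) -> np.ndarray:
    """Unnormalised betweenness: each unordered pair counted once,
    endpoints excluded, disconnected pairs contribute nothing."""
    n = a.shape[0]
    dist = floyd_warshall(a)
    sigma = geodesic_counts(a, dist)
    out = np.zeros(n)
    for i, j in itertools.combinations(range(n), 2):
        if not np.isfinite(dist[i, j]):
            continue
        for v in range(n):
            if v in (i, j):
                continue
            if dist[i, v] + dist[v, j] == dist[i, j]:
                out[v] += sigma[i, v] * sigma[v, j] / sigma[i, j]
    return out


def brute_closeness(a: np.ndarray) -> np.ndarray:
    """(n-1) / sum of distances, substituting n for unreachable pairs."""
    n = a.shape[0]
    dist = floyd_warshall(a)
    subst = np.where(np.isfinite(dist), dist, float(n))
    np.fill_diagonal(subst, 0.0)
    return (n - 1) / subst.sum(axis=1)


def brute_eigenvector(a: np.ndarray) -> np.ndarray:
    """Principal eigenvector via full symmetric eigendecomposition,
    rescaled to max entry 1."""
    vals, vecs = np.linalg.eigh(a)
    v = vecs[:, np.argmax(vals)]
    v = np.abs(v)
    return v / v.max()


def union_find_components(labels: list[str], edges) -> dict[str, int]:
    """Component partition by union-find, ids assigned by decreasing size
    then smallest member label (the package's deterministic convention)."""
    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups: dict[str, list[str]] = {}
    for lab in labels:
        groups.setdefault(find(lab), []).append(lab)
    comps = sorted((sorted(g) for g in groups.values()),
                   key=lambda c: (-len(c), c[0]))
    return {lab: cid for cid, comp in enumerate(comps, 1) for lab in comp}


def connected_edge_subsets(n: int):
    """Yield every connected labelled graph on exactly n nodes as an edge
    list over labels a, b, c, ... (exhaustive enumeration)."""
    labels = [chr(ord("a") + i) for i in range(n)]
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(1, 1 << len(pairs)):
        edges = [pairs[k] for k in range(len(pairs)) if bits >> k & 1]
        # quick union-find connectivity over all n nodes
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in edges:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
        if len({find(i) for i in range(n)}) == 1:
            yield labels, [(labels[u], labels[v]) for u, v in edges]
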