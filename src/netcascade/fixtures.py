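"""Deterministic synthetic network generators.

These produce the structural motifs the perturbation analyses assume —
scale-free hubs (preferential attachment), bipartite interaction webs,
connector nodes bridging modules — so every operation is testable without
downloading any empirical network.  The same spec always yields the
bit-identical network.

Labels are zero-padded so lexicographic tie-breaking matches numeric
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_io import Network, NetType

__all__ = ["FixtureSpec", "generate", "star", "path", "complete",
           "erdos_renyi", "barabasi_albert", "bipartite_web",
           "two_modules_bridge"]

KINDS = ("star", "path", "complete", "erdos_renyi", "barabasi_albert",
         "bipartite_web", "two_modules_bridge")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def _width(n: int) -> int:
    return max(2, len(str(n)))


def star(n: int) -> Network:
    """Hub plus n leaves; the canonical single-point-of-failure graph."""
    if n < 1:
        raise ValueError("star requires n >= 1 leaves")
    w = _width(n)
    return Network.from_edges(("hub", f"leaf{i:0{w}d}") for i in range(1, n + 1))


def path(n: int) -> Network:
    """n nodes in a line."""
    if n < 2:
        raise ValueError("path requires n >= 2 nodes")
    w = _width(n)
    labels = [f"n{i:0{w}d}" for i in range(1, n + 1)]
    return Network.from_edges(zip(labels, labels[1:]))


def complete(n: int) -> Network:
    if n < 2:
        raise ValueError("complete requires n >= 2 nodes")
    w = _width(n)
    labels = [f"n{i:0{w}d}" for i in range(1, n + 1)]
    return Network.from_edges(
        (labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)
    )


def erdos_renyi(n: int, p: float, seed: int) -> Network:
    """G(n, p): each pair independently with probability p.

    Isolated nodes are dropped so the result stays representable as an
    edge list.  Raises if no edge is drawn at all.
    """
    if n < 2 or not (0 < p <= 1):
        raise ValueError("erdos_renyi requires n >= 2 and p in (0, 1]")
    rng = np.random.default_rng(seed)
    w = _width(n)
    labels = [f"n{i:0{w}d}" for i in range(1, n + 1)]
    edges = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    if not edges:
        raise ValueError(f"erdos_renyi(n={n}, p={p}, seed={seed}) drew no edges")
    return Network.from_edges(edges)


def barabasi_albert(n: int, m: int, seed: int) -> Network:
    """Preferential attachment: seed (m+1)-clique, then each arriving node
    links to m distinct existing nodes with probability proportional to
    their current degree.

    Edge count is fixed by construction: C(m+1, 2) + m * (n - m - 1).
    """
    if m < 1 or n < m + 1:
        raise ValueError("barabasi_albert requires m >= 1 and n >= m + 1")
    rng = np.random.default_rng(seed)
    w = _width(n)
    labels = [f"n{i:0{w}d}" for i in range(1, n + 1)]
    degree = np.zeros(n, dtype=np.int64)
    edges: list[tuple[str, str]] = []
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            edges.append((labels[i], labels[j]))
            degree[i] += 1
            degree[j] += 1
    for new in range(m + 1, n):
        weights = degree[:new].astype(float)
        targets = rng.choice(new, size=m, replace=False, p=weights / weights.sum())
        for t in sorted(int(t) for t in targets):
            edges.append((labels[t], labels[new]))
            degree[t] += 1
            degree[new] += 1
    net = Network.from_edges(edges)
    expected = m * (m + 1) // 2 + m * (n - m - 1)
    assert net.edge_count == expected, "construction edge ledger mismatch"
    return net


def bipartite_web(n_rows: int, n_cols: int, connectance: float, seed: int) -> Network:
    """Bipartite interaction web (e.g. plants x pollinators).

    Edges run only between row nodes ``r*`` and column nodes ``c*``; every
    row and every column is guaranteed at least one interaction, then
    random links are added until roughly ``connectance * n_rows * n_cols``
    interactions exist.
    """
    if n_rows < 1 or n_cols < 1 or not (0 < connectance <= 1):
        raise ValueError("bipartite_web requires n_rows, n_cols >= 1 and "
                         "connectance in (0, 1]")
    rng = np.random.default_rng(seed)
    rw, cw = _width(n_rows), _width(n_cols)
    rows = [f"r{i:0{rw}d}" for i in range(1, n_rows + 1)]
    cols = [f"c{j:0{cw}d}" for j in range(1, n_cols + 1)]
    edges: set[tuple[str, str]] = set()
    for r in rows:
        edges.add((str(rng.choice(cols)), r))
    covered = {c for c, _ in edges}
    for c in cols:
        if c not in covered:
            edges.add((c, str(rng.choice(rows))))
    target = max(len(edges), int(round(connectance * n_rows * n_cols)))
    cells = [(c, r) for r in rows for c in cols]
    order = rng.permutation(len(cells))
    for k in order:
        if len(edges) >= target:
            break
        edges.add(cells[int(k)])
    return Network.from_edges(edges, net_type=NetType.ECOLOGICAL_BIPARTITE)


def two_modules_bridge(k: int) -> Network:
    """Two k-cliques joined by a single bridge node with one edge into
    each clique — the connector scenario where removing one node of
    modest degree fragments the network in two."""
    if k < 2:
        raise ValueError("two_modules_bridge requires cliques of k >= 2")
    w = _width(k)
    a = [f"a{i:0{w}d}" for i in range(1, k + 1)]
    b = [f"b{i:0{w}d}" for i in range(1, k + 1)]
    edges = [(x[i], x[j]) for x in (a, b) for i in range(k) for j in range(i + 1, k)]
    edges += [("bridge", a[0]), ("bridge", b[0])]
    return Network.from_edges(edges)


def generate(spec: FixtureSpec) -> Network:
    """Dispatch on :class:`FixtureSpec`; same spec, same network, always."""
    p = dict(spec.params)
    if spec.kind == "star":
        return star(**p)
    if spec.kind == "path":
        return path(**p)
    if spec.kind == "complete":
        return complete(**p)
    if spec.kind == "erdos_renyi":
        return erdos_renyi(seed=spec.seed, **p)
    if spec.kind == "barabasi_albert":
        return barabasi_albert(seed=spec.seed, **p)
    if spec.kind == "bipartite_web":
        return bipartite_web(seed=spec.seed, **p)
    if spec.kind == "two_modules_bridge":
        return two_modules_bridge(**p)
    raise ValueError(spec.kind)  # pragma: no cover
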