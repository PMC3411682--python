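"""Read, validate, simplify and write whitespace edge-list networks.

The on-disk format is one interaction per line: two whitespace-separated
node labels.  Parsing simplifies the input to a binary undirected graph —
self-loops are dropped, duplicate lines (including reversed duplicates)
collapse to a single edge, and any columns beyond the first two are
ignored.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import enum
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "NetType",
    "Network",
    "ParseReport",
    "EdgeListError",
    "parse_edge_list",
    "read_edge_list",
    "write_edge_list",
    "export_graphml",
]


class NetType(str, enum.Enum):
    """Declared kind of the network.

    Metadata only: a node may be a gene, protein or a species, but no
    algorithm branches on this tag — it just labels reports.
    """

    PPI = "ppi"
    GENETIC = "genetic"
    COEXPRESSION = "coexpression"
    ECOLOGICAL_BIPARTITE = "ecological_bipartite"
    SOCIAL = "social"
    GENERIC = "generic"


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


def _norm_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Network:
    """A simple (loop-free, duplicate-free) undirected graph.

    Parameters
    ----------
    nodes
        Node labels.  May include isolated nodes (degree 0) after a
        perturbation, but a freshly parsed network has none, since every
        node enters via an edge line.
    edges
        Unordered pairs of distinct labels, stored as sorted 2-tuples.
    net_type
        Declared network kind; metadata only.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    net_type: NetType = NetType.GENERIC

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r} violates Network invariants")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside node set")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
        net_type: NetType = NetType.GENERIC,
    ) -> "Network":
        """Build a network from edge pairs, normalising order and duplicates."""
        norm = frozenset(_norm_edge(str(u), str(v)) for u, v in edges)
        nodes = frozenset(x for e in norm for x in e) | frozenset(map(str, extra_nodes))
        return cls(nodes=nodes, edges=norm, net_type=net_type)

    # -- basic structure ------------------------------------------------

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        if node not in self.nodes:
            raise KeyError(node)
        return sum(node in e for e in self.edges)

    def degrees(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for u, v in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    def has_edge(self, u: str, v: str) -> bool:
        return _norm_edge(u, v) in self.edges

    def isolated_nodes(self) -> frozenset[str]:
        touched = {x for e in self.edges for x in e}
        return frozenset(self.nodes - touched)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def __contains__(self, node: str) -> bool:
        return node in self.nodes


@dataclass
class ParseReport:
    """Bookkeeping for one parse: every input line is accounted for.

    ``input_lines == retained_edges + dropped_loops + collapsed_duplicates
    + skipped_lines`` (blank and comment lines).
    """

    input_lines: int = 0
    retained_edges: int = 0
    dropped_loops: int = 0
    collapsed_duplicates: int = 0
    skipped_lines: int = 0
    extra_column_lines: int = 0
    loop_labels: list[str] = field(default_factory=list)

    def check(self) -> None:
        total = (
            self.retained_edges
            + self.dropped_loops
            + self.collapsed_duplicates
            + self.skipped_lines
        )
        if total != self.input_lines:
            raise AssertionError(
                f"parse report does not balance: {total} != {self.input_lines}"
            )


def parse_edge_list(
    text: str, net_type: NetType | str = NetType.GENERIC
) -> tuple[Network, ParseReport]:
    """Parse a whitespace-delimited two-column edge list.

    The first two tokens of each non-blank, non-comment line are the node
    labels; extra tokens (e.g. weights) are ignored with a warning so
    weighted lists degrade gracefully to binary.  Self-loop lines are
    dropped silently but counted in the report; duplicate and reversed
    duplicate lines collapse to one edge.

    Raises
    ------
    EdgeListError
        On a line with fewer than two tokens (naming the line number), or
        when zero edges remain after filtering ("empty network").
    """
    net_type = NetType(net_type)
    report = ParseReport()
    edges: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        report.input_lines += 1
        line = raw.strip()
        if not line or line.startswith("#"):
            report.skipped_lines += 1
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise EdgeListError(
                f"line {lineno}: expected at least 2 whitespace-separated "
                f"labels, got {len(tokens)}: {raw!r}"
            )
        if len(tokens) > 2:
            report.extra_column_lines += 1
        u, v = tokens[0], tokens[1]
        if u == v:
            report.dropped_loops += 1
            report.loop_labels.append(u)
            continue
        e = _norm_edge(u, v)
        if e in edges:
            report.collapsed_duplicates += 1
        else:
            edges.add(e)
            report.retained_edges += 1
    if not edges:
        raise EdgeListError("empty network: no edges remain after filtering")
    if report.extra_column_lines:
        warnings.warn(
            f"{report.extra_column_lines} line(s) had extra columns beyond the "
            "first two; treated as binary interactions",
            stacklevel=2,
        )
    report.check()
    return Network.from_edges(edges, net_type=net_type), report


def read_edge_list(
    path, net_type: NetType | str = NetType.GENERIC
) -> tuple[Network, ParseReport]:
    """Parse an edge-list file (UTF-8 text)."""
    with open(path, encoding="utf-8") as fh:
        return parse_edge_list(fh.read(), net_type=net_type)


def write_edge_list(net: Network) -> str:
    """Serialise edges, one per line, lexicographically sorted.

    Isolated nodes are not representable in an edge list; callers wanting
    them must report ``net.isolated_nodes()`` in a side-car.  Round-trip
    through :func:`parse_edge_list` reproduces the network up to isolates.
    """
    return "".join(f"{u} {v}\n" for u, v in sorted(net.edges))


def export_graphml(
    net: Network, path, component_ids: Mapping[str, int] | None = None
) -> None:
    """Write the network as GraphML 1.0, optionally tagging each node with
    its connected-component id as a node attribute ``component``."""
    if component_ids is not None:
        missing = net.nodes - set(component_ids)
        if missing:
            raise ValueError(f"component_ids missing nodes: {sorted(missing)[:5]}")
    g = net.to_networkx()
    if component_ids is not None:
        nx.set_node_attributes(g, {n: int(component_ids[n]) for n in g}, "component")
    nx.write_graphml(g, path)


def validate_graphml(path) -> tuple[int, int]:
    """Return (node count, edge count) of a GraphML file via a plain XML read."""
    ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
    root = ET.parse(path).getroot()
    return (
        len(root.findall(".//g:node", ns)),
        len(root.findall(".//g:edge", ns)),
    )
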