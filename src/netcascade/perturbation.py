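"""Single and clustered perturbations with secondary-extinction accounting.

A perturbation removes one or more nodes (with their incident edges) or
one or more edges, all *simultaneously*.  Any surviving node left with no
links has lost its entire support to the remaining sub-network and is
counted as a secondary extinction: it is non-functional and is removed
from the remaining network as well.  One round suffices — removing an
already-isolated node cannot isolate anyone else — so no cascading
re-evaluation is needed within a single perturbation event.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_io import Network, _norm_edge
from .topology import NetworkSummary, connected_components, summarize

__all__ = [
    "PerturbationResult",
    "FragmentationReport",
    "remove_nodes",
    "remove_edges",
    "fragmentation_report",
]


@dataclass(frozen=True)
class PerturbationResult:
    """Outcome of one perturbation event.

    ``primaries`` are the deliberately removed nodes (or edges, for edge
    perturbations); ``secondaries`` the survivors that became isolated and
    were therefore removed from ``remaining`` too.  Node conservation
    holds for node removals:
    ``before.size == remaining.size + len(primaries) + len(secondaries)``.
    """

    primaries: tuple
    secondaries: frozenset[str]
    remaining: Network
    before: NetworkSummary
    after: NetworkSummary

    @property
    def delta(self) -> dict[str, float]:
        """after − before, field by field (component_sizes excluded)."""
        out = {}
        for name in ("size", "edge_count", "density", "avg_degree",
                     "avg_path_length", "n_components", "diameter"):
            out[name] = getattr(self.after, name) - getattr(self.before, name)
        return out


def _finalize(
    net: Network,
    primaries: tuple,
    primary_nodes: frozenset[str],
    kept_edges: frozenset[tuple[str, str]],
    include_paths: bool,
) -> PerturbationResult:
    survivors = net.nodes - primary_nodes
    touched = {x for e in kept_edges for x in e}
    secondaries = frozenset(survivors - touched)
    remaining = Network(
        nodes=frozenset(touched), edges=kept_edges, net_type=net.net_type
    )
    return PerturbationResult(
        primaries=primaries,
        secondaries=secondaries,
        remaining=remaining,
        before=summarize(net, include_paths=include_paths),
        after=summarize(remaining, include_paths=include_paths)
        if remaining.size
        else summarize(remaining, include_paths=False),
    )


def remove_nodes(
    net: Network, targets: list[str], include_paths: bool = True
) -> PerturbationResult:
    """Remove the target nodes and their incident edges simultaneously.

    Survivors whose degree falls to zero are secondaries and are removed
    from the remaining network.  Targets must exist, be non-empty and
    duplicate-free; group size is unlimited.
    """
    if not targets:
        raise ValueError("empty target list")
    if len(set(targets)) != len(targets):
        dupes = sorted({t for t in targets if targets.count(t) > 1})
        raise ValueError(f"duplicate targets: {dupes}")
    unknown = [t for t in targets if t not in net.nodes]
    if unknown:
        raise KeyError(f"unknown target node(s): {unknown}")
    gone = frozenset(targets)
    kept = frozenset(e for e in net.edges if gone.isdisjoint(e))
    return _finalize(net, tuple(targets), gone, kept, include_paths)


def remove_edges(
    net: Network, targets: list[tuple[str, str]], include_paths: bool = True
) -> PerturbationResult:
    """Remove the target edges simultaneously.

    A node stripped of all its edges becomes a secondary extinction even
    though it was never named — the perturbation targeted interactions,
    not the entity itself.
    """
    if not targets:
        raise ValueError("empty target list")
    norm = [_norm_edge(u, v) for u, v in targets]
    missing = [e for e in norm if e not in net.edges]
    if missing:
        raise KeyError(f"nonexistent edge(s): {missing}")
    gone = frozenset(norm)
    kept = frozenset(net.edges - gone)
    return _finalize(net, tuple(norm), frozenset(), kept, include_paths)


@dataclass(frozen=True)
class FragmentationReport:
    n_components_before: int
    n_components_after: int
    partition_after: dict[str, int]
    fragmented: bool
    collapsed: bool

    @property
    def new_component_count(self) -> int:
        return self.n_components_after - self.n_components_before


def fragmentation_report(before: Network, after: Network) -> FragmentationReport:
    """Compare component structure before and after a perturbation.

    Flags ``fragmented`` when the component count increased, ``collapsed``
    when nothing functional remains.
    """
    if not after.nodes <= before.nodes:
        raise ValueError("after-network is not a subset of before-network")
    nb = len(set(connected_components(before).values())) if before.nodes else 0
    part = connected_components(after) if after.nodes else {}
    na = len(set(part.values()))
    return FragmentationReport(
        n_components_before=nb,
        n_components_after=na,
        partition_after=part,
        fragmented=na > nb,
        collapsed=after.size == 0,
    )
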