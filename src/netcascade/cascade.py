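"""Sequential perturbation cascades, collapse detection and co-extinction
curves.

A cascade removes one primary node per step — in descending or ascending
degree order, or in a seeded random shuffle — re-analysing the reduced
functional network after every removal.  Nodes that already vanished as
secondary extinctions are skipped and never consume a step, so the
percentage axis counts realised primary removals over the original node
count.  The collapse step is the first step after which no functional
(linked) node remains.

Degree ranking is ``static`` by default (the node list is sorted once on
the input network and removed in that order); ``dynamic`` re-ranks the
current remaining network before every pick.  Ties are always broken
lexicographically by label so every run is reproducible.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_io import Network
from .perturbation import remove_nodes
from .topology import NetworkSummary, summarize

__all__ = [
    "CascadeSpec",
    "CascadeRecord",
    "CoextinctionCurve",
    "ALL_METRICS",
    "degree_ranking",
    "run_cascade",
    "leave_one_out_scan",
    "compare_curves",
    "replicate_envelope",
    "curve_to_frame",
    "curve_to_csv",
]

ALL_METRICS = frozenset(
    {"size", "n_components", "avg_degree", "avg_path_length", "density",
     "secondary_count"}
)


@dataclass(frozen=True)
class CascadeSpec:
    """Configuration of one sequential-perturbation run.

    ``order``: ``descending`` (generalists first), ``ascending``
    (specialists first) or ``random``.  ``ranking``: ``static`` sorts once
    on the input network, ``dynamic`` re-ranks after every removal.
    Random order requires a ``seed``; replicate r uses ``seed + (r - 1)``.
    ``recorded_metrics`` limits the per-step summary work (the all-pairs
    distance pass behind ``avg_path_length`` dominates run time on large
    graphs).  ``max_steps`` truncates long cascades; a truncated curve may
    report no collapse.
    """

    order: str = "descending"
    ranking: str = "static"
    seed: int | None = None
    replicates: int = 1
    recorded_metrics: frozenset[str] = ALL_METRICS
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if self.order not in ("descending", "ascending", "random"):
            raise ValueError(f"unknown order {self.order!r}")
        if self.ranking not in ("static", "dynamic"):
            raise ValueError(f"unknown ranking {self.ranking!r}")
        if self.order == "random" and self.seed is None:
            raise ValueError("random order requires a seed")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = frozenset(self.recorded_metrics) - ALL_METRICS
        if unknown:
            raise ValueError(f"unknown recorded metrics: {sorted(unknown)}")
        object.__setattr__(self, "recorded_metrics", frozenset(self.recorded_metrics))

    @property
    def label(self) -> str:
        if self.order == "random":
            return f"random_seed{self.seed}"
        return f"{'desc' if self.order == 'descending' else 'asc'}_{self.ranking}"


@dataclass(frozen=True)
class CascadeRecord:
    """State after one primary removal.

    Conservation holds at every record:
    ``original_size == step + cumulative_secondaries + remaining_size``.
    """

    step: int
    primary: str
    secondaries_this_step: frozenset[str]
    cumulative_secondaries: int
    remaining_size: int
    pct_primaries_removed: float
    summary: NetworkSummary


@dataclass(frozen=True)
class CoextinctionCurve:
    """Full trace of one cascade, plus where (if ever) it collapsed.

    ``collapse_step`` is the first step after which the functional network
    is empty, or ``None`` for curves truncated before collapse.
    ``removal_order`` records the realised primary sequence (for random
    cascades, the permutation actually consumed) for auditability.
    """

    spec: CascadeSpec
    original_size: int
    records: tuple[CascadeRecord, ...]
    collapse_step: int | None
    removal_order: tuple[str, ...]
    label: str = field(default="")

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", self.spec.label)


def _degree_sorted(net: Network, descending: bool) -> list[str]:
    deg = net.degrees()
    sign = -1 if descending else 1
    return sorted(net.nodes, key=lambda n: (sign * deg[n], n))


def degree_ranking(net: Network, order: str, ranking: str = "static"):
    """Static: the full removal permutation, sorted by initial degree with
    lexicographic tie-break.  Dynamic: a policy function mapping the
    current remaining network to the next extreme-degree pick."""
    if net.size == 0:
        raise ValueError("empty network")
    descending = order == "descending"
    if ranking == "static":
        return _degree_sorted(net, descending)

    def policy(current: Network) -> str:
        return _degree_sorted(current, descending)[0]

    return policy


def _shuffled_order(net: Network, seed: int) -> list[str]:
    # Fisher–Yates permutation of the label-sorted node list so the same
    # seed gives the same order regardless of set-iteration details.
    labels = sorted(net.nodes)
    rng = np.random.default_rng(seed)
    for i in range(len(labels) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        labels[i], labels[j] = labels[j], labels[i]
    return labels


def _run_single(net: Network, spec: CascadeSpec, seed: int | None) -> CoextinctionCurve:
    include_paths = "avg_path_length" in spec.recorded_metrics
    original_size = net.size
    if spec.order == "random":
        pending: list[str] | None = _shuffled_order(net, seed)
        policy = None
    elif spec.ranking == "static":
        pending = degree_ranking(net, spec.order, "static")
        policy = None
    else:
        pending = None
        policy = degree_ranking(net, spec.order, "dynamic")

    current = net
    records: list[CascadeRecord] = []
    removal_order: list[str] = []
    cum_sec = 0
    step = 0
    idx = 0
    while current.size > 0:
        if spec.max_steps is not None and step >= spec.max_steps:
            break
        if pending is not None:
            # skip ranked nodes that already vanished as secondaries
            while idx < len(pending) and pending[idx] not in current.nodes:
                idx += 1
            if idx >= len(pending):
                break
            primary = pending[idx]
            idx += 1
        else:
            primary = policy(current)
        step += 1
        result = remove_nodes(current, [primary], include_paths=include_paths)
        current = result.remaining
        cum_sec += len(result.secondaries)
        records.append(
            CascadeRecord(
                step=step,
                primary=primary,
                secondaries_this_step=result.secondaries,
                cumulative_secondaries=cum_sec,
                remaining_size=current.size,
                pct_primaries_removed=100.0 * step / original_size,
                summary=result.after,
            )
        )
        removal_order.append(primary)
    collapse = step if (records and records[-1].remaining_size == 0) else None
    return CoextinctionCurve(
        spec=spec,
        original_size=original_size,
        records=tuple(records),
        collapse_step=collapse,
        removal_order=tuple(removal_order),
        label=spec.label if seed is None or spec.order != "random"
        else f"random_seed{seed}",
    )


def run_cascade(net: Network, spec: CascadeSpec):
    """Run a cascade to collapse (or exhaustion/truncation).

    Returns one :class:`CoextinctionCurve`, or a list of curves when
    ``spec.replicates > 1`` with random order (replicate r reuses the spec
    with seed ``spec.seed + r - 1``).
    """
    if net.size == 0:
        raise ValueError("empty network")
    if spec.order == "random" and spec.replicates > 1:
        return [
            _run_single(net, spec, spec.seed + r) for r in range(spec.replicates)
        ]
    return _run_single(net, spec, spec.seed)


def leave_one_out_scan(net: Network, include_paths: bool = True) -> pd.DataFrame:
    """Remove each node in turn from an independent copy of the network
    and tabulate the resulting topology (removals never accumulate).

    One row per node: the secondary count plus the summary of the
    functional remainder.  Rows are directly comparable across networks.
    """
    if net.size == 0:
        raise ValueError("empty network")
    rows = []
    for node in sorted(net.nodes):
        res = remove_nodes(net, [node], include_paths=include_paths)
        s = res.after
        rows.append(
            {
                "node": node,
                "secondary_count": len(res.secondaries),
                "size": s.size,
                "edge_count": s.edge_count,
                "density": s.density,
                "avg_degree": s.avg_degree,
                "avg_path_length": s.avg_path_length,
                "n_components": s.n_components,
            }
        )
    return pd.DataFrame(rows)


def _metric_value(rec: CascadeRecord, metric: str) -> float:
    if metric in ("remaining_size", "size"):
        return rec.remaining_size
    if metric == "secondary_count":
        return rec.cumulative_secondaries
    if metric == "secondaries_this_step":
        return len(rec.secondaries_this_step)
    return getattr(rec.summary, metric)


def compare_curves(curves: list[CoextinctionCurve], metric: str) -> pd.DataFrame:
    """Align several co-extinction curves from the same original network.

    Long-format table with columns ``curve``, ``step``,
    ``pct_primaries_removed`` and ``value`` (the requested metric), for
    side-by-side plotting of extinction sequences.
    """
    if not curves:
        raise ValueError("no curves to compare")
    sizes = {c.original_size for c in curves}
    if len(sizes) > 1:
        raise ValueError(f"curves derive from different originals: sizes {sorted(sizes)}")
    rows = []
    for curve in curves:
        for rec in curve.records:
            rows.append(
                {
                    "curve": curve.label,
                    "step": rec.step,
                    "pct_primaries_removed": rec.pct_primaries_removed,
                    "value": _metric_value(rec, metric),
                }
            )
    return pd.DataFrame(rows)


def replicate_envelope(curves: list[CoextinctionCurve], metric: str) -> pd.DataFrame:
    """Per-step mean and min/max envelope across random replicates."""
    long = compare_curves(curves, metric)
    env = (
        long.groupby("step")["value"]
        .agg(mean="mean", min="min", max="max")
        .reset_index()
    )
    env["pct_primaries_removed"] = 100.0 * env["step"] / curves[0].original_size
    return env


_CSV_COLUMNS = [
    "step", "primary", "n_secondaries", "cumulative_secondaries",
    "remaining_size", "pct_removed", "density", "avg_degree",
    "avg_path_length", "n_components",
]


def curve_to_frame(curve: CoextinctionCurve) -> pd.DataFrame:
    """Fixed-column per-step table of one curve (documented CSV layout)."""
    rows = []
    for rec in curve.records:
        rows.append(
            {
                "step": rec.step,
                "primary": rec.primary,
                "n_secondaries": len(rec.secondaries_this_step),
                "cumulative_secondaries": rec.cumulative_secondaries,
                "remaining_size": rec.remaining_size,
                "pct_removed": rec.pct_primaries_removed,
                "density": rec.summary.density,
                "avg_degree": rec.summary.avg_degree,
                "avg_path_length": rec.summary.avg_path_length,
                "n_components": rec.summary.n_components,
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def curve_to_csv(curve: CoextinctionCurve) -> str:
    """Deterministic CSV text for one curve: identical (network, spec,
    seed) inputs give byte-identical output."""
    buf = io.StringIO()
    df = curve_to_frame(curve)
    df.to_csv(buf, index=False, float_format="%.10g", lineterminator="\n")
    return buf.getvalue()
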