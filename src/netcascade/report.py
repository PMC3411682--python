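"""CSV reporters, run manifests, and best-effort network rendering.

All scientific content lives in the CSV outputs, which have fixed column
orders and are byte-reproducible from the same inputs.  Images are
illustrative only: the force-directed (Fruchterman–Reingold) layout is
stochastic and explicitly excluded from reproducibility guarantees, but
node colour is determined solely by connected-component id.
"""

from __future__ import annotations

import json
import platform
import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

from .graph_io import Network
from .perturbation import PerturbationResult
from .topology import NetworkSummary, connected_components

__all__ = ["render_network", "summary_frame", "perturbation_frames",
           "write_manifest"]

# qualitative palette cycled over component ids; identical id => identical colour
_PALETTE = plt.get_cmap("tab20").colors


def render_network(
    net: Network, out_path, labels: bool = False, seed: int | None = None
) -> Path:
    """Draw the network with Fruchterman–Reingold layout, colouring each
    node by its connected component (largest component = colour 1).

    ``seed`` fixes the layout's starting positions; the image remains
    best-effort and is not guaranteed bit-identical across platforms.
    """
    if net.size == 0:
        raise ValueError("cannot render an empty network")
    out_path = Path(out_path)
    comp = connected_components(net)
    g = net.to_networkx()
    pos = nx.spring_layout(g, seed=seed)  # Fruchterman-Reingold
    order = sorted(net.nodes)
    colors = [_PALETTE[(comp[n] - 1) % len(_PALETTE)] for n in order]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx_edges(g, pos, ax=ax, alpha=0.4)
    nx.draw_networkx_nodes(g, pos, nodelist=order, node_color=colors,
                           node_size=120, ax=ax)
    if labels:
        nx.draw_networkx_labels(g, pos, ax=ax, font_size=7)
    ax.set_axis_off()
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
    return out_path


def summary_frame(summary: NetworkSummary) -> pd.DataFrame:
    """One-row DataFrame with the documented column order."""
    d = summary.as_dict()
    d["component_sizes"] = ";".join(map(str, d["component_sizes"]))
    cols = ["size", "edge_count", "density", "avg_degree", "avg_path_length",
            "n_components", "component_sizes", "diameter"]
    return pd.DataFrame([d], columns=cols)


def perturbation_frames(result: PerturbationResult) -> pd.DataFrame:
    """Before/after/delta summary table for a perturbation event."""
    before = summary_frame(result.before).iloc[0]
    after = summary_frame(result.after).iloc[0]
    rows = []
    for name in before.index:
        b, a = before[name], after[name]
        delta = a - b if name != "component_sizes" else ""
        rows.append({"indicator": name, "before": b, "after": a, "delta": delta})
    return pd.DataFrame(rows, columns=["indicator", "before", "after", "delta"])


def write_manifest(out_dir, command: str, options: dict) -> Path:
    """Machine-readable record of a run: inputs, options, seed, versions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = {
        "command": command,
        "options": {k: (str(v) if isinstance(v, Path) else v)
                    for k, v in options.items()},
        "versions": {
            "netcascade": __version__,
            "python": sys.version.split()[0],
            "networkx": nx.__version__,
            "platform": platform.platform(),
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
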