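"""Sociogram rendering and temporal comparison tables.

A sociogram draws the transfer network either at the hospitals' geographic
coordinates (longitude, latitude) or with a deterministic force-directed
layout. Node size is monotone in the chosen degree metric and designated
base (hub) hospitals are drawn in their own color — the conventional view in
which a regionalized hub-and-spoke system appears as local stars around the
hubs.

Every rendering also emits a JSON *manifest* (node/arc counts, the arcs
actually drawn, the layout positions) next to the image; quantitative checks
assert on the manifest, never on pixels, because rasterization differs
across backends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

from .metrics import NetworkMetrics
from .netbuild import TransferNetwork, extract_skeleton


@dataclass
class SociogramSpec:
    """Declarative description of one sociogram view."""

    layout: str = "geographic"  # or "force_directed"
    node_size_by: str = "in_degree"  # or "total_degree" / "constant"
    hub_color: str = "crimson"
    nonhub_color: str = "steelblue"
    min_weight: int = 1
    max_weight: int | None = None
    title: str = ""

    def __post_init__(self):
        if self.layout not in ("geographic", "force_directed"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.node_size_by not in ("in_degree", "total_degree", "constant"):
            raise ValueError(f"unknown node_size_by {self.node_size_by!r}")


def _positions(
    net: TransferNetwork, spec: SociogramSpec, seed: int
) -> dict[str, tuple[float, float]]:
    if spec.layout == "geographic":
        missing = [
            v for v, h in net.nodes.items()
            if h.longitude != h.longitude or h.latitude != h.latitude
        ]
        if missing:
            raise ValueError(
                f"geographic layout needs coordinates; missing for {missing[:5]}"
            )
        return {v: (h.longitude, h.latitude) for v, h in net.nodes.items()}
    import networkx as nx

    pos = nx.spring_layout(net.to_networkx(), seed=seed)
    return {v: (float(x), float(y)) for v, (x, y) in pos.items()}


def render_sociogram(
    net: TransferNetwork,
    spec: SociogramSpec,
    out_path: str | Path,
    seed: int = 0,
) -> dict:
    """Render a sociogram to ``out_path`` and return (and write) its manifest.

    Arcs outside [min_weight, max_weight] are filtered before drawing (the
    skeleton view); the manifest lists exactly the arcs drawn. The manifest
    is written alongside the image as ``<out_path>.manifest.json``.
    """
    out_path = Path(out_path)
    view = extract_skeleton(net, spec.min_weight, spec.max_weight)
    pos = _positions(view, spec, seed)

    in_deg = {v: 0 for v in view.nodes}
    out_deg = {v: 0 for v in view.nodes}
    for s, r in view.arcs:
        out_deg[s] += 1
        in_deg[r] += 1
    if spec.node_size_by == "in_degree":
        metric = in_deg
    elif spec.node_size_by == "total_degree":
        metric = {v: in_deg[v] + out_deg[v] for v in view.nodes}
    else:
        metric = {v: 1 for v in view.nodes}
    sizes = {v: 30.0 + 18.0 * metric[v] for v in view.nodes}

    fig = Figure(figsize=(8, 8))
    ax = fig.add_subplot(111)
    max_w = max(view.arcs.values(), default=1)
    for (s, r), w in sorted(view.arcs.items()):
        x0, y0 = pos[s]
        x1, y1 = pos[r]
        ax.annotate(
            "",
            xy=(x1, y1), xytext=(x0, y0),
            arrowprops=dict(
                arrowstyle="-|>", lw=0.4 + 1.6 * w / max_w,
                color="0.55", alpha=0.6, shrinkA=4, shrinkB=4,
            ),
        )
    order = sorted(view.nodes)
    xs = [pos[v][0] for v in order]
    ys = [pos[v][1] for v in order]
    colors = [
        spec.hub_color if view.nodes[v].is_base else spec.nonhub_color
        for v in order
    ]
    ax.scatter(xs, ys, s=[sizes[v] for v in order], c=colors, zorder=3,
               edgecolors="white", linewidths=0.5)
    ax.set_title(spec.title or view.period_label)
    ax.set_xlabel("longitude" if spec.layout == "geographic" else "")
    ax.set_ylabel("latitude" if spec.layout == "geographic" else "")
    fig.savefig(out_path, dpi=150)

    manifest = {
        "layout": spec.layout,
        "node_size_by": spec.node_size_by,
        "min_weight": spec.min_weight,
        "max_weight": spec.max_weight,
        "n_nodes_drawn": view.n_nodes,
        "n_arcs_drawn": view.n_arcs,
        "n_arcs_filtered": net.n_arcs - view.n_arcs,
        "arcs": [[s, r, int(w)] for (s, r), w in sorted(view.arcs.items())],
        "node_sizes": {v: sizes[v] for v in order},
        "positions": {v: [round(pos[v][0], 9), round(pos[v][1], 9)] for v in order},
        "hub_nodes": [v for v in order if view.nodes[v].is_base],
    }
    Path(str(out_path) + ".manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n"
    )
    return manifest


@dataclass
class TemporalReport:
    """Per-year network statistics with monotone-trend flags."""

    table: pd.DataFrame
    non_decreasing: dict[str, bool]
    strictly_increasing: dict[str, bool]


_TREND_COLUMNS = ("nodes", "ties", "density", "in_degree_centralization",
                  "reciprocity")


def temporal_report(yearly: Mapping[int, NetworkMetrics]) -> TemporalReport:
    """Tabulate yearly network statistics and flag monotone trends.

    One row per calendar year with node/tie counts, density, in-degree
    centralization and reciprocity; a column is flagged non-decreasing
    (resp. strictly increasing) when each year's value is >= (resp. >) the
    previous year's.
    """
    if len(yearly) < 2:
        raise ValueError("temporal report needs at least 2 years")
    rows = []
    for year in sorted(yearly):
        m = yearly[year]
        rows.append(
            {
                "year": year,
                "nodes": m.n_nodes,
                "ties": m.n_arcs,
                "density": m.density,
                "in_degree_centralization": m.in_degree_centralization,
                "reciprocity": m.reciprocity,
            }
        )
    table = pd.DataFrame(rows)
    non_dec, strict = {}, {}
    for col in _TREND_COLUMNS:
        diffs = np.diff(table[col].to_numpy(dtype=float))
        non_dec[col] = bool((diffs >= 0).all())
        strict[col] = bool((diffs > 0).all())
    return TemporalReport(table=table, non_decreasing=non_dec,
                          strictly_increasing=strict)
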