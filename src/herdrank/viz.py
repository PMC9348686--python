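"""Plots: category bar charts, dominance-value boxplots, sociograms.

Every plotting function returns the aggregates it drew (counts, quartiles,
edge list) alongside writing the image, so the numbers are testable without
inspecting pixels. Figures use the non-interactive matplotlib backend and
are written as PNG or SVG depending on the output suffix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .dominance import (
    HIERARCHY_LABELS,
    RANK_LABELS,
    DominanceTable,
    SocioMatrix,
)
from .errors import ParameterError, ValidationError


@dataclass(frozen=True)
class PlotSpec:
    """What to draw and where to put it.

    ``grouping`` picks the categorical variable for bar/box plots;
    ``direction`` is only meaningful for sociograms (``"reactor"``
    transposes the matrix so arrows show who each animal was displaced by).
    """

    kind: str = "bar"  # bar | box | sociogram
    grouping: str = "social_hierarchy"  # social_hierarchy | social_rank
    direction: str = "actor"  # actor | reactor (sociogram only)
    path: str | Path = "plot.png"

    def __post_init__(self) -> None:
        if self.kind not in ("bar", "box", "sociogram"):
            raise ParameterError(f"unknown plot kind {self.kind!r}")
        if self.grouping not in ("social_hierarchy", "social_rank"):
            raise ParameterError(f"unknown grouping {self.grouping!r}")
        if self.direction not in ("actor", "reactor"):
            raise ParameterError(f"unknown direction {self.direction!r}")


def _category_order(grouping: str) -> tuple[str, ...]:
    return HIERARCHY_LABELS if grouping == "social_hierarchy" else RANK_LABELS


def plot_dominance_bar(
    t: DominanceTable, spec: PlotSpec | None = None
) -> dict[str, int]:
    """Bar chart of animal counts per social category.

    Returns the plotted counts, keyed by category in ascending dominance
    order; categories with no animals are omitted.
    """
    spec = spec or PlotSpec(kind="bar")
    if len(t.df) == 0:
        raise ValidationError("cannot plot an empty dominance table")
    if spec.grouping not in t.df.columns:
        raise ValidationError(
            f"dominance table has no {spec.grouping!r} column; recompute "
            "with the matching flag")
    counts = t.df[spec.grouping].value_counts()
    ordered = {c: int(counts[c]) for c in _category_order(spec.grouping)
               if c in counts}
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(list(ordered), list(ordered.values()), color="steelblue")
    ax.set_xlabel(spec.grouping.replace("_", " "))
    ax.set_ylabel("number of animals")
    fig.tight_layout()
    fig.savefig(spec.path)
    plt.close(fig)
    return ordered


def plot_dominance_box(
    t: DominanceTable,
    values: str = "dominance_value",
    spec: PlotSpec | None = None,
) -> dict[str, dict[str, float]]:
    """Boxplot of a numeric variable per social category.

    Returns per-category summary statistics (min, q1, median, q3, max,
    mean) for the plotted variable.
    """
    spec = spec or PlotSpec(kind="box")
    if len(t.df) == 0:
        raise ValidationError("cannot plot an empty dominance table")
    if values not in t.df.columns:
        raise ValidationError(f"no column {values!r} in the dominance table")
    if spec.grouping not in t.df.columns:
        raise ValidationError(
            f"dominance table has no {spec.grouping!r} column")

    stats: dict[str, dict[str, float]] = {}
    groups: list[np.ndarray] = []
    names: list[str] = []
    for cat in _category_order(spec.grouping):
        vals = t.df.loc[t.df[spec.grouping] == cat, values].to_numpy(float)
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        stats[cat] = {
            "min": float(vals.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
        }
        groups.append(vals)
        names.append(cat)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(groups, tick_labels=names, showmeans=True)
    ax.set_xlabel(spec.grouping.replace("_", " "))
    ax.set_ylabel(values.replace("_", " "))
    fig.tight_layout()
    fig.savefig(spec.path)
    plt.close(fig)
    return stats


def plot_sociogram(
    m: SocioMatrix, spec: PlotSpec | None = None
) -> list[tuple[str, str, int]]:
    """Circular directed sociogram of the interaction counts.

    Nodes sit on a circle in canonical label order; an arrow i→j is drawn
    for every nonzero count, with width proportional to the count
    (normalised to the maximum). ``direction="reactor"`` transposes the
    matrix first, so arrows point from each animal to those that displaced
    it. Returns the drawn edges as (source, target, weight) triples.
    """
    spec = spec or PlotSpec(kind="sociogram")
    if m.n == 0:
        raise ValidationError("cannot plot an empty sociomatrix")
    X = m.values.T if spec.direction == "reactor" else m.values

    g = nx.DiGraph()
    g.add_nodes_from(m.labels)
    edges: list[tuple[str, str, int]] = []
    for i, a in enumerate(m.labels):
        for j, b in enumerate(m.labels):
            if X[i, j] > 0:
                g.add_edge(a, b, weight=int(X[i, j]))
                edges.append((a, b, int(X[i, j])))
    if not edges:
        import logging

        logging.getLogger("herdrank").warning(
            "all-zero sociomatrix: sociogram has no edges")

    pos = nx.circular_layout(g)
    max_w = max((w for _, _, w in edges), default=1)
    widths = [3.0 * w / max_w for _, _, w in edges]
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=450,
                           node_color="lightsteelblue")
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=7)
    if edges:
        nx.draw_networkx_edges(
            g, pos, ax=ax, edgelist=[(a, b) for a, b, _ in edges],
            width=widths, arrows=True, arrowsize=9,
            connectionstyle="arc3,rad=0.15", edge_color="gray")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(spec.path)
    plt.close(fig)
    return edges
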