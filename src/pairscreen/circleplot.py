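"""Circular bubble plot of screen results.

Heatmaps work poorly for interaction screens because hits are rare; the
circular bubble plot instead draws one radial axis per labeled
perturbation and places each pair's bubble on that axis, with

* distance from the center encoding significance (``-log10 p``, capped so
  the most significant hits sit on the circumference),
* bubble area encoding effect magnitude (``|log2`` relative magnitude``|``,
  so a 2-fold increase and a 2-fold decrease are equal-sized), and
* color encoding direction (reduced fitness red, increased fitness black
  by default).

Rendering is deterministic -- no jitter; overplotting is mitigated by
transparency.  The exact bubble geometry can be exported as a CSV so the
identity behind any point can be looked up in a machine-readable form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pairscreen.screen_io import ResultTable

__all__ = ["PlotSpec", "layout_circle", "render"]

_RADIUS_STATS = ("p_combined", "p_a", "p_b")
_SIZE_STATS = ("rel_mag_a", "rel_mag_b")


@dataclass(frozen=True)
class PlotSpec:
    """Visual encoding of a circular bubble plot.

    Attributes
    ----------
    radius_stat : str
        P-value column mapped to radius; a value of 1 sits at the center.
    radius_cap : float
        ``-log10 p`` at which bubbles reach the circumference (radius 1).
    size_stat : str
        Relative-magnitude column mapped to bubble size.
    size_range : tuple
        Bubble sizes in points at ``|log2 rel_mag| = 0`` and at
        ``size_log2_cap`` (linear in between, capped above).
    size_log2_cap : float
        ``|log2 rel_mag|`` at which bubbles reach maximum size.
    color_down, color_up : str
        Colors for relative magnitude below 1 (reduced fitness) and at or
        above 1 (increased fitness).
    label_axis : str
        Which perturbation set gets the radial axes and circumference
        labels ("A" or "B").
    axis_order : tuple or None
        Explicit ordering of the labeled perturbations; default sorted.
    """

    radius_stat: str = "p_combined"
    radius_cap: float = 10.0
    size_stat: str = "rel_mag_a"
    size_range: tuple[float, float] = (2.0, 14.0)
    size_log2_cap: float = 3.0
    color_down: str = "red"
    color_up: str = "black"
    label_axis: str = "B"
    axis_order: tuple[str, ...] | None = None
    alpha: float = 0.6

    def __post_init__(self) -> None:
        if self.radius_stat not in _RADIUS_STATS:
            raise ValueError(f"radius_stat must be one of {_RADIUS_STATS}")
        if self.size_stat not in _SIZE_STATS:
            raise ValueError(f"size_stat must be one of {_SIZE_STATS}")
        if self.radius_cap <= 0:
            raise ValueError("radius_cap must be positive")
        if not self.size_range[0] < self.size_range[1]:
            raise ValueError("size_range must be (min, max) with min < max")
        if self.label_axis not in ("A", "B"):
            raise ValueError("label_axis must be 'A' or 'B'")


def layout_circle(results: ResultTable, spec: PlotSpec | None = None) -> pd.DataFrame:
    """Compute bubble geometry: one row per plottable result row.

    Returns a frame with columns ``label`` (the axis perturbation),
    ``other`` (the second perturbation of the pair), ``angle`` (radians),
    ``radius`` in [0, 1], ``size`` (points), ``color``, ``x`` and ``y``.
    Rows with a missing radius statistic are skipped and counted in the
    frame's ``attrs["n_skipped"]``; an exact p of 0 is drawn on the
    circumference with a warning.
    """
    spec = spec or PlotSpec()
    df = results.data
    if len(df) == 0:
        raise ValueError("empty result table")
    label_col, other_col = (
        ("pertA", "pertB") if spec.label_axis == "A" else ("pertB", "pertA")
    )
    labels = (
        list(spec.axis_order)
        if spec.axis_order is not None
        else sorted(df[label_col].unique())
    )
    unknown = set(df[label_col]) - set(labels)
    if spec.axis_order is not None and unknown:
        raise ValueError(f"axis_order misses perturbations: {sorted(unknown)}")
    angle_of = {lbl: 2.0 * math.pi * k / len(labels) for k, lbl in enumerate(labels)}

    p = df[spec.radius_stat].to_numpy(dtype=float)
    keep = ~np.isnan(p)
    n_skipped = int((~keep).sum())
    if (p[keep] == 0).any():
        warnings.warn(
            f"{int((p[keep] == 0).sum())} p-values of exactly 0 drawn at radius 1",
            stacklevel=2,
        )
    sub = df[keep]
    pk = p[keep]
    with np.errstate(divide="ignore"):
        neglog = -np.log10(pk)
    radius = np.minimum(neglog, spec.radius_cap) / spec.radius_cap

    rel = sub[spec.size_stat].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2mag = np.abs(np.log2(rel))
    log2mag = np.where(np.isfinite(log2mag), log2mag, spec.size_log2_cap)
    smin, smax = spec.size_range
    size = smin + (smax - smin) * np.minimum(log2mag, spec.size_log2_cap) / spec.size_log2_cap
    color = np.where(rel < 1.0, spec.color_down, spec.color_up)

    angle = sub[label_col].map(angle_of).to_numpy(dtype=float)
    geom = pd.DataFrame(
        {
            "label": sub[label_col].to_numpy(),
            "other": sub[other_col].to_numpy(),
            "angle": angle,
            "radius": radius,
            "size": size,
            "color": color,
            "x": radius * np.cos(angle),
            "y": radius * np.sin(angle),
        }
    )
    geom.attrs["n_skipped"] = n_skipped
    geom.attrs["labels"] = labels
    geom.attrs["spec"] = spec
    return geom


def render(
    geometry: pd.DataFrame,
    path: str,
    spec: PlotSpec | None = None,
    format: str | None = None,
    geometry_csv: str | None = None,
) -> None:
    """Draw the bubble plot to a PNG (raster) or PDF (vector) file.

    ``format`` defaults to the extension of ``path``.  Output is
    deterministic for a fixed geometry.  ``geometry_csv`` optionally writes
    the bubble coordinates (including the second perturbation of each
    pair) next to the figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if len(geometry) == 0:
        raise ValueError("no bubbles to draw (all rows skipped)")
    spec = spec or geometry.attrs.get("spec") or PlotSpec()
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt not in ("png", "pdf"):
        raise ValueError("format must be 'png' or 'pdf'")
    labels = geometry.attrs.get("labels") or sorted(geometry["label"].unique())

    fig, ax = plt.subplots(figsize=(8, 8))
    ax.set_aspect("equal")
    ax.axis("off")
    circle = plt.Circle((0, 0), 1.0, fill=False, color="0.7", lw=1.0)
    ax.add_patch(circle)
    for lbl in labels:
        ang = 2.0 * math.pi * labels.index(lbl) / len(labels)
        ax.plot([0, math.cos(ang)], [0, math.sin(ang)], color="0.9", lw=0.5, zorder=0)
        ax.annotate(
            str(lbl),
            (1.06 * math.cos(ang), 1.06 * math.sin(ang)),
            ha="center",
            va="center",
            fontsize=7,
            rotation=math.degrees(ang) - 90 if 0 < ang < math.pi else 0,
        )
    ax.scatter(
        geometry["x"],
        geometry["y"],
        s=geometry["size"] ** 2,
        c=geometry["color"],
        alpha=spec.alpha,
        linewidths=0,
    )
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    fig.savefig(path, format=fmt, dpi=150)
    plt.close(fig)
    if geometry_csv is not None:
        geometry.to_csv(geometry_csv, index=False)
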