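"""Map products: winsorized diverging colour scales, point maps, histograms.

Values at target locations are coloured relative to the map mean: the top
and bottom 4% are pinned to the brightest ends of a diverging palette and
the remainder is binned into equal ranges between the two cuts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")  # headless, deterministic output
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .space_engine import SpaceResult  # noqa: E402

__all__ = [
    "ColorScale",
    "winsorized_color_values",
    "color_table",
    "render_map",
    "MAPPABLE_COMPONENTS",
]

MAPPABLE_COMPONENTS = (
    "a2_raw", "c2_or_d2_raw", "e2_raw",
    "a2_std", "c2_or_d2_std", "e2_std",
    "total_variance", "weighted_mean",
)

_COLUMN_FOR = {c: c for c in MAPPABLE_COMPONENTS} | {
    "weighted_mean": "weighted_mean_trait"}


@dataclass(frozen=True)
class ColorScale:
    """Winsorized diverging scale: white at the mean, +-1 at the 4% cuts."""

    center: float
    low_cut: float
    high_cut: float
    n_bins: int = 256


def winsorized_color_values(values: Sequence[float], q: float = 0.04,
                            n_bins: int = 256,
                            ) -> tuple[np.ndarray, np.ndarray, ColorScale]:
    """Assign each value a bin index and a colour coordinate in [-1, 1].

    The ceil(q*n) largest values map to +1 and the ceil(q*n) smallest to -1
    (ties broken by position via a stable sort); interior values map linearly
    into equal ranges between the cuts, centred on the mean of all values.
    Returns (bin indices, colour coordinates, scale).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if not 0.0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = v.size
    k = math.ceil(q * n)
    order = np.argsort(v, kind="stable")
    low_idx = order[:k]
    high_idx = order[n - k:]
    center = float(v.mean())
    low_cut = float(v[order[k - 1]])
    high_cut = float(v[order[n - k]])

    coords = np.zeros(n)
    if v.max() > v.min():  # degenerate (all-identical) vectors map to 0
        scale = max(high_cut - center, center - low_cut)
        if scale > 0:
            coords = np.clip((v - center) / scale, -1.0, 1.0)
        coords[low_idx] = -1.0
        coords[high_idx] = 1.0

    bins = np.minimum((np.floor((coords + 1.0) / 2.0 * n_bins)).astype(int),
                      n_bins - 1)
    return bins, coords, ColorScale(center, low_cut, high_cut, n_bins)


def color_table(space_result: SpaceResult | pd.DataFrame, component: str,
                q: float = 0.04, n_bins: int = 256) -> pd.DataFrame:
    """Per-target colour coordinates for a component, for external viewers."""
    table = _component_table(space_result, component)
    vals = table[_COLUMN_FOR[component]].to_numpy()
    bins, coords, _ = winsorized_color_values(vals, q=q, n_bins=n_bins)
    return pd.DataFrame({"target_id": table["target_id"].to_numpy(),
                         "value": vals, "color_coordinate": coords,
                         "bin": bins})


def _component_table(space_result: SpaceResult | pd.DataFrame,
                     component: str) -> pd.DataFrame:
    if component not in MAPPABLE_COMPONENTS:
        raise ValueError(
            f"unknown component {component!r}; valid names: "
            + ", ".join(MAPPABLE_COMPONENTS))
    table = (space_result.table if isinstance(space_result, SpaceResult)
             else space_result)
    # non-converged rows are excluded before computing the colour cuts
    table = table[table["converged"].astype(bool)].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("no converged rows to map")
    return table


def render_map(space_result: SpaceResult | pd.DataFrame, component: str,
               boundary_geometry=None, out_path: str | Path = "map",
               q: float = 0.04, n_bins: int = 256, hist_bins: int = 30,
               cmap: str = "RdBu_r", dpi: int = 150) -> tuple[Path, Path]:
    """Write a point map and a matching histogram for one component.

    ``boundary_geometry`` may be a shapely (multi)polygon or line drawn as an
    outline under the points.  Returns the two written paths
    (``<out>_map.png``, ``<out>_hist.png``); output is deterministic for
    identical inputs.
    """
    table = _component_table(space_result, component)
    col = _COLUMN_FOR[component]
    vals = table[col].to_numpy()
    bins, coords, scale = winsorized_color_values(vals, q=q, n_bins=n_bins)
    palette = plt.get_cmap(cmap)
    point_colors = palette((coords + 1.0) / 2.0)

    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    map_path = out.with_name(out.name + "_map.png")
    hist_path = out.with_name(out.name + "_hist.png")

    fig, ax = plt.subplots(figsize=(6, 7))
    if boundary_geometry is not None:
        _draw_boundary(ax, boundary_geometry)
    ax.scatter(table["x"], table["y"], c=point_colors, s=14,
               edgecolors="none")
    ax.set_aspect("equal")
    ax.set_title(component)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.savefig(map_path, dpi=dpi)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    counts, edges = np.histogram(vals, bins=hist_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # colour each bar the same way as points with that value
    _, bar_coords, _ = winsorized_color_values(
        np.concatenate([vals, centers]), q=q, n_bins=n_bins)
    bar_colors = palette((bar_coords[len(vals):] + 1.0) / 2.0)
    ax.bar(centers, counts, width=(edges[1] - edges[0]) * 0.95,
           color=bar_colors)
    ax.axvline(scale.center, color="k", lw=0.8)
    ax.set_xlabel(component)
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(hist_path, dpi=dpi)
    plt.close(fig)
    return map_path, hist_path


def _draw_boundary(ax, geometry) -> None:
    geoms = getattr(geometry, "geoms", [geometry])
    for g in geoms:
        exterior = getattr(g, "exterior", None)
        coords = (np.asarray(exterior.coords) if exterior is not None
                  else np.asarray(getattr(g, "coords", [])))
        if len(coords):
            ax.plot(coords[:, 0], coords[:, 1], color="0.6", lw=0.8)
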