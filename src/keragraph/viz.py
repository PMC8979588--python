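"""Property heat maps and histogram figures.

Exports are data-faithful matplotlib figures: vertex positions plotted in
projection, color-coded by a segment property (brightness, length,
curvature or azimuth), with a colorbar.  Deterministic colormap choice so
repeated runs produce identical figures.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .filament_metrics import CurvatureParams, mean_curvature
from .models import NetworkModel
from .orientation_stats import segment_orientation

__all__ = ["property_heatmap", "brightness_histogram_figure", "radial_polygon_figure"]

_PROPERTY_CMAPS = {
    "brightness": "inferno",
    "length": "viridis",
    "curvature": "plasma",
    "azimuth": "twilight",
}


def _segment_property(model: NetworkModel, prop: str) -> list[float | None]:
    if prop == "brightness":
        return [s.mean_intensity for s in model.segments]
    if prop == "length":
        return [s.arc_length for s in model.segments]
    if prop == "curvature":
        params = CurvatureParams()
        return [mean_curvature(s, params) for s in model.segments]
    if prop == "azimuth":
        vals = []
        for s in model.segments:
            try:
                vals.append(segment_orientation(s)[0])
            except ValueError:
                vals.append(None)
        return vals
    raise ValueError(f"unknown property {prop!r}")


def property_heatmap(
    model: NetworkModel,
    prop: str,
    path: str | Path,
    projection: str = "xy",
    z_slice: tuple[float, float] | None = None,
    point_size: float = 2.0,
) -> Path:
    """Plot vertices color-coded by a per-segment property.

    ``projection="xy"`` shows a maximum-style top view (all z pooled);
    pass ``z_slice=(z0, z1)`` in µm to restrict to a slab.  Raises if the
    property has no finite values (e.g. curvature on all-too-short
    segments).
    """
    values = _segment_property(model, prop)
    if all(v is None for v in values):
        raise ValueError(f"property {prop!r} has no values on this model")

    xs, ys, cs = [], [], []
    for s, v in zip(model.segments, values):
        if v is None:
            continue
        pts = s.positions
        if z_slice is not None:
            keep = (pts[:, 2] >= z_slice[0]) & (pts[:, 2] <= z_slice[1])
            pts = pts[keep]
        if projection == "xy":
            xs.append(pts[:, 0])
            ys.append(pts[:, 1])
        elif projection == "xz":
            xs.append(pts[:, 0])
            ys.append(pts[:, 2])
        else:
            raise ValueError(f"unknown projection {projection!r}")
        cs.append(np.full(len(pts), v))

    fig, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(
        np.concatenate(xs),
        np.concatenate(ys),
        c=np.concatenate(cs),
        s=point_size,
        cmap=_PROPERTY_CMAPS[prop],
        linewidths=0,
    )
    ax.set_aspect("equal")
    ax.set_xlabel("x [µm]")
    ax.set_ylabel("y [µm]" if projection == "xy" else "z [µm]")
    fig.colorbar(sc, ax=ax, label=prop)
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def brightness_histogram_figure(cell_metrics, path: str | Path) -> Path:
    """Bar plot of the segment brightness histogram (max normalized to 100)."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    edges = cell_metrics.brightness_bin_edges
    ax.bar(
        edges[:-1],
        cell_metrics.brightness_hist,
        width=np.diff(edges),
        align="edge",
        color="#444444",
    )
    ax.set_xlabel("relative segment brightness (max = 100)")
    ax.set_ylabel("frequency")
    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def radial_polygon_figure(radial_hist: np.ndarray, path: str | Path) -> Path:
    """Polar polygon plot of a radial orientation histogram."""
    n = len(radial_hist)
    theta = np.radians(np.arange(n) * 360.0 / n + 180.0 / n)
    theta = np.append(theta, theta[0])
    r = np.append(radial_hist, radial_hist[0])
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.plot(theta, r, color="tab:blue")
    ax.fill(theta, r, alpha=0.3, color="tab:blue")
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
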