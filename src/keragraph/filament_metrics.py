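"""Per-segment and per-cell geometry and brightness metrics.

Implements the quantities used to characterize keratin network
architecture: segment arc/chord length, bending ratio (chord/arc, 1 =
perfectly straight), discrete curvature |dT/ds| of the smoothed centre
line, an apparent persistence length from pooled tangent correlations,
filament density (length per unit cell volume), brightness histograms
normalized so the brightest segment maps to 100, and the brightness ~
curvature Pearson correlation.

The persistence length is "apparent": network segments are pinned at
nodes, so the fitted decay length of <cos theta(Δs)> = exp(-Δs/Lp)
(3D convention) reflects the embedded, constrained conformation rather
than a freely fluctuating filament.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .models import ImageStack, NetworkModel, Segment

log = logging.getLogger(__name__)

__all__ = [
    "CurvatureParams",
    "SegmentMetrics",
    "CellMetrics",
    "arc_length",
    "bending_ratio",
    "mean_curvature",
    "apparent_persistence_length",
    "segment_metrics_table",
    "cell_totals",
    "cell_volume",
    "thickness_curvature_correlation",
]


@dataclass
class CurvatureParams:
    """Discretization of the curvature estimator.

    resample_step
        Uniform arc-length resampling step in µm.  Default 0.044 µm, the
        finest lateral voxel spacing of the source acquisitions, so the
        estimator is stable at the sampling density the data provides.
    smooth_window
        Odd moving-average window (in resampled vertices) applied to the
        coordinates before differentiation; suppresses pixel-scale jitter.
    """

    resample_step: float = 0.044
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if self.resample_step <= 0:
            raise ValueError("resample_step must be > 0")
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 3")


@dataclass
class SegmentMetrics:
    segment_id: int
    arc_length: float  # µm
    chord_length: float  # µm
    bending_ratio: float  # chord/arc in (0, 1]
    mean_brightness: float  # a.u.
    mean_curvature: float | None  # µm⁻¹; None if too short to estimate
    azimuth: float | None  # degrees in [0, 180)
    elevation: float | None  # degrees in (-90, 90]


@dataclass
class CellMetrics:
    cell_id: str
    n_segments: int
    mean_segment_length: float  # µm
    total_length: float  # µm
    cell_volume: float | None  # µm³
    density: float | None  # µm filament per µm³
    apparent_persistence_length: float | None  # µm
    brightness_hist: np.ndarray  # normalized frequencies
    brightness_bin_edges: np.ndarray  # last edge exactly at 100
    thickness_curvature_pearson: float | None
    n_curvature_excluded: int = 0  # segments too short for curvature

    @property
    def total_length_mm(self) -> float:
        return self.total_length / 1000.0


# ---------------------------------------------------------------------------
# per-segment geometry


def _pts(segment) -> np.ndarray:
    return segment.positions if hasattr(segment, "positions") else np.asarray(segment)


def arc_length(segment) -> float:
    """Polyline length: sum of consecutive vertex distances, µm."""
    pts = _pts(segment)
    if len(pts) < 2:
        raise ValueError("need >= 2 vertices")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def bending_ratio(segment) -> float:
    """Chord length over arc length, in (0, 1]; 1 = straight, 0 = closed loop."""
    pts = _pts(segment)
    arc = arc_length(pts)
    if arc <= 0:
        raise ValueError("arc length must be > 0")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    return chord / arc


def _resample(pts: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length step (endpoints kept)."""
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = s[-1]
    n = max(int(np.floor(total / step)) + 1, 2)
    grid = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(grid, s, pts[:, k]) for k in range(3)])


def mean_curvature(segment, params: CurvatureParams | None = None) -> float | None:
    """Mean unsigned curvature |dT/ds| along the smoothed centre line, µm⁻¹.

    The polyline is resampled at a uniform arc-length step, coordinates
    are smoothed by a centred moving average, unit tangents are formed by
    central differences and curvature is the magnitude of the tangent
    derivative with respect to arc length, averaged over interior samples.
    Returns ``None`` when fewer than 4 resampled points are available
    (segment too short for the stencil); callers exclude and count these.
    """
    if params is None:
        params = CurvatureParams()
    pts = _pts(segment)
    res = _resample(pts, params.resample_step)
    if len(res) < 4:
        return None
    h = np.linalg.norm(res[1] - res[0])  # uniform by construction
    w = min(params.smooth_window, len(res) if len(res) % 2 == 1 else len(res) - 1)
    if w >= 3:
        sm = uniform_filter1d(res, size=w, axis=0, mode="nearest")
    else:
        sm = res
    tang = np.gradient(sm, h, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tang = tang / norms
    dT = np.gradient(tang, h, axis=0)
    kappa = np.linalg.norm(dT, axis=1)
    # interior only: edge stencils and smoothing edges bias the estimate
    margin = max(w // 2, 1)
    core = kappa[margin:-margin] if len(kappa) > 2 * margin else kappa[1:-1]
    if len(core) == 0:
        return None
    return float(core.mean())


# ---------------------------------------------------------------------------
# persistence length


def apparent_persistence_length(
    segments: Sequence[Segment],
    max_lag: float = 1.0,
    step: float | None = None,
) -> float:
    """Fit Lp from pooled tangent-tangent correlations, µm.

    Every segment is resampled at uniform *step* (default max_lag/20);
    tangent pairs separated by contour lag Δs <= max_lag are pooled across
    segments into per-lag bins, and ln<cos theta> = -Δs/Lp is fitted by
    least squares through the origin.  Effectively straight input (all
    correlations ~ 1) returns ``inf``.  If correlations turn non-positive
    inside the fit range, the fit uses the positive prefix and warns.
    """
    if step is None:
        step = max_lag / 20.0
    if step <= 0 or max_lag <= 0:
        raise ValueError("step and max_lag must be > 0")
    n_lags = int(round(max_lag / step))
    sums = np.zeros(n_lags + 1)
    counts = np.zeros(n_lags + 1, dtype=int)
    for seg in segments:
        pts = _resample(_pts(seg), step)
        if len(pts) < 3:
            continue
        tang = np.diff(pts, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        m = len(tang)
        for k in range(1, min(n_lags, m - 1) + 1):
            dots = np.einsum("ij,ij->i", tang[:-k], tang[k:])
            sums[k] += dots.sum()
            counts[k] += len(dots)
    valid = counts > 0
    valid[0] = False
    if not np.any(valid):
        raise ValueError("pooled contour length too short for max_lag")
    lags = np.arange(n_lags + 1)[valid] * step
    corr = sums[valid] / counts[valid]
    if np.any(corr <= 0):
        cut = int(np.argmax(corr <= 0))
        log.warning(
            "non-positive tangent correlation at lag %.3g µm; "
            "fitting positive prefix only", lags[cut],
        )
        lags, corr = lags[:cut], corr[:cut]
        if len(lags) == 0:
            raise ValueError("no positive correlations to fit")
    y = np.log(corr)
    slope = float((lags @ y) / (lags @ lags))
    if slope >= -1e-9:
        return float("inf")
    return -1.0 / slope


# ---------------------------------------------------------------------------
# per-cell aggregation


def segment_metrics_table(
    model: NetworkModel,
    curvature_params: CurvatureParams | None = None,
    length_weighted_brightness: bool = False,
) -> pd.DataFrame:
    """One row of :class:`SegmentMetrics` per segment, as a DataFrame.

    Mean segment brightness is the unweighted mean of vertex intensities
    by default; ``length_weighted_brightness`` weights each vertex by the
    polyline length it subtends instead.
    """
    from .orientation_stats import segment_orientation

    rows = []
    for s in model.segments:
        arc = s.arc_length
        chord = float(np.linalg.norm(s.chord))
        if length_weighted_brightness and len(s) > 1:
            edge = np.linalg.norm(np.diff(s.positions, axis=0), axis=1)
            w = np.zeros(len(s))
            w[:-1] += edge / 2
            w[1:] += edge / 2
            bright = float(np.average(s.intensities, weights=w))
        else:
            bright = s.mean_intensity
        try:
            az, el = segment_orientation(s)
        except ValueError:
            az = el = None
        rows.append(
            SegmentMetrics(
                segment_id=s.segment_id,
                arc_length=arc,
                chord_length=chord,
                bending_ratio=chord / arc if arc > 0 else 0.0,
                mean_brightness=bright,
                mean_curvature=mean_curvature(s, curvature_params),
                azimuth=az,
                elevation=el,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def cell_totals(
    model: NetworkModel,
    volume: float | None = None,
    curvature_params: CurvatureParams | None = None,
    n_brightness_bins: int = 50,
    persistence_max_lag: float | None = 1.0,
) -> CellMetrics:
    """Aggregate per-cell metrics from a network model.

    Brightness histogram bins span [0, 100] after rescaling so the
    brightest segment's mean brightness equals 100; frequencies sum to 1.
    Density (filament length per µm³) requires *volume*.  Curvature-
    excluded (too short) segments are counted, not silently dropped.
    """
    if not model.segments:
        raise ValueError("empty model")
    table = segment_metrics_table(model, curvature_params)
    lengths = table["arc_length"].to_numpy()
    total = float(lengths.sum())

    bright = table["mean_brightness"].to_numpy()
    bmax = bright.max()
    scaled = bright / bmax * 100.0 if bmax > 0 else bright
    edges = np.linspace(0.0, 100.0, n_brightness_bins + 1)
    hist, _ = np.histogram(scaled, bins=edges)
    hist = hist / hist.sum()

    curv = table["mean_curvature"]
    n_excluded = int(curv.isna().sum())
    pearson = thickness_curvature_correlation_from_table(table)

    lp = None
    if persistence_max_lag is not None:
        try:
            lp = apparent_persistence_length(model.segments, persistence_max_lag)
        except ValueError:
            log.warning("persistence length not estimable for %s", model.cell_id)

    return CellMetrics(
        cell_id=model.cell_id,
        n_segments=len(model.segments),
        mean_segment_length=total / len(model.segments),
        total_length=total,
        cell_volume=volume,
        density=None if volume is None else total / volume,
        apparent_persistence_length=lp,
        brightness_hist=hist,
        brightness_bin_edges=edges,
        thickness_curvature_pearson=pearson,
        n_curvature_excluded=n_excluded,
    )


def cell_volume(
    stack: ImageStack,
    method: str = "otsu",
    level: float | None = None,
) -> float:
    """Cell volume in µm³ from an intensity threshold on the stack.

    ``method="fixed"`` counts voxels >= *level*; ``method="otsu"`` picks
    the threshold separating the intracellular background fluorescence
    from the dark exterior (Otsu's criterion) and ignores *level*.
    """
    vox = stack.voxels
    if not np.any(vox > 0):
        log.warning("all-zero stack; volume = 0")
        return 0.0
    if method == "fixed":
        if level is None:
            raise ValueError("fixed threshold requires level")
        thr = level
    elif method == "otsu":
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(vox)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(np.count_nonzero(vox >= thr)) * stack.voxel_volume


def thickness_curvature_correlation(metrics: Sequence[SegmentMetrics]) -> float:
    """Pearson r between mean segment brightness and mean curvature."""
    table = pd.DataFrame([m.__dict__ for m in metrics])
    r = thickness_curvature_correlation_from_table(table)
    if r is None:
        raise ValueError("need >= 3 segments with curvature estimates")
    return r


def thickness_curvature_correlation_from_table(table: pd.DataFrame) -> float | None:
    ok = table.dropna(subset=["mean_curvature"])
    if len(ok) < 3:
        return None
    b = ok["mean_brightness"].to_numpy(dtype=float)
    c = ok["mean_curvature"].to_numpy(dtype=float)
    if np.std(b) == 0 or np.std(c) == 0:
        return None
    return float(stats.pearsonr(b, c).statistic)
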