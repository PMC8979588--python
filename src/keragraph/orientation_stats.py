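"""Directional statistics of network segments.

Two complementary analyses:

* **Fold-invariant angle histograms.**  Segment endpoints are
  interchangeable, so a segment and its reverse are the same orientation;
  chord directions are canonicalized to azimuth in [0°, 180°) (elevation
  sign flips with the vector).  Azimuth/elevation histograms are compared
  with a uniform reference by the total absolute per-bin deviation
  D = Σ_b |f_b − e_b|, which is 0 for a perfect match and approaches 2 for
  a single-bin degenerate distribution.

* **Center-translocated radial analysis.**  Each segment chord is moved
  to the cell center with its center-proximal endpoint at the origin, so
  all vectors point outward.  Their angular distribution gives radial
  polygon histograms (xy and yz projections), and their length-weighted
  vector sum gives the network sum vector; |sum| / total length is an
  anisotropy index in [0, 1] (0 = isotropic, 1 = perfectly parallel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .models import NetworkModel, Segment

log = logging.getLogger(__name__)

__all__ = [
    "OrientationSummary",
    "segment_orientation",
    "uniformity_deviation",
    "cell_center",
    "translocate_outward",
    "radial_histograms",
    "sum_vector",
    "orientation_summary",
]

N_ANGLE_BINS = 180  # 1° bins for azimuth/elevation
N_RADIAL_BINS = 36  # 10° bins for radial polygons


@dataclass
class OrientationSummary:
    azimuth_hist: np.ndarray  # N_ANGLE_BINS bins over [0°, 180°), sums to 1
    elevation_hist: np.ndarray  # N_ANGLE_BINS bins over (-90°, 90°], sums to 1
    azimuth_deviation: float  # D vs flat reference
    elevation_deviation: float  # D vs flat reference
    elevation_deviation_solid_angle: float  # D vs cos-weighted reference
    radial_hist_xy: np.ndarray  # N_RADIAL_BINS summed projected magnitudes
    radial_hist_yz: np.ndarray
    sum_vector: np.ndarray  # (3,) µm
    anisotropy_index: float  # |sum| / Σ arc length, in [0, 1]
    cell_center: np.ndarray  # (3,) µm


def segment_orientation(segment: Segment | np.ndarray) -> tuple[float, float]:
    """Azimuth and elevation (degrees) of the segment chord.

    Azimuth is measured in the xy-plane from +x; elevation from the
    horizontal plane.  The chord is flipped if necessary so azimuth lies
    in [0°, 180°); the elevation sign follows the flip.  A purely vertical
    chord reports azimuth 0° and elevation 90°.
    """
    if hasattr(segment, "chord"):
        v = segment.chord
    else:
        v = np.asarray(segment, dtype=float)
    if np.linalg.norm(v) == 0:
        raise ValueError("zero chord has no orientation")
    x, y, z = v
    if y < 0 or (y == 0 and x < 0) or (x == 0 and y == 0 and z < 0):
        x, y, z = -x, -y, -z
    az = float(np.degrees(np.arctan2(y, x))) % 360.0
    if az >= 180.0:  # only az == 180.0 - fp edge of atan2(0, -x)
        az -= 180.0
        z = -z
    el = float(np.degrees(np.arctan2(z, np.hypot(x, y))))
    return az, el


def _fold_angles(model: NetworkModel) -> tuple[np.ndarray, np.ndarray]:
    az, el = [], []
    for s in model.segments:
        try:
            a, e = segment_orientation(s)
        except ValueError:
            continue
        az.append(a)
        el.append(e)
    return np.asarray(az), np.asarray(el)


def uniformity_deviation(
    hist: np.ndarray,
    expected: str = "flat",
) -> float:
    """Total absolute deviation of a normalized histogram from a reference.

    D = Σ_b |f_b − e_b|.  ``expected="flat"`` uses e_b = 1/nbins;
    ``"solid_angle"`` uses e_b ∝ cos(bin center) over (−90°, 90°], the
    reference for elevations of isotropically oriented 3D segments (a
    uniform 3D orientation field is *not* flat in elevation).
    Ranges over [0, 2·(1 − 1/nbins)].
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if not np.isclose(total, 1.0):
        log.warning("histogram not normalized (sum=%g); normalizing", total)
        hist = hist / total
    n = len(hist)
    if expected == "flat":
        ref = np.full(n, 1.0 / n)
    elif expected == "solid_angle":
        centers = np.linspace(-90.0, 90.0, n, endpoint=False) + 90.0 / n
        ref = np.cos(np.radians(centers))
        ref /= ref.sum()
    else:
        raise ValueError(f"unknown expected reference {expected!r}")
    return float(np.abs(hist - ref).sum())


def cell_center(model: NetworkModel) -> np.ndarray:
    """Mean of the mean vertex positions of all segments, µm."""
    if not model.segments:
        raise ValueError("empty model")
    means = np.array([s.positions.mean(axis=0) for s in model.segments])
    return means.mean(axis=0)


def translocate_outward(
    model: NetworkModel,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Origin-anchored outward chord vectors, one per segment, (n, 3) µm.

    Each segment chord is re-anchored at the cell center with its
    center-proximal endpoint at the origin: vector = far endpoint − near
    endpoint.  Equidistant endpoints keep the original vertex order
    (logged).
    """
    if center is None:
        center = cell_center(model)
    vectors = []
    n_ties = 0
    for s in model.segments:
        a, b = s.positions[0], s.positions[-1]
        da, db = np.linalg.norm(a - center), np.linalg.norm(b - center)
        if da < db:
            vectors.append(b - a)
        elif db < da:
            vectors.append(a - b)
        else:
            n_ties += 1
            vectors.append(b - a)
    if n_ties:
        log.info("%d segment(s) with equidistant endpoints kept original order", n_ties)
    return np.asarray(vectors)


def radial_histograms(
    vectors: np.ndarray,
    n_bins: int = N_RADIAL_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial polygon histograms of outward vectors in xy and yz.

    Vectors are binned by the angle of their planar projection into
    ``n_bins`` bins over [0°, 360°); each bin accumulates the projected
    vector magnitudes, so total weight equals the summed projected
    magnitudes and longer segments contribute proportionally more.
    """
    vectors = np.asarray(vectors, dtype=float)

    def polygon(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        mag = np.hypot(u, v)
        ang = np.degrees(np.arctan2(v, u)) % 360.0
        idx = np.minimum((ang / (360.0 / n_bins)).astype(int), n_bins - 1)
        out = np.zeros(n_bins)
        np.add.at(out, idx[mag > 0], mag[mag > 0])
        return out

    xy = polygon(vectors[:, 0], vectors[:, 1])
    yz = polygon(vectors[:, 1], vectors[:, 2])
    return xy, yz


def sum_vector(
    model: NetworkModel,
    center: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Length-weighted vector sum of outward segment directions.

    Each segment contributes its outward unit chord direction scaled by
    its arc length.  Returns the sum vector (µm) and the anisotropy index
    |sum| / Σ arc lengths ∈ [0, 1].
    """
    vectors = translocate_outward(model, center)
    lengths = np.array([s.arc_length for s in model.segments])
    norms = np.linalg.norm(vectors, axis=1)
    ok = norms > 0
    units = np.zeros_like(vectors)
    units[ok] = vectors[ok] / norms[ok, None]
    total = float(lengths.sum())
    vec = (units * lengths[:, None]).sum(axis=0)
    anis = float(np.linalg.norm(vec) / total) if total > 0 else 0.0
    return vec, anis


def orientation_summary(model: NetworkModel) -> OrientationSummary:
    """Run both directional analyses on a model."""
    az, el = _fold_angles(model)
    if len(az) == 0:
        raise ValueError("no oriented segments")
    az_hist, _ = np.histogram(az, bins=N_ANGLE_BINS, range=(0.0, 180.0))
    el_hist, _ = np.histogram(el, bins=N_ANGLE_BINS, range=(-90.0, 90.0))
    az_hist = az_hist / az_hist.sum()
    el_hist = el_hist / el_hist.sum()

    center = cell_center(model)
    vectors = translocate_outward(model, center)
    xy, yz = radial_histograms(vectors)
    vec, anis = sum_vector(model, center)

    return OrientationSummary(
        azimuth_hist=az_hist,
        elevation_hist=el_hist,
        azimuth_deviation=uniformity_deviation(az_hist, "flat"),
        elevation_deviation=uniformity_deviation(el_hist, "flat"),
        elevation_deviation_solid_angle=uniformity_deviation(el_hist, "solid_angle"),
        radial_hist_xy=xy,
        radial_hist_yz=yz,
        sum_vector=vec,
        anisotropy_index=anis,
        cell_center=center,
    )
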