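import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from keragraph.filament_metrics import (
    CurvatureParams,
    SegmentMetrics,
    apparent_persistence_length,
    arc_length,
    bending_ratio,
    cell_totals,
    cell_volume,
    mean_curvature,
    thickness_curvature_correlation,
)
from keragraph.models import GraphParams, ImageStack
from keragraph.network_graph import build_network
from keragraph.synthetic_data import wlc_chain

from conftest import straight_snake


def arc(radius, span, n, pitch=0.0):
    t = np.linspace(0.0, span, n)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), pitch * t])


# --- arc length & bending ---


def test_arc_length_two_points():
    assert arc_length(np.array([[0.0, 0, 0], [1, 0, 0]])) == pytest.approx(1.0)


def test_arc_length_quarter_circle():
    pts = arc(1.0, np.pi / 2, 100)
    assert arc_length(pts) == pytest.approx(np.pi / 2, rel=1e-3)


def test_arc_length_matches_pairwise_sum_oracle():
    rng = np.random.default_rng(3)
    pts = np.cumsum(rng.normal(0, 0.2, (30, 3)), axis=0)
    oracle = sum(
        float(np.sqrt(((pts[i + 1] - pts[i]) ** 2).sum())) for i in range(len(pts) - 1)
    )
    assert arc_length(pts) == pytest.approx(oracle, rel=1e-12)


def test_bending_straight_is_one():
    assert bending_ratio(np.array([[0.0, 0, 0], [0.5, 0, 0], [1, 0, 0]])) == 1.0


def test_bending_semicircle():
    assert bending_ratio(arc(1.0, np.pi, 400)) == pytest.approx(2 / np.pi, rel=5e-3)


def test_bending_closed_loop_is_zero():
    pts = arc(1.0, 2 * np.pi, 100)
    pts[-1] = pts[0]
    assert bending_ratio(pts) == pytest.approx(0.0, abs=1e-12)


def test_bending_invariant_under_isometry():
    rng = np.random.default_rng(11)
    pts = np.cumsum(rng.normal(0, 0.2, (20, 3)), axis=0)
    base = bending_ratio(pts)
    for seed in range(5):
        rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        moved = pts @ rot.T + rng.uniform(-5, 5, 3)
        assert bending_ratio(moved) == pytest.approx(base, rel=1e-9)


# --- curvature ---


def test_curvature_straight_line_zero():
    pts = np.column_stack([np.linspace(0, 5, 200), np.zeros(200), np.zeros(200)])
    assert mean_curvature(pts) < 1e-9


def test_curvature_circle():
    pts = arc(2.0, np.pi, 400)
    assert mean_curvature(pts) == pytest.approx(0.5, rel=0.05)


def test_curvature_helix():
    # helix radius r, pitch parameter c: kappa = r / (r² + c²)
    r, c = 1.0, 0.5
    t = np.linspace(0, 6 * np.pi, 2000)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t), c * t])
    assert mean_curvature(pts) == pytest.approx(r / (r**2 + c**2), rel=0.05)


def test_curvature_scales_inversely_with_size():
    pts = arc(2.0, np.pi, 400)
    k1 = mean_curvature(pts)
    k2 = mean_curvature(pts * 3.0, CurvatureParams(resample_step=0.044 * 3))
    assert k2 == pytest.approx(k1 / 3.0, rel=0.02)


def test_curvature_isometry_invariant():
    pts = arc(1.5, 2.0, 300)
    base = mean_curvature(pts)
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    assert mean_curvature(pts @ rot.T + np.array([3, -2, 7])) == pytest.approx(
        base, rel=1e-6
    )


def test_curvature_too_short_returns_none():
    assert mean_curvature(np.array([[0.0, 0, 0], [0.01, 0, 0]])) is None


# --- persistence length ---


def test_persistence_length_recovery():
    rng = np.random.default_rng(17)
    lp = 2.6
    chains = [
        wlc_chain(rng, np.zeros(3), np.array([1.0, 0, 0]), 400, lp / 20, lp)
        for _ in range(40)
    ]
    fit = apparent_persistence_length(chains, max_lag=2 * lp, step=lp / 20)
    assert fit == pytest.approx(lp, rel=0.2)


def test_persistence_straight_is_infinite():
    segs = [np.column_stack([np.linspace(0, 5, 100), np.zeros(100), np.zeros(100)])]
    assert apparent_persistence_length(segs, max_lag=1.0) == np.inf


def test_persistence_stable_under_max_lag_halving():
    rng = np.random.default_rng(23)
    lp = 2.0
    chains = [
        wlc_chain(rng, np.zeros(3), np.array([0, 0, 1.0]), 500, 0.1, lp)
        for _ in range(40)
    ]
    full = apparent_persistence_length(chains, max_lag=2.0, step=0.1)
    half = apparent_persistence_length(chains, max_lag=1.0, step=0.1)
    assert abs(half - full) / full < 0.1


# --- per-cell totals ---


def test_cell_totals_basic(params):
    snakes = [
        straight_snake((0, 10 * i, 0), (1, 0, 0), L, 5, brightness=50.0 * (i + 1), sid=i)
        for i, L in enumerate([1.0, 2.0, 3.0])
    ]
    model = build_network(snakes, params)
    m = cell_totals(model, volume=2.0, persistence_max_lag=None)
    assert m.n_segments == 3
    assert m.total_length == pytest.approx(6.0)
    assert m.mean_segment_length == pytest.approx(2.0)
    assert m.density == pytest.approx(3.0)
    assert m.brightness_hist.sum() == pytest.approx(1.0)
    assert m.brightness_bin_edges[-1] == 100.0
    # brightest segment mean brightness rescaled exactly to 100
    assert m.brightness_hist[-1] > 0


def test_cell_volume_fixed_threshold():
    vox = np.zeros((10, 10, 10))
    vox[:5] = 2.0
    st = ImageStack(vox, (0.1, 0.1, 0.1))
    assert cell_volume(st, "fixed", level=1.0) == pytest.approx(0.5)


def test_cell_volume_full_cube():
    st = ImageStack(np.full((4, 4, 4), 9.0), (0.5, 0.5, 0.5))
    assert cell_volume(st, "fixed", level=1.0) == pytest.approx(4**3 * 0.125)


def test_cell_volume_otsu_bimodal():
    rng = np.random.default_rng(4)
    vox = rng.normal(10, 1, (20, 20, 20))
    fg = np.zeros_like(vox, dtype=bool)
    fg[:, :10, :] = True  # planted foreground: half the voxels
    vox[fg] += 100
    st = ImageStack(np.clip(vox, 0, None), (0.1, 0.1, 0.1))
    planted = fg.sum() * st.voxel_volume
    assert cell_volume(st, "otsu") == pytest.approx(planted, rel=0.05)


def test_cell_volume_all_zero_warns(caplog):
    st = ImageStack(np.zeros((4, 4, 4)), (0.1, 0.1, 0.1))
    with caplog.at_level("WARNING"):
        assert cell_volume(st, "otsu") == 0.0


# --- thickness/curvature correlation ---


def metrics_row(i, bright, curv):
    return SegmentMetrics(
        segment_id=i, arc_length=1.0, chord_length=1.0, bending_ratio=1.0,
        mean_brightness=bright, mean_curvature=curv, azimuth=0.0, elevation=0.0,
    )


def test_correlation_identical_pairs_is_one():
    rows = [metrics_row(i, v, v) for i, v in enumerate([1.0, 2.0, 5.0, 9.0])]
    assert thickness_curvature_correlation(rows) == pytest.approx(1.0)


def test_correlation_antimonotone_negative():
    rows = [metrics_row(i, v, 10 - v) for i, v in enumerate([1.0, 2.0, 5.0, 9.0])]
    assert thickness_curvature_correlation(rows) < 0


def test_correlation_independent_draws_small():
    rng = np.random.default_rng(8)
    rows = [
        metrics_row(i, rng.uniform(1, 100), rng.uniform(0.1, 5)) for i in range(1000)
    ]
    assert abs(thickness_curvature_correlation(rows)) < 0.1


def test_correlation_needs_three_segments():
    with pytest.raises(ValueError):
        thickness_curvature_correlation([metrics_row(0, 1, 1), metrics_row(1, 2, 2)])
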