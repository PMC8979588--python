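import numpy as np
import pytest

from keragraph.models import GraphParams, Snake
from keragraph.network_graph import build_network
from keragraph.orientation_stats import (
    N_ANGLE_BINS,
    cell_center,
    orientation_summary,
    radial_histograms,
    segment_orientation,
    sum_vector,
    translocate_outward,
    uniformity_deviation,
)

from conftest import straight_snake


def two_point_model(chords, origin_step=5.0):
    """One isolated two-vertex snake per chord, spaced apart on a line."""
    snakes = []
    for i, c in enumerate(chords):
        start = np.array([0.0, 0.0, 0.0]) + np.array([origin_step * i, 0, 0])
        snakes.append(
            Snake(i, np.vstack([start, start + np.asarray(c, dtype=float)]),
                  np.array([1.0, 1.0]))
        )
    return build_network(snakes, GraphParams(epsilon=0.01))


# --- folded orientation ---


@pytest.mark.parametrize(
    "chord, want_az, want_el",
    [
        ((1, 0, 0), 0.0, 0.0),
        ((0, -1, 0), 90.0, 0.0),  # folded: endpoints are interchangeable
        ((0, 0, 1), 0.0, 90.0),
        ((-1, 0, 0), 0.0, 0.0),
        ((1, 1, 0), 45.0, 0.0),
        ((1, 0, 1), 0.0, 45.0),
        ((-1, 0, 1), 0.0, -45.0),  # flip to +x inverts elevation sign
    ],
)
def test_segment_orientation_canonical(chord, want_az, want_el):
    az, el = segment_orientation(np.asarray(chord, dtype=float))
    assert az == pytest.approx(want_az, abs=1e-9)
    assert el == pytest.approx(want_el, abs=1e-9)
    assert 0.0 <= az < 180.0


def test_orientation_zero_chord_rejected():
    with pytest.raises(ValueError):
        segment_orientation(np.zeros(3))


def test_fold_invariance_of_all_outputs():
    """Reversing any segment's vertex order changes no directional output."""
    rng = np.random.default_rng(6)
    chords = rng.normal(size=(40, 3))
    model = two_point_model(chords)
    flipped_model = two_point_model(chords)
    for s in flipped_model.segments[::2]:  # flip half the segments
        s.positions = s.positions[::-1].copy()
        s.intensities = s.intensities[::-1].copy()
    a = orientation_summary(model)
    b = orientation_summary(flipped_model)
    np.testing.assert_allclose(a.azimuth_hist, b.azimuth_hist)
    np.testing.assert_allclose(a.elevation_hist, b.elevation_hist)
    np.testing.assert_allclose(a.sum_vector, b.sum_vector, atol=1e-9)
    assert a.anisotropy_index == pytest.approx(b.anisotropy_index)


def test_rotation_about_z_shifts_azimuth_circularly():
    rng = np.random.default_rng(12)
    chords = rng.normal(size=(200, 3))
    shift_deg = 40
    ang = np.radians(shift_deg)
    rot = np.array(
        [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
    )
    a = orientation_summary(two_point_model(chords))
    b = orientation_summary(two_point_model(chords @ rot.T))
    np.testing.assert_allclose(
        np.roll(a.azimuth_hist, shift_deg), b.azimuth_hist, atol=1e-12
    )


# --- uniformity deviation ---


def test_deviation_flat_is_zero():
    assert uniformity_deviation(np.full(180, 1 / 180), "flat") == pytest.approx(0.0)


def test_deviation_one_bin_degenerate():
    h = np.zeros(180)
    h[0] = 1.0
    assert uniformity_deviation(h, "flat") == pytest.approx(2 - 2 / 180)


def test_deviation_isotropic_azimuth_small():
    rng = np.random.default_rng(99)
    dirs = rng.normal(size=(10_000, 3))
    az = np.array([segment_orientation(d)[0] for d in dirs])
    hist, _ = np.histogram(az, bins=N_ANGLE_BINS, range=(0, 180))
    assert uniformity_deviation(hist / hist.sum(), "flat") < 0.15


def test_deviation_solid_angle_reference_for_isotropic_elevation():
    # elevations of isotropic 3D directions follow cos(el), not a flat law
    rng = np.random.default_rng(100)
    dirs = rng.normal(size=(20_000, 3))
    el = np.array([segment_orientation(d)[1] for d in dirs])
    hist, _ = np.histogram(el, bins=N_ANGLE_BINS, range=(-90, 90))
    hist = hist / hist.sum()
    assert uniformity_deviation(hist, "solid_angle") < 0.15
    assert uniformity_deviation(hist, "flat") > 0.3


def test_deviation_normalizes_with_warning(caplog):
    with caplog.at_level("WARNING"):
        d = uniformity_deviation(np.full(10, 2.0), "flat")
    assert d == pytest.approx(0.0)
    assert "normaliz" in caplog.text


# --- cell center / translocation ---


def test_cell_center_two_level_mean_oracle(params):
    rng = np.random.default_rng(21)
    snakes = [
        Snake(i, np.cumsum(rng.normal(0, 0.5, (5, 3)), axis=0) + rng.uniform(0, 9, 3),
              np.ones(5))
        for i in range(6)
    ]
    model = build_network(snakes, GraphParams(epsilon=1e-6))
    oracle = np.mean([s.positions.mean(axis=0) for s in model.segments], axis=0)
    np.testing.assert_allclose(cell_center(model), oracle, atol=1e-12)


def test_translocate_outward_and_inward():
    # one radially-outward and one radially-inward segment around a center
    out_seg = Snake(0, np.array([[2.0, 0, 0], [3.0, 0, 0]]), np.ones(2))
    in_seg = Snake(1, np.array([[-3.0, 0, 0], [-2.0, 0, 0]]), np.ones(2))
    model = build_network([out_seg, in_seg], GraphParams(epsilon=0.01))
    vecs = translocate_outward(model, center=np.zeros(3))
    # both must point away from the center
    for v, s in zip(vecs, model.segments):
        far = max(
            [s.positions[0], s.positions[-1]], key=lambda p: np.linalg.norm(p)
        )
        assert np.dot(v, far) > 0


def test_translocate_tie_keeps_original(caplog):
    seg = Snake(0, np.array([[-1.0, 0, 0], [1.0, 0, 0]]), np.ones(2))
    model = build_network([seg], GraphParams(epsilon=0.01))
    with caplog.at_level("INFO"):
        vecs = translocate_outward(model, center=np.zeros(3))
    np.testing.assert_allclose(vecs[0], [2.0, 0, 0])


# --- radial histograms & sum vector ---


def test_radial_histogram_single_direction():
    vecs = np.tile([1.0, 0, 0], (7, 1))
    xy, yz = radial_histograms(vecs)
    assert np.count_nonzero(xy) == 1
    assert xy[0] == pytest.approx(7.0)  # bin [0°, 10°)
    assert np.count_nonzero(yz) == 0  # zero-magnitude yz projections dropped


def test_radial_histogram_conserves_projected_weight():
    rng = np.random.default_rng(31)
    vecs = rng.normal(size=(500, 3))
    xy, yz = radial_histograms(vecs)
    assert xy.sum() == pytest.approx(np.hypot(vecs[:, 0], vecs[:, 1]).sum())
    assert yz.sum() == pytest.approx(np.hypot(vecs[:, 1], vecs[:, 2]).sum())


def test_radial_histogram_isotropic_balanced():
    rng = np.random.default_rng(41)
    vecs = rng.normal(size=(10_000, 3))
    xy, _ = radial_histograms(vecs)
    assert xy.max() / xy.min() < 2.0


def test_sum_vector_opposite_segments_cancel():
    a = Snake(0, np.array([[1.0, 0, 0], [2.0, 0, 0]]), np.ones(2))
    b = Snake(1, np.array([[-1.0, 0, 0], [-2.0, 0, 0]]), np.ones(2))
    model = build_network([a, b], GraphParams(epsilon=0.01))
    vec, anis = sum_vector(model, center=np.zeros(3))
    np.testing.assert_allclose(vec, 0, atol=1e-9)
    assert anis == pytest.approx(0.0, abs=1e-9)


def test_sum_vector_parallel_network_fully_anisotropic():
    snakes = [
        straight_snake((0, 0.5 * i, 0), (1, 0, 0), 3.0, 5, sid=i) for i in range(10)
    ]
    model = build_network(snakes, GraphParams(epsilon=0.01))
    _, anis = sum_vector(model)
    assert anis == pytest.approx(1.0, abs=1e-9)


def test_sum_vector_isotropic_small():
    rng = np.random.default_rng(55)
    # random orientations anchored on a coarse grid, positions symmetric
    snakes = []
    i = 0
    for gx in range(10):
        for gy in range(10):
            for gz in range(10):
                pos = np.array([gx, gy, gz], dtype=float) * 3.0
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                snakes.append(
                    Snake(i, np.vstack([pos, pos + d]), np.ones(2))
                )
                i += 1
    model = build_network(snakes, GraphParams(epsilon=0.01))
    _, anis = sum_vector(model)
    assert anis < 0.05


def test_sum_vector_rotates_with_network():
    rng = np.random.default_rng(61)
    snakes = [
        Snake(i, np.cumsum(rng.normal(0, 0.5, (4, 3)), axis=0) + rng.uniform(0, 9, 3),
              np.ones(4))
        for i in range(20)
    ]
    ang = 0.7
    rot = np.array(
        [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
    )
    rotated = [Snake(s.snake_id, s.positions @ rot.T, s.intensities) for s in snakes]
    gp = GraphParams(epsilon=1e-6)
    v0, anis0 = sum_vector(build_network(snakes, gp))
    v1, anis1 = sum_vector(build_network(rotated, gp))
    np.testing.assert_allclose(v1, rot @ v0, atol=1e-9)
    assert anis1 == pytest.approx(anis0, rel=1e-9)
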