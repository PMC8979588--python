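"""Ground-truth synthetic filament networks, snake files and image stacks.

Keratin filaments are emulated as discrete worm-like chains (WLC): at each
polyline step of length ``h`` the tangent is deflected by a Gaussian polar
angle (uniform azimuth around the previous tangent) whose variance is
``2h/Lp``.  For a Gaussian polar angle beta, E[cos beta] = exp(-var/2), so
this choice makes the tangent correlation decay exactly as
<cos theta(Δs)> = exp(-Δs/Lp) — the same 3D convention the persistence-
length estimator fits, which is what makes parameter recovery a
meaningful closure test.

Branches are planted by breaking a parent chain at an interior vertex and
starting a new chain within ``junction_jitter`` of the break point; the
emitted snakes break at planted junctions, so the graph builder must
re-associate them by epsilon-clustering.  Keeping ``junction_jitter``
below epsilon/2 while filaments are separated by more than 2·epsilon
guarantees planted junctions — and only planted junctions — cluster.

Voxelization rasterizes segment polylines into an anisotropic voxel grid
with a Gaussian cross-section (the PSF), amplitude proportional to
segment brightness, then adds Gaussian (and optionally Poisson) noise.
Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .models import GraphParams, ImageStack, NetworkModel, Node, Segment, Snake
from .snake_io import write_snakes

__all__ = ["SynthParams", "generate_network", "wlc_chain", "voxelize", "fixture_suite"]


@dataclass
class SynthParams:
    """Study-condition parameters of the generator.

    Defaults emulate the source acquisitions: airyscan-scale anisotropic
    voxels (0.065/0.065 µm laterally, 0.18 µm axially), segment-scale
    persistence length 2.6 µm, filament lengths of a few µm and a
    log-normal brightness spread.
    """

    box: tuple[float, float, float] = (10.0, 10.0, 4.0)  # µm (x, y, z)
    n_filaments: int = 20
    filament_length: float = 4.0  # µm contour length per filament
    step: float = 0.1  # µm polyline step
    persistence_length: float = 2.6  # µm
    branch_probability: float = 0.5  # per-filament chance of one Y-junction
    brightness_mu: float = 4.0  # log-normal log-mean, a.u.
    brightness_sigma: float = 0.5  # log-normal log-sd
    junction_jitter: float = 0.03  # µm, must stay < epsilon/2
    voxel_spacing: tuple[float, float, float] = (0.18, 0.065, 0.065)  # µm (z, y, x)
    psf_sigma: tuple[float, float, float] = (0.25, 0.1, 0.1)  # µm (z, y, x)
    noise_sigma: float = 0.0  # additive Gaussian sd, a.u.
    poisson_noise: bool = False
    placement: str = "grid"  # "grid" guarantees > 2·epsilon separation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("filament_length", "step", "persistence_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.step > min(self.box):
            raise ValueError("box too small for polyline step")
        if self.junction_jitter < 0:
            raise ValueError("junction_jitter must be >= 0")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def wlc_chain(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    n_steps: int,
    step: float,
    lp: float,
) -> np.ndarray:
    """Sample a discrete worm-like chain of ``n_steps`` segments.

    Tangent update: rotate by a Gaussian polar angle with variance
    ``2*step/lp`` about a uniformly random perpendicular axis, giving the
    exact exponential tangent-correlation decay with decay length ``lp``.
    """
    pts = np.empty((n_steps + 1, 3))
    pts[0] = start
    t = np.asarray(direction, dtype=float)
    t = t / np.linalg.norm(t)
    sigma = np.sqrt(2.0 * step / lp)
    for i in range(n_steps):
        pts[i + 1] = pts[i] + step * t
        beta = rng.normal(0.0, sigma)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        # orthonormal frame around t
        ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        n1 = np.cross(t, ref)
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(t, n1)
        axis = np.cos(phi) * n1 + np.sin(phi) * n2
        t = np.cos(beta) * t + np.sin(beta) * axis
        t /= np.linalg.norm(t)
    return pts


@dataclass
class GroundTruth:
    """Planted quantities the analysis pipeline should recover."""

    n_nodes: int
    n_junctions: int  # degree-3 planted branch points
    n_segments: int
    segment_lengths: np.ndarray  # µm, per emitted snake piece
    segment_brightness: np.ndarray  # a.u.
    total_length: float  # µm
    params: SynthParams


def generate_network(
    params: SynthParams,
) -> tuple[NetworkModel, list[Snake], GroundTruth]:
    """Generate a planted filament network.

    Returns the ground-truth network model, the snakes a segmentation
    tool would have emitted (broken at planted junctions), and the
    planted-quantity record.  Byte-reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n_par_steps = max(int(round(params.filament_length / params.step)), 2)
    branch_len = params.filament_length / 2.0
    n_br_steps = max(int(round(branch_len / params.step)), 2)

    if params.placement == "grid":
        # one filament (plus branch) per grid cell; reach bound is the
        # contour length, so this guarantees inter-filament separation
        reach = params.filament_length + branch_len
        cell = 2.0 * reach + 1.0
        n_side = int(np.ceil(np.sqrt(params.n_filaments)))
        centers = [
            np.array([(i + 0.5) * cell, (j + 0.5) * cell, reach])
            for i in range(n_side)
            for j in range(n_side)
        ][: params.n_filaments]
    elif params.placement == "random":
        box = np.asarray(params.box)
        centers = [rng.uniform(0.1, 0.9, size=3) * box for _ in range(params.n_filaments)]
    else:
        raise ValueError(f"unknown placement {params.placement!r}")

    snakes: list[Snake] = []
    nodes: list[Node] = []
    segments: list[Segment] = []
    seg_lengths: list[float] = []
    seg_bright: list[float] = []
    n_junctions = 0
    sid = 0

    def add_piece(pts: np.ndarray, bright: float, node_a: int, node_b: int):
        nonlocal sid
        ints = np.full(len(pts), bright)
        snakes.append(Snake(snake_id=sid, positions=pts.copy(), intensities=ints.copy()))
        segments.append(
            Segment(
                segment_id=len(segments),
                positions=pts.copy(),
                intensities=ints,
                end_nodes=(node_a, node_b),
                source=(sid, (0, len(pts) - 1)),
            )
        )
        seg_lengths.append(float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()))
        seg_bright.append(bright)
        sid += 1

    def add_node(pos: np.ndarray, members, degree: int) -> int:
        nodes.append(
            Node(node_id=len(nodes), position=pos.copy(), members=members, degree=degree)
        )
        return len(nodes) - 1

    # spurious (unplanted) contacts between the emitted snake pieces would
    # make graph recovery ambiguous; the planted junction is the only
    # cross-snake proximity allowed, so branched filaments are resampled
    # until every other cross-piece vertex pair clears the clustering
    # radius with margin
    eps_ref = 1.1 * max(params.voxel_spacing[1:])

    def pieces_are_clean(pieces: list[np.ndarray], intended: set) -> bool:
        for ia in range(len(pieces)):
            for ib in range(ia + 1, len(pieces)):
                d = np.linalg.norm(
                    pieces[ia][:, None, :] - pieces[ib][None, :, :], axis=2
                )
                for (pa, va), (pb, vb) in [(x, y) for x in intended for y in intended]:
                    if pa == ia and pb == ib:
                        d[va, vb] = np.inf
                if d.min() <= 1.2 * eps_ref:
                    return False
        return True

    for center in centers:
        bright = lambda: float(
            rng.lognormal(params.brightness_mu, params.brightness_sigma)
        )
        if rng.uniform() >= params.branch_probability:
            chain = wlc_chain(
                rng, center, _random_unit(rng), n_par_steps, params.step,
                params.persistence_length,
            )
            a = add_node(chain[0], [(sid, 0)], 1)
            b = add_node(chain[-1], [(sid, len(chain) - 1)], 1)
            add_piece(chain, bright(), a, b)
        else:
            for _attempt in range(100):
                chain = wlc_chain(
                    rng, center, _random_unit(rng), n_par_steps, params.step,
                    params.persistence_length,
                )
                k = int(rng.integers(n_par_steps // 3, 2 * n_par_steps // 3 + 1))
                jpos = chain[k]
                jitter = _random_unit(rng) * rng.uniform(0, params.junction_jitter)
                # branch leaves roughly sideways so its first steps cannot
                # fall back onto the parent
                tangent = chain[k + 1] - chain[k - 1]
                tangent /= np.linalg.norm(tangent)
                while True:
                    bdir = _random_unit(rng)
                    if abs(bdir @ tangent) < 0.5:  # > 60° from the parent axis
                        break
                bchain = wlc_chain(
                    rng, jpos + jitter, bdir, n_br_steps, params.step,
                    params.persistence_length,
                )
                pieces = [chain[: k + 1], chain[k:], bchain]
                intended = {(0, k), (1, 0), (2, 0)}
                if pieces_are_clean(pieces, intended):
                    break
            a = add_node(chain[0], [(sid, 0)], 1)
            j = add_node(jpos, [(sid, k)], 3)
            b = add_node(chain[-1], [(sid + 1, len(chain) - 1 - k)], 1)
            c = add_node(bchain[-1], [(sid + 2, len(bchain) - 1)], 1)
            add_piece(chain[: k + 1], bright(), a, j)
            add_piece(chain[k:], bright(), j, b)
            add_piece(bchain, bright(), j, c)
            n_junctions += 1

    model = NetworkModel(
        cell_id=f"synthetic-seed{params.seed}",
        nodes=nodes,
        segments=segments,
        params=GraphParams(reference_voxel=max(params.voxel_spacing[1:])),
        spacing=np.asarray(params.voxel_spacing),
    )
    truth = GroundTruth(
        n_nodes=len(nodes),
        n_junctions=n_junctions,
        n_segments=len(segments),
        segment_lengths=np.asarray(seg_lengths),
        segment_brightness=np.asarray(seg_bright),
        total_length=float(np.sum(seg_lengths)),
        params=params,
    )
    return model, snakes, truth


def voxelize(model: NetworkModel, params: SynthParams) -> ImageStack:
    """Rasterize a network into a noisy anisotropic fluorescence stack.

    Polylines are sampled at sub-voxel resolution and deposited as
    intensity mass (brightness × path length) into the nearest voxel,
    then blurred with the Gaussian PSF; noise is added last and the
    result clipped at zero.
    """
    spacing = np.asarray(params.voxel_spacing, dtype=float)  # (z, y, x)
    all_pos = model.all_positions()
    if len(all_pos):
        hi = all_pos.max(axis=0)  # (x, y, z) µm
        extent = np.array([hi[2], hi[1], hi[0]]) + 4 * np.asarray(params.psf_sigma)
    else:
        extent = np.array([params.box[2], params.box[1], params.box[0]])
    shape = tuple(np.maximum(np.ceil(extent / spacing).astype(int) + 1, 4))
    vol = np.zeros(shape)

    ds = min(spacing) / 2.0
    for seg in model.segments:
        pts = seg.positions
        edge = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        total = edge.sum()
        if total == 0:
            continue
        n_samples = max(int(np.ceil(total / ds)), 2)
        s = np.concatenate([[0.0], np.cumsum(edge)])
        grid = np.linspace(0.0, total, n_samples)
        sample = np.column_stack(
            [np.interp(grid, s, pts[:, k]) for k in range(3)]
        )  # (n, 3) x,y,z µm
        amp = seg.mean_intensity * total / n_samples
        iz = np.clip(np.round(sample[:, 2] / spacing[0]).astype(int), 0, shape[0] - 1)
        iy = np.clip(np.round(sample[:, 1] / spacing[1]).astype(int), 0, shape[1] - 1)
        ix = np.clip(np.round(sample[:, 0] / spacing[2]).astype(int), 0, shape[2] - 1)
        np.add.at(vol, (iz, iy, ix), amp)

    sigma_vox = np.asarray(params.psf_sigma) / spacing
    vol = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="constant")

    rng = np.random.default_rng(params.seed + 1)
    if params.poisson_noise:
        vol = rng.poisson(np.clip(vol, 0, None)).astype(float)
    if params.noise_sigma > 0:
        vol = vol + rng.normal(0.0, params.noise_sigma, size=vol.shape)
    return ImageStack(voxels=np.clip(vol, 0.0, None), spacing=spacing)


# ---------------------------------------------------------------------------
# deterministic named fixtures


def _straight(start, direction, length, n, brightness, sid):
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    pts = np.asarray(start) + np.outer(np.linspace(0, length, n), direction)
    return Snake(snake_id=sid, positions=pts, intensities=np.full(n, brightness))


def fixture_suite(outdir: str | Path, scale: str = "tiny") -> dict[str, dict]:
    """Write the deterministic fixture set; returns metadata per fixture.

    Fixtures: ``isolated`` filament, ``y_junction``, ``x_crossing``,
    ``star`` (degree-5 node), ``parallel`` bundle array (keratinocyte-like
    anisotropy) and ``isotropic`` shell (simple-epithelium-like isotropy).
    Each is written as a snake file plus a ground-truth JSON.  ``scale``
    controls the size of the statistical fixtures (``tiny`` or ``desk``).
    """
    if scale not in ("tiny", "desk"):
        raise ValueError("scale must be 'tiny' or 'desk'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_iso = 1000 if scale == "tiny" else 4000
    n_par = 50 if scale == "tiny" else 200
    rng = np.random.default_rng(1234)

    fixtures: dict[str, dict] = {}

    def emit(name: str, snakes: list[Snake], truth: dict):
        snake_path = outdir / f"{name}.snakes.txt"
        truth_path = outdir / f"{name}.truth.json"
        write_snakes(snakes, snake_path, dialect="tsoax")
        truth_path.write_text(json.dumps(truth, indent=1))
        fixtures[name] = {"snakes": snake_path, "truth": truth_path, **truth}

    # isolated filament: one snake, two loose ends
    emit(
        "isolated",
        [_straight((0, 0, 0), (1, 0.2, 0.1), 3.0, 30, 100.0, 0)],
        {"n_nodes": 2, "degree_histogram": {}, "n_segments": 1},
    )

    # Y-junction: a branch snake ends at an interior vertex of a through snake
    through = _straight((0, 0, 0), (1, 0, 0), 2.0, 21, 100.0, 0)
    branch = _straight((1.0, 0.005, 0), (0.5, 1, 0), 1.0, 11, 80.0, 1)
    emit(
        "y_junction",
        [through, branch],
        {"n_nodes": 4, "degree_histogram": {"3": 1.0}, "n_segments": 3},
    )

    # X-crossing: two snakes crossing at interior vertices
    emit(
        "x_crossing",
        [
            _straight((0, 0, 0), (1, 0, 0), 2.0, 21, 100.0, 0),
            _straight((1.0, -1.0, 0.005), (0, 1, 0), 2.0, 21, 90.0, 1),
        ],
        {"n_nodes": 5, "degree_histogram": {"4": 1.0}, "n_segments": 4},
    )

    # star: a through snake plus three snakes ending at its midpoint (degree 5)
    # branch directions mutually > 45° apart so only the hub vertex clusters
    star_snakes = [_straight((0, 0, 0), (1, 0, 0), 2.0, 21, 100.0, 0)]
    for i, d in enumerate([(0, 1, 0), (0.5, -1, 0), (-0.5, -1, 0.3)]):
        d = np.asarray(d, dtype=float)
        d /= np.linalg.norm(d)
        start = np.array([1.0, 0, 0]) + d * 0.01
        star_snakes.append(_straight(start, d, 1.0, 11, 70.0 + 5 * i, i + 1))
    emit(
        "star",
        star_snakes,
        {"n_nodes": 6, "degree_histogram": {"5": 1.0}, "n_segments": 5},
    )

    # parallel bundle array: HaCaT-like anisotropy, all chords along +x
    par = [
        _straight((0, 0.2 * i, 0.05 * (i % 5)), (1, 0, 0), 4.0, 21, 60.0 + i, i)
        for i in range(n_par)
    ]
    emit(
        "parallel",
        par,
        {"n_nodes": 2 * n_par, "n_segments": n_par, "anisotropy": "high"},
    )

    # isotropic set: short segments with uniformly random orientations,
    # anchored on a coarse 3D grid so no two snakes ever cluster
    iso = []
    n_side = int(np.ceil(n_iso ** (1 / 3)))
    pitch = 2.0  # µm between anchors; far above any epsilon in use
    i = 0
    for gx in range(n_side):
        for gy in range(n_side):
            for gz in range(n_side):
                if i >= n_iso:
                    break
                pos = np.array([gx, gy, gz], dtype=float) * pitch
                d = _random_unit(rng)
                iso.append(
                    Snake(
                        snake_id=i,
                        positions=np.vstack([pos, pos + d * 0.5]),
                        intensities=np.array([50.0, 50.0]),
                    )
                )
                i += 1
    emit(
        "isotropic",
        iso,
        {"n_nodes": 2 * n_iso, "n_segments": n_iso, "anisotropy": "low"},
    )

    return fixtures
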