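"""Core in-memory containers for snakes, image stacks and network models.

Conventions used throughout the package:

* All geometry lives in micrometres, right-handed axes, ``z`` along the
  optical axis.  Point arrays are ``(n, 3)`` with columns ``x, y, z``.
* Voxel arrays are indexed ``(z, y, x)``, zero-based, with a matching
  ``spacing`` triple in micrometres per voxel.
* Fluorescence intensity ("brightness") is in arbitrary units and is used
  as a proxy for filament bundle thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Vertex",
    "Snake",
    "ImageStack",
    "GraphParams",
    "Node",
    "Segment",
    "NetworkModel",
]


class Vertex(NamedTuple):
    """A single sampled point of a filament: 3D position plus brightness."""

    position: np.ndarray  # shape (3,), µm, (x, y, z)
    intensity: float  # a.u., >= 0


def _as_points(positions) -> np.ndarray:
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"positions must be (n, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("positions contain non-finite values")
    return pts


def _as_intensities(intensities, n: int) -> np.ndarray:
    ints = np.asarray(intensities, dtype=float)
    if ints.shape != (n,):
        raise ValueError(f"intensities must have shape ({n},), got {ints.shape}")
    if not np.all(np.isfinite(ints)) or np.any(ints < 0):
        raise ValueError("intensities must be finite and non-negative")
    return ints


@dataclass
class Snake:
    """An ordered open polygonal chain (active contour) tracing one filament.

    Snakes are the raw unit of SOAC-family segmentation output: a polyline
    of >= 2 vertices, each carrying a position and a fluorescence intensity.
    Vertex order is meaningful and preserved from the source file.
    """

    snake_id: int
    positions: np.ndarray  # (n, 3) µm
    intensities: np.ndarray  # (n,) a.u.

    def __post_init__(self) -> None:
        self.positions = _as_points(self.positions)
        n = len(self.positions)
        if n < 2:
            raise ValueError(f"snake {self.snake_id}: needs >= 2 vertices, got {n}")
        self.intensities = _as_intensities(self.intensities, n)
        steps = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError(
                f"snake {self.snake_id}: consecutive vertices must be distinct"
            )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def vertices(self) -> Iterator[Vertex]:
        for p, i in zip(self.positions, self.intensities):
            yield Vertex(p, float(i))


@dataclass
class ImageStack:
    """A 3D fluorescence stack: non-negative voxels plus voxel spacing.

    ``voxels`` is (z, y, x); ``spacing`` is µm/voxel in the same (z, y, x)
    order.  Airyscan-type acquisitions are anisotropic (z spacing several
    times the lateral spacing), which every consumer of this class honors.
    """

    voxels: np.ndarray
    spacing: np.ndarray  # (3,) µm/voxel, (z, y, x)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array (z, y, x)")
        if np.any(self.voxels < 0):
            raise ValueError("voxel intensities must be non-negative")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive values (z, y, x)")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.spacing))


@dataclass
class GraphParams:
    """Parameters of the node/segment graph construction.

    epsilon
        Clustering radius in µm.  Vertices of *different* snakes closer
        than epsilon are merged into one node.  Defaults to
        1.1 x reference_voxel, the convention used for airyscan stacks.
    reference_voxel
        Voxel size (µm) epsilon is derived from; by convention the larger
        lateral (xy) spacing of the acquisition.
    """

    epsilon: float | None = None
    reference_voxel: float = 0.065

    def __post_init__(self) -> None:
        if self.epsilon is None:
            self.epsilon = 1.1 * self.reference_voxel
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class Node:
    """A junction or filament end point of the network.

    A node is either the merged cluster of near-coincident vertices from
    different snakes (a junction) or a single snake terminus (a loose end).
    ``degree`` counts incident segment endpoints; 1 = loose end, 2 = a
    through-connection within a filament, 3 = Y-branch, 4 = X-crossing,
    >= 5 = star.
    """

    node_id: int
    position: np.ndarray  # (3,) µm, centroid of member vertices
    members: list[tuple[int, int]]  # (snake_id, vertex_index)
    degree: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.members:
            raise ValueError("node needs at least one member vertex")


@dataclass
class Segment:
    """A node-bounded piece of a snake — the network's edge.

    Unlike an abstract graph edge a segment keeps the full polyline
    trajectory and per-vertex brightness between its two end nodes.
    """

    segment_id: int
    positions: np.ndarray  # (m, 3) µm; first/last coincide with end nodes
    intensities: np.ndarray  # (m,) a.u.
    end_nodes: tuple[int, int]
    source: tuple[int, tuple[int, int]]  # (snake_id, (first_idx, last_idx))

    def __post_init__(self) -> None:
        self.positions = _as_points(self.positions)
        m = len(self.positions)
        if m < 2:
            raise ValueError("segment needs >= 2 vertices")
        self.intensities = _as_intensities(self.intensities, m)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def arc_length(self) -> float:
        return float(
            np.linalg.norm(np.diff(self.positions, axis=0), axis=1).sum()
        )

    @property
    def chord(self) -> np.ndarray:
        return self.positions[-1] - self.positions[0]

    @property
    def mean_intensity(self) -> float:
        return float(self.intensities.mean())

    @property
    def vertices(self) -> Iterator[Vertex]:
        for p, i in zip(self.positions, self.intensities):
            yield Vertex(p, float(i))


@dataclass
class NetworkModel:
    """The Euclidean 3D network map of one cell: nodes plus segments."""

    cell_id: str
    nodes: list[Node]
    segments: list[Segment]
    params: GraphParams = field(default_factory=GraphParams)
    spacing: np.ndarray | None = None  # (3,) µm (z, y, x) if known

    def __post_init__(self) -> None:
        if self.spacing is not None:
            self.spacing = np.asarray(self.spacing, dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def total_length(self) -> float:
        """Total arc length of all segments, µm."""
        return float(sum(s.arc_length for s in self.segments))

    def node_by_id(self, node_id: int) -> Node:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def all_positions(self) -> np.ndarray:
        """All segment vertex positions stacked into one (n, 3) array."""
        if not self.segments:
            return np.empty((0, 3))
        return np.vstack([s.positions for s in self.segments])

    def all_intensities(self) -> np.ndarray:
        if not self.segments:
            return np.empty((0,))
        return np.concatenate([s.intensities for s in self.segments])


def snakes_from_segments(segments: Sequence[Segment]) -> list[Snake]:
    """Reinterpret segments as snakes (used for graph idempotence checks)."""
    return [
        Snake(snake_id=i, positions=s.positions.copy(), intensities=s.intensities.copy())
        for i, s in enumerate(segments)
    ]
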