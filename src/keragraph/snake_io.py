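"""File I/O: snake files, TIFF stacks, network models, OBJ geometry.

Two snake dialects are supported.  The ``tsoax`` dialect is the plain-text
layout written by SOAC-family segmentation tools: comment/header lines
starting with ``#`` or ``$`` (ignored), then whitespace-separated rows

    snake_id  point_index  x  y  z  intensity

with snakes contiguous and ``point_index`` ascending within a snake.  An
optional trailing junction section introduced by a line starting with
``[`` is parsed and logged but otherwise ignored — node association is
recomputed by :mod:`keragraph.network_graph` rather than trusted from the
segmentation tool.  The ``polyline_table`` dialect is a delimited table
with a header naming at least ``snake_id, x, y, z, intensity`` columns.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

from .models import GraphParams, NetworkModel, Node, Segment, Snake

log = logging.getLogger(__name__)

Dialect = Literal["tsoax", "polyline_table"]


class SnakeParseError(ValueError):
    """Raised when a snake file cannot be parsed; names the offending line."""


# ---------------------------------------------------------------------------
# snakes


def read_snakes(
    path: str | Path,
    dialect: Dialect = "tsoax",
    scale: float = 1.0,
) -> list[Snake]:
    """Read snakes from *path*.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tsoax"`` (6-column rows, see module docstring) or
        ``"polyline_table"`` (delimited table with a header).
    scale
        Multiplied into all coordinates at read time; set it to the voxel
        size to convert voxel-unit files to µm.  Intensities are untouched.
    """
    path = Path(path)
    if dialect == "tsoax":
        return _read_tsoax(path, scale)
    if dialect == "polyline_table":
        return _read_table(path, scale)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsoax(path: Path, scale: float) -> list[Snake]:
    groups: list[tuple[int, list[list[float]]]] = []
    seen: set[int] = set()
    current_id: int | None = None
    n_junction_lines = 0
    in_junctions = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("["):
                in_junctions = True
                continue
            if in_junctions:
                n_junction_lines += 1
                continue
            if line.startswith("#") or line.startswith("$"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise SnakeParseError(
                    f"{path}:{lineno}: expected 6 columns "
                    f"(snake_id point_index x y z intensity), got {len(fields)}"
                )
            try:
                sid = int(float(fields[0]))
                vals = [float(f) for f in fields[2:6]]
            except ValueError as exc:
                raise SnakeParseError(f"{path}:{lineno}: non-numeric field: {exc}")
            if current_id is None or sid != current_id:
                if sid in seen:
                    raise SnakeParseError(
                        f"{path}:{lineno}: snake_id {sid} is interleaved; "
                        "snakes must be contiguous blocks"
                    )
                seen.add(sid)
                current_id = sid
                groups.append((sid, []))
            groups[-1][1].append(vals)

    if n_junction_lines:
        log.info(
            "%s: ignored %d junction record(s); nodes are recomputed",
            path,
            n_junction_lines,
        )
    return _groups_to_snakes(groups, scale, str(path))


def _read_table(path: Path, scale: float) -> list[Snake]:
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SnakeParseError(f"{path}: cannot parse table: {exc}")
    required = {"snake_id", "x", "y", "z", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise SnakeParseError(f"{path}: missing columns {sorted(missing)}")
    for col in required:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            lineno = int(bad[0]) + 2 if len(bad) else "?"
            raise SnakeParseError(f"{path}:{lineno}: non-numeric value in {col!r}")

    groups: list[tuple[int, list[list[float]]]] = []
    seen: set[int] = set()
    current_id: int | None = None
    for row_idx, row in enumerate(df.itertuples(index=False)):
        sid = int(row.snake_id)
        if current_id is None or sid != current_id:
            if sid in seen:
                raise SnakeParseError(
                    f"{path}:{row_idx + 2}: snake_id {sid} is interleaved"
                )
            seen.add(sid)
            current_id = sid
            groups.append((sid, []))
        groups[-1][1].append([row.x, row.y, row.z, row.intensity])
    return _groups_to_snakes(groups, scale, str(path))


def _groups_to_snakes(groups, scale: float, origin: str) -> list[Snake]:
    snakes = []
    for sid, rows in groups:
        arr = np.asarray(rows, dtype=float)
        if len(arr) < 2:
            raise SnakeParseError(
                f"{origin}: snake {sid} has {len(arr)} vertex; need >= 2"
            )
        snakes.append(
            Snake(snake_id=sid, positions=arr[:, :3] * scale, intensities=arr[:, 3])
        )
    return snakes


def write_snakes(
    snakes: Sequence[Snake],
    path: str | Path,
    dialect: Dialect = "tsoax",
) -> None:
    """Write snakes to *path* such that :func:`read_snakes` inverts it."""
    path = Path(path)
    for s in snakes:
        if not np.all(np.isfinite(s.positions)):
            raise ValueError(f"snake {s.snake_id}: non-finite coordinate")
    if dialect == "tsoax":
        with open(path, "w") as fh:
            fh.write("# snake_id point_index x y z intensity\n")
            for s in snakes:
                for k, (p, i) in enumerate(zip(s.positions, s.intensities)):
                    fh.write(
                        f"{s.snake_id} {k} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {i:.9g}\n"
                    )
    elif dialect == "polyline_table":
        rows = []
        for s in snakes:
            for p, i in zip(s.positions, s.intensities):
                rows.append((s.snake_id, p[0], p[1], p[2], i))
        pd.DataFrame(
            rows, columns=["snake_id", "x", "y", "z", "intensity"]
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# image stacks


def read_stack(
    path: str | Path,
    spacing: Sequence[float] | None = None,
) -> "ImageStack":
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    Voxel spacing is taken from TIFF resolution metadata when present;
    *spacing* (z, y, x in µm) overrides it and is required when the file
    carries none.
    """
    from .models import ImageStack

    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if tf.pages[0].samplesperpixel != 1:
            raise ValueError(
                f"{path}: RGB/multichannel TIFFs are not supported; "
                "convert to a grayscale stack"
            )
        arr = tf.asarray()
        meta_spacing = _spacing_from_tiff(tf)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale stack, got shape {arr.shape} "
            "(RGB/multichannel TIFFs are not supported)"
        )
    if spacing is None:
        spacing = meta_spacing
    if spacing is None:
        raise ValueError(f"{path}: no voxel spacing in metadata; pass spacing=")
    return ImageStack(voxels=np.asarray(arr, dtype=float), spacing=spacing)


def _spacing_from_tiff(tf: tifffile.TiffFile):
    try:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        zstep = None
        if tf.imagej_metadata:
            zstep = tf.imagej_metadata.get("spacing")
        if xres and yres and zstep:
            xr = xres.value[0] / xres.value[1]
            yr = yres.value[0] / yres.value[1]
            return (float(zstep), 1.0 / yr, 1.0 / xr)
    except Exception:  # metadata layouts vary; treat any failure as absent
        pass
    return None


def write_stack(stack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as an ImageJ-style TIFF with spacing."""
    path = Path(path)
    dz, dy, dx = stack.spacing
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": float(dz), "unit": "um", "axes": "ZYX"},
    )


# ---------------------------------------------------------------------------
# network models


def write_network(
    model: NetworkModel,
    path: str | Path,
    format: Literal["json", "graphml", "csv_tables"] = "json",
) -> list[Path]:
    """Serialize a network model; returns the file(s) written.

    ``json`` is lossless (all vertices and intensities).  ``graphml``
    carries node positions and per-segment summary attributes (arc length,
    mean brightness, vertex count).  ``csv_tables`` writes three tables
    (``<stem>.nodes.csv``, ``<stem>.segments.csv``, ``<stem>.vertices.csv``).
    """
    path = Path(path)
    if format == "json":
        payload = {
            "cell_id": model.cell_id,
            "params": {
                "epsilon": model.params.epsilon,
                "reference_voxel": model.params.reference_voxel,
            },
            "spacing": None if model.spacing is None else list(map(float, model.spacing)),
            "nodes": [
                {
                    "node_id": n.node_id,
                    "position": list(map(float, n.position)),
                    "members": [list(m) for m in n.members],
                    "degree": n.degree,
                }
                for n in model.nodes
            ],
            "segments": [
                {
                    "segment_id": s.segment_id,
                    "end_nodes": list(s.end_nodes),
                    "source": [s.source[0], list(s.source[1])],
                    "positions": s.positions.tolist(),
                    "intensities": s.intensities.tolist(),
                }
                for s in model.segments
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return [path]

    if format == "graphml":
        import networkx as nx

        g = nx.MultiGraph(cell_id=model.cell_id)
        for n in model.nodes:
            g.add_node(
                n.node_id,
                x=float(n.position[0]),
                y=float(n.position[1]),
                z=float(n.position[2]),
                degree=n.degree,
            )
        for s in model.segments:
            g.add_edge(
                *s.end_nodes,
                key=s.segment_id,
                segment_id=s.segment_id,
                arc_length=s.arc_length,
                mean_brightness=s.mean_intensity,
                n_vertices=len(s),
            )
        nx.write_graphml(g, path)
        return [path]

    if format == "csv_tables":
        stem = path.with_suffix("") if path.suffix else path
        nodes_p = stem.with_suffix(".nodes.csv")
        segs_p = stem.with_suffix(".segments.csv")
        verts_p = stem.with_suffix(".vertices.csv")
        with open(nodes_p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node_id", "x", "y", "z", "degree", "n_members"])
            for n in model.nodes:
                w.writerow([n.node_id, *n.position, n.degree, len(n.members)])
        with open(segs_p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["segment_id", "node_a", "node_b", "n_vertices", "arc_length",
                 "mean_brightness", "source_snake"]
            )
            for s in model.segments:
                w.writerow(
                    [s.segment_id, *s.end_nodes, len(s), s.arc_length,
                     s.mean_intensity, s.source[0]]
                )
        with open(verts_p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["segment_id", "vertex_index", "x", "y", "z", "intensity"])
            for s in model.segments:
                for k, (p, i) in enumerate(zip(s.positions, s.intensities)):
                    w.writerow([s.segment_id, k, *p, i])
        return [nodes_p, segs_p, verts_p]

    raise ValueError(f"unknown format {format!r}")


def read_network(path: str | Path) -> NetworkModel:
    """Inverse of ``write_network(..., format='json')``."""
    with open(path) as fh:
        payload = json.load(fh)
    params = GraphParams(**payload["params"])
    nodes = [
        Node(
            node_id=n["node_id"],
            position=np.array(n["position"]),
            members=[tuple(m) for m in n["members"]],
            degree=n["degree"],
        )
        for n in payload["nodes"]
    ]
    segments = [
        Segment(
            segment_id=s["segment_id"],
            positions=np.array(s["positions"]),
            intensities=np.array(s["intensities"]),
            end_nodes=tuple(s["end_nodes"]),
            source=(s["source"][0], tuple(s["source"][1])),
        )
        for s in payload["segments"]
    ]
    spacing = payload.get("spacing")
    return NetworkModel(
        cell_id=payload["cell_id"],
        nodes=nodes,
        segments=segments,
        params=params,
        spacing=None if spacing is None else np.asarray(spacing),
    )


# ---------------------------------------------------------------------------
# OBJ export


def export_obj(
    model: NetworkModel,
    path: str | Path,
    radius_scale: float = 0.01,
    tubes: bool = False,
    tube_sides: int = 8,
    seed: int = 0,
) -> dict[str, Path]:
    """Export the network as Wavefront OBJ geometry.

    Each segment is written as a polyline (``l`` records over its vertex
    chain).  OBJ has no portable per-line thickness attribute, so tube
    radius (``radius_scale`` x mean segment brightness) goes into a sidecar
    CSV; with ``tubes=True`` tessellated ``tube_sides``-gon tube meshes are
    emitted instead of polylines.  Every segment gets a random material
    color in a companion ``.mtl`` file, reproducible from *seed*.

    Returns the paths written (keys ``obj``, ``mtl``, ``radii``).
    """
    if radius_scale <= 0:
        raise ValueError("radius_scale must be > 0")
    path = Path(path)
    mtl_path = path.with_suffix(".mtl")
    radii_path = path.with_suffix(".radii.csv")
    rng = np.random.default_rng(seed)

    lines: list[str] = [f"# keragraph network export: {model.cell_id}",
                        f"mtllib {mtl_path.name}"]
    mtl_lines: list[str] = []
    radii_rows: list[tuple[int, float]] = []
    v_offset = 0
    for s in model.segments:
        if s.arc_length == 0:
            log.warning("segment %d has zero length; skipped", s.segment_id)
            continue
        radius = radius_scale * s.mean_intensity
        radii_rows.append((s.segment_id, radius))
        color = rng.uniform(0.1, 1.0, size=3)
        mtl_lines.append(f"newmtl seg{s.segment_id}")
        mtl_lines.append(f"Kd {color[0]:.4f} {color[1]:.4f} {color[2]:.4f}")
        lines.append(f"usemtl seg{s.segment_id}")
        if tubes:
            verts, faces = _tube_mesh(s.positions, radius, tube_sides)
            for v in verts:
                lines.append(f"v {v[0]:.6g} {v[1]:.6g} {v[2]:.6g}")
            for f in faces:
                lines.append("f " + " ".join(str(i + 1 + v_offset) for i in f))
            v_offset += len(verts)
        else:
            for p in s.positions:
                lines.append(f"v {p[0]:.6g} {p[1]:.6g} {p[2]:.6g}")
            idx = range(v_offset + 1, v_offset + len(s) + 1)
            lines.append("l " + " ".join(map(str, idx)))
            v_offset += len(s)

    path.write_text("\n".join(lines) + "\n")
    mtl_path.write_text("\n".join(mtl_lines) + "\n")
    with open(radii_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["segment_id", "tube_radius"])
        w.writerows(radii_rows)
    return {"obj": path, "mtl": mtl_path, "radii": radii_path}


def _tube_mesh(points: np.ndarray, radius: float, sides: int):
    """Sweep a ``sides``-gon along the polyline with parallel-transport frames."""
    tangents = np.diff(points, axis=0)
    tangents = np.vstack([tangents, tangents[-1]])
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    # initial normal: any vector not parallel to the first tangent
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    normal = np.cross(tangents[0], ref)
    normal /= np.linalg.norm(normal)

    verts = []
    for i, (p, t) in enumerate(zip(points, tangents)):
        if i > 0:
            # rotate previous normal into the new tangent plane
            normal = normal - (normal @ t) * t
            nrm = np.linalg.norm(normal)
            if nrm < 1e-12:
                normal = np.cross(t, ref)
                nrm = np.linalg.norm(normal)
            normal /= nrm
        binormal = np.cross(t, normal)
        for k in range(sides):
            ang = 2 * np.pi * k / sides
            verts.append(p + radius * (np.cos(ang) * normal + np.sin(ang) * binormal))
    faces = []
    for i in range(len(points) - 1):
        for k in range(sides):
            a = i * sides + k
            b = i * sides + (k + 1) % sides
            c = (i + 1) * sides + (k + 1) % sides
            d = (i + 1) * sides + k
            faces.append((a, b, c, d))
    return np.asarray(verts), faces
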