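"""Build the node/segment network model from raw snakes.

Segmentation tools of the SOAC family emit independent polylines
("snakes") that meet, cross and overlap at filament junctions without any
explicit connectivity.  This module recovers that connectivity:

1. Every pair of vertices from *different* snakes closer than epsilon is
   linked; the transitive closure of these links (single linkage) yields
   candidate clusters.  Same-snake pairs never link — consecutive polyline
   vertices are always within epsilon of each other, so allowing them
   would collapse entire snakes into single nodes.
2. Each cluster becomes one node at the unweighted centroid of its member
   vertices.
3. Each snake is split at its clustered vertices into segments; every
   snake start/end vertex is a node as well (loose end, or part of a
   cluster).  Runs of consecutive same-node vertices along one snake are
   contracted so no zero-length segment arises.
4. Node degree = number of incident segment endpoints; degree >= 3 marks a
   branching (3 = Y, 4 = X, >= 5 = star).

The result is a Euclidean 3D network map: nodes joined by segments that
retain full polyline geometry and brightness.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .models import GraphParams, NetworkModel, Node, Segment, Snake

log = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "node_degree_histogram",
    "filaments_from_segments",
]


def _junction_clusters(snakes: Sequence[Snake], epsilon: float):
    """Single-linkage clusters under 'distance <= eps AND different snakes'.

    Returns a label per global vertex index (-1 = unclustered) and the
    number of clusters.  Only clusters of >= 2 vertices are kept, which is
    automatic because every link joins two vertices.
    """
    points = np.vstack([s.positions for s in snakes])
    snake_of = np.concatenate(
        [np.full(len(s), i) for i, s in enumerate(snakes)]
    )
    n = len(points)
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=epsilon, output_type="ndarray")
    if len(pairs):
        cross = snake_of[pairs[:, 0]] != snake_of[pairs[:, 1]]
        pairs = pairs[cross]
    labels = np.full(n, -1, dtype=int)
    if len(pairs) == 0:
        return labels, 0
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, comp = connected_components(graph, directed=False)
    # keep only components that actually contain a link
    linked = np.zeros(n, dtype=bool)
    linked[pairs.ravel()] = True
    keep = np.unique(comp[linked])
    remap = {c: i for i, c in enumerate(keep)}
    for idx in np.flatnonzero(np.isin(comp, keep)):
        labels[idx] = remap[comp[idx]]
    return labels, len(keep)


def build_network(
    snakes: Sequence[Snake],
    params: GraphParams | None = None,
    cell_id: str = "cell",
    spacing=None,
) -> NetworkModel:
    """Convert snakes into a node/segment network model.

    Raises ``ValueError`` on an empty snake list or non-positive epsilon.
    Output is independent of snake input order: nodes are relabeled by
    lexicographically sorted centroid and segments by their end nodes.
    """
    if params is None:
        params = GraphParams()
    if not snakes:
        raise ValueError("need at least one snake")
    eps = params.epsilon
    if eps is None or eps <= 0:
        raise ValueError("epsilon must be > 0")

    labels, n_clusters = _junction_clusters(snakes, eps)

    # global vertex index bookkeeping
    offsets = np.cumsum([0] + [len(s) for s in snakes])

    # cluster members and centroids
    cluster_members: dict[int, list[tuple[int, int]]] = defaultdict(list)
    cluster_points: dict[int, list[np.ndarray]] = defaultdict(list)
    for si, s in enumerate(snakes):
        for vi in range(len(s)):
            lab = labels[offsets[si] + vi]
            if lab >= 0:
                cluster_members[lab].append((s.snake_id, vi))
                cluster_points[lab].append(s.positions[vi])

    # provisional nodes: one per cluster, plus one per unclustered terminus
    node_pos: list[np.ndarray] = []
    node_members: list[list[tuple[int, int]]] = []
    cluster_node: dict[int, int] = {}
    for lab in range(n_clusters):
        cluster_node[lab] = len(node_pos)
        node_pos.append(np.mean(cluster_points[lab], axis=0))
        node_members.append(cluster_members[lab])

    def terminus_node(si: int, vi: int) -> int:
        lab = labels[offsets[si] + vi]
        if lab >= 0:
            return cluster_node[lab]
        node_pos.append(snakes[si].positions[vi].copy())
        node_members.append([(snakes[si].snake_id, vi)])
        return len(node_pos) - 1

    # split snakes at anchors (clustered vertex runs + termini)
    raw_segments: list[tuple[np.ndarray, np.ndarray, int, int, tuple]] = []
    n_self_contacts = 0
    for si, s in enumerate(snakes):
        n = len(s)
        labs = labels[offsets[si]: offsets[si] + n]
        # anchors: (first_idx, last_idx, node_id) — contiguous same-cluster
        # runs collapse to one anchor so no zero-length segment appears
        anchors: list[tuple[int, int, int]] = []
        vi = 0
        while vi < n:
            if labs[vi] >= 0:
                j = vi
                while j + 1 < n and labs[j + 1] == labs[vi]:
                    j += 1
                anchors.append((vi, j, cluster_node[labs[vi]]))
                vi = j + 1
            else:
                vi += 1
        # snake termini are always nodes
        if not anchors or anchors[0][0] > 0:
            anchors.insert(0, (0, 0, terminus_node(si, 0)))
        if anchors[-1][1] < n - 1:
            anchors.append((n - 1, n - 1, terminus_node(si, n - 1)))

        seen_nodes = [a[2] for a in anchors]
        if len(set(seen_nodes)) < len(seen_nodes):
            n_self_contacts += 1

        for (i0, j0, na), (i1, _, nb) in zip(anchors[:-1], anchors[1:]):
            pos = s.positions[j0: i1 + 1].copy()
            ints = s.intensities[j0: i1 + 1].copy()
            if len(pos) < 2:
                continue
            # snap endpoints to node centroids, keep interior untouched
            pos[0] = node_pos[na]
            pos[-1] = node_pos[nb]
            raw_segments.append((pos, ints, na, nb, (s.snake_id, (j0, i1))))

    if n_self_contacts:
        log.info(
            "%d snake(s) revisit one of their own nodes (self-contact loops "
            "are not merged)", n_self_contacts,
        )
    if not raw_segments:
        raise ValueError("no segments could be formed (all snakes degenerate)")

    # canonical node relabeling by sorted centroid; drop unused nodes
    used: set[int] = set()
    for _pos, _ints, na, nb, _src in raw_segments:
        used.add(na)
        used.add(nb)
    order = sorted(used, key=lambda i: tuple(node_pos[i]))
    relabel = {old: new for new, old in enumerate(order)}

    nodes = [
        Node(
            node_id=relabel[old],
            position=node_pos[old],
            members=sorted(node_members[old]),
        )
        for old in order
    ]
    nodes.sort(key=lambda nd: nd.node_id)

    seg_sort_key = lambda rec: (
        tuple(sorted((relabel[rec[2]], relabel[rec[3]]))),
        tuple(rec[0][0]),
        tuple(rec[0][-1]),
        rec[4],
    )
    raw_segments.sort(key=seg_sort_key)
    segments = []
    for k, (pos, ints, na, nb, src) in enumerate(raw_segments):
        segments.append(
            Segment(
                segment_id=k,
                positions=pos,
                intensities=ints,
                end_nodes=(relabel[na], relabel[nb]),
                source=src,
            )
        )

    degree = defaultdict(int)
    for s in segments:
        degree[s.end_nodes[0]] += 1
        degree[s.end_nodes[1]] += 1
    for nd in nodes:
        nd.degree = degree[nd.node_id]

    return NetworkModel(
        cell_id=cell_id,
        nodes=nodes,
        segments=segments,
        params=params,
        spacing=spacing,
    )


def node_degree_histogram(model: NetworkModel) -> dict[int, float]:
    """Relative frequency of node degrees over branching nodes (degree >= 3).

    Degree equals the segment/node ratio of a junction: 3 is a Y-shaped
    branch, 4 an X-shaped crossing of two filaments, and higher values are
    star-like configurations.  Degree-1 (loose ends) and degree-2 nodes
    (through-connections within a filament) are excluded.
    """
    if not model.nodes:
        raise ValueError("empty model")
    degrees = [n.degree for n in model.nodes if n.degree >= 3]
    if not degrees:
        log.warning("no branching nodes (degree >= 3) in model %s", model.cell_id)
        return {}
    total = len(degrees)
    hist: dict[int, float] = {}
    for d in sorted(set(degrees)):
        hist[d] = degrees.count(d) / total
    return hist


def filaments_from_segments(model: NetworkModel) -> list[list[int]]:
    """Concatenate segments through degree-2 nodes into maximal chains.

    A keratin filament typically consists of multiple consecutive segments
    joined end-to-end; this recovers those chains.  Returns ordered lists
    of segment ids; the chains partition the segment set.
    """
    deg = {n.node_id: n.degree for n in model.nodes}
    incident: dict[int, list[int]] = defaultdict(list)
    for s in model.segments:
        incident[s.end_nodes[0]].append(s.segment_id)
        incident[s.end_nodes[1]].append(s.segment_id)
    seg_by_id = {s.segment_id: s for s in model.segments}

    visited: set[int] = set()
    chains: list[list[int]] = []

    def other_end(seg: Segment, node: int) -> int:
        a, b = seg.end_nodes
        return b if node == a else a

    def walk(start_seg: int, start_node: int) -> list[int]:
        """Follow segments from start_node through degree-2 nodes."""
        chain = [start_seg]
        visited.add(start_seg)
        node = other_end(seg_by_id[start_seg], start_node)
        while deg[node] == 2:
            nxt = [sid for sid in incident[node] if sid not in visited]
            if not nxt:
                break  # closed loop or already-consumed continuation
            chain.append(nxt[0])
            visited.add(nxt[0])
            node = other_end(seg_by_id[nxt[0]], node)
        return chain

    # start at every segment endpoint whose node is not a pass-through
    for s in sorted(model.segments, key=lambda s: s.segment_id):
        if s.segment_id in visited:
            continue
        a, b = s.end_nodes
        if deg[a] != 2:
            chains.append(walk(s.segment_id, a))
        elif deg[b] != 2:
            chains.append(walk(s.segment_id, b))
    # leftover: pure cycles of degree-2 nodes
    for s in sorted(model.segments, key=lambda s: s.segment_id):
        if s.segment_id not in visited:
            chains.append(walk(s.segment_id, s.end_nodes[0]))
    return chains
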