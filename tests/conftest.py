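import numpy as np
import pytest

from keragraph.models import GraphParams, Snake


def straight_snake(start, direction, length, n, brightness=100.0, sid=0):
    """A straight n-vertex snake of given length from start along direction."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pts = np.asarray(start, dtype=float) + np.outer(np.linspace(0.0, length, n), d)
    return Snake(snake_id=sid, positions=pts, intensities=np.full(n, brightness))


@pytest.fixture
def params():
    return GraphParams(epsilon=0.0715, reference_voxel=0.065)


@pytest.fixture
def y_snakes():
    """Two snakes forming a Y: a branch ends at the through snake's midpoint."""
    through = straight_snake((0, 0, 0), (1, 0, 0), 2.0, 21, 100.0, sid=0)
    branch = straight_snake((1.0, 0.005, 0), (0.3, 1, 0), 1.0, 11, 80.0, sid=1)
    return [through, branch]


@pytest.fixture
def x_snakes():
    """Two snakes crossing at interior vertices (degree-4 node)."""
    return [
        straight_snake((0, 0, 0), (1, 0, 0), 2.0, 21, 100.0, sid=0),
        straight_snake((1.0, -1.0, 0.005), (0, 1, 0), 2.0, 21, 90.0, sid=1),
    ]


def brute_force_clusters(snakes, eps):
    """O(n²) single-linkage closure over cross-snake pairs within eps.

    Independent oracle for the production KD-tree/sparse-graph path:
    explicit pairwise distances and BFS transitive closure.  Returns the
    set of clusters as frozensets of (snake_id, vertex_index).
    """
    verts = [
        (s.snake_id, i, s.positions[i]) for s in snakes for i in range(len(s))
    ]
    n = len(verts)
    adj = [[] for _ in range(n)]
    for a in range(n):
        for b in range(a + 1, n):
            if verts[a][0] != verts[b][0] and (
                np.linalg.norm(verts[a][2] - verts[b][2]) <= eps
            ):
                adj[a].append(b)
                adj[b].append(a)
    seen, parts = set(), set()
    for i in range(n):
        if i in seen or not adj[i]:
            continue
        comp, stack = [], [i]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(adj[v])
        parts.add(frozenset((verts[v][0], verts[v][1]) for v in comp))
    return parts


def random_snake_set(rng, max_vertices=200):
    """A random multi-snake instance with plenty of chance contacts."""
    snakes = []
    total = 0
    for sid in range(int(rng.integers(2, 7))):
        npts = int(rng.integers(3, 20))
        if total + npts > max_vertices:
            break
        pts = np.cumsum(rng.normal(0, 0.3, (npts, 3)), axis=0) + rng.uniform(0, 2, 3)
        snakes.append(Snake(sid, pts, np.abs(rng.normal(50, 10, npts))))
        total += npts
    if len(snakes) < 2:
        snakes.append(
            Snake(90, np.array([[0.0, 0, 0], [0.5, 0, 0]]), np.array([1.0, 1.0]))
        )
    return snakes
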