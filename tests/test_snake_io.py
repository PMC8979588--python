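import numpy as np
import pytest

from keragraph.models import GraphParams, ImageStack, NetworkModel, Snake
from keragraph.network_graph import build_network
from keragraph.snake_io import (
    SnakeParseError,
    export_obj,
    read_network,
    read_snakes,
    read_stack,
    write_network,
    write_snakes,
    write_stack,
)

from conftest import straight_snake


def make_snakes():
    rng = np.random.default_rng(42)
    out = []
    for sid in (3, 7):
        n = int(rng.integers(3, 8))
        pts = np.cumsum(rng.uniform(0.05, 0.3, (n, 3)), axis=0)
        out.append(Snake(sid, pts, rng.uniform(1, 100, n)))
    return out


def test_parse_single_snake_order_preserved(tmp_path):
    f = tmp_path / "one.txt"
    f.write_text(
        "# header\n$ param\n"
        "0 0 1.0 2.0 3.0 10\n0 1 1.5 2.0 3.0 11\n0 2 2.0 2.5 3.0 12\n"
    )
    snakes = read_snakes(f, "tsoax")
    assert len(snakes) == 1 and len(snakes[0]) == 3
    np.testing.assert_allclose(snakes[0].positions[0], [1, 2, 3])
    np.testing.assert_allclose(snakes[0].intensities, [10, 11, 12])


@pytest.mark.parametrize("dialect", ["tsoax", "polyline_table"])
def test_roundtrip(tmp_path, dialect):
    snakes = make_snakes()
    f = tmp_path / "rt.txt"
    write_snakes(snakes, f, dialect)
    back = read_snakes(f, dialect)
    assert [s.snake_id for s in back] == [s.snake_id for s in snakes]
    for a, b in zip(snakes, back):
        np.testing.assert_allclose(a.positions, b.positions, atol=1e-6)
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-6)


def test_voxel_unit_scale_applied(tmp_path):
    f = tmp_path / "vox.txt"
    f.write_text("0 0 10 20 2 5\n0 1 20 20 2 5\n")
    snakes = read_snakes(f, "tsoax", scale=0.065)
    np.testing.assert_allclose(snakes[0].positions[0], [0.65, 1.3, 0.13])


def test_interleaved_snake_ids_rejected(tmp_path):
    f = tmp_path / "bad.txt"
    f.write_text("0 0 0 0 0 1\n0 1 1 0 0 1\n1 0 5 5 5 1\n1 1 6 5 5 1\n0 2 2 0 0 1\n")
    with pytest.raises(SnakeParseError, match="interleaved"):
        read_snakes(f, "tsoax")


def test_short_snake_rejected_with_location(tmp_path):
    f = tmp_path / "short.txt"
    f.write_text("0 0 0 0 0 1\n")
    with pytest.raises(SnakeParseError, match="need >= 2"):
        read_snakes(f, "tsoax")


def test_non_numeric_field_names_line(tmp_path):
    f = tmp_path / "nn.txt"
    f.write_text("0 0 0 0 0 1\n0 1 oops 0 0 1\n")
    with pytest.raises(SnakeParseError, match=":2"):
        read_snakes(f, "tsoax")


def test_table_missing_column(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text("snake_id,x,y,z\n0,0,0,0\n0,1,0,0\n")
    with pytest.raises(SnakeParseError, match="intensity"):
        read_snakes(f, "polyline_table")


def test_junction_section_ignored(tmp_path):
    f = tmp_path / "junc.txt"
    f.write_text("0 0 0 0 0 1\n0 1 1 0 0 1\n[junctions]\n0.5 0 0\n")
    snakes = read_snakes(f, "tsoax")
    assert len(snakes) == 1 and len(snakes[0]) == 2


def test_write_refuses_nan(tmp_path):
    s = Snake(0, np.array([[0.0, 0, 0], [1, 0, 0]]), np.array([1.0, 1.0]))
    s.positions[1, 1] = np.nan  # corrupt after construction
    with pytest.raises(ValueError, match="non-finite"):
        write_snakes([s], tmp_path / "nan.txt")


def test_empty_snake_list_writes_header_only(tmp_path):
    f = tmp_path / "empty.txt"
    write_snakes([], f)
    lines = f.read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("#")


# --- stacks ---


def test_stack_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    st = ImageStack(rng.random((4, 4, 4)), (0.18, 0.065, 0.065))
    f = tmp_path / "st.tif"
    write_stack(st, f)
    back = read_stack(f)
    np.testing.assert_allclose(back.voxels, st.voxels, rtol=1e-6)
    np.testing.assert_allclose(back.spacing, st.spacing, rtol=1e-4)


def test_2d_tiff_becomes_single_plane(tmp_path):
    import tifffile

    f = tmp_path / "flat.tif"
    tifffile.imwrite(f, np.ones((5, 6), dtype=np.float32))
    st = read_stack(f, spacing=(0.2, 0.1, 0.1))
    assert st.voxels.shape == (1, 5, 6)


def test_rgb_tiff_rejected(tmp_path):
    import tifffile

    f = tmp_path / "rgb.tif"
    tifffile.imwrite(f, np.zeros((4, 4, 3), dtype=np.uint8), photometric="rgb")
    with pytest.raises(ValueError, match="RGB|multichannel|grayscale"):
        read_stack(f, spacing=(1, 1, 1))


def test_missing_spacing_errors(tmp_path):
    import tifffile

    f = tmp_path / "nospc.tif"
    tifffile.imwrite(f, np.zeros((2, 4, 4), dtype=np.float32))
    with pytest.raises(ValueError, match="spacing"):
        read_stack(f)


# --- network serialization ---


@pytest.fixture
def model(y_snakes, params):
    return build_network(y_snakes, params)


def test_json_roundtrip_lossless(tmp_path, model):
    f = tmp_path / "net.json"
    write_network(model, f, "json")
    back = read_network(f)
    assert back.n_nodes == model.n_nodes
    assert back.n_segments == model.n_segments
    for a, b in zip(model.segments, back.segments):
        np.testing.assert_allclose(a.positions, b.positions)
        np.testing.assert_allclose(a.intensities, b.intensities)
        assert a.end_nodes == b.end_nodes


def test_graphml_counts(tmp_path, model):
    import networkx as nx

    f = tmp_path / "net.graphml"
    write_network(model, f, "graphml")
    g = nx.read_graphml(f)
    assert g.number_of_nodes() == model.n_nodes
    assert g.number_of_edges() == model.n_segments


def test_csv_tables_conserve_vertices(tmp_path, model):
    import pandas as pd

    files = write_network(model, tmp_path / "net", "csv_tables")
    verts = pd.read_csv([f for f in files if "vertices" in f.name][0])
    assert len(verts) == sum(len(s) for s in model.segments)


def test_empty_network_serializes(tmp_path):
    empty = NetworkModel("none", nodes=[], segments=[], params=GraphParams())
    files = write_network(empty, tmp_path / "e", "csv_tables")
    import pandas as pd

    for f in files:
        assert len(pd.read_csv(f)) == 0
    write_network(empty, tmp_path / "e.json", "json")
    assert read_network(tmp_path / "e.json").n_segments == 0


# --- OBJ export ---


def test_obj_single_segment_records(tmp_path, params):
    model = build_network([straight_snake((0, 0, 0), (1, 0, 0), 1.0, 2)], params)
    out = export_obj(model, tmp_path / "m.obj", radius_scale=0.01)
    lines = out["obj"].read_text().splitlines()
    assert sum(l.startswith("v ") for l in lines) == 2
    assert sum(l.startswith("l ") for l in lines) == 1
    assert out["mtl"].exists()


def test_obj_vertex_count_conserved(tmp_path, model):
    out = export_obj(model, tmp_path / "m.obj")
    lines = out["obj"].read_text().splitlines()
    n_v = sum(l.startswith("v ") for l in lines)
    assert n_v == sum(len(s) for s in model.segments)


def test_obj_radius_tracks_brightness(tmp_path, params):
    bright = straight_snake((0, 0, 0), (1, 0, 0), 1.0, 5, brightness=200.0, sid=0)
    dim = straight_snake((0, 5, 0), (1, 0, 0), 1.0, 5, brightness=50.0, sid=1)
    model = build_network([bright, dim], params)
    out = export_obj(model, tmp_path / "m.obj", radius_scale=0.01)
    import pandas as pd

    radii = pd.read_csv(out["radii"])["tube_radius"]
    assert radii.max() / radii.min() == pytest.approx(4.0)


def test_obj_tube_mesh_emits_faces(tmp_path, model):
    out = export_obj(model, tmp_path / "t.obj", tubes=True, tube_sides=8)
    lines = out["obj"].read_text().splitlines()
    assert sum(l.startswith("f ") for l in lines) > 0


def test_obj_colors_deterministic(tmp_path, model):
    a = export_obj(model, tmp_path / "a.obj", seed=5)["mtl"].read_text()
    b = export_obj(model, tmp_path / "b.obj", seed=5)["mtl"].read_text()
    assert a == b
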