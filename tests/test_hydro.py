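import math

import networkx as nx
import numpy as np
import pytest

from lakescape import hydro
from lakescape.hydro import (
    DemGrid,
    FlowField,
    SampleSites,
    ShorelineRing,
    StreamNetwork,
    euclidean_matrix,
    extract_shoreline,
    extract_stream_network,
    fill_sinks,
    flow_accumulation,
    flow_direction,
    network_euclidean_matrix,
    network_path_matrix,
    read_esri_ascii,
    shoreline_matrix,
    snap_points,
    write_esri_ascii,
)

OFFSETS = {code: (dr, dc) for code, dr, dc in hydro.D8}


def trace_to_terminal(directions, r, c):
    nr, nc = directions.shape
    for _ in range(directions.size + 1):
        code = directions[r, c]
        if code <= 0:
            return (r, c)
        dr, dc = OFFSETS[code]
        rr, cc = r + dr, c + dc
        if not (0 <= rr < nr and 0 <= cc < nc):
            return (r, c)
        r, c = rr, cc
    raise AssertionError("flow path did not terminate")


def random_filled_dem(rng, n=50):
    dem = DemGrid(rng.uniform(0, 10, size=(n, n)), cellsize=1.0)
    return fill_sinks(dem, epsilon=1e-5)


class TestEsriAscii:
    def test_round_trip(self, tmp_path, rng):
        dem = DemGrid(rng.uniform(0, 5, size=(4, 6)), 2.5, 100.0, 200.0)
        write_esri_ascii(dem, tmp_path / "d.asc")
        back = read_esri_ascii(tmp_path / "d.asc")
        assert back.nrows == 4 and back.ncols == 6
        assert back.cellsize == 2.5 and back.xllcorner == 100.0
        np.testing.assert_allclose(back.elevations, dem.elevations, atol=1e-6)


class TestFillSinks:
    def test_monotone_slope_unchanged(self):
        z = np.tile(np.arange(5, 0, -1, dtype=float), (4, 1))
        dem = DemGrid(z, 1.0)
        np.testing.assert_array_equal(fill_sinks(dem, 0.0).elevations, z)

    def test_center_sink_raised_to_spill(self):
        z = np.full((3, 3), 5.0)
        z[1, 1] = 1.0
        z[0, 1] = 4.0  # the open edge cell
        filled = fill_sinks(DemGrid(z, 1.0), 0.0)
        assert filled.elevations[1, 1] == pytest.approx(4.0)

    def test_idempotent_and_never_lowers(self, rng):
        dem = DemGrid(rng.uniform(0, 10, size=(20, 20)), 1.0)
        once = fill_sinks(dem, 0.0)
        twice = fill_sinks(once, 0.0)
        assert (once.elevations >= dem.elevations - 1e-12).all()
        np.testing.assert_allclose(twice.elevations, once.elevations)

    def test_all_nodata_error(self):
        dem = DemGrid(np.full((3, 3), -9999.0), 1.0)
        with pytest.raises(ValueError):
            fill_sinks(dem)


class TestFlowDirection:
    def test_uniform_east_slope(self):
        z = np.tile(np.arange(10, 0, -1, dtype=float), (5, 1))
        d = flow_direction(DemGrid(z, 1.0))
        assert (d[1:-1, :-1] == 1).all()  # interior flows east
        assert (d[:, -1] == 0).all()  # last column is the outlet

    def test_single_row(self):
        d = flow_direction(DemGrid(np.array([[3.0, 2.0, 1.0, 0.0]]), 1.0))
        np.testing.assert_array_equal(d, [[1, 1, 1, 0]])

    def test_flat_interior_raises_with_hint(self):
        z = np.full((5, 5), 2.0)
        z[0, 0] = 1.0
        with pytest.raises(ValueError, match="epsilon"):
            flow_direction(DemGrid(z, 1.0))

    def test_epsilon_filled_bowl_is_acyclic(self, rng):
        z = np.full((9, 9), 5.0)
        z[2:7, 2:7] = 1.0  # a bowl
        filled = fill_sinks(DemGrid(z, 1.0), epsilon=1e-5)
        directions = flow_direction(filled)
        flow_accumulation(directions)  # raises on cycles
        for r in range(9):
            for c in range(9):
                tr, tc = trace_to_terminal(directions, r, c)
                assert tr in (0, 8) or tc in (0, 8)


class TestFlowAccumulation:
    def test_chain(self):
        d = np.array([[1, 1, 1, 1, 0]])
        np.testing.assert_array_equal(flow_accumulation(d), [[0, 1, 2, 3, 4]])

    def test_confluence(self):
        # two headwaters merging into the middle cell of a column
        directions = np.array([[4], [4], [0]])  # both flow south
        acc = flow_accumulation(directions)
        assert acc[2, 0] == 2

    def test_cycle_detected(self):
        d = np.array([[1, 16]])  # east then west: a 2-cycle
        with pytest.raises(ValueError, match="cycle"):
            flow_accumulation(d)

    def test_conservation_on_random_grids(self, rng):
        filled = random_filled_dem(rng, n=10)
        directions = flow_direction(filled)
        acc = flow_accumulation(directions)
        n = filled.nrows * filled.ncols
        # every cell's path terminates somewhere; outlets account for all cells
        terminals = {}
        for r in range(10):
            for c in range(10):
                t = trace_to_terminal(directions, r, c)
                terminals[t] = terminals.get(t, 0) + 1
        for (r, c), count in terminals.items():
            assert acc[r, c] + 1 == count
        assert sum(terminals.values()) == n


class TestStreamNetwork:
    def test_chain_with_threshold(self):
        flow = FlowField(
            np.array([[1, 1, 1, 1, 0]]), np.array([[0, 1, 2, 3, 4]]), cellsize=1.0
        )
        net = extract_stream_network(flow, threshold=2)
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 2

    def test_strahler_y_junction(self):
        # two order-1 arms joining: the downstream chain becomes order 2
        directions = np.array(
            [
                [4, 0, 4],  # two headwaters flowing south
                [2, 0, 8],  # arms converge SE / SW into (2, 1)
                [0, 4, 0],
                [0, 0, 0],
            ]
        )
        acc = flow_accumulation(directions)
        net = extract_stream_network(FlowField(directions, acc, 1.0), threshold=1)
        assert net.graph.nodes[(1, 0)]["strahler"] == 1
        assert net.graph.nodes[(1, 2)]["strahler"] == 1
        assert net.graph.nodes[(2, 1)]["strahler"] == 2
        assert net.graph.nodes[(3, 1)]["strahler"] == 2

    def test_no_qualifying_cell(self):
        flow = FlowField(np.array([[1, 0]]), np.array([[0, 1]]), 1.0)
        with pytest.raises(ValueError, match="threshold"):
            extract_stream_network(flow, threshold=5)


class TestShoreline:
    def test_square_lake_perimeter(self):
        z = np.full((10, 10), 5.0)
        z[3:7, 3:7] = 1.0
        ring = extract_shoreline(DemGrid(z, 2.0), water_level=4.0)
        assert ring.perimeter == pytest.approx(16 * 2.0)
        np.testing.assert_allclose(ring.vertices[0], ring.vertices[-1])

    def test_no_water_error(self):
        z = np.full((5, 5), 5.0)
        with pytest.raises(ValueError, match="no submerged"):
            extract_shoreline(DemGrid(z, 1.0), water_level=1.0)

    def test_two_lakes_error(self):
        z = np.full((7, 7), 5.0)
        z[1, 1] = 0.0
        z[5, 5] = 0.0
        with pytest.raises(ValueError, match="2 submerged"):
            extract_shoreline(DemGrid(z, 1.0), water_level=1.0)

    def test_edge_touching_error(self):
        z = np.full((5, 5), 5.0)
        z[0, 2] = 0.0
        with pytest.raises(ValueError, match="edge"):
            extract_shoreline(DemGrid(z, 1.0), water_level=1.0)


def square_ring(side=10.0):
    v = np.array(
        [[0, 0], [side, 0], [side, side], [0, side], [0, 0]], dtype=float
    )
    return ShorelineRing(v)


def y_network():
    """Three 10 m arms meeting at a central vertex."""
    g = nx.Graph()
    coords = {"L1": (-10.0, 0.0), "L2": (10.0, 0.0), "L3": (0.0, 10.0), "C": (0.0, 0.0)}
    for k, (x, y) in coords.items():
        g.add_node(k, x=x, y=y, accumulation=1, strahler=1)
    segments = []
    for leaf in ("L1", "L2", "L3"):
        g.add_edge(leaf, "C", length=10.0)
        segments.append((leaf, "C"))
    return StreamNetwork(g, segments, cellsize=10.0)


class TestSnapping:
    def test_point_on_ring_distance_zero(self):
        sites = SampleSites(["a"], [[5.0, 0.0]])
        snapped = snap_points(sites, square_ring())
        assert snapped.snap_dist[0] == pytest.approx(0.0)
        assert snapped.snap_arc[0] == pytest.approx(5.0)

    def test_tie_goes_to_lower_segment_index(self):
        # centre of the square is equidistant from all four sides
        sites = SampleSites(["a"], [[5.0, 5.0]])
        snapped = snap_points(sites, square_ring())
        assert snapped.snap_arc[0] == pytest.approx(5.0)  # first side, mid-point

    def test_against_densified_oracle(self, rng):
        ring = square_ring(7.0)
        pts = rng.uniform(-3, 10, size=(10, 2))
        snapped = snap_points(SampleSites([f"p{i}" for i in range(10)], pts), ring)
        # brute force: nearest among ring points spaced 1 cm apart
        dense_arcs = np.arange(0, ring.perimeter, 0.01)
        dense = np.array([ring.point_at(a) for a in dense_arcs])
        for i, p in enumerate(pts):
            d = np.linalg.norm(dense - p, axis=1).min()
            assert abs(snapped.snap_dist[i] - d) <= 0.01

    def test_snap_to_network(self):
        net = y_network()
        sites = SampleSites(["a", "b"], [[-10.0, 0.0], [0.0, 3.0]])
        snapped = snap_points(sites, net)
        assert snapped.snap_dist[0] == pytest.approx(0.0)
        assert snapped.snap_dist[1] == pytest.approx(0.0)


class TestDistanceMatrices:
    def test_euclidean_3_4_5(self):
        sites = SampleSites(["a", "b"], [[0.0, 0.0], [3.0, 4.0]])
        assert euclidean_matrix(sites).values[0, 1] == pytest.approx(5.0)

    def test_euclidean_properties(self, rng):
        pts = rng.uniform(0, 100, size=(8, 2))
        m = euclidean_matrix(SampleSites([f"p{i}" for i in range(8)], pts))
        assert np.allclose(m.values, m.values.T)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert m.values[i, j] <= m.values[i, k] + m.values[k, j] + 1e-9

    def test_shoreline_takes_shorter_arc(self):
        ring = square_ring(10.0)  # perimeter 40
        sites = SampleSites(
            ["a", "b", "c"], [[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]
        )
        snapped = snap_points(sites, ring)
        m = shoreline_matrix(snapped, ring)
        assert m.values[0, 1] == pytest.approx(10.0)  # arc 0 vs 10
        assert m.values[0, 2] == pytest.approx(10.0)  # arc 0 vs 30: wrap around
        assert (m.values <= ring.perimeter / 2 + 1e-9).all()

    def test_unsnapped_sites_rejected(self):
        sites = SampleSites(["a", "b"], [[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="snapped"):
            shoreline_matrix(sites, square_ring())
        with pytest.raises(ValueError, match="snapped"):
            network_path_matrix(sites, y_network())

    def test_network_euclidean_same_vertex(self):
        net = y_network()
        sites = SampleSites(["a", "b"], [[0.1, -0.1], [-0.1, -0.1]])
        snapped = snap_points(sites, net)
        m = network_euclidean_matrix(snapped, net)
        assert m.values[0, 1] == pytest.approx(0.2, abs=0.25)

    def test_y_network_leaf_to_leaf_path(self):
        net = y_network()
        sites = SampleSites(
            ["a", "b", "c"], [[-10.0, 0.0], [10.0, 0.0], [0.0, 10.0]]
        )
        snapped = snap_points(sites, net)
        m = network_path_matrix(snapped, net)
        assert m.values[0, 1] == pytest.approx(20.0)
        assert m.values[0, 2] == pytest.approx(20.0)

    def test_path_at_least_chord(self, lake, rng):
        from lakescape import synth

        sites = synth.place_sites(lake["ring"], n_sites=12, seed=5)
        snapped = snap_points(sites, lake["net"])
        chord = network_euclidean_matrix(snapped, lake["net"]).values
        path = network_path_matrix(snapped, lake["net"]).values
        assert (path >= chord - 1e-6).all()
        assert np.isfinite(path).all()

    def test_shoreline_at_least_euclidean_between_snapped(self, lake):
        from lakescape import synth

        sites = synth.place_sites(lake["ring"], n_sites=12, seed=5)
        snapped = snap_points(sites, lake["ring"])
        arc = shoreline_matrix(snapped, lake["ring"]).values
        eu = euclidean_matrix(
            SampleSites(list(snapped.ids), snapped.snap_xy)
        ).values
        assert (arc >= eu - 1e-6).all()
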