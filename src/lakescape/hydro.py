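"""Raster hydrology and the four geographic distance models.

From a DEM (ESRI ASCII grid, planar metres) the module derives sink-filled
elevations, D8 flow directions (ESRI codes, E=1 clockwise to NE=128),
flow accumulation, a thresholded stream network with Strahler orders, and a
lake shoreline ring; sample sites snap to either target and yield four
pairwise distance matrices:

* Euclidean (straight line between recorded coordinates),
* shoreline (shorter arc along the lake perimeter),
* network Euclidean (straight line between positions snapped to the stream
  network),
* network path (shortest path along the stream network).

Grid convention: row 0 is the northernmost row; the cell centre of (row, col)
sits at x = xllcorner + (col + 0.5) * cellsize,
        y = yllcorner + (nrows - row - 0.5) * cellsize.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from .distances import DistanceMatrix

_SQRT2 = math.sqrt(2.0)
# D8 ESRI codes clockwise from east, with (drow, dcol) offsets (row 0 = north)
D8 = [
    (1, 0, 1),  # E
    (2, 1, 1),  # SE
    (4, 1, 0),  # S
    (8, 1, -1),  # SW
    (16, 0, -1),  # W
    (32, -1, -1),  # NW
    (64, -1, 0),  # N
    (128, -1, 1),  # NE
]
_CODE_TO_OFFSET = {code: (dr, dc) for code, dr, dc in D8}


@dataclass
class DemGrid:
    elevations: np.ndarray  # (nrows, ncols), row 0 = north
    cellsize: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.elevations.ndim != 2:
            raise ValueError("elevations must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.elevations.shape[0]

    @property
    def ncols(self) -> int:
        return self.elevations.shape[1]

    def valid(self) -> np.ndarray:
        return self.elevations != self.nodata

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.xllcorner + (col + 0.5) * self.cellsize,
            self.yllcorner + (self.nrows - row - 0.5) * self.cellsize,
        )


@dataclass
class FlowField:
    """D8 directions (0 = outlet off-grid, -1 = nodata) and accumulation."""

    directions: np.ndarray
    accumulation: np.ndarray
    cellsize: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0


@dataclass
class ShorelineRing:
    """Closed, simple, counter-clockwise ring of planar vertices."""

    vertices: np.ndarray  # (m+1, 2), first == last

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if not np.allclose(self.vertices[0], self.vertices[-1]):
            raise ValueError("ring is not closed")
        if self.perimeter <= 0:
            raise ValueError("degenerate ring")

    @property
    def perimeter(self) -> float:
        return float(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum())

    def segments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.vertices[i], self.vertices[i + 1]) for i in range(len(self.vertices) - 1)]

    def point_at(self, arc: float) -> np.ndarray:
        """Planar point at arc length ``arc`` (wrapped) along the ring."""
        arc = arc % self.perimeter
        for a, b in self.segments():
            seg = float(np.linalg.norm(b - a))
            if arc <= seg:
                return a + (b - a) * (arc / seg if seg > 0 else 0.0)
            arc -= seg
        return self.vertices[-1]


@dataclass
class StreamNetwork:
    """Stream cells as graph vertices; edges follow D8 between them."""

    graph: nx.Graph  # nodes (row, col); attrs x, y, accumulation, strahler
    segments: list[tuple[tuple[int, int], tuple[int, int]]]  # deterministic order
    cellsize: float

    def segment_coords(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        u, v = self.segments[k]
        gu, gv = self.graph.nodes[u], self.graph.nodes[v]
        return np.array([gu["x"], gu["y"]]), np.array([gv["x"], gv["y"]])


@dataclass
class SampleSites:
    ids: list[str]
    coords: np.ndarray  # (n, 2) planar metres
    # populated by snap_points:
    snap_kind: str | None = None  # "shoreline" | "network"
    snap_xy: np.ndarray | None = None
    snap_dist: np.ndarray | None = None
    snap_arc: np.ndarray | None = None  # shoreline arc positions
    snap_seg: list[int] | None = None  # network segment index
    snap_offset: np.ndarray | None = None  # metres along the segment

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate site ids")
        if self.coords.shape != (len(self.ids), 2):
            raise ValueError("coords must be (n, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path) -> None:
        pd.DataFrame({"id": self.ids, "x": self.coords[:, 0], "y": self.coords[:, 1]}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "SampleSites":
        df = pd.read_csv(path)
        return cls(df["id"].astype(str).tolist(), df[["x", "y"]].to_numpy(dtype=float))


# ---- ESRI ASCII grid I/O ------------------------------------------------------


def read_esri_ascii(path) -> DemGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII header missing {key}")
    data = np.loadtxt(lines[i:].__iter__(), dtype=float)
    data = data.reshape(int(header["nrows"]), int(header["ncols"]))
    return DemGrid(
        data,
        header["cellsize"],
        header.get("xllcorner", 0.0),
        header.get("yllcorner", 0.0),
        header.get("nodata_value", -9999.0),
    )


def write_esri_ascii(dem: DemGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {dem.ncols}\n")
        fh.write(f"nrows {dem.nrows}\n")
        fh.write(f"xllcorner {dem.xllcorner}\n")
        fh.write(f"yllcorner {dem.yllcorner}\n")
        fh.write(f"cellsize {dem.cellsize}\n")
        fh.write(f"NODATA_value {dem.nodata}\n")
        for row in dem.elevations:
            fh.write(" ".join(format(v, ".6f") for v in row) + "\n")


# ---- sink filling and D8 flow --------------------------------------------------


def fill_sinks(dem: DemGrid, epsilon: float = 1e-5) -> DemGrid:
    """Priority-flood sink filling.

    Every non-nodata cell gains a non-ascending (strictly descending when
    epsilon > 0) 8-neighbour path to the grid edge; elevations only rise.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    z = dem.elevations
    valid = dem.valid()
    if not valid.any():
        raise ValueError("all-nodata grid cannot be filled")
    nr, nc = z.shape
    filled = np.full_like(z, np.inf)
    filled[~valid] = dem.nodata
    visited = ~valid
    heap: list[tuple[float, int, int, int]] = []
    counter = 0

    def seed(r, c):
        nonlocal counter
        if not visited[r, c]:
            visited[r, c] = True
            filled[r, c] = z[r, c]
            heapq.heappush(heap, (z[r, c], counter, r, c))
            counter += 1

    # seed the open boundary: grid-edge cells and cells adjacent to nodata
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            if r in (0, nr - 1) or c in (0, nc - 1):
                seed(r, c)
            else:
                for _, dr, dc in D8:
                    if not valid[r + dr, c + dc]:
                        seed(r, c)
                        break
    if not heap:
        raise ValueError("no non-nodata cell on the open boundary")
    while heap:
        elev, _, r, c = heapq.heappop(heap)
        for _, dr, dc in D8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not visited[rr, cc]:
                visited[rr, cc] = True
                filled[rr, cc] = max(z[rr, cc], elev + epsilon)
                heapq.heappush(heap, (filled[rr, cc], counter, rr, cc))
                counter += 1
    return DemGrid(filled, dem.cellsize, dem.xllcorner, dem.yllcorner, dem.nodata)


def flow_direction(dem: DemGrid) -> np.ndarray:
    """Steepest-descent D8 codes on a sink-filled DEM.

    Drop is divided by the travel distance (cellsize, or cellsize*sqrt(2)
    diagonally); ties break toward the lowest code. Edge (or nodata-adjacent)
    cells with no lower neighbour become outlets (code 0); an interior cell
    with no strictly lower neighbour is an unresolved flat and raises.
    """
    z = dem.elevations
    valid = dem.valid()
    nr, nc = z.shape
    out = np.full((nr, nc), -1, dtype=int)
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            best_slope, best_code, open_boundary = 0.0, 0, False
            if r in (0, nr - 1) or c in (0, nc - 1):
                open_boundary = True
            for code, dr, dc in D8:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc) or not valid[rr, cc]:
                    open_boundary = True  # off-grid or nodata counts as an exit
                    continue
                dist = dem.cellsize * (_SQRT2 if dr and dc else 1.0)
                slope = (z[r, c] - z[rr, cc]) / dist
                if slope > best_slope:
                    best_slope, best_code = slope, code
            if best_code == 0 and not open_boundary:
                raise ValueError(
                    f"unresolved flat at interior cell {(r, c)}; "
                    "fill sinks with epsilon > 0 first"
                )
            out[r, c] = best_code
    return out


def flow_accumulation(directions: np.ndarray) -> np.ndarray:
    """Upstream contributing-cell counts (headwaters = 0); raises on cycles."""
    nr, nc = directions.shape
    acc = np.zeros((nr, nc), dtype=np.int64)
    indeg = np.zeros((nr, nc), dtype=np.int64)
    active = directions >= 0
    for r in range(nr):
        for c in range(nc):
            code = directions[r, c]
            if code > 0:
                dr, dc = _CODE_TO_OFFSET[code]
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and active[rr, cc]:
                    indeg[rr, cc] += 1
    queue = [(r, c) for r in range(nr) for c in range(nc) if active[r, c] and indeg[r, c] == 0]
    processed = 0
    while queue:
        r, c = queue.pop()
        processed += 1
        code = directions[r, c]
        if code > 0:
            dr, dc = _CODE_TO_OFFSET[code]
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and active[rr, cc]:
                acc[rr, cc] += acc[r, c] + 1
                indeg[rr, cc] -= 1
                if indeg[rr, cc] == 0:
                    queue.append((rr, cc))
    if processed != int(active.sum()):
        raise ValueError("cycle detected in flow directions")
    return acc


def flow_field(dem: DemGrid) -> FlowField:
    """Convenience: directions + accumulation for a sink-filled DEM."""
    directions = flow_direction(dem)
    return FlowField(
        directions, flow_accumulation(directions), dem.cellsize, dem.xllcorner, dem.yllcorner
    )


# ---- stream network ------------------------------------------------------------


def extract_stream_network(flow: FlowField, threshold: int) -> StreamNetwork:
    """Cells with accumulation >= threshold, joined along D8 directions.

    Edge lengths are cellsize (orthogonal) or cellsize*sqrt(2) (diagonal);
    Strahler orders are annotated on the qualifying cells.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    directions, acc = flow.directions, flow.accumulation
    nr, nc = directions.shape
    qualify = (acc >= threshold) & (directions >= 0)
    if not qualify.any():
        raise ValueError(f"no cell reaches accumulation threshold {threshold}")

    g = nx.Graph()
    downstream: dict[tuple[int, int], tuple[int, int]] = {}
    segments = []
    for r in range(nr):
        for c in range(nc):
            if not qualify[r, c]:
                continue
            x = flow.xllcorner + (c + 0.5) * flow.cellsize
            y = flow.yllcorner + (nr - r - 0.5) * flow.cellsize
            g.add_node((r, c), x=x, y=y, accumulation=int(acc[r, c]), strahler=0)
    for r in range(nr):
        for c in range(nc):
            if not qualify[r, c]:
                continue
            code = directions[r, c]
            if code > 0:
                dr, dc = _CODE_TO_OFFSET[code]
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and qualify[rr, cc]:
                    length = flow.cellsize * (_SQRT2 if dr and dc else 1.0)
                    g.add_edge((r, c), (rr, cc), length=length)
                    downstream[(r, c)] = (rr, cc)
                    segments.append(((r, c), (rr, cc)))

    _annotate_strahler(g, downstream)
    return StreamNetwork(g, segments, flow.cellsize)


def _annotate_strahler(g: nx.Graph, downstream: dict) -> None:
    upstream: dict[tuple[int, int], list] = {n: [] for n in g.nodes}
    for u, v in downstream.items():
        upstream[v].append(u)
    indeg = {n: len(upstream[n]) for n in g.nodes}
    queue = [n for n in g.nodes if indeg[n] == 0]
    while queue:
        n = queue.pop()
        ups = [g.nodes[u]["strahler"] for u in upstream[n]]
        if not ups:
            order = 1
        else:
            top = max(ups)
            order = top + 1 if ups.count(top) >= 2 else top
        g.nodes[n]["strahler"] = order
        d = downstream.get(n)
        if d is not None:
            indeg[d] -= 1
            if indeg[d] == 0:
                queue.append(d)


# ---- shoreline -----------------------------------------------------------------


def extract_shoreline(dem: DemGrid, water_level: float) -> ShorelineRing:
    """Trace the boundary of the single submerged 4-connected region.

    Returns a counter-clockwise closed ring following cell edges between
    submerged (elevation < water_level) and dry cells.
    """
    submerged = (dem.elevations < water_level) & dem.valid()
    if not submerged.any():
        raise ValueError("no submerged cells at this water level")
    labels, ncomp = ndimage.label(submerged, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if ncomp != 1:
        sizes = ndimage.sum_labels(submerged, labels, index=range(1, ncomp + 1))
        raise ValueError(
            f"{ncomp} submerged components (sizes {[int(s) for s in sizes]}); expected one lake"
        )
    if submerged[0, :].any() or submerged[-1, :].any() or submerged[:, 0].any() or submerged[:, -1].any():
        raise ValueError("submerged region touches the grid edge (open boundary)")

    nr, nc = submerged.shape
    cs, x0, y0 = dem.cellsize, dem.xllcorner, dem.yllcorner

    def corner(r, c):
        # lattice corner at the NW of cell (r, c), in planar coords
        return (x0 + c * cs, y0 + (nr - r) * cs)

    # directed boundary edges keeping water on the left (CCW outer ring, y up)
    edges: dict[tuple, list[tuple]] = {}
    for r in range(nr):
        for c in range(nc):
            if not submerged[r, c]:
                continue
            nw, ne = corner(r, c), corner(r, c + 1)
            sw, se = corner(r + 1, c), corner(r + 1, c + 1)
            if r == 0 or not submerged[r - 1, c]:  # north side: walk west
                edges.setdefault(ne, []).append(nw)
            if r == nr - 1 or not submerged[r + 1, c]:  # south side: walk east
                edges.setdefault(sw, []).append(se)
            if c == 0 or not submerged[r, c - 1]:  # west side: walk south
                edges.setdefault(nw, []).append(sw)
            if c == nc - 1 or not submerged[r, c + 1]:  # east side: walk north
                edges.setdefault(se, []).append(ne)

    total_edges = sum(len(v) for v in edges.values())
    start = min(edges)
    ring = [start]
    prev_dir = None
    cur = start
    used = 0
    while True:
        outs = edges[cur]
        if len(outs) == 1 or prev_dir is None:
            nxt = outs[0]
        else:
            # corner where two diagonal water cells touch: take the left turn
            def turn(candidate):
                dx, dy = candidate[0] - cur[0], candidate[1] - cur[1]
                px, py = prev_dir
                return px * dy - py * dx  # cross product; left turn positive
            nxt = max(outs, key=turn)
        outs.remove(nxt)
        if not outs:
            del edges[cur]
        prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
        ring.append(nxt)
        used += 1
        cur = nxt
        if cur == start:
            break
    if used != total_edges:
        raise ValueError("boundary has multiple rings (island or lagoon?)")
    return ShorelineRing(_merge_collinear(np.array(ring, dtype=float)))


def _merge_collinear(ring: np.ndarray) -> np.ndarray:
    """Drop vertices interior to straight runs (keeps geometry, shrinks ring)."""
    keep = [ring[0]]
    for k in range(1, len(ring) - 1):
        a, b, c = keep[-1], ring[k], ring[k + 1]
        if (b[0] - a[0]) * (c[1] - b[1]) - (b[1] - a[1]) * (c[0] - b[0]) != 0:
            keep.append(b)
    keep.append(ring[-1])
    return np.array(keep)


# ---- snapping ------------------------------------------------------------------


def _nearest_on_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray):
    """(distance, offset along segment, foot point)."""
    ab = b - a
    L2 = float(ab @ ab)
    t = 0.0 if L2 == 0 else float(np.clip((p - a) @ ab / L2, 0.0, 1.0))
    foot = a + t * ab
    return float(np.linalg.norm(p - foot)), t * math.sqrt(L2), foot


def snap_points(sites: SampleSites, target) -> SampleSites:
    """Snap each site to the nearest point of a shoreline ring or stream network.

    Ties break toward the lower segment index. Returns a new SampleSites with
    snap positions, distances and (for shorelines) arc positions recorded.
    """
    if isinstance(target, ShorelineRing):
        segs = target.segments()
        cum = np.concatenate(
            [[0.0], np.cumsum([np.linalg.norm(b - a) for a, b in segs])]
        )
        arcs, xys, dists = [], [], []
        for p in sites.coords:
            best = (math.inf, -1, 0.0, None)
            for k, (a, b) in enumerate(segs):
                d, off, foot = _nearest_on_segment(p, a, b)
                if d < best[0] - 1e-12:
                    best = (d, k, off, foot)
            dists.append(best[0])
            arcs.append(cum[best[1]] + best[2])
            xys.append(best[3])
        return SampleSites(
            list(sites.ids),
            sites.coords.copy(),
            snap_kind="shoreline",
            snap_xy=np.array(xys),
            snap_dist=np.array(dists),
            snap_arc=np.array(arcs),
        )
    if isinstance(target, StreamNetwork):
        if not target.segments:
            raise ValueError("stream network has no segments to snap to")
        segids, offs, xys, dists = [], [], [], []
        for p in sites.coords:
            best = (math.inf, -1, 0.0, None)
            for k in range(len(target.segments)):
                a, b = target.segment_coords(k)
                d, off, foot = _nearest_on_segment(p, a, b)
                if d < best[0] - 1e-12:
                    best = (d, k, off, foot)
            dists.append(best[0])
            segids.append(best[1])
            offs.append(best[2])
            xys.append(best[3])
        return SampleSites(
            list(sites.ids),
            sites.coords.copy(),
            snap_kind="network",
            snap_xy=np.array(xys),
            snap_dist=np.array(dists),
            snap_seg=segids,
            snap_offset=np.array(offs),
        )
    raise TypeError(f"cannot snap to {type(target).__name__}")


# ---- distance matrices ---------------------------------------------------------


def euclidean_matrix(sites: SampleSites) -> DistanceMatrix:
    """Planar straight-line distances between recorded coordinates."""
    if sites.n < 2:
        raise ValueError("need at least 2 sites")
    return DistanceMatrix(list(sites.ids), cdist(sites.coords, sites.coords), "metres")


def shoreline_matrix(sites: SampleSites, ring: ShorelineRing) -> DistanceMatrix:
    """Shorter-arc distances along the shoreline between snapped positions."""
    if sites.snap_kind != "shoreline" or sites.snap_arc is None:
        raise ValueError("sites must be snapped to the shoreline first")
    P = ring.perimeter
    a = sites.snap_arc
    d = np.abs(a[:, None] - a[None, :])
    vals = np.minimum(d, P - d)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(sites.ids), vals, "metres")


def network_euclidean_matrix(sites: SampleSites, net: StreamNetwork) -> DistanceMatrix:
    """Straight-line distances between network-snapped positions."""
    if sites.snap_kind != "network" or sites.snap_xy is None:
        raise ValueError("sites must be snapped to the stream network first")
    return DistanceMatrix(list(sites.ids), cdist(sites.snap_xy, sites.snap_xy), "metres")


def network_path_matrix(sites: SampleSites, net: StreamNetwork) -> DistanceMatrix:
    """Undirected shortest-path lengths along the network between snapped sites.

    Snapped positions split their segments; pairs in different components get
    +inf (flagged disconnected, not an error).
    """
    if sites.snap_kind != "network" or sites.snap_seg is None:
        raise ValueError("sites must be snapped to the stream network first")
    g = net.graph.copy()
    site_nodes = []
    per_segment: dict[int, list[tuple[float, str]]] = {}
    for i, sid in enumerate(sites.ids):
        k = sites.snap_seg[i]
        off = float(sites.snap_offset[i])
        u, v = net.segments[k]
        length = net.graph.edges[u, v]["length"]
        node = ("site", sid)
        g.add_node(node)
        g.add_edge(node, u, length=off)
        g.add_edge(node, v, length=max(length - off, 0.0))
        per_segment.setdefault(k, []).append((off, node))
        site_nodes.append(node)
    # direct links between sites sharing a segment
    for entries in per_segment.values():
        for a in range(len(entries)):
            for b in range(a + 1, len(entries)):
                off_a, na = entries[a]
                off_b, nb = entries[b]
                w = abs(off_a - off_b)
                if not g.has_edge(na, nb) or g.edges[na, nb]["length"] > w:
                    g.add_edge(na, nb, length=w)

    n = sites.n
    vals = np.full((n, n), np.inf)
    np.fill_diagonal(vals, 0.0)
    for i, src in enumerate(site_nodes):
        lengths = nx.single_source_dijkstra_path_length(g, src, weight="length")
        for j, dst in enumerate(site_nodes):
            if dst in lengths:
                vals[i, j] = lengths[dst]
    vals = np.minimum(vals, vals.T)  # guard symmetry against float noise
    return DistanceMatrix(list(sites.ids), vals, "metres")
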