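"""Road-network simplification, equidistant sampling and street-level aggregation.

A vector road network (polylines with width/length/type attributes) is
simplified to centerlines the way raster-GIS workflows do it: rasterize at a
20 m cell, morphologically close small gaps around crossings and between the
carriageways of dual-lane roads, thin to a one-cell-wide skeleton
(Zhang–Suen), and trace the skeleton back to vector polylines whose
attributes are inherited (and, where carriageways merged, averaged) from the
source roads.  Sampling sites are then placed every 100 m of arc length along
the simplified roads, and per-site GVI values are aggregated to street level
as unweighted means, classed into five Jenks natural-breaks intervals.

Road types follow the seven-class taxonomy T1–T7: motorway, national way,
urban expressway, major road, minor road, provincial road, county road.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from scipy.ndimage import binary_closing
from skimage.draw import line as draw_line
from skimage.morphology import disk, skeletonize

__all__ = [
    "ROAD_TYPES",
    "CLASS_LABELS",
    "RoadPolyline",
    "RasterGrid",
    "SamplingSite",
    "StreetGVIRecord",
    "rasterize_fill_thin",
    "vectorize_centerlines",
    "sample_equidistant",
    "attach_nearest_svp",
    "aggregate_street_gvi",
    "classify_natural_breaks",
]

ROAD_TYPES = ("T1", "T2", "T3", "T4", "T5", "T6", "T7")

#: ascending five-class labels for natural-breaks GVI maps
CLASS_LABELS = ("very_low", "low", "medium", "high", "very_high")

DEFAULT_CELL_SIZE = 20.0  # metres
DEFAULT_SAMPLING_INTERVAL = 100.0  # metres
DEFAULT_SVP_RADIUS = 50.0  # metres


@dataclass
class RoadPolyline:
    """A road centerline in a projected metric CRS with its attributes."""

    road_id: str | int
    coordinates: np.ndarray  # (n, 2) planar metres
    width: float
    road_type: str
    length: float | None = None  # arc length; computed if omitted

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be an (n, 2) array")
        if len(self.coordinates) < 2:
            raise ValueError(f"road {self.road_id}: need >= 2 vertices")
        if self.road_type not in ROAD_TYPES:
            raise ValueError(f"road {self.road_id}: unknown road_type {self.road_type!r}")
        arc = float(LineString(self.coordinates).length)
        if self.length is None:
            self.length = arc
        elif arc > 0 and abs(self.length - arc) > 1e-3 * arc:
            raise ValueError(
                f"road {self.road_id}: declared length {self.length} differs from "
                f"arc length {arc:.2f} by more than 0.1%"
            )

    @property
    def geometry(self) -> LineString:
        return LineString(self.coordinates)


@dataclass
class RasterGrid:
    """Boolean occupancy raster in world coordinates.

    ``occupancy[row, col]`` covers the square with lower-left corner
    ``(origin_x + col*cell_size, origin_y + row*cell_size)``; row indices
    increase with y (northing).
    """

    occupancy: np.ndarray
    cell_size: float = DEFAULT_CELL_SIZE
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.occupancy = np.asarray(self.occupancy, dtype=bool)

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_size
        return np.stack([x, y], axis=-1)


@dataclass(frozen=True)
class SamplingSite:
    site_id: str | int
    coordinate: tuple[float, float]
    road_id: str | int
    chainage: float  # metres from the road's start vertex


@dataclass(frozen=True)
class StreetGVIRecord:
    road_id: str | int
    mean_gvi: float
    n_sites: int
    length: float
    width: float
    road_type: str
    gvi_class: str | None = None


def _looks_geographic(roads: Iterable[RoadPolyline]) -> bool:
    coords = np.concatenate([r.coordinates for r in roads], axis=0)
    return bool(
        np.all(np.abs(coords[:, 0]) <= 180.0) and np.all(np.abs(coords[:, 1]) <= 90.0)
    )


def rasterize_fill_thin(
    roads: Sequence[RoadPolyline],
    cell_size: float = DEFAULT_CELL_SIZE,
    fill_radius: int = 1,
) -> RasterGrid:
    """Rasterize roads, close gaps, and thin to a one-cell-wide skeleton.

    Steps: (1) burn every polyline into a boolean grid at ``cell_size``
    resolution (Bresenham lines between consecutive vertices); (2) fill gaps
    around crossings and between close parallel carriageways by morphological
    closing with a disk of ``fill_radius`` cells; (3) thin to an 8-connected
    skeleton with the Zhang–Suen algorithm.

    Raises
    ------
    ValueError
        If the coordinates look geographic (all within ±180°/±90°): geometry
        must be in a projected metric CRS.
    """
    if len(roads) == 0:
        raise ValueError("no roads to rasterize")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if _looks_geographic(roads):
        raise ValueError(
            "coordinates look like geographic degrees; project to a metric CRS first"
        )
    coords = np.concatenate([r.coordinates for r in roads], axis=0)
    margin = (fill_radius + 2) * cell_size
    x0 = float(coords[:, 0].min() - margin)
    y0 = float(coords[:, 1].min() - margin)
    n_cols = int(math.ceil((coords[:, 0].max() + margin - x0) / cell_size)) + 1
    n_rows = int(math.ceil((coords[:, 1].max() + margin - y0) / cell_size)) + 1

    occ = np.zeros((n_rows, n_cols), dtype=bool)
    for road in roads:
        cols = np.floor((road.coordinates[:, 0] - x0) / cell_size).astype(int)
        rows = np.floor((road.coordinates[:, 1] - y0) / cell_size).astype(int)
        for (r1, c1), (r2, c2) in zip(zip(rows, cols), zip(rows[1:], cols[1:])):
            rr, cc = draw_line(r1, c1, r2, c2)
            occ[rr, cc] = True

    if fill_radius > 0:
        occ = binary_closing(occ, structure=disk(fill_radius))
    skel = skeletonize(occ, method="zhang")
    skel = _prune_thick_cells(skel)
    return RasterGrid(occupancy=skel, cell_size=cell_size, origin=(x0, y0))


def _is_simple(occ: np.ndarray, r: int, c: int) -> bool:
    # removable without changing local 8-connectivity: the occupied
    # neighbourhood minus the cell stays one connected component
    from scipy.ndimage import label

    patch = occ[r - 1: r + 2, c - 1: c + 2].copy()
    patch[1, 1] = False
    if patch.sum() < 2:
        return False  # endpoint or isolated cell
    return label(patch, structure=np.ones((3, 3)))[1] == 1


def _prune_thick_cells(skel: np.ndarray) -> np.ndarray:
    """Remove residual 2x2 blocks the thinning pass can leave at X-crossings."""
    occ = skel.copy()
    for _ in range(8):
        blocks = occ[:-1, :-1] & occ[1:, :-1] & occ[:-1, 1:] & occ[1:, 1:]
        if not blocks.any():
            break
        progress = False
        for r, c in np.argwhere(blocks):
            cells = [(r + dr, c + dc) for dr in (0, 1) for dc in (0, 1)]
            cells.sort(key=lambda p: -occ[max(p[0] - 1, 0): p[0] + 2,
                                          max(p[1] - 1, 0): p[1] + 2].sum())
            for rr, cc in cells:
                if 0 < rr < occ.shape[0] - 1 and 0 < cc < occ.shape[1] - 1 \
                        and occ[rr, cc] and _is_simple(occ, rr, cc):
                    occ[rr, cc] = False
                    progress = True
                    break
        if not progress:
            break
    return occ


_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(occ: np.ndarray) -> tuple[dict[tuple[int, int], list[tuple[int, int]]], set]:
    cells = set(zip(*np.nonzero(occ)))
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r, c in cells:
        adj[(r, c)] = [(r + dr, c + dc) for dr, dc in _NEIGH if (r + dr, c + dc) in cells]
    # drop redundant diagonal links (a diagonal step bridged by an occupied
    # orthogonal cell) so staircase cells don't read as junctions
    for cell, nb in adj.items():
        pruned = []
        for other in nb:
            dr, dc = other[0] - cell[0], other[1] - cell[1]
            if dr != 0 and dc != 0:
                if (cell[0] + dr, cell[1]) in cells or (cell[0], cell[1] + dc) in cells:
                    continue
            pruned.append(other)
        adj[cell] = pruned
    nodes = {cell for cell, nb in adj.items() if len(nb) != 2}
    return adj, nodes


def vectorize_centerlines(
    grid: RasterGrid,
    source_roads: Sequence[RoadPolyline] | None = None,
    attribute_tolerance: float | None = None,
) -> list[RoadPolyline]:
    """Trace a thinned raster back to centerline polylines.

    The skeleton is interpreted as an 8-connected graph; polylines are the
    maximal paths between node cells (junctions and endpoints, i.e. cells of
    degree != 2), plus isolated cycles.  When ``source_roads`` is given, each
    traced polyline inherits attributes from every source road lying within
    ``attribute_tolerance`` metres of it (default ``(fill_radius+1)`` cells'
    worth, i.e. 2 cells): width is the mean over contributing roads — so a
    merged dual carriageway averages its lanes' widths — and the road type is
    the modal contributing type.  Without source roads, width 0 and type T5
    placeholders are assigned.
    """
    occ = grid.occupancy
    if not occ.any():
        return []
    if attribute_tolerance is None:
        attribute_tolerance = 2.0 * grid.cell_size

    adj, nodes = _skeleton_graph(occ)
    visited_edges: set[frozenset] = set()
    paths: list[list[tuple[int, int]]] = []

    def walk(start: tuple[int, int], nxt: tuple[int, int]) -> list[tuple[int, int]]:
        path = [start, nxt]
        prev, cur = start, nxt
        while cur not in nodes:
            candidates = [n for n in adj[cur] if n != prev]
            if not candidates:
                break
            prev, cur = cur, candidates[0]
            path.append(cur)
            if cur == start:  # closed loop back to a non-node start
                break
        return path

    for node in sorted(nodes):
        for nb in adj[node]:
            edge = frozenset((node, nb))
            if edge in visited_edges:
                continue
            path = walk(node, nb)
            for a, b in zip(path, path[1:]):
                visited_edges.add(frozenset((a, b)))
            if len(path) >= 2:
                paths.append(path)

    # pure cycles with no junction cell (every cell degree 2)
    seen_cells = {c for p in paths for c in p}
    for cell in sorted(adj):
        if cell in seen_cells or len(adj[cell]) != 2:
            continue
        path = walk(cell, adj[cell][0])
        for a, b in zip(path, path[1:]):
            visited_edges.add(frozenset((a, b)))
        seen_cells.update(path)
        if len(path) >= 2:
            paths.append(path)

    source_geoms = [r.geometry for r in source_roads] if source_roads else []
    out: list[RoadPolyline] = []
    for i, path in enumerate(paths):
        rows = np.array([p[0] for p in path])
        cols = np.array([p[1] for p in path])
        coords = grid.cell_center(rows, cols)
        geom = LineString(coords)
        width, rtype, rid = 0.0, "T5", f"C{i}"
        if source_roads:
            contrib = [
                r for r, g in zip(source_roads, source_geoms)
                if g.distance(geom) <= attribute_tolerance
            ]
            if contrib:
                width = float(np.mean([r.width for r in contrib]))
                types = [r.road_type for r in contrib]
                rtype = max(set(types), key=lambda t: (types.count(t), -ROAD_TYPES.index(t)))
                rid = "+".join(str(r.road_id) for r in contrib) + f"#{i}"
        out.append(RoadPolyline(road_id=rid, coordinates=coords, width=width, road_type=rtype))
    return out


def sample_equidistant(
    road: RoadPolyline,
    interval: float = DEFAULT_SAMPLING_INTERVAL,
    start_index: int = 0,
) -> list[SamplingSite]:
    """Place sampling sites every ``interval`` metres of arc length along a road.

    Sites sit at chainages 0, interval, 2*interval, ... up to the road length;
    a trailing remainder shorter than the interval yields no extra site, so a
    road of length L carries floor(L/interval) + 1 sites.  A zero-length road
    degenerates to a single site at its start.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    geom = road.geometry
    length = geom.length
    n = int(math.floor(length / interval + 1e-9)) + 1 if length > 0 else 1
    sites = []
    for k in range(n):
        chain = min(k * interval, length)
        pt: Point = geom.interpolate(chain)
        sites.append(
            SamplingSite(
                site_id=start_index + k,
                coordinate=(float(pt.x), float(pt.y)),
                road_id=road.road_id,
                chainage=float(chain),
            )
        )
    return sites


def attach_nearest_svp(
    sites: Sequence[SamplingSite],
    svp_locations: np.ndarray,
    max_radius: float = DEFAULT_SVP_RADIUS,
) -> dict[str | int, int | None]:
    """Match each site to the nearest picture location within ``max_radius`` metres.

    Returns a mapping site_id -> index into ``svp_locations`` (or None when no
    location lies within the radius; being unmatched is a value, not an
    error).  The radius is inclusive: a picture exactly at ``max_radius``
    matches.
    """
    from scipy.spatial import cKDTree

    svp = np.asarray(svp_locations, dtype=np.float64)
    out: dict[str | int, int | None] = {}
    if svp.size == 0:
        return {s.site_id: None for s in sites}
    tree = cKDTree(svp)
    pts = np.array([s.coordinate for s in sites])
    dist, idx = tree.query(pts)
    for s, d, i in zip(sites, dist, idx):
        out[s.site_id] = int(i) if d <= max_radius else None
    return out


def aggregate_street_gvi(
    sites_with_gvi: pd.DataFrame,
    roads: Sequence[RoadPolyline],
    k_classes: int = 5,
    classify: bool = True,
) -> list[StreetGVIRecord]:
    """Aggregate per-site GVI to street level as unweighted means.

    ``sites_with_gvi`` needs columns ``road_id`` and ``gvi``.  Each road's
    record carries the site count and the road's attributes; roads with no
    sites are omitted.  When ``classify`` is set and enough distinct means
    exist, the street means are classed into ``k_classes`` natural-breaks
    intervals labelled very_low ... very_high.
    """
    grouped = sites_with_gvi.groupby("road_id")["gvi"].agg(["mean", "count"])
    by_id = {r.road_id: r for r in roads}
    records = []
    for road_id, row in grouped.iterrows():
        road = by_id.get(road_id)
        records.append(
            StreetGVIRecord(
                road_id=road_id,
                mean_gvi=float(row["mean"]),
                n_sites=int(row["count"]),
                length=road.length if road else float("nan"),
                width=road.width if road else float("nan"),
                road_type=road.road_type if road else "T5",
            )
        )
    if classify and len({r.mean_gvi for r in records}) >= k_classes:
        _, labels = classify_natural_breaks([r.mean_gvi for r in records], k=k_classes)
        records = [
            StreetGVIRecord(
                r.road_id, r.mean_gvi, r.n_sites, r.length, r.width, r.road_type, lab
            )
            for r, lab in zip(records, labels)
        ]
    return records


def classify_natural_breaks(
    values: Sequence[float], k: int = 5
) -> tuple[np.ndarray, list[str]]:
    """Jenks natural-breaks classification of 1-D values into k classes.

    Finds the partition of the sorted values into k contiguous classes that
    minimizes the total within-class sum of squared deviations (Fisher–Jenks
    dynamic programming, exact).  Returns the k+1 class edges (data values:
    minimum, the k-1 upper break values, maximum) and a per-input label list
    — ``very_low ... very_high`` for k = 5, ``class_1 ... class_k`` otherwise.

    Raises
    ------
    ValueError
        If fewer than k distinct values are supplied.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.ndim != 1 or vals.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    if len(np.unique(vals)) < k:
        raise ValueError(f"need at least {k} distinct values for {k} classes")

    order = np.argsort(vals, kind="stable")
    v = vals[order]
    n = v.size
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csum2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def ssd(i: int, j: int) -> float:
        # within-class SSD of v[i..j] inclusive
        m = j - i + 1
        s = csum[j + 1] - csum[i]
        return (csum2[j + 1] - csum2[i]) - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                t = cost[c - 1, i] + ssd(i, j - 1)
                if t < best:
                    best, arg = t, i
            cost[c, j], back[c, j] = best, arg

    # recover class boundaries (start indices)
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = back[c, j]
        bounds.append(j)
    bounds.reverse()  # [0, i1, ..., n]

    edges = np.empty(k + 1)
    edges[0] = v[0]
    for c in range(1, k + 1):
        edges[c] = v[bounds[c] - 1]

    labels_for_k = list(CLASS_LABELS) if k == 5 else [f"class_{i+1}" for i in range(k)]
    class_of_sorted = np.empty(n, dtype=int)
    for c in range(k):
        class_of_sorted[bounds[c]: bounds[c + 1]] = c
    class_of_input = np.empty(n, dtype=int)
    class_of_input[order] = class_of_sorted
    return edges, [labels_for_k[c] for c in class_of_input]
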