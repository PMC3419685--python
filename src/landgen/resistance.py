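"""Cost surfaces, least-cost distances, and circuit-theory resistance.

A cost surface assigns a positive traversal cost to every non-NODATA cell of
a land-cover raster.  Cells are nodes of an 8-connected grid graph; moving
between neighbouring cells costs cellsize x (c_from + c_to)/2, scaled by
sqrt(2) for diagonal moves — the COSTDISTANCE convention.  Least-cost
distance is the Dijkstra shortest path on that graph.  Resistance distance
treats each edge as a resistor of that same value and returns the effective
electrical resistance between two cells, which integrates all parallel
routes rather than only the single best one; current maps accumulate the
per-cell current magnitude when every sampled group injects current
(scaled to its size) toward one grounded focal group in turn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu
from scipy.spatial.distance import squareform, pdist

from landgen.matrices import PairwiseMatrix
from landgen.rasters import LandscapeRaster

SQRT2 = float(np.sqrt(2.0))

#: default circuit scenario: expansive plantation matrix at moderate cost,
#: everything else cheap
DEFAULT_CIRCUIT_COSTS = {
    "forest": 1.0,
    "oil_palm": 20.0,
    "pasture": 2.0,
    "river": 2.0,
    "residential": 5.0,
    "other": 2.0,
}


@dataclass
class CostSurface:
    """Per-cell positive traversal costs tied to a raster's geometry."""

    raster: LandscapeRaster
    costs: np.ndarray  # (nrows, ncols) float, nan at NODATA
    provenance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.costs = np.asarray(self.costs, dtype=float)
        valid = ~np.isnan(self.costs)
        if not (self.costs[valid] > 0).all():
            raise ValueError("traversal costs must be positive")

    @property
    def cellsize(self) -> float:
        return self.raster.cellsize


@dataclass
class ResistanceResult:
    """Pairwise effective resistances and/or a cumulative current map."""

    matrix: PairwiseMatrix | None
    current: np.ndarray | None
    tol: float
    residual: float


def build_cost_surface(
    raster: LandscapeRaster, focal_class: str, cost: float
) -> CostSurface:
    """One-class surface: focal-class cells get ``cost``, all others cost 1."""
    code = raster.code_of(focal_class)
    if cost < 1:
        raise ValueError("focal cost must be >= 1")
    if not (raster.data == code).any():
        warnings.warn(f"class {focal_class!r} absent from raster: uniform surface")
    costs = np.where(raster.data == code, float(cost), 1.0)
    costs[~raster.valid] = np.nan
    return CostSurface(raster=raster, costs=costs, provenance={focal_class: cost})


def build_multiclass_surface(
    raster: LandscapeRaster, class_costs: dict[str, float] | None = None
) -> CostSurface:
    """Surface with one cost per land-cover class (circuit-map scenario)."""
    class_costs = dict(DEFAULT_CIRCUIT_COSTS) if class_costs is None else class_costs
    costs = np.full(raster.data.shape, np.nan)
    for code, name in raster.legend.items():
        if name not in class_costs:
            raise ValueError(f"no cost given for class {name!r}")
        costs[raster.data == code] = float(class_costs[name])
    costs[~raster.valid] = np.nan
    return CostSurface(raster=raster, costs=costs, provenance=dict(class_costs))


# ---------------------------------------------------------------------------
# grid graph construction

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, 1)]  # upper half; symmetric


def _grid_edges(surface: CostSurface):
    """Edge list (u, v, weight) over valid cells, nodes indexed row-major."""
    costs = surface.costs
    nrows, ncols = costs.shape
    cellsize = surface.cellsize
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    valid = ~np.isnan(costs)
    us, vs, ws = [], [], []
    for dr, dc in _NEIGHBOURS:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        r1 = slice(max(0, dr), nrows + min(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        c1 = slice(max(0, dc), ncols + min(0, dc))
        ok = valid[r0, c0] & valid[r1, c1]
        w = cellsize * 0.5 * (costs[r0, c0] + costs[r1, c1])
        if dr != 0 and dc != 0:
            w = w * SQRT2
        us.append(idx[r0, c0][ok])
        vs.append(idx[r1, c1][ok])
        ws.append(w[ok])
    return np.concatenate(us), np.concatenate(vs), np.concatenate(ws)


def _grid_graph(surface: CostSurface) -> sparse.csr_matrix:
    n = surface.costs.size
    u, v, w = _grid_edges(surface)
    g = sparse.coo_matrix((np.concatenate([w, w]),
                           (np.concatenate([u, v]), np.concatenate([v, u]))),
                          shape=(n, n))
    return g.tocsr()


def snap_points(surface: CostSurface, coords: np.ndarray) -> np.ndarray:
    """Node index (row-major) of the valid cell containing each point."""
    nodes = []
    for x, y in np.asarray(coords, dtype=float):
        row, col = surface.raster.xy_to_rowcol(x, y)
        if np.isnan(surface.costs[row, col]):
            raise ValueError(f"point ({x}, {y}) snaps to a NODATA cell")
        nodes.append(row * surface.costs.shape[1] + col)
    return np.asarray(nodes, dtype=np.int64)


# ---------------------------------------------------------------------------
# distances


def least_cost_matrix(
    surface: CostSurface, coords: np.ndarray, ids: list[str] | None = None
) -> PairwiseMatrix:
    """All-pairs least-cost (Dijkstra) distances between snapped points.

    Point pairs in disconnected graph components get infinite distance.
    """
    coords = np.asarray(coords, dtype=float)
    nodes = snap_points(surface, coords)
    graph = _grid_graph(surface)
    uniq, inverse = np.unique(nodes, return_inverse=True)
    dist = csgraph.dijkstra(graph, directed=False, indices=uniq)[:, uniq]
    values = dist[inverse][:, inverse]
    values = 0.5 * (values + values.T)  # exact symmetry
    np.fill_diagonal(values, 0.0)
    if np.isinf(values).any():
        warnings.warn("some point pairs are in disconnected components (inf)")
    if ids is None:
        ids = [f"p{i}" for i in range(len(coords))]
    return PairwiseMatrix(ids=list(ids), values=values, kind="least_cost")


def euclidean_matrix(
    coords: np.ndarray, ids: list[str] | None = None
) -> PairwiseMatrix:
    """Planar straight-line distances (projected metric coordinates)."""
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    values = squareform(pdist(coords))
    if ids is None:
        ids = [f"p{i}" for i in range(len(coords))]
    return PairwiseMatrix(ids=list(ids), values=values, kind="euclidean")


# ---------------------------------------------------------------------------
# circuit theory


def _conductance_laplacian(surface: CostSurface):
    """Graph Laplacian with per-edge conductance = 1/edge resistance."""
    n = surface.costs.size
    u, v, w = _grid_edges(surface)
    c = 1.0 / w
    adj = sparse.coo_matrix(
        (np.concatenate([c, c]), (np.concatenate([u, v]), np.concatenate([v, u]))),
        shape=(n, n),
    ).tocsr()
    deg = sparse.diags(np.asarray(adj.sum(axis=1)).ravel())
    return (deg - adj).tocsc(), adj


def resistance_matrix(
    surface: CostSurface,
    coords: np.ndarray,
    ids: list[str] | None = None,
    tol: float = 1e-8,
) -> ResistanceResult:
    """All-pairs effective resistance between snapped points.

    One node per solve is grounded (the component's first point); effective
    resistance comes from the textbook identity
    R_ij = v_i(i) + v_j(j) - 2 v_i(j) with L v_p = e_p on the grounded
    Laplacian.  Disconnected pairs are infinite.
    """
    coords = np.asarray(coords, dtype=float)
    nodes = snap_points(surface, coords)
    lap, adj = _conductance_laplacian(surface)
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    m = len(nodes)
    values = np.full((m, m), np.inf)
    np.fill_diagonal(values, 0.0)
    residual = 0.0
    for comp in np.unique(labels[nodes]):
        in_comp = np.flatnonzero(labels == comp)
        pts = np.flatnonzero(labels[nodes] == comp)
        if len(pts) < 2:
            continue
        pos = {node: k for k, node in enumerate(in_comp)}
        sub = lap[np.ix_(in_comp, in_comp)].tocsc()
        ground = pos[nodes[pts[0]]]
        keep = np.ones(len(in_comp), dtype=bool)
        keep[ground] = False
        reduced = sub[np.ix_(keep, keep)].tocsc()
        lu = splu(reduced)
        kept_index = np.cumsum(keep) - 1  # position within reduced system
        volts = {}
        for p in pts[1:]:
            b = np.zeros(keep.sum())
            b[kept_index[pos[nodes[p]]]] = 1.0
            v = lu.solve(b)
            residual = max(residual, float(np.abs(reduced @ v - b).max()))
            volts[p] = v
        for ii, p in enumerate(pts):
            for q in pts[ii + 1 :]:
                kp = nodes[p]
                kq = nodes[q]
                if p == pts[0]:
                    r = volts[q][kept_index[pos[kq]]]
                else:
                    vp, vq = volts[p], volts[q]
                    r = (
                        vp[kept_index[pos[kp]]]
                        + vq[kept_index[pos[kq]]]
                        - 2.0 * vp[kept_index[pos[kq]]]
                    )
                values[p, q] = values[q, p] = float(r)
    if residual > tol:
        raise RuntimeError(f"linear solve residual {residual:.3e} exceeds tol {tol}")
    if ids is None:
        ids = [f"p{i}" for i in range(m)]
    mat = PairwiseMatrix(ids=list(ids), values=values, kind="resistance")
    return ResistanceResult(matrix=mat, current=None, tol=tol, residual=residual)


def current_map(
    surface: CostSurface,
    group_coords: np.ndarray,
    group_sizes: np.ndarray,
    mode: str = "all_to_one",
    buffer: float = 10000.0,
    tol: float = 1e-8,
) -> ResistanceResult:
    """Cumulative all-to-one current map over the grid.

    Each sampled group is grounded in turn while every other group injects
    current proportional to its size; per-cell current magnitudes (half the
    sum of absolute incident edge currents) accumulate across focal choices.
    ``buffer`` clips the grid to cells within that distance (metres) of the
    groups' bounding box before solving.
    """
    if mode != "all_to_one":
        raise ValueError("only the all_to_one mode is implemented")
    group_coords = np.asarray(group_coords, dtype=float)
    group_sizes = np.asarray(group_sizes, dtype=float)
    if len(group_coords) < 2:
        raise ValueError("need at least 2 groups")

    surface = _clip_to_buffer(surface, group_coords, buffer)
    nodes = snap_points(surface, group_coords)
    lap, adj = _conductance_laplacian(surface)
    u, v, w = _grid_edges(surface)
    cond = 1.0 / w
    n = surface.costs.size
    cumulative = np.zeros(n)
    residual = 0.0
    for focal in range(len(nodes)):
        ground = nodes[focal]
        keep = np.ones(n, dtype=bool)
        keep[ground] = False
        # drop isolated / NODATA nodes to keep the system nonsingular
        deg = np.asarray(adj.sum(axis=1)).ravel()
        keep &= deg > 0
        inj = np.zeros(n)
        for other in range(len(nodes)):
            if other != focal:
                inj[nodes[other]] += group_sizes[other]
        reduced = lap[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))].tocsc()
        b = inj[keep]
        sol = splu(reduced).solve(b)
        residual = max(residual, float(np.abs(reduced @ sol - b).max()))
        volts = np.zeros(n)
        volts[keep] = sol
        edge_cur = cond * (volts[u] - volts[v])
        node_cur = np.zeros(n)
        np.add.at(node_cur, u, np.abs(edge_cur))
        np.add.at(node_cur, v, np.abs(edge_cur))
        cumulative += 0.5 * node_cur
    if residual > tol:
        raise RuntimeError(f"linear solve residual {residual:.3e} exceeds tol {tol}")
    return ResistanceResult(
        matrix=None,
        current=cumulative.reshape(surface.costs.shape),
        tol=tol,
        residual=residual,
    )


def _clip_to_buffer(
    surface: CostSurface, coords: np.ndarray, buffer: float
) -> CostSurface:
    r = surface.raster
    rows, cols = [], []
    for x, y in coords:
        row, col = r.xy_to_rowcol(x, y)
        rows.append(row)
        cols.append(col)
    pad = int(np.ceil(buffer / r.cellsize))
    r0 = max(0, min(rows) - pad)
    r1 = min(r.nrows, max(rows) + pad + 1)
    c0 = max(0, min(cols) - pad)
    c1 = min(r.ncols, max(cols) + pad + 1)
    if (r0, r1, c0, c1) == (0, r.nrows, 0, r.ncols):
        return surface
    clipped = LandscapeRaster(
        data=r.data[r0:r1, c0:c1],
        xllcorner=r.xllcorner + c0 * r.cellsize,
        yllcorner=r.yllcorner + (r.nrows - r1) * r.cellsize,
        cellsize=r.cellsize,
        nodata=r.nodata,
        legend=dict(r.legend),
    )
    return CostSurface(
        raster=clipped,
        costs=surface.costs[r0:r1, c0:c1],
        provenance=dict(surface.provenance),
    )


# ---------------------------------------------------------------------------
# residential-area classifier


def classify_residential(
    residence_mask: np.ndarray,
    cellsize: float,
    linkage_distance: float = 100.0,
    min_area_m2: float = 30000.0,
) -> np.ndarray:
    """Merge residences closer than 100 m and keep clusters above 3 ha.

    Residence cells are dilated by half the linkage distance (50 m), so two
    footprints whose dilations touch are less than 100 m apart; 8-connected
    components of the dilated mask define clusters (single linkage).
    Clusters whose *original* footprint area strictly exceeds 3 ha become
    class ``residential`` (code 5); smaller ones fall to ``other`` (code 6).
    Returns an int raster with codes {0, 5, 6}.
    """
    residence_mask = np.asarray(residence_mask, dtype=bool)
    radius_cells = 0.5 * linkage_distance / cellsize
    r = int(np.floor(radius_cells))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    structure = (dy**2 + dx**2) * cellsize**2 <= (0.5 * linkage_distance) ** 2
    dilated = ndimage.binary_dilation(residence_mask, structure=structure)
    labels, n_clusters = ndimage.label(dilated, structure=np.ones((3, 3)))
    out = np.zeros(residence_mask.shape, dtype=np.int64)
    for lbl in range(1, n_clusters + 1):
        cells = residence_mask & (labels == lbl)
        area = cells.sum() * cellsize**2
        out[cells] = 5 if area > min_area_m2 else 6
    return out
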