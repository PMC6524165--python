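"""Geometric-graph analysis of single-molecule localization data.

A localization table is a list of fluorophore coordinates in nm.  It can be
rendered into a pixel image (Gaussian accumulation or plain binning) and fed
to the ridge-filter pipeline, or analyzed directly through the classical
geometric graphs: the Delaunay triangulation (empty-circumcircle triangles),
its dual Voronoi tessellation (cell areas approximate reciprocal local
density), the Euclidean minimum spanning tree (EMST, the shortest subtree of
the Delaunay graph connecting every localization), and the nearest-neighbor
graph (NNG, a subgraph of the EMST whose edge lengths measure density and
clustering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import Delaunay, Voronoi, cKDTree, QhullError

from laminmesh.types import LocalizationSet, RasterImage

logger = logging.getLogger(__name__)


@dataclass
class GeometricGraph:
    kind: str  # delaunay | voronoi | emst | nng
    vertices: np.ndarray  # (n, 2) nm coordinates
    edges: np.ndarray  # (m, 2) vertex index pairs
    lengths: np.ndarray  # (m,) Euclidean edge lengths (nm)
    triangles: np.ndarray = None  # type: ignore[assignment]  # delaunay only
    triangle_areas: np.ndarray = None  # type: ignore[assignment]
    cells: list = field(default_factory=list)  # voronoi: polygons per input point
    cell_areas: np.ndarray = None  # type: ignore[assignment]  # nan if unbounded
    cell_unbounded: np.ndarray = None  # type: ignore[assignment]
    nn_distances: np.ndarray = None  # type: ignore[assignment]  # nng only
    n_duplicates_merged: int = 0


def _dedup(locs: LocalizationSet) -> tuple[np.ndarray, int]:
    """Merge coincident points, preserving first-occurrence order."""
    _, idx = np.unique(locs.points, axis=0, return_index=True)
    pts = locs.points[np.sort(idx)]
    n_dup = len(locs.points) - len(pts)
    if n_dup:
        logger.info("merged %d coincident duplicate localizations", n_dup)
    return pts, n_dup


def render_localizations(
    locs: LocalizationSet,
    pixel_nm: float = 20.0,
    mode: str = "gaussian",
    sigma_nm: float = 20.0,
    pad_px: int = 2,
) -> RasterImage:
    """Render a localization set onto a pixel grid.

    ``binning`` adds 1 to the containing pixel of each point (half-open bins,
    image sum = n exactly); ``gaussian`` accumulates a unit-integral 2D
    Gaussian per point, integrated over each pixel (separable erf
    differences) and truncated at 4 sigma, so the image sum is n up to
    truncation loss and the rendering tends to plain binning as sigma -> 0.
    The grid origin is the floor of the bounding-box minimum minus ``pad_px``
    pixels.
    """
    if len(locs) < 1:
        raise ValueError("cannot render an empty localization set")
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be positive")
    if mode not in ("gaussian", "binning"):
        raise ValueError(f"mode must be 'gaussian' or 'binning', got {mode!r}")
    x, y = locs.points[:, 0], locs.points[:, 1]
    if mode == "gaussian":
        # enough margin that border points keep their full (truncated) mass
        pad_px = max(pad_px, int(np.ceil(4.0 * sigma_nm / pixel_nm)) + 1)
    col0 = int(np.floor(x.min() / pixel_nm)) - pad_px
    row0 = int(np.floor(y.min() / pixel_nm)) - pad_px
    ncol = int(np.floor(x.max() / pixel_nm)) - col0 + 1 + pad_px
    nrow = int(np.floor(y.max() / pixel_nm)) - row0 + 1 + pad_px
    img = np.zeros((nrow, ncol))
    if mode == "binning":
        cols = np.floor(x / pixel_nm).astype(int) - col0
        rows = np.floor(y / pixel_nm).astype(int) - row0
        np.add.at(img, (rows, cols), 1.0)
    else:
        if sigma_nm <= 0:
            raise ValueError("sigma_nm must be positive for gaussian rendering")
        from scipy.special import ndtr

        sig_px = sigma_nm / pixel_nm
        rad = max(int(np.ceil(4.0 * sig_px)) + 1, 1)

        def axis_weights(coord_px: float, n: int) -> tuple[np.ndarray, int]:
            # mass of N(coord_px, sig_px) in each pixel [k, k+1) near the point
            k0 = max(int(np.floor(coord_px)) - rad, 0)
            k1 = min(int(np.floor(coord_px)) + rad + 1, n - 1)
            edges = np.arange(k0, k1 + 2, dtype=float)
            cdf = ndtr((edges - coord_px) / sig_px)
            return np.diff(cdf), k0

        for xi, yi in zip(x, y):
            wc, c0 = axis_weights(xi / pixel_nm - col0, ncol)
            wr, r0 = axis_weights(yi / pixel_nm - row0, nrow)
            img[r0 : r0 + len(wr), c0 : c0 + len(wc)] += np.outer(wr, wc)
    out = RasterImage(img, pixel_nm)
    out.origin_px = (row0, col0)
    return out


def _edge_lengths(pts: np.ndarray, edges: np.ndarray) -> np.ndarray:
    if len(edges) == 0:
        return np.zeros(0)
    d = pts[edges[:, 0]] - pts[edges[:, 1]]
    return np.hypot(d[:, 0], d[:, 1])


def delaunay_graph(locs: LocalizationSet) -> GeometricGraph:
    """Delaunay triangulation: every triangle's circumcircle is empty."""
    pts, n_dup = _dedup(locs)
    if len(pts) < 3:
        raise ValueError("Delaunay triangulation needs at least 3 distinct points")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate input (collinear points?): {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("degenerate input: all points collinear")
    edges = set()
    for s in tri.simplices:
        for a, b in ((s[0], s[1]), (s[1], s[2]), (s[0], s[2])):
            edges.add((min(a, b), max(a, b)))
    edges = np.array(sorted(edges))
    p = pts[tri.simplices]
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    return GeometricGraph(
        kind="delaunay",
        vertices=pts,
        edges=edges,
        lengths=_edge_lengths(pts, edges),
        triangles=tri.simplices.copy(),
        triangle_areas=areas,
        n_duplicates_merged=n_dup,
    )


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_tessellation(locs: LocalizationSet) -> GeometricGraph:
    """Voronoi tessellation: cell boundaries equidistant between localizations.

    Unbounded boundary cells are flagged and excluded from area statistics
    (their area is reported as NaN); ``1 / cell_area`` of a bounded cell is
    the local density proxy.
    """
    pts, n_dup = _dedup(locs)
    if len(pts) < 2:
        raise ValueError("Voronoi tessellation needs at least 2 distinct points")
    if len(pts) == 2:
        return _voronoi_two_points(pts, n_dup)
    try:
        vor = Voronoi(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate input (collinear points?): {exc}") from exc
    finite_edges = np.array(
        [rv for rv in vor.ridge_vertices if -1 not in rv], dtype=int
    ).reshape(-1, 2)
    cells, areas, unbounded = [], [], []
    for pi in range(len(pts)):
        region = vor.regions[vor.point_region[pi]]
        if len(region) == 0 or -1 in region:
            cells.append(None)
            areas.append(np.nan)
            unbounded.append(True)
        else:
            poly = vor.vertices[region]
            cells.append(poly)
            areas.append(_polygon_area(poly))
            unbounded.append(False)
    return GeometricGraph(
        kind="voronoi",
        vertices=vor.vertices,
        edges=finite_edges,
        lengths=_edge_lengths(vor.vertices, finite_edges),
        cells=cells,
        cell_areas=np.array(areas),
        cell_unbounded=np.array(unbounded),
        n_duplicates_merged=n_dup,
    )


def _voronoi_two_points(pts: np.ndarray, n_dup: int) -> GeometricGraph:
    """Two points: the diagram is their perpendicular bisector (one infinite edge)."""
    mid = pts.mean(axis=0)
    d = pts[1] - pts[0]
    perp = np.array([-d[1], d[0]])
    perp = perp / np.hypot(*perp)
    span = 10.0 * np.hypot(*d)
    verts = np.array([mid - span * perp, mid + span * perp])
    return GeometricGraph(
        kind="voronoi",
        vertices=verts,
        edges=np.array([[0, 1]]),
        lengths=_edge_lengths(verts, np.array([[0, 1]])),
        cells=[None, None],
        cell_areas=np.array([np.nan, np.nan]),
        cell_unbounded=np.array([True, True]),
        n_duplicates_merged=n_dup,
    )


def emst(locs: LocalizationSet) -> GeometricGraph:
    """Euclidean minimum spanning tree over the Delaunay edge set.

    Connected with exactly n-1 edges; coincident duplicates are merged first.
    Collinear inputs (no triangulation) fall back to the complete graph.
    """
    pts, n_dup = _dedup(locs)
    if len(pts) < 2:
        raise ValueError("EMST needs at least 2 distinct points")
    if len(pts) == 2:
        edges = np.array([[0, 1]])
    else:
        try:
            dg = delaunay_graph(LocalizationSet(pts))
            cand = dg.edges
        except ValueError:
            ii, jj = np.triu_indices(len(pts), k=1)
            cand = np.stack([ii, jj], axis=1)
        w = _edge_lengths(pts, cand)
        n = len(pts)
        graph = sparse.coo_matrix((w, (cand[:, 0], cand[:, 1])), shape=(n, n))
        mst = minimum_spanning_tree(graph.tocsr())
        ii, jj = mst.nonzero()
        edges = np.stack([np.minimum(ii, jj), np.maximum(ii, jj)], axis=1)
        edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))]
    return GeometricGraph(
        kind="emst",
        vertices=pts,
        edges=edges,
        lengths=_edge_lengths(pts, edges),
        n_duplicates_merged=n_dup,
    )


def nng(locs: LocalizationSet) -> GeometricGraph:
    """Nearest-neighbor graph and per-point nearest-neighbor distances.

    Each localization links to its closest neighbor; the directed links are
    reported as an undirected unique edge set, plus all n distances.
    """
    pts, n_dup = _dedup(locs)
    if len(pts) < 2:
        raise ValueError("nearest-neighbor graph needs at least 2 distinct points")
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=2)
    nn_dist = dist[:, 1]
    nn_idx = idx[:, 1]
    pairs = {(min(i, int(j)), max(i, int(j))) for i, j in enumerate(nn_idx)}
    edges = np.array(sorted(pairs))
    return GeometricGraph(
        kind="nng",
        vertices=pts,
        edges=edges,
        lengths=_edge_lengths(pts, edges),
        nn_distances=nn_dist,
        n_duplicates_merged=n_dup,
    )
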