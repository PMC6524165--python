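"""Self-validation benchmarks: recompute the package's headline checks from scratch.

Each function runs one verifiable property of the pipeline end to end —
closed-form resolution numbers, the widefield phase-sum identity, steering
exactness against direct convolution, exhaustive classifier oracles, the
geometric-graph inclusion chain, phantom meshwork recovery, and the Euler
relation on rasterized planar meshes.  The test suite asserts on these
results and ``scripts/acceptance.py`` reports them as numbers; the oracles
used here (brute-force enumeration, complete-graph MST, direct convolution)
are deliberately independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from laminmesh import nucleus_mask as nm
from laminmesh import pipeline, simqc, skeleton_graph as sg, smlm_graph as smg, synthetic
from laminmesh.nucleus_mask import NucleusMask
from laminmesh.steerable import FilterBank, SteerableFilterConfig, detect_orientations
from laminmesh.types import LocalizationSet, RasterImage, Skeleton


# ---------------------------------------------------------------------------
# closed-form resolution arithmetic
# ---------------------------------------------------------------------------

def resolution_numbers() -> dict:
    """Rayleigh/Nyquist numbers for 525 nm emission at NA 1.49, eta 1.52.

    Linear SIM doubles both limits; the pixel-size bound is half the ~115 nm
    SIM lateral resolution.
    """
    p = simqc.ResolutionParams(lambda_nm=525.0, na=1.49, eta=1.52)
    lateral = simqc.rayleigh_lateral(p)
    axial = simqc.rayleigh_axial(p)
    sim_lateral_nm = 115.0  # the conventional "~2x better" figure for linear SIM
    return {
        "rayleigh_lateral_nm": lateral,
        "rayleigh_axial_nm": axial,
        # 3D-SIM halves the (nearest-nm) widefield axial limit
        "sim_axial_nm": round(axial) / 2.0,
        "nyquist_pixel_bound_nm": simqc.nyquist_pixel_bound(sim_lateral_nm),
    }


# ---------------------------------------------------------------------------
# widefield phase-sum identity
# ---------------------------------------------------------------------------

def widefield_identity_error(seed: int = 0, size: int = 256) -> float:
    """Worst relative error of widefield synthesis over P in {2, 3, 5}."""
    rng = np.random.default_rng(seed)
    obj = RasterImage(rng.random((size, size)) + 0.5, 32.0)
    worst = 0.0
    for n_phases in (2, 3, 5):
        model = synthetic.IlluminationModel(n_phases=n_phases)
        stack = synthetic.make_sim_raw(obj, model)
        wf = simqc.synthesize_widefield(stack)
        err = np.abs(wf.widefield.pixels - obj.pixels).max() / obj.pixels.max()
        worst = max(worst, float(err))
    return worst


# ---------------------------------------------------------------------------
# steering equivalence
# ---------------------------------------------------------------------------

def steering_equivalence_error(
    n_seeds: int = 20, seed0: int = 0, size: int = 64, n_dense: int = 361
) -> float:
    """Max relative gap between the analytic maximal response and the max of
    direct convolutions with rotated kernels over a dense angle grid."""
    cfg = SteerableFilterConfig()
    bank = FilterBank(cfg)
    pad = bank.radius
    angles = np.arange(n_dense) * np.pi / n_dense
    kernels = [bank.kernel_at(t) for t in angles]
    worst = 0.0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed0 + k)
        img = rng.random((size, size))
        field = detect_orientations(RasterImage(img, 32.0), cfg)
        padded = np.pad(img, pad, mode="reflect")
        dense = np.full((size, size), -np.inf)
        for kern in kernels:
            # even-symmetric kernel: convolution == correlation
            resp = fftconvolve(padded, kern, mode="valid")
            np.maximum(dense, resp, out=dense)
        scale = np.abs(field.response).max()
        worst = max(worst, float(np.abs(field.response - dense).max() / scale))
    return worst


# ---------------------------------------------------------------------------
# exhaustive branch-point oracle
# ---------------------------------------------------------------------------

def branchpoint_oracle_agreement() -> float:
    """Fraction of all 512 3x3 neighborhoods where the classifier matches a
    brute-force evaluation of the branch-point predicate (scipy labeling)."""
    agree = 0
    total = 0
    for center in (False, True):
        for code in range(256):
            neigh = np.zeros((3, 3), bool)
            neigh[1, 1] = center
            for i, (dr, dc) in enumerate(sg._OFFSETS):
                if code >> i & 1:
                    neigh[1 + dr, 1 + dc] = True
            img = np.zeros((5, 5), bool)
            img[1:4, 1:4] = neigh
            cls = sg.find_branchpoints(Skeleton(img, np.zeros((5, 5))))
            got = cls[2, 2]
            if not center:
                want = sg.BACKGROUND
            else:
                whites = int(neigh.sum()) - 1
                if whites <= 1:
                    want = sg.ENDPOINT
                else:
                    want = sg.EDGE_PIXEL
                    if whites >= 3:
                        black = ~neigh.copy()
                        black[1, 1] = False
                        _, n_black = ndimage.label(
                            black, structure=ndimage.generate_binary_structure(2, 1)
                        )
                        if n_black >= 2:
                            want = sg.BRANCHPOINT
            agree += int(got == want)
            total += 1
    return agree / total


# ---------------------------------------------------------------------------
# hysteresis oracle
# ---------------------------------------------------------------------------

def hysteresis_oracle_agreement(n_grids: int = 500, seed0: int = 0) -> float:
    """Fraction of random 16x16 grids where hysteresis at the 95th/70th
    percentiles matches brute-force component enumeration."""
    ok = 0
    for k in range(n_grids):
        rng = np.random.default_rng(seed0 + k)
        values = rng.integers(0, 8, size=(16, 16)).astype(float)
        nonzero = values[values > 0]
        hi = np.percentile(nonzero, 95)
        lo = np.percentile(nonzero, 70)
        got = nm.hysteresis_threshold(values, hi, lo)
        # oracle: label low mask, keep components whose max reaches hi
        labels, n = ndimage.label(values >= lo, structure=np.ones((3, 3), bool))
        want = np.zeros_like(got)
        for lab in range(1, n + 1):
            comp = labels == lab
            if values[comp].max() >= hi:
                want |= comp
        ok += int(np.array_equal(got, want))
    return ok / n_grids


# ---------------------------------------------------------------------------
# geometric-graph suite
# ---------------------------------------------------------------------------

def geometric_graph_checks(seed0: int = 0) -> dict:
    """Inclusion chain, EMST oracle, Voronoi cell areas and duality."""
    import networkx as nx

    # NNG subset EMST subset Delaunay on 100-point sets, 50 seeds
    chain_violations = 0
    for k in range(50):
        rng = np.random.default_rng(seed0 + k)
        locs = LocalizationSet(points=rng.random((100, 2)) * 1e4)
        nng_e = {tuple(e) for e in smg.nng(locs).edges}
        emst_e = {tuple(e) for e in smg.emst(locs).edges}
        del_e = {tuple(e) for e in smg.delaunay_graph(locs).edges}
        if not (nng_e <= emst_e <= del_e):
            chain_violations += 1

    # EMST total length equals the complete-graph MST oracle, 200 seeds
    emst_max_rel_gap = 0.0
    rng = np.random.default_rng(seed0 + 1000)
    for _ in range(200):
        n = int(rng.integers(2, 9))
        pts = rng.random((n, 2)) * 100
        total = smg.emst(LocalizationSet(points=pts)).lengths.sum()
        G = nx.Graph()
        for i in range(n):
            for j in range(i + 1, n):
                G.add_edge(i, j, weight=float(np.linalg.norm(pts[i] - pts[j])))
        oracle = sum(
            d["weight"] for _, _, d in nx.minimum_spanning_tree(G).edges(data=True)
        )
        emst_max_rel_gap = max(emst_max_rel_gap, abs(total - oracle) / oracle)

    # interior Voronoi cells of a unit 7x7 grid have area 1
    xs, ys = np.meshgrid(np.arange(7.0), np.arange(7.0))
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
    vor = smg.voronoi_tessellation(LocalizationSet(points=pts))
    interior = [
        i
        for i, (x, y) in enumerate(pts)
        if 1 <= x <= 5 and 1 <= y <= 5 and not vor.cell_unbounded[i]
    ]
    grid_area_err = float(np.abs(vor.cell_areas[interior] - 1.0).max())

    # Voronoi vertices are Delaunay circumcenters (duality)
    rng = np.random.default_rng(seed0 + 2000)
    pts = rng.random((100, 2)) * 1e4
    locs = LocalizationSet(points=pts)
    vor = smg.voronoi_tessellation(locs)
    dela = smg.delaunay_graph(locs)
    centers = []
    for tri in dela.triangles:
        a, b, c = pts[tri]
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
        centers.append((ux, uy))
    centers = np.asarray(centers)
    duality_err = 0.0
    for v in vor.vertices:
        duality_err = max(
            duality_err, float(np.linalg.norm(centers - v, axis=1).min() / 1e4)
        )

    return {
        "chain_violations": chain_violations,
        "emst_max_rel_gap": emst_max_rel_gap,
        "grid_cell_area_err": grid_area_err,
        "duality_rel_err": duality_err,
    }


# ---------------------------------------------------------------------------
# end-to-end phantom recovery
# ---------------------------------------------------------------------------

def _truth_sample_points(truth) -> np.ndarray:
    pts = []
    for s in truth.segments_px:
        for a, b in zip(s[:-1], s[1:]):
            n = int(np.hypot(*(b - a))) + 1
            for t in np.linspace(0.0, 1.0, n):
                pts.append(a * (1 - t) + b * t)
    return np.asarray(pts)


def recovery_ensemble(noise: str, seeds, base_seed: int = 0) -> dict:
    """Run the full pipeline on meshwork phantoms and score against truth.

    Returns pooled junction recall (within 3 px), per-seed interior face
    counts vs truth, pooled edge recall/precision at 2 px, and audit-log
    consistency flags.
    """
    params = synthetic.MeshPhantomParams(noise=noise)
    hits = []
    faces_det, faces_truth = [], []
    edge_recall_num = edge_recall_den = 0
    edge_prec_num = edge_prec_den = 0
    logs_consistent = True
    monotone = True
    for seed in seeds:
        img, truth = synthetic.make_mesh_phantom(params, seed=base_seed + seed)
        res = pipeline.segment_and_audit(img)
        g = res.graph
        deg = g.junction_degrees()
        det = np.asarray(g.junctions, dtype=float)[deg > 0]
        tj = np.asarray(truth.junctions_px)
        if len(det):
            d = np.sqrt(((tj[:, None, :] - det[None, :, :]) ** 2).sum(-1)).min(axis=1)
        else:
            d = np.full(len(tj), np.inf)
        hits.append(d <= 3.0)

        interior = [f for f in g.faces if not f.touches_mask_boundary]
        faces_det.append(len(interior))
        faces_truth.append(truth.n_faces)

        h, w = g.shape
        raster = g.rasterize()
        pts = _truth_sample_points(truth)
        ri = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        ci = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        d2r = ndimage.distance_transform_edt(~raster)
        edge_recall_num += int((d2r[ri, ci] <= 2.0).sum())
        edge_recall_den += len(pts)
        tr = np.zeros((h, w), bool)
        tr[ri, ci] = True
        d2t = ndimage.distance_transform_edt(~tr)
        edge_prec_num += int((d2t[raster] <= 2.0).sum())
        edge_prec_den += int(raster.sum())

        n_in = len(res.segmentation.graph.edges)
        n_out = len(res.graph.edges)
        monotone &= n_out <= n_in
        monotone &= {e.id for e in res.graph.edges} <= {
            e.id for e in res.segmentation.graph.edges
        }
        logs_consistent &= n_in == n_out + len(res.removal_log)

    hits = np.concatenate(hits)
    faces_det = np.asarray(faces_det)
    faces_truth = np.asarray(faces_truth)
    return {
        "junction_recall": float(hits.mean()),
        "n_truth_junctions": int(len(hits)),
        "faces_detected_total": int(faces_det.sum()),
        "faces_truth_total": int(faces_truth.sum()),
        "face_count_rel_err": float(
            (faces_det.sum() - faces_truth.sum()) / faces_truth.sum()
        ),
        "edge_recall": edge_recall_num / edge_recall_den,
        "edge_precision": edge_prec_num / edge_prec_den,
        "stages_monotone": bool(monotone),
        "removal_logs_exhaustive": bool(logs_consistent),
    }


# ---------------------------------------------------------------------------
# Euler relation on rasterized planar meshes
# ---------------------------------------------------------------------------

def _euler_of_graph(g) -> tuple[int, bool]:
    """(V - E + F_interior + 1, connected) of a mesh graph with faces."""
    import networkx as nx

    deg = g.junction_degrees()
    V = int((deg > 0).sum())
    E = len(g.edges)
    Fi = sum(1 for f in g.faces if not f.touches_mask_boundary)
    G = nx.MultiGraph()
    for jid in np.flatnonzero(deg > 0):
        G.add_node(int(jid))
    free = 10**6
    for e in g.edges:
        a, b = e.endpoints
        a = int(a) if a is not None else (free := free + 1)
        b = int(b) if b is not None else (free := free + 1)
        G.add_edge(a, b)
    connected = nx.is_connected(G) if len(G) else False
    return V - E + Fi + 1, connected


def _paths_cross_outside_junctions(g, clearance: float = 3.0) -> bool:
    """True when two edge paths share a pixel away from every junction node —
    the rasterization then fails to be a planar embedding."""
    junctions = np.asarray(g.junctions, dtype=float).reshape(-1, 2)
    seen: dict[tuple, int] = {}
    for e in g.edges:
        for p in set(e.path):
            seen[p] = seen.get(p, 0) + 1
    for p, count in seen.items():
        if count < 2:
            continue
        if len(junctions) == 0:
            return True
        d = np.hypot(junctions[:, 0] - p[0], junctions[:, 1] - p[1]).min()
        if d > clearance:
            return True
    return False


def graph_from_truth(truth) -> "sg.MeshGraph":
    """Rasterize the truth polylines at 1 px and convert to a mesh graph."""
    from skimage.draw import polygon as sk_polygon

    shape = truth.params.shape
    m = np.zeros(shape, bool)
    for seg in truth.segments_px:
        v = np.round(seg).astype(int)
        for a, b in zip(v[:-1], v[1:]):
            for p in sg.bresenham_line(tuple(a), tuple(b)):
                if 0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]:
                    m[p] = True
    sk = sg.thin_skeleton(Skeleton(m, np.zeros(shape)))
    cls = sg.find_branchpoints(sk)
    g = sg.consolidate_junctions(sk, cls)
    rr, cc = sk_polygon(
        truth.nucleus_polygon_px[:, 0], truth.nucleus_polygon_px[:, 1], shape
    )
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    mask = ndimage.binary_dilation(mask, iterations=3)
    # min_area_px drops 1-px pockets enclosed by crossing junction-link
    # pixels; they are rasterization artifacts, not faces of the mesh
    return sg.extract_faces(g, NucleusMask(mask, {}), min_area_px=4)


def graph_from_grid(n_lines: int = 4, spacing: int = 14) -> "sg.MeshGraph":
    """Rasterized rectangular grid mesh inside a generous mask."""
    size = spacing * (n_lines + 1)
    m = np.zeros((size, size), bool)
    coords = [spacing * (k + 1) for k in range(n_lines)]
    lo, hi = coords[0], coords[-1]
    for c in coords:
        m[c, lo : hi + 1] = True
        m[lo : hi + 1, c] = True
    sk = Skeleton(m, np.zeros((size, size)))
    cls = sg.find_branchpoints(sk)
    g = sg.consolidate_junctions(sk, cls)
    return sg.extract_faces(g, NucleusMask(np.ones((size, size), bool), {}))


def euler_relation_check(seeds, base_seed: int = 0) -> dict:
    """Euler residual V - E + F + 1 on grid meshes and rasterized Voronoi
    phantom truths; degenerate rasterizations (crossing paths) are excluded
    since they are not planar embeddings."""
    residuals = []
    n_checked = n_skipped = 0
    for n_lines in (2, 3, 4):
        g = graph_from_grid(n_lines)
        r, conn = _euler_of_graph(g)
        assert conn
        residuals.append(r)
        n_checked += 1
    params = synthetic.MeshPhantomParams()
    for seed in seeds:
        _, truth = synthetic.make_mesh_phantom(params, seed=base_seed + seed)
        g = graph_from_truth(truth)
        r, conn = _euler_of_graph(g)
        if not conn or _paths_cross_outside_junctions(g):
            n_skipped += 1
            continue
        residuals.append(r)
        n_checked += 1
    residuals = np.asarray(residuals)
    return {
        "max_abs_residual_minus_2": int(np.abs(residuals - 2).max()),
        "n_checked": n_checked,
        "n_skipped_nonplanar": n_skipped,
        "residuals": residuals.tolist(),
    }
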