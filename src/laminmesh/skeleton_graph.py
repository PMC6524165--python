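"""From thresholded ridge centerlines to an object-based meshwork graph.

Pipeline: binarize the NMS map at the foreground threshold, drop isolated
short segments, extend endpoints along their local orientation to bridge the
gaps the single-orientation detector leaves at fiber crossings, classify
pixels (edge / branch point / endpoint), consolidate branch-point zones into
single-pixel junction nodes at component centroids, record edges as ordered
pixel paths linked to junctions by Bresenham lines, and extract the enclosed
faces.  All pixel components use 8-connectivity; faces use the complementary
4-connectivity so regions cannot leak through diagonal gaps in the skeleton.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from laminmesh.types import MeshEdge, MeshFace, MeshGraph, NMSMap, OrientationField, Skeleton
from laminmesh.nucleus_mask import NucleusMask, STRUCT8

# pixel classification codes
BACKGROUND, EDGE_PIXEL, BRANCHPOINT, ENDPOINT = 0, 1, 2, 3

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
# 4-adjacent pairs among the 8 ring positions (the white center never links them)
_RING_ADJ = [
    (0, 1), (1, 2),  # top row
    (0, 3), (2, 4),  # top corners to sides
    (3, 5), (4, 7),  # sides to bottom corners
    (5, 6), (6, 7),  # bottom row
]


def bresenham_line(p0: tuple, p1: tuple) -> list:
    """Integer Bresenham line from p0 to p1 inclusive, in traversal order."""
    x0, y0 = int(p0[0]), int(p0[1])
    x1, y1 = int(p1[0]), int(p1[1])
    dx, sx = abs(x1 - x0), (1 if x0 < x1 else -1)
    dy, sy = -abs(y1 - y0), (1 if y0 < y1 else -1)
    err = dx + dy
    out = []
    while True:
        out.append((x0, y0))
        if x0 == x1 and y0 == y1:
            return out
        e2 = 2 * err
        if e2 >= dy:
            err += dy
            x0 += sx
        if e2 <= dx:
            err += dx
            y0 += sy


def binarize_nms(nms: NMSMap, threshold: float) -> Skeleton:
    """Keep nonzero NMS pixels at or above ``threshold``, carrying orientation."""
    mask = (nms.values > 0) & (nms.values >= threshold)
    return Skeleton(mask=mask, theta=nms.theta.copy())


def thin_skeleton(sk: Skeleton) -> Skeleton:
    """Reduce the skeleton to unit width by morphological thinning.

    Non-maximum suppression leaves occasional 2-pixel-thick staircases along
    diagonal ridges which would masquerade as branch points; thinning
    restores the single-pixel centerline.  Orientation and extension flags
    are carried over (thinning only removes pixels).
    """
    from skimage.morphology import skeletonize

    mask = skeletonize(sk.mask)
    return Skeleton(mask=mask, theta=sk.theta.copy(), extensions=sk.extensions & mask)


def prune_short_segments(sk: Skeleton, min_px: int = 5) -> Skeleton:
    """Remove *isolated* connected components with fewer than ``min_px`` pixels.

    Only whole components are judged: a short spur attached to a longer
    segment is part of a larger component and survives this stage.
    """
    if min_px < 1:
        raise ValueError("min_px must be >= 1")
    labels, n = ndimage.label(sk.mask, structure=STRUCT8)
    if n == 0:
        return Skeleton(sk.mask.copy(), sk.theta.copy(), sk.extensions.copy())
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.concatenate([[False], sizes >= min_px])  # label 0 = background
    mask = keep[labels]
    return Skeleton(mask=mask, theta=sk.theta.copy(), extensions=sk.extensions & mask)


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(mask.astype(int), kernel, mode="constant", cval=0)


def skeleton_endpoints(mask: np.ndarray) -> np.ndarray:
    """Skeleton pixels with exactly one 8-neighbor."""
    return mask & (_neighbor_count(mask) == 1)


def extend_endpoints(
    sk: Skeleton,
    field: OrientationField,
    max_extend_px: int = 10,
) -> Skeleton:
    """March from each endpoint along its local orientation to close gaps.

    Two candidate directions are tried from every endpoint — the local
    orientation at the endpoint pixel, and the principal axis of the
    trailing skeleton pixels (useful when the per-pixel orientation is
    contaminated by whatever stronger structure suppressed the ridge there)
    — each signed to point away from the segment; pixels on the Bresenham
    line are added until an existing skeleton pixel is met, and the shorter
    successful bridge wins.  Extensions that leave the image or exceed
    ``max_extend_px`` added pixels are discarded entirely (an unconnected
    extension would end free-standing and be audit-removed).  Added pixels
    are flagged so the audit can re-validate them.
    """
    if max_extend_px < 0:
        raise ValueError("max_extend_px must be >= 0")
    mask = sk.mask.copy()
    theta = sk.theta.copy()
    extensions = sk.extensions.copy()
    if max_extend_px == 0:
        return Skeleton(mask, theta, extensions)
    h, w = mask.shape
    eps = np.argwhere(skeleton_endpoints(sk.mask))
    labels, _ = ndimage.label(sk.mask, structure=STRUCT8)
    committed = mask.copy()
    tail_r = 6  # window for the trailing-direction fit
    def _march(r: int, c: int, dr: float, dc: float):
        target = (
            int(round(r + dr * (max_extend_px + 1))),
            int(round(c + dc * (max_extend_px + 1))),
        )
        added = []
        for q in bresenham_line((r, c), target)[1:]:
            qr, qc = q
            if not (0 <= qr < h and 0 <= qc < w):
                return None  # ran off the image: discard
            if committed[qr, qc]:
                return added
            if len(added) >= max_extend_px:
                return None
            added.append(q)
        return None

    for r, c in eps:
        # the unique neighbor tells us which way the segment lies
        away = None
        for orr, occ in _OFFSETS:
            rr, cc = r + orr, c + occ
            if 0 <= rr < h and 0 <= cc < w and sk.mask[rr, cc]:
                away = (r - rr, c - cc)
                break
        if away is None:
            away = (0.0, 0.0)  # isolated pixel: direction sign is arbitrary

        candidates = []
        t_loc = field.theta[r, c]
        candidates.append((np.sin(t_loc), np.cos(t_loc)))
        # trailing pixels of this endpoint's own segment give a second,
        # less local direction estimate
        r0, r1 = max(r - tail_r, 0), min(r + tail_r + 1, h)
        c0, c1 = max(c - tail_r, 0), min(c + tail_r + 1, w)
        local = np.argwhere(labels[r0:r1, c0:c1] == labels[r, c]) + (r0, c0)
        if len(local) >= 4:
            centered = local.astype(float) - local.mean(axis=0)
            _, s, vt = np.linalg.svd(centered, full_matrices=False)
            if s[0] > 0 and (len(s) < 2 or s[1] / s[0] <= 0.5):
                candidates.append((vt[0][0], vt[0][1]))

        best = None
        for dr, dc in candidates:
            if dr * away[0] + dc * away[1] < 0:
                dr, dc = -dr, -dc
            added = _march(r, c, dr, dc)
            if added and (best is None or len(added) < len(best)):
                best = added
        if best:
            t = np.mod(
                np.arctan2(best[-1][0] - r, best[-1][1] - c), np.pi
            )
            for qr, qc in best:
                committed[qr, qc] = True
                extensions[qr, qc] = True
                theta[qr, qc] = t
    return Skeleton(mask=committed, theta=theta, extensions=extensions)


def _build_classification_lut() -> np.ndarray:
    """Classify all 256 possible 8-neighborhood configurations of a white pixel.

    Branch point: >= 3 white neighbors whose intervening black ring pixels are
    not 4-connected (i.e. the black pixels split into >= 2 components, so the
    white neighbors form separate branches).  Endpoint: <= 1 white neighbor.
    """
    lut = np.empty(256, dtype=np.uint8)
    for code in range(256):
        whites = [i for i in range(8) if code >> i & 1]
        blacks = set(range(8)) - set(whites)
        if len(whites) <= 1:
            lut[code] = ENDPOINT
            continue
        if len(whites) >= 3:
            # count 4-connected components of the black ring pixels
            parent = {b: b for b in blacks}

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for a, b in _RING_ADJ:
                if a in blacks and b in blacks:
                    parent[find(a)] = find(b)
            n_black_components = len({find(b) for b in blacks})
            if n_black_components >= 2:
                lut[code] = BRANCHPOINT
                continue
        lut[code] = EDGE_PIXEL
    return lut


_CLASS_LUT = _build_classification_lut()


def find_branchpoints(sk: Skeleton) -> np.ndarray:
    """Classify every skeleton pixel as EDGE_PIXEL, BRANCHPOINT or ENDPOINT."""
    kernel = np.array([[1, 2, 4], [8, 0, 16], [32, 64, 128]])
    codes = ndimage.convolve(sk.mask.astype(int), kernel[::-1, ::-1], mode="constant", cval=0)
    out = np.zeros(sk.mask.shape, dtype=np.uint8)
    out[sk.mask] = _CLASS_LUT[codes[sk.mask]]
    return out


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _trace_path(pixels: np.ndarray) -> list:
    """Order the pixels of one 8-connected component from end to end.

    Components are expected to be (near-)unit-width paths; a greedy walk from
    a degree-1 pixel (or anywhere, for cycles) visits every pixel, preferring
    4-neighbors so diagonal shortcuts do not skip path pixels.
    """
    pts = [tuple(p) for p in pixels]
    if len(pts) == 1:
        return pts
    index = set(pts)
    nbrs = {}
    for r, c in pts:
        ns = []
        for orr, occ in _OFFSETS:
            q = (r + orr, c + occ)
            if q in index:
                ns.append(q)
        nbrs[(r, c)] = ns
    start = next((p for p in pts if len(nbrs[p]) == 1), pts[0])
    order, seen = [start], {start}
    cur = start
    while len(order) < len(pts):
        cand = [q for q in nbrs[cur] if q not in seen]
        if not cand:
            # branching residue: jump to the earliest visited pixel that still
            # has unvisited neighbors and continue from there
            rest = [p for p in order if any(q not in seen for q in nbrs[p])]
            if not rest:
                break
            cur = rest[0]
            cand = [q for q in nbrs[cur] if q not in seen]
        # prefer 4-adjacent continuation
        cand.sort(key=lambda q: abs(q[0] - cur[0]) + abs(q[1] - cur[1]))
        cur = cand[0]
        order.append(cur)
        seen.add(cur)
    return order


def consolidate_junctions(sk: Skeleton, classification: np.ndarray) -> MeshGraph:
    """Collapse branch-point zones to single-pixel junctions and link edges.

    Junction zones are branch points plus the <=2-pixel segments connecting
    them; each 8-connected zone becomes one junction at its rounded centroid.
    Remaining skeleton components become edges, recorded as ordered pixel
    paths; each terminal touching a zone is joined to the junction node by a
    Bresenham line.
    """
    h, w = sk.mask.shape
    branch = classification == BRANCHPOINT
    rest = sk.mask & ~branch
    rest_labels, n_rest = ndimage.label(rest, structure=STRUCT8)

    # short connector components (<= 2 px) adjacent to >= 2 branch pixels
    zone = branch.copy()
    branch_pix = set(map(tuple, np.argwhere(branch)))
    for lab in range(1, n_rest + 1):
        pix = np.argwhere(rest_labels == lab)
        if len(pix) > 2:
            continue
        adjacent_branch = set()
        for r, c in pix:
            for orr, occ in _OFFSETS:
                q = (r + orr, c + occ)
                if q in branch_pix:
                    adjacent_branch.add(q)
        if len(adjacent_branch) >= 2:
            for r, c in pix:
                zone[r, c] = True

    zone_labels, n_zone = ndimage.label(zone, structure=STRUCT8)
    junctions = []
    for lab in range(1, n_zone + 1):
        pix = np.argwhere(zone_labels == lab)
        cr, cc = pix.mean(axis=0)
        junctions.append(
            (
                min(max(_round_half_away(cr), 0), h - 1),
                min(max(_round_half_away(cc), 0), w - 1),
            )
        )

    edge_mask = sk.mask & ~zone
    edge_labels, n_edges = ndimage.label(edge_mask, structure=STRUCT8)

    def adjacent_junction(pixel: tuple) -> int | None:
        r, c = pixel
        counts: dict[int, int] = {}
        for orr, occ in _OFFSETS:
            rr, cc = r + orr, c + occ
            if 0 <= rr < h and 0 <= cc < w and zone_labels[rr, cc] > 0:
                jid = zone_labels[rr, cc] - 1
                counts[jid] = counts.get(jid, 0) + 1
        if not counts:
            return None
        return max(counts, key=lambda k: (counts[k], -k))

    edges = []
    for lab in range(1, n_edges + 1):
        pix = np.argwhere(edge_labels == lab)
        path = _trace_path(pix)
        closed = (
            len(path) >= 3
            and max(abs(path[0][0] - path[-1][0]), abs(path[0][1] - path[-1][1])) <= 1
        )
        j0 = adjacent_junction(path[0])
        j1 = adjacent_junction(path[-1])
        if len(path) == 1 and j0 is not None and j1 == j0:
            # a single pixel may bridge two different junctions
            r, c = path[0]
            seen = set()
            for orr, occ in _OFFSETS:
                rr, cc = r + orr, c + occ
                if 0 <= rr < h and 0 <= cc < w and zone_labels[rr, cc] > 0:
                    seen.add(zone_labels[rr, cc] - 1)
            if len(seen) >= 2:
                ordered = sorted(seen)
                j0, j1 = ordered[0], ordered[1]
        full_path = list(path)
        n_head = n_tail = 0
        if j0 is not None:
            head = bresenham_line(junctions[j0], path[0])
            full_path = head[:-1] + full_path
            n_head = len(head) - 1
        if j1 is not None and not (len(path) == 1 and j1 == j0):
            tail = bresenham_line(path[-1], junctions[j1])
            full_path = full_path + tail[1:]
            n_tail = len(tail) - 1
        has_ext = bool(sk.extensions[tuple(np.array(path).T)].any()) if len(path) else False
        attrs = {"n_head": n_head, "n_tail": n_tail}
        if closed:
            attrs["closed"] = True
        edges.append(
            MeshEdge(
                id=lab - 1,
                path=full_path,
                endpoints=(j0, j1),
                has_extension=has_ext,
                attrs=attrs,
            )
        )

    return MeshGraph(junctions=junctions, edges=edges, shape=(h, w))


def _relinked_edge(e: MeshEdge, junctions: list, j0, j1) -> MeshEdge:
    """Rebuild an edge's path from its core with fresh junction links."""
    core = list(e.core)
    path = list(core)
    n_head = n_tail = 0
    if j0 is not None and tuple(junctions[j0]) != tuple(path[0]):
        head = bresenham_line(junctions[j0], core[0])
        path = head[:-1] + path
        n_head = len(head) - 1
    if j1 is not None and tuple(junctions[j1]) != tuple(path[-1]):
        tail = bresenham_line(core[-1], junctions[j1])
        path = path + tail[1:]
        n_tail = len(tail) - 1
    attrs = dict(e.attrs)
    attrs["n_head"] = n_head
    attrs["n_tail"] = n_tail
    return MeshEdge(
        id=e.id,
        path=path,
        endpoints=(j0, j1),
        has_extension=e.has_extension,
        attrs=attrs,
    )


def contract_short_edges(g: MeshGraph, max_len_px: float) -> MeshGraph:
    """Contract junction-to-junction edges shorter than ``max_len_px``.

    Fibers meeting at a shallow angle coalesce into a single detected ridge
    *before* their geometric vertex, so one true junction often appears as a
    small polygon of nearby nodes connected by very short edges at the
    filter's resolution scale.  Contracting those short edges (union-find
    over their endpoints) collapses each such polygon into one node at the
    rounded centroid of its members; the contracted edges are absorbed into
    the junction and all other edges are re-linked.
    """
    if len(g.junctions) == 0 or max_len_px <= 0:
        return g
    pts = np.asarray(g.junctions, dtype=float)
    n = len(pts)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    contracted = set()
    for e in g.edges:
        j0, j1 = e.endpoints
        if (
            j0 is not None
            and j1 is not None
            and j0 != j1
            and e.length_px <= max_len_px
            and not e.attrs.get("closed")
        ):
            parent[find(j0)] = find(j1)
            contracted.add(e.id)
    roots = sorted({find(i) for i in range(n)})
    cluster_of = {i: roots.index(find(i)) for i in range(n)}
    h, w = g.shape
    new_junctions = []
    for r in roots:
        members = pts[[i for i in range(n) if find(i) == r]]
        cr, cc = members.mean(axis=0)
        new_junctions.append(
            (
                min(max(_round_half_away(cr), 0), h - 1),
                min(max(_round_half_away(cc), 0), w - 1),
            )
        )
    new_edges = []
    for e in g.edges:
        if e.id in contracted:
            continue  # absorbed into the junction
        j0 = cluster_of[e.endpoints[0]] if e.endpoints[0] is not None else None
        j1 = cluster_of[e.endpoints[1]] if e.endpoints[1] is not None else None
        if (
            j0 is not None
            and j0 == j1
            and e.length_px <= max_len_px
            and not e.attrs.get("closed")
        ):
            continue  # a parallel short edge inside the same cluster
        new_edges.append(_relinked_edge(e, new_junctions, j0, j1))
    return MeshGraph(
        junctions=new_junctions,
        edges=new_edges,
        faces=[],
        shape=g.shape,
        pixel_size_nm=g.pixel_size_nm,
    )


def refine_junction_positions(
    g: MeshGraph,
    fit_from_px: float = 4.0,
    fit_len_px: float = 8.0,
    max_shift_px: float = 6.0,
) -> MeshGraph:
    """Re-localize junctions at the intersection of incident edge tangents.

    Converging ridges blur into a single detected centerline before their
    geometric vertex, displacing the morphological branch point up-stream by
    roughly sigma/tan(half-angle).  A better vertex estimate is the
    least-squares intersection of straight lines fitted to each incident
    edge *outside* that coalescence zone (path points between
    ``fit_from_px`` and ``fit_from_px + fit_len_px`` of arc length from the
    junction).  Junctions with fewer than three usable incident directions,
    ill-conditioned intersections, or solutions farther than
    ``max_shift_px`` keep their centroid position.  Edge paths are re-linked
    to moved junctions with Bresenham segments.
    """
    if not g.junctions:
        return g
    h, w = g.shape
    incident: dict[int, list] = {}
    for e in g.edges:
        for end_idx, jid in enumerate(e.endpoints):
            if jid is not None:
                incident.setdefault(jid, []).append((e, end_idx))

    def _arc_window(path: np.ndarray, from_junction_end: int) -> np.ndarray | None:
        pts = path if from_junction_end == 0 else path[::-1]
        steps = np.hypot(*np.diff(pts, axis=0).T) if len(pts) > 1 else np.zeros(0)
        arc = np.concatenate([[0.0], np.cumsum(steps)])
        sel = (arc >= fit_from_px) & (arc <= fit_from_px + fit_len_px)
        window = pts[sel]
        return window if len(window) >= 3 else None

    new_junctions = list(g.junctions)
    for jid, inc in incident.items():
        lines = []
        for e, end_idx in inc:
            window = _arc_window(np.asarray(e.path, dtype=float), end_idx)
            if window is None:
                continue
            centroid = window.mean(axis=0)
            u, s, vt = np.linalg.svd(window - centroid, full_matrices=False)
            if s[0] <= 0 or (len(s) > 1 and s[1] / s[0] > 0.35):
                continue  # too curved to trust a straight-line fit
            lines.append((centroid, vt[0]))
        if len(lines) < 3:
            continue
        A = np.zeros((2, 2))
        b = np.zeros(2)
        for p, d in lines:
            proj = np.eye(2) - np.outer(d, d)
            A += proj
            b += proj @ p
        if np.linalg.cond(A) > 1e6:
            continue
        x = np.linalg.solve(A, b)
        old = np.asarray(g.junctions[jid], dtype=float)
        if np.hypot(*(x - old)) > max_shift_px:
            continue
        # only trust the move if the fitted lines genuinely co-intersect and
        # the intersection explains them better than the current position
        def mean_residual(q):
            return float(
                np.mean(
                    [np.hypot(*((np.eye(2) - np.outer(d, d)) @ (q - p))) for p, d in lines]
                )
            )

        if mean_residual(x) > min(1.5, mean_residual(old)):
            continue
        new_junctions[jid] = (
            min(max(_round_half_away(x[0]), 0), h - 1),
            min(max(_round_half_away(x[1]), 0), w - 1),
        )

    new_edges = [
        _relinked_edge(e, new_junctions, e.endpoints[0], e.endpoints[1])
        for e in g.edges
    ]
    return MeshGraph(
        junctions=new_junctions,
        edges=new_edges,
        faces=[],
        shape=g.shape,
        pixel_size_nm=g.pixel_size_nm,
    )


def extract_faces(g: MeshGraph, mask: NucleusMask, min_area_px: int = 1) -> MeshGraph:
    """Find the 2D regions enclosed by the meshwork edges.

    Faces are 4-connected components of non-skeleton pixels inside the
    nucleus mask; each records its pixels and the ids of the edges bounding
    it.  Regions outside the mask are never faces; a face reaching the mask
    boundary is flagged ``touches_mask_boundary`` (the merged exterior region
    of the mesh, not an enclosed face proper).  ``min_area_px`` discards
    pockets smaller than the given pixel count — crossing Bresenham link
    segments near a junction can enclose 1-2 stray pixels that are
    rasterization artifacts, not meshwork faces.
    """
    raster = g.rasterize()
    if raster.shape != mask.mask.shape:
        raise ValueError("graph and mask shapes differ")
    background = mask.mask & ~raster
    labels, n = ndimage.label(background, structure=ndimage.generate_binary_structure(2, 1))
    # a face touches the mask boundary if any pixel is 4-adjacent to ~mask or
    # lies on the image frame (the mask is cut off there)
    outside = ~mask.mask
    border = ndimage.binary_dilation(
        outside, structure=ndimage.generate_binary_structure(2, 1)
    ) & mask.mask
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = np.unique(labels[border & (labels > 0)])

    face_edges: dict[int, set] = {lab: set() for lab in range(1, n + 1)}
    h, w = raster.shape
    for e in g.edges:
        seen = set()
        for r, c in e.path:
            for orr, occ in _OFFSETS + [(0, 0)]:
                rr, cc = r + orr, c + occ
                if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] > 0:
                    seen.add(int(labels[rr, cc]))
        for lab in seen:
            face_edges[lab].add(e.id)

    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    faces = [
        MeshFace(
            id=lab - 1,
            pixels=np.argwhere(labels == lab),
            edge_ids=sorted(face_edges[lab]),
            touches_mask_boundary=bool(lab in touching),
        )
        for lab in range(1, n + 1)
        if sizes[lab - 1] >= min_area_px
    ]
    return MeshGraph(
        junctions=g.junctions,
        edges=g.edges,
        faces=faces,
        shape=g.shape,
        pixel_size_nm=g.pixel_size_nm,
    )
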