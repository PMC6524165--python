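"""Edge- and face-level auditing of the meshwork, and meshwork statistics.

The initial object-based meshwork contains spurious edges (background ridges,
over-eager endpoint extensions).  Auditing removes edges in a fixed stage
order using the reconstructed fluorescence image and the band-ratio image,
with automatic thresholds (Otsu for bimodal separations, Rosin's unimodal
corner for long-tailed ones), then prunes free-standing chains:

  B  distance-weighted mean ratio intensity around the edge path below the
     ratio-image threshold;
  C  minimum or mean reconstructed intensity along the path below threshold,
     or normalized intensity range (max-min)/mean above threshold
     (an inconsistent fiber);
  D  fraction of path pixels at or above the Otsu threshold of the in-mask
     ratio image below 0.5 (insufficient overlap);
  E  the edge separates two faces whose merged interior matches the ratio
     image better than the edge does;
  free  iterative removal of edges with a free-standing endpoint.

Every stage only removes edges; every removal is logged with its score and
threshold, so |edges_in| = |edges_out| + sum of stage removals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters

from laminmesh.nucleus_mask import NucleusMask
from laminmesh.skeleton_graph import extract_faces
from laminmesh.types import MeshGraph, RasterImage

ThresholdSpec = Union[str, float]  # "otsu" | "rosin" | explicit value


@dataclass
class AuditConfig:
    enable_b: bool = True
    enable_c: bool = True
    enable_d: bool = True
    enable_e: bool = True
    enable_free: bool = True
    d0_px: float = 2.0  # Gaussian distance-weight scale; matches the filter sigma
    b_method: ThresholdSpec = "rosin"  # on in-mask ratio values
    c_min_method: ThresholdSpec = "rosin"  # on in-mask recon values
    c_mean_method: ThresholdSpec = "otsu"  # on in-mask recon values
    c_range_threshold: float = 2.0  # normalized range above this = inconsistent
    d_method: ThresholdSpec = "otsu"  # on in-mask ratio values
    d_overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.d0_px > 0:
            raise ValueError("d0_px must be positive")


@dataclass
class MeshworkStats:
    face_areas_nm2: np.ndarray  # interior (enclosed) faces only
    edge_lengths_nm: np.ndarray
    junction_count: int
    junction_degrees: np.ndarray
    pixel_size_nm: float

    def summary(self) -> dict:
        def q(a):
            if len(a) == 0:
                return {"n": 0}
            return {
                "n": int(len(a)),
                "mean": float(np.mean(a)),
                "median": float(np.median(a)),
                "q25": float(np.percentile(a, 25)),
                "q75": float(np.percentile(a, 75)),
                "min": float(np.min(a)),
                "max": float(np.max(a)),
            }

        degs = self.junction_degrees
        return {
            "faces": q(self.face_areas_nm2),
            "edges": q(self.edge_lengths_nm),
            "junctions": {
                "n": int(self.junction_count),
                "n_nodes": int(len(degs)),
                "degree_histogram": {
                    int(d): int((degs == d).sum()) for d in np.unique(degs)
                },
            },
            "pixel_size_nm": float(self.pixel_size_nm),
        }

    def to_frames(self) -> dict:
        return {
            "faces": pd.DataFrame({"area_nm2": self.face_areas_nm2}),
            "edges": pd.DataFrame({"length_nm": self.edge_lengths_nm}),
            "junctions": pd.DataFrame({"degree": self.junction_degrees}),
        }


def auto_threshold(values, method: ThresholdSpec, nbins: int = 256) -> float:
    """Automatic threshold of a 1D sample.

    ``otsu``: split maximizing between-class variance on an ``nbins``
    histogram.  ``rosin``: unimodal corner — the bin between the histogram
    peak and the last nonempty bin at maximal perpendicular distance from the
    peak-to-tail chord.  A float is passed through unchanged.
    """
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot threshold an empty sample")
    if np.unique(values).size < 2:
        raise ValueError("cannot threshold a constant sample: no split exists")
    if method == "otsu":
        return float(filters.threshold_otsu(values, nbins=nbins))
    if method == "rosin":
        return _rosin_threshold(values, nbins=nbins)
    raise ValueError(f"unknown threshold method {method!r}")


def _rosin_threshold(values: np.ndarray, nbins: int = 256) -> float:
    hist, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(hist))
    nonempty = np.flatnonzero(hist)
    last = int(nonempty[-1])
    if last <= peak:
        # unimodal corner undefined when the peak is the tail end; mirror it
        first = int(nonempty[0])
        if first >= peak:
            raise ValueError("histogram has no descending flank for Rosin threshold")
        hist, centers = hist[::-1], centers[::-1]
        peak, last = nbins - 1 - peak, nbins - 1 - first
    p0 = np.array([peak, hist[peak]], dtype=float)
    p1 = np.array([last, hist[last]], dtype=float)
    chord = p1 - p0
    norm = np.hypot(*chord)
    ks = np.arange(peak, last + 1)
    rel = np.stack([ks - p0[0], hist[peak : last + 1] - p0[1]], axis=1)
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    best = int(ks[np.flatnonzero(dist == dist.max())[-1]])
    return float(centers[best])


# ---------------------------------------------------------------------------
# edge scores
# ---------------------------------------------------------------------------

def _distance_weighted_score(
    path: list, image: np.ndarray, d0: float, exclude_path: bool = False
) -> float:
    """Gaussian distance-weighted mean of ``image`` in a +-2*d0 band around a path."""
    pad = int(np.ceil(2.0 * d0)) + 1
    p = np.asarray(path)
    r0, c0 = p.min(axis=0) - pad
    r1, c1 = p.max(axis=0) + pad + 1
    h, w = image.shape
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, h), min(c1, w)
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[p[:, 0] - r0, p[:, 1] - c0] = True
    d = ndimage.distance_transform_edt(~local)
    wgt = np.where(d <= 2.0 * d0, np.exp(-(d**2) / (2.0 * d0**2)), 0.0)
    if exclude_path:
        wgt[local] = 0.0
    total = wgt.sum()
    if total == 0:
        return 0.0
    return float((wgt * image[r0:r1, c0:c1]).sum() / total)


def _face_band_score(pixels: np.ndarray, path: list, image: np.ndarray, d0: float) -> float:
    """Gaussian distance-weighted mean of ``image`` over face pixels near a path."""
    p = np.asarray(path, dtype=float)
    pr, pc = pixels[:, 0].astype(float), pixels[:, 1].astype(float)
    # distance from each face pixel to the nearest path pixel
    d = np.full(len(pixels), np.inf)
    for rr, cc in p:
        d = np.minimum(d, np.hypot(pr - rr, pc - cc))
    wgt = np.where(d <= 2.0 * d0, np.exp(-(d**2) / (2.0 * d0**2)), 0.0)
    total = wgt.sum()
    if total == 0:
        return 0.0
    return float((wgt * image[pixels[:, 0], pixels[:, 1]]).sum() / total)


def _path_values(path: list, image: np.ndarray) -> np.ndarray:
    p = np.asarray(path)
    return image[p[:, 0], p[:, 1]]


def _path_outside_junctions(edge, junctions, radius: float) -> list:
    """Path pixels farther than ``radius`` from either endpoint junction.

    The band ratio is systematically depressed inside a junction's
    convergence zone (the blurred reference is elevated where several fibers
    meet), so ratio-based stages only weigh the part of an edge outside
    those disks.  Returns [] when the whole edge lies inside them.
    """
    p = np.asarray(edge.path, dtype=float)
    keep = np.ones(len(p), dtype=bool)
    for jid in edge.endpoints:
        if jid is None:
            continue
        jr, jc = junctions[jid]
        keep &= np.hypot(p[:, 0] - jr, p[:, 1] - jc) > radius
    return [tuple(map(int, q)) for q in p[keep]]


def audit_meshwork(
    g: MeshGraph,
    recon: RasterImage,
    ratio: RasterImage,
    cfg: AuditConfig | None = None,
    mask: Optional[NucleusMask] = None,
) -> tuple[MeshGraph, list]:
    """Apply the staged edge audit; returns the refined graph and removal log.

    ``mask`` restricts the threshold samples and face extraction to the
    nucleus; without one the whole frame is used.
    """
    cfg = cfg or AuditConfig()
    if recon.pixels.shape != ratio.pixels.shape or (
        g.shape is not None and tuple(g.shape) != recon.pixels.shape
    ):
        raise ValueError("graph, reconstructed image and ratio image must share a grid")
    if mask is None:
        mask = NucleusMask(np.ones(recon.pixels.shape, dtype=bool), {"origin": "full-frame"})
    in_mask_ratio = ratio.pixels[mask.mask]
    in_mask_recon = recon.pixels[mask.mask]

    log: list[dict] = []
    edges = list(g.edges)

    def remove(stage: str, drop: dict) -> None:
        nonlocal edges
        if not drop:
            return
        for e in edges:
            if e.id in drop:
                score, thr = drop[e.id]
                log.append(
                    {"stage": stage, "edge_id": e.id, "score": score, "threshold": thr}
                )
        edges = [e for e in edges if e.id not in drop]

    exclusion = 2.0 * cfg.d0_px  # junction convergence-disk radius

    if cfg.enable_b and edges:
        thr = auto_threshold(in_mask_ratio, cfg.b_method)
        drop = {}
        for e in edges:
            scored = _path_outside_junctions(e, g.junctions, exclusion)
            if len(scored) < 3:
                continue  # entirely inside junction zones: no evidence either way
            score = _distance_weighted_score(scored, ratio.pixels, cfg.d0_px)
            if score < thr:
                drop[e.id] = (score, thr)
        remove("B:ratio-band", drop)

    if cfg.enable_c and edges:
        thr_min = auto_threshold(in_mask_recon, cfg.c_min_method)
        thr_mean = auto_threshold(in_mask_recon, cfg.c_mean_method)
        drop = {}
        for e in edges:
            # score the detected core; the synthetic link pixels joining a
            # path to its junction node may cross dim ground when the node
            # is slightly displaced, and would fail the minimum-intensity
            # check spuriously.  Short paths (mostly links) keep the full
            # path so junction glue is still audited.
            core = e.core
            scored = core if len(core) >= 5 else e.path
            vals = _path_values(scored, recon.pixels)
            vmin, vmean = float(vals.min()), float(vals.mean())
            nrange = float((vals.max() - vals.min()) / vmean) if vmean > 0 else np.inf
            if vmin < thr_min:
                drop[e.id] = (vmin, thr_min)
            elif vmean < thr_mean:
                drop[e.id] = (vmean, thr_mean)
            elif nrange > cfg.c_range_threshold:
                drop[e.id] = (nrange, cfg.c_range_threshold)
        remove("C:intensity", drop)

    if cfg.enable_d and edges:
        thr = auto_threshold(in_mask_ratio, cfg.d_method)
        drop = {}
        for e in edges:
            scored = _path_outside_junctions(e, g.junctions, exclusion)
            if len(scored) < 3:
                continue
            vals = _path_values(scored, ratio.pixels)
            frac = float((vals >= thr).mean())
            if frac < cfg.d_overlap_fraction:
                drop[e.id] = (frac, cfg.d_overlap_fraction)
        remove("D:ratio-overlap", drop)

    if cfg.enable_e and edges:
        faces_graph = extract_faces(g.with_edges(edges), mask)
        by_edge: dict[int, list] = {}
        for f in faces_graph.faces:
            if f.touches_mask_boundary:
                continue
            for eid in f.edge_ids:
                by_edge.setdefault(eid, []).append(f)
        drop = {}
        for e in edges:
            adj = by_edge.get(e.id, [])
            if len(adj) != 2:
                continue
            edge_score = _distance_weighted_score(e.path, ratio.pixels, cfg.d0_px)
            merged = np.vstack([adj[0].pixels, adj[1].pixels])
            face_score = _face_band_score(merged, e.path, ratio.pixels, cfg.d0_px)
            if edge_score < face_score:
                drop[e.id] = (edge_score, face_score)
        remove("E:face-merge", drop)

    if cfg.enable_free:
        while True:
            deg: dict[int, int] = {}
            for e in edges:
                for j in e.endpoints:
                    if j is not None:
                        deg[j] = deg.get(j, 0) + 1
            drop = {}
            for e in edges:
                if e.attrs.get("closed"):
                    continue  # an isolated closed loop has no free end
                free = any(
                    j is None or deg.get(j, 0) <= 1 for j in e.endpoints
                )
                if free:
                    drop[e.id] = (np.nan, np.nan)
            if not drop:
                break
            remove("free-standing", drop)

    audited = extract_faces(g.with_edges(edges), mask)
    return audited, log


def meshwork_stats(g: MeshGraph, pixel_size_nm: float | None = None) -> MeshworkStats:
    """Quantify an audited meshwork: face areas, edge lengths, junction degrees.

    Face areas are pixel counts times pixel area; only enclosed faces (not
    touching the mask boundary) enter the area distribution.  Edge lengths sum
    unit and sqrt(2) steps along the path.
    """
    px = pixel_size_nm if pixel_size_nm is not None else g.pixel_size_nm
    areas = np.array(
        [f.area_px * px**2 for f in g.faces if not f.touches_mask_boundary], dtype=float
    )
    lengths = np.array([e.length_px * px for e in g.edges], dtype=float)
    deg = g.junction_degrees()
    active = deg[deg > 0]
    # degree-2 nodes are waypoints where a fiber was split during tracing;
    # a junction proper is a node where at least three edges meet
    return MeshworkStats(
        face_areas_nm2=areas,
        edge_lengths_nm=lengths,
        junction_count=int((deg >= 3).sum()),
        junction_degrees=active,
        pixel_size_nm=float(px),
    )
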