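"""End-to-end meshwork segmentation: filtering through audited graph.

Ties the stages together in dependency order: steerable orientation
detection, non-maximum suppression, nucleus masking, foreground
thresholding, skeleton cleanup, graph conversion, auditing, statistics.
Each stage remains individually callable from its own module; this wrapper
exists for the command line and for whole-pipeline tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from laminmesh import audit as audit_mod
from laminmesh import nucleus_mask as nm
from laminmesh import simqc
from laminmesh import skeleton_graph as sg
from laminmesh import steerable
from laminmesh.types import MeshGraph, NMSMap, OrientationField, RasterImage, Skeleton


@dataclass
class SegmentationResult:
    field: OrientationField
    nms: NMSMap
    mask: nm.NucleusMask
    threshold: float
    skeleton: Skeleton
    graph: MeshGraph


def segment_meshwork(
    img: RasterImage,
    steer_cfg: Optional[steerable.SteerableFilterConfig] = None,
    seg_cfg: Optional[nm.SegmentationConfig] = None,
    max_extend_px: int = 10,
    nms_threshold: Optional[float] = None,
) -> SegmentationResult:
    """Run filtering, masking and graph conversion on one image.

    ``nms_threshold`` overrides the mask-contrast foreground threshold when
    given; everything else follows the stage defaults.
    """
    img.require_pipeline_size()
    seg_cfg = seg_cfg or nm.SegmentationConfig()
    field = steerable.detect_orientations(img, steer_cfg)
    nms_map = steerable.nonmax_suppress(field)
    mask = nm.make_nucleus_mask(nms_map, seg_cfg)
    thr = (
        nms_threshold
        if nms_threshold is not None
        else nm.mask_contrast_threshold(field.response, mask)
    )
    sk = sg.binarize_nms(nms_map, thr)
    sk = sg.thin_skeleton(sk)
    sk = sg.prune_short_segments(sk, seg_cfg.min_segment_px)
    sk = sg.extend_endpoints(sk, field, max_extend_px)
    sk = sg.thin_skeleton(sk)
    classification = sg.find_branchpoints(sk)
    graph = sg.consolidate_junctions(sk, classification)
    graph.pixel_size_nm = img.pixel_size_nm
    graph = sg.extract_faces(graph, mask)
    return SegmentationResult(
        field=field, nms=nms_map, mask=mask, threshold=float(thr), skeleton=sk, graph=graph
    )


@dataclass
class AuditedResult:
    segmentation: SegmentationResult
    ratio: RasterImage
    graph: MeshGraph
    removal_log: list
    stats: audit_mod.MeshworkStats


def segment_and_audit(
    img: RasterImage,
    steer_cfg: Optional[steerable.SteerableFilterConfig] = None,
    seg_cfg: Optional[nm.SegmentationConfig] = None,
    audit_cfg: Optional[audit_mod.AuditConfig] = None,
    max_extend_px: int = 10,
    widefield_resolution_nm: float = 250.0,
    min_face_area_px: int = 9,
) -> AuditedResult:
    """Segment, then audit against the image and its band-ratio."""
    seg = segment_meshwork(img, steer_cfg, seg_cfg, max_extend_px)
    ratio = simqc.band_ratio(img, widefield_resolution_nm=widefield_resolution_nm)
    if audit_cfg is None:
        sigma = (steer_cfg or steerable.SteerableFilterConfig()).sigma_px
        audit_cfg = audit_mod.AuditConfig(d0_px=sigma)
    graph, log = audit_mod.audit_meshwork(
        seg.graph, img, ratio, audit_cfg, mask=seg.mask
    )
    # branch points sit up-stream of the geometric vertex where converging
    # ridges coalesce; re-localize each junction from its incident edge
    # tangents once the audit has removed spurious edges
    sigma = (steer_cfg or steerable.SteerableFilterConfig()).sigma_px
    graph = sg.refine_junction_positions(
        graph, fit_from_px=2.0 * sigma, fit_len_px=8.0 * sigma
    )
    graph = sg.extract_faces(graph, seg.mask, min_face_area_px)
    stats = audit_mod.meshwork_stats(graph)
    return AuditedResult(
        segmentation=seg, ratio=ratio, graph=graph, removal_log=log, stats=stats
    )
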