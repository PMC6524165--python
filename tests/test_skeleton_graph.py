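"""Skeleton-to-graph conversion: pruning, extension, branch points, junctions, faces."""

import numpy as np
import pytest
from scipy import ndimage

from laminmesh import skeleton_graph as sg
from laminmesh.nucleus_mask import NucleusMask
from laminmesh.types import OrientationField, Skeleton


def make_skeleton(shape, pixels, theta=0.0):
    m = np.zeros(shape, bool)
    for p in pixels:
        m[p] = True
    return Skeleton(m, np.full(shape, float(theta)))


class TestBresenham:
    def test_shallow_diagonal_example(self):
        assert sg.bresenham_line((0, 0), (3, 1)) == [(0, 0), (1, 0), (2, 1), (3, 1)]

    def test_endpoints_always_included_and_connected(self, rng):
        for _ in range(50):
            a = tuple(rng.integers(-20, 20, 2))
            b = tuple(rng.integers(-20, 20, 2))
            line = sg.bresenham_line(a, b)
            assert line[0] == a and line[-1] == b
            steps = np.abs(np.diff(np.array(line), axis=0))
            assert steps.max(initial=0) <= 1  # 8-connected path


class TestBinarize:
    def test_zero_threshold_keeps_nms_support(self, rng):
        from laminmesh.types import NMSMap

        values = np.where(rng.random((16, 16)) > 0.7, rng.random((16, 16)), 0.0)
        nms = NMSMap(values, np.zeros_like(values))
        skel = sg.binarize_nms(nms, 0.0)
        assert np.array_equal(skel.mask, values > 0)

    def test_threshold_above_max_empties_skeleton(self, rng):
        from laminmesh.types import NMSMap

        values = rng.random((8, 8))
        skel = sg.binarize_nms(NMSMap(values, np.zeros_like(values)), 2.0)
        assert not skel.mask.any()

    def test_exact_pixel_set_at_intermediate_threshold(self):
        from laminmesh.types import NMSMap

        values = np.array([[0.0, 1.0, 2.0], [3.0, 0.0, 4.0]])
        skel = sg.binarize_nms(NMSMap(values, np.zeros_like(values)), 2.0)
        assert sorted(map(tuple, np.argwhere(skel.mask))) == [(0, 2), (1, 0), (1, 2)]

    def test_monotone_in_threshold(self, rng):
        from laminmesh.types import NMSMap

        values = rng.random((16, 16))
        nms = NMSMap(values, np.zeros_like(values))
        lo = sg.binarize_nms(nms, 0.3).mask
        hi = sg.binarize_nms(nms, 0.6).mask
        assert np.all(lo | ~hi)


class TestPruneShortSegments:
    def test_isolated_four_pixel_segment_removed(self):
        skel = make_skeleton((8, 8), [(2, k) for k in range(2, 6)])
        out = sg.prune_short_segments(skel, min_px=5)
        assert not out.mask.any()

    def test_isolated_five_pixel_segment_kept(self):
        skel = make_skeleton((8, 8), [(2, k) for k in range(2, 7)])
        out = sg.prune_short_segments(skel, min_px=5)
        assert out.mask.sum() == 5

    def test_attached_spur_survives(self):
        pixels = [(4, k) for k in range(1, 31)] + [(3, 10), (2, 10), (1, 10)]
        skel = make_skeleton((8, 32), pixels)
        out = sg.prune_short_segments(skel, min_px=5)
        assert out.mask.sum() == 33

    def test_monotone_in_min_px(self, rng):
        m = rng.random((24, 24)) > 0.7
        skel = Skeleton(m, np.zeros((24, 24)))
        small = sg.prune_short_segments(skel, 3).mask
        large = sg.prune_short_segments(skel, 6).mask
        assert np.all(small | ~large)


class TestExtendEndpoints:
    def test_collinear_gap_bridged(self):
        pixels = [(5, k) for k in range(2, 8)] + [(5, k) for k in range(11, 19)]
        skel = make_skeleton((11, 21), pixels, theta=0.0)
        field = OrientationField(np.zeros((11, 21)), np.zeros((11, 21)))
        out = sg.extend_endpoints(skel, field, max_extend_px=10)
        labels, n = ndimage.label(out.mask, structure=np.ones((3, 3), bool))
        assert n == 1
        assert out.extensions.sum() == 3  # exactly the gap pixels

    def test_orientation_off_border_adds_nothing(self):
        pixels = [(5, k) for k in range(0, 6)]  # endpoint facing the left border
        skel = make_skeleton((11, 11), pixels, theta=0.0)
        field = OrientationField(np.zeros((11, 11)), np.zeros((11, 11)))
        out = sg.extend_endpoints(skel, field, max_extend_px=10)
        # right endpoint extends to nothing (runs off), left also: mask unchanged
        assert np.array_equal(out.mask, skel.mask)

    def test_zero_budget_is_identity(self):
        skel = make_skeleton((8, 8), [(4, 1), (4, 2), (4, 3)])
        field = OrientationField(np.zeros((8, 8)), np.zeros((8, 8)))
        out = sg.extend_endpoints(skel, field, max_extend_px=0)
        assert np.array_equal(out.mask, skel.mask)

    def test_unconnected_extension_discarded(self):
        pixels = [(5, k) for k in range(2, 8)]  # nothing to the right within reach
        skel = make_skeleton((11, 40), pixels, theta=0.0)
        field = OrientationField(np.zeros((11, 40)), np.zeros((11, 40)))
        out = sg.extend_endpoints(skel, field, max_extend_px=5)
        assert np.array_equal(out.mask, skel.mask)


def brute_force_classify(neigh3x3):
    """Oracle for the 3x3 rule: >=3 white 8-neighbors whose intervening black
    pixels are not 4-connected (= more than one 4-component of black ring
    pixels); endpoint at <=1 white neighbor."""
    whites = int(neigh3x3.sum()) - 1  # exclude white center
    if whites <= 1:
        return sg.ENDPOINT
    if whites >= 3:
        black = ~neigh3x3.copy()
        black[1, 1] = False  # center is white
        _, n_black = ndimage.label(black, structure=ndimage.generate_binary_structure(2, 1))
        if n_black >= 2:
            return sg.BRANCHPOINT
    return sg.EDGE_PIXEL


class TestFindBranchpoints:
    def test_plus_cross_center_is_branchpoint(self):
        pixels = [(4, k) for k in range(2, 7)] + [(k, 4) for k in range(2, 7)]
        skel = make_skeleton((9, 9), pixels)
        cls = sg.find_branchpoints(skel)
        assert cls[4, 4] == sg.BRANCHPOINT

    def test_straight_line_interior_is_edge_pixel(self):
        skel = make_skeleton((5, 9), [(2, k) for k in range(1, 8)])
        cls = sg.find_branchpoints(skel)
        assert np.all(cls[2, 2:7] == sg.EDGE_PIXEL)
        assert cls[2, 1] == sg.ENDPOINT and cls[2, 7] == sg.ENDPOINT

    def test_all_512_neighborhoods_match_brute_force(self):
        # every 3x3 configuration with a white center, embedded in isolation
        for code in range(256):
            neigh = np.zeros((3, 3), bool)
            neigh[1, 1] = True
            for i, (dr, dc) in enumerate(sg._OFFSETS):
                if code >> i & 1:
                    neigh[1 + dr, 1 + dc] = True
            img = np.zeros((5, 5), bool)
            img[1:4, 1:4] = neigh
            cls = sg.find_branchpoints(Skeleton(img, np.zeros((5, 5))))
            assert cls[2, 2] == brute_force_classify(neigh), f"config {code}"


class TestConsolidateJunctions:
    def test_single_branchpoint_becomes_junction_at_itself(self):
        pixels = [(4, k) for k in range(1, 8)] + [(k, 4) for k in range(1, 4)]
        skel = make_skeleton((9, 9), pixels)
        cls = sg.find_branchpoints(skel)
        g = sg.consolidate_junctions(skel, cls)
        assert (4, 4) in g.junctions

    def test_two_branchpoints_with_short_connector_merge(self):
        # T-junctions at (4,4) and (4,7) joined by a 2-px run (4,5),(4,6)
        pixels = (
            [(4, k) for k in range(1, 11)]
            + [(k, 4) for k in range(1, 4)]
            + [(k, 7) for k in range(5, 8)]
        )
        skel = make_skeleton((9, 12), pixels)
        cls = sg.find_branchpoints(skel)
        assert cls[4, 4] == sg.BRANCHPOINT and cls[4, 7] == sg.BRANCHPOINT
        g = sg.consolidate_junctions(skel, cls)
        # zone = {(4,4),(4,5),(4,6),(4,7)} -> centroid (4, 5.5) -> rounds to (4, 6)
        assert (4, 6) in g.junctions
        assert len(g.junctions) == 1

    def test_edge_paths_are_8_connected_and_linked(self, audited_phantom):
        res, _ = audited_phantom
        for e in res.graph.edges:
            p = np.asarray(e.path)
            if len(p) > 1:
                steps = np.abs(np.diff(p, axis=0)).max(axis=1)
                assert steps.max() <= 1
            for jid, end in zip(e.endpoints, [p[0], p[-1]]):
                if jid is not None:
                    assert tuple(end) == tuple(res.graph.junctions[jid])


class TestExtractFaces:
    @staticmethod
    def graph_from_pixels(shape, pixels):
        skel = make_skeleton(shape, pixels)
        cls = sg.find_branchpoints(skel)
        return sg.consolidate_junctions(skel, cls)

    def test_rectangle_boundary_encloses_one_face(self):
        pixels = (
            [(2, k) for k in range(2, 9)]
            + [(8, k) for k in range(2, 9)]
            + [(k, 2) for k in range(3, 8)]
            + [(k, 8) for k in range(3, 8)]
        )
        g = self.graph_from_pixels((12, 12), pixels)
        mask = NucleusMask(np.ones((12, 12), bool), {})
        g = sg.extract_faces(g, mask)
        inner = [f for f in g.faces if not f.touches_mask_boundary]
        assert len(inner) == 1
        assert inner[0].area_px == 5 * 5

    def test_three_by_three_grid_of_squares_gives_nine_faces(self):
        pixels = []
        for line in (2, 8, 14, 20):
            pixels += [(line, k) for k in range(2, 21)]
            pixels += [(k, line) for k in range(2, 21)]
        g = self.graph_from_pixels((24, 24), pixels)
        g = sg.extract_faces(g, NucleusMask(np.ones((24, 24), bool), {}))
        inner = [f for f in g.faces if not f.touches_mask_boundary]
        assert len(inner) == 9
        assert all(f.area_px == 25 for f in inner)

    def test_no_edges_yields_single_face_of_mask_interior(self):
        from laminmesh.types import MeshGraph

        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        g = MeshGraph(junctions=[], edges=[], shape=(10, 10))
        g = sg.extract_faces(g, NucleusMask(mask, {}))
        assert len(g.faces) == 1
        assert g.faces[0].area_px == 36

    def test_outside_mask_is_never_a_face(self):
        from laminmesh.types import MeshGraph

        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        g = sg.extract_faces(
            MeshGraph(junctions=[], edges=[], shape=(10, 10)), NucleusMask(mask, {})
        )
        covered = np.zeros((10, 10), bool)
        for f in g.faces:
            covered[f.pixels[:, 0], f.pixels[:, 1]] = True
        assert not covered[~mask].any()

    def test_faces_record_their_bounding_edges(self):
        pixels = (
            [(2, k) for k in range(2, 9)]
            + [(8, k) for k in range(2, 9)]
            + [(k, 2) for k in range(3, 8)]
            + [(k, 8) for k in range(3, 8)]
        )
        g = self.graph_from_pixels((12, 12), pixels)
        g = sg.extract_faces(g, NucleusMask(np.ones((12, 12), bool), {}))
        inner = [f for f in g.faces if not f.touches_mask_boundary][0]
        assert len(inner.edge_ids) >= 1


class TestRefineAndContract:
    def test_contract_merges_junction_pair_connected_by_short_edge(self):
        # H-shape: two T junctions joined by a 3-px bar
        pixels = (
            [(k, 3) for k in range(1, 10)]
            + [(k, 9) for k in range(1, 10)]
            + [(5, k) for k in range(4, 9)]
        )
        skel = make_skeleton((11, 13), pixels)
        cls = sg.find_branchpoints(skel)
        g = sg.consolidate_junctions(skel, cls)
        assert len(g.junctions) == 2
        g2 = sg.contract_short_edges(g, max_len_px=8.0)
        assert len(g2.junctions) == 1
        # the four vertical legs remain
        assert len(g2.edges) == len(g.edges) - 1

    def test_refine_moves_displaced_vertex_to_tangent_intersection(self):
        # three straight legs whose lines meet at (12, 12), but the recorded
        # junction sits displaced at (10, 12)
        from laminmesh.types import MeshEdge, MeshGraph

        legs = []
        for d in [(-1, 0), (1, 1), (1, -1)]:
            path = [(12 + d[0] * k, 12 + d[1] * k) for k in range(11, 0, -1)]
            legs.append(path)
        edges = [
            MeshEdge(id=i, path=p + [(10, 12)], endpoints=(None, 0), attrs={})
            for i, p in enumerate(legs)
        ]
        g = MeshGraph(junctions=[(10, 12)], edges=edges, shape=(25, 25))
        g2 = sg.refine_junction_positions(g, fit_from_px=2, fit_len_px=8)
        assert g2.junctions[0] == (12, 12)
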