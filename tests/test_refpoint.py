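import math
import warnings

import numpy as np
import pytest
from scipy import ndimage as ndi

from ffaleak import synthetic as syn
from ffaleak.io_core import FFAImage
from ffaleak.refpoint import (
    ReferencePointError,
    build_graph,
    fit_local_line,
    prune,
    reference_point,
    reference_point_from_mask,
    skeletonize,
    vote,
)


def _euler_holes(mask):
    """Number of holes = components of the background not touching the border."""
    inv_labels, n = ndi.label(~mask)
    border = set(inv_labels[0]) | set(inv_labels[-1]) | set(inv_labels[:, 0]) | set(inv_labels[:, -1])
    return len(set(range(1, n + 1)) - border)


class TestSkeletonize:
    def test_solid_bar_thins_to_single_line(self):
        mask = np.zeros((20, 60), bool)
        mask[8:13, 5:55] = True
        skel = skeletonize(mask)
        cols = skel[:, 15:45]
        assert (cols.sum(axis=0) == 1).all()

    def test_single_pixel_survives(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert (skeletonize(mask) == mask).all()

    def test_empty_mask_gives_empty_skeleton(self):
        assert not skeletonize(np.zeros((8, 8), bool)).any()

    def test_annulus_keeps_its_hole(self):
        rr, cc = np.indices((64, 64))
        d2 = (rr - 32) ** 2 + (cc - 32) ** 2
        ring = (d2 <= 25**2) & (d2 >= 15**2)
        skel = skeletonize(ring)
        assert _euler_holes(skel) == 1
        labels, n = ndi.label(skel, structure=np.ones((3, 3)))
        assert n == 1


class TestBuildGraph:
    def test_straight_line(self):
        skel = np.zeros((20, 60), bool)
        skel[10, 5:55] = True
        g = build_graph(skel)
        kinds = [d["kind"] for _, d in g.graph.nodes(data=True)]
        assert kinds.count("termination") == 2
        assert g.n_edges() == 1
        assert len(g.chains[0]) == 50

    def test_plus_shape(self):
        skel = np.zeros((21, 21), bool)
        skel[10, 2:19] = True
        skel[2:19, 10] = True
        g = build_graph(skel)
        kinds = [d["kind"] for _, d in g.graph.nodes(data=True)]
        assert kinds.count("bifurcation") == 1
        assert kinds.count("termination") == 4
        assert g.n_edges() == 4

    def test_closed_loop_becomes_anchored_cycle(self):
        rr, cc = np.indices((32, 32))
        ring = np.abs(np.hypot(rr - 16, cc - 16) - 10) < 0.6
        skel = skeletonize(ring)
        g = build_graph(skel)
        assert g.n_edges() == 1
        u, v, _ = list(g.graph.edges(data=True))[0]
        assert u == v  # self-edge

    def test_chain_endpoints_belong_to_their_nodes(self):
        skel = np.zeros((21, 21), bool)
        skel[10, 2:19] = True
        skel[2:10, 10] = True
        g = build_graph(skel)
        for u, v, d in g.graph.edges(data=True):
            chain = d["chain"]
            assert chain[0] in g.graph.nodes[u]["pixels"] or chain[0] in g.graph.nodes[v]["pixels"]
            assert chain[-1] in g.graph.nodes[u]["pixels"] or chain[-1] in g.graph.nodes[v]["pixels"]


class TestPrune:
    def _y_shape(self, spur_len=3):
        skel = np.zeros((40, 40), bool)
        skel[20, 2:30] = True  # main line
        for k in range(1, spur_len + 1):  # diagonal spur from (20, 15)
            skel[20 - k, 15 + k] = True
        return skel

    def test_zero_threshold_is_identity(self):
        skel = self._y_shape()
        g = prune(build_graph(skel), 0)
        assert (g.skeleton == skel).all()

    def test_short_spur_removed_and_edges_merged(self):
        g = prune(build_graph(self._y_shape(3)), 10)
        assert g.n_edges() == 1
        kinds = [d["kind"] for _, d in g.graph.nodes(data=True)]
        assert kinds.count("bifurcation") == 0

    def test_long_spur_kept(self):
        g = prune(build_graph(self._y_shape(15)), 10)
        assert g.n_edges() == 3

    def test_cascading_stubs_removed_iteratively(self):
        # a comb: main line with many short teeth; removing teeth leaves a
        # clean line after repeated passes
        skel = np.zeros((30, 80), bool)
        skel[15, 5:75] = True
        for c in range(10, 70, 6):
            skel[12:15, c] = True
        g = prune(build_graph(skel), 8)
        assert g.n_edges() == 1
        # teeth gone, and the short left-end stub exposed by the first tooth
        # junction (cols 5..9) was itself pruned in a later pass
        assert len(g.chains[0]) == 65
        assert set(np.argwhere(g.skeleton)[:, 0]) == {15}

    def test_idempotent(self):
        g1 = prune(build_graph(self._y_shape(3)), 10)
        g2 = prune(g1, 10)
        assert (g1.skeleton == g2.skeleton).all()


class TestFitLocalLine:
    def test_horizontal_points(self):
        chain = [(10, c) for c in range(30)]
        fit = fit_local_line(chain, 15, 8.0)
        assert abs(fit.direction[0]) < 1e-9
        assert abs(fit.point[0] - 10) < 1e-9

    def test_vertical_points_supported(self):
        chain = [(r, 7) for r in range(30)]
        fit = fit_local_line(chain, 15, 8.0)
        assert abs(fit.direction[1]) < 1e-9

    def test_diagonal_direction(self):
        chain = [(k, k) for k in range(30)]
        fit = fit_local_line(chain, 15, 10.0)
        d = np.abs(fit.direction)
        assert np.allclose(d, [1 / math.sqrt(2)] * 2, atol=1e-9)

    def test_arc_tangent_within_ten_degrees(self):
        R, L0 = 90.0, 30.0
        thetas = np.linspace(0, math.pi / 2, 200)
        chain = [(R * math.sin(t), R * math.cos(t)) for t in thetas]
        i = 100
        fit = fit_local_line(chain, i, L0)
        t_i = thetas[i]
        tangent = np.array([math.cos(t_i), -math.sin(t_i)])
        ang = math.degrees(math.acos(min(1.0, abs(float(np.dot(fit.direction, tangent))))))
        assert ang < 10.0

    def test_too_few_points_skipped(self):
        chain = [(0, 0), (20, 20)]
        assert fit_local_line(chain, 0, 5.0) is None


class TestVote:
    def _graph_from_skel(self, skel):
        return build_graph(skel)

    def test_single_straight_chain_votes_on_its_own_line(self):
        skel = np.zeros((64, 64), bool)
        skel[20, 4:60] = True
        acc = vote(self._graph_from_skel(skel), 10.0)
        assert acc.A[20].max() == acc.A.max()
        # votes are concentrated on row 20
        assert acc.A[20].sum() > 0.95 * acc.A.sum()

    def test_vote_count_conservation(self):
        skel = np.zeros((64, 64), bool)
        skel[20, 4:60] = True
        skel[4:60, 40] = True
        acc = vote(self._graph_from_skel(skel), 10.0)
        assert acc.A.sum() == acc.total_votes

    def test_two_crossing_chains_peak_at_intersection(self):
        skel = np.zeros((200, 200), bool)
        skel[100, 10:80] = True  # horizontal, crosses col 100 when extended
        skel[10:80, 100] = True  # vertical
        acc = vote(self._graph_from_skel(skel), 15.0)
        peak = np.unravel_index(np.argmax(acc.A), acc.A.shape)
        assert abs(peak[0] - 100) <= 1 and abs(peak[1] - 100) <= 1

    def test_spoke_phantom_peak_at_center(self):
        spec = syn.PhantomSpec(
            n_primaries=6, depth=0, tortuosity=0.0, noise_std=0.0,
            jitter_translation_max=0.0, jitter_angle_max=0.0,
        )
        img, truth = syn.generate_vessel_tree(spec, np.random.default_rng(0))
        skel = skeletonize(truth.centerline_mask)
        g = prune(build_graph(skel), 20)
        acc = vote(g, 30.0)
        sm = ndi.gaussian_filter(acc.A.astype(float), 2.0)
        peak = np.unravel_index(np.argmax(sm), sm.shape)
        c = truth.convergence_point
        assert math.hypot(peak[0] - c[0], peak[1] - c[1]) <= 2.0

    def test_empty_graph_warns_and_returns_zero(self):
        g = build_graph(np.zeros((16, 16), bool))
        with pytest.warns(UserWarning):
            acc = vote(g, 10.0)
        assert acc.total_votes == 0 and not acc.A.any()


class TestReferencePoint:
    def test_recovers_phantom_convergence_point(self, still_frame):
        frame, truth = still_frame
        pt = reference_point(frame)
        c = truth.convergence_point
        assert math.hypot(pt[0] - c[0], pt[1] - c[1]) <= 5.0

    def test_translation_equivariance(self, still_frame):
        frame, truth = still_frame
        pt = reference_point(frame)
        shifted = np.roll(frame.pixels, (20, -10), axis=(0, 1))
        roi = np.roll(frame.roi, (20, -10), axis=(0, 1))
        pt2 = reference_point(FFAImage(shifted, roi, 0.0))
        assert abs(pt2[0] - pt[0] - 20) <= 2 and abs(pt2[1] - pt[1] + 10) <= 2

    def test_vessel_free_frame_raises(self):
        with pytest.raises(ReferencePointError):
            reference_point_from_mask(np.zeros((64, 64), bool))
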