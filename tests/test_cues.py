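"""Convexity, closure and symmetry indices against oracles and invariances."""

import numpy as np
import pytest

from contourcues import closure, convexity, local_frame
from contourcues.cues import (
    N_RAYS,
    PROBE_OFFSET,
    crossing_count,
    cue_vector,
    dos,
    optimal_axis,
    symmetry_index,
)
from contourcues.geometry import LocalFrame
from contourcues.synth import generate_arc, generate_blob

from conftest import make_patch, mirror_patch, oracle_closure, rot90_patch


class TestConvexity:
    def test_straight_contour_is_zero(self, vertical_line_patch):
        assert convexity(local_frame(vertical_line_patch)) == 0.0

    def test_circle_radius_20_closed_form(self):
        frame = local_frame(generate_arc(20, 180))
        assert convexity(frame) == pytest.approx(np.log(1.05), rel=0.1)


class TestClosure:
    def test_straight_line_is_zero(self, vertical_line_patch):
        frame = local_frame(vertical_line_patch)
        assert closure(vertical_line_patch, frame) == 0

    def test_enclosing_circle_positive_with_full_convex_count(self):
        patch = generate_arc(12, 360)
        frame = local_frame(patch)
        probe = np.array(patch.center, float) + PROBE_OFFSET * frame.convex_normal
        assert crossing_count(patch, probe, frame.convex_normal) == N_RAYS
        assert closure(patch, frame) > 0

    def test_mirror_invariance(self, random_patch_pool):
        for patch, frame in random_patch_pool[:6]:
            mirrored = mirror_patch(patch)
            assert closure(mirrored, local_frame(mirrored)) == closure(patch, frame)

    def test_range_and_oracle_agreement(self, random_patch_pool):
        for patch, frame in random_patch_pool:
            c = closure(patch, frame)
            assert -N_RAYS <= c <= N_RAYS
            assert c == oracle_closure(patch, frame)

    def test_nested_circles_closure_complements_concave_count(self):
        # while the convex probe stays enclosed, Closure = 16 - N_concave
        for radius in (8, 12, 16):
            patch = generate_arc(radius, 360)
            frame = local_frame(patch)
            probe_in = np.array(patch.center, float) + PROBE_OFFSET * frame.convex_normal
            probe_out = np.array(patch.center, float) - PROBE_OFFSET * frame.convex_normal
            assert crossing_count(patch, probe_in, frame.convex_normal) == N_RAYS
            n_concave = crossing_count(patch, probe_out, -frame.convex_normal)
            assert closure(patch, frame) == N_RAYS - n_concave


class TestDos:
    def test_one_sided_contour_no_mirror_partner(self):
        grid = np.zeros((69, 69), dtype=np.uint8)
        grid[34, 20:35] = 1
        patch = make_patch(grid)
        # axis at column 54: the whole (even dilated) contour lies left of it
        assert dos(patch, 0, -20) == 0.0
        assert dos(patch, 0, -20, dilate=False) == 0.0

    def test_symmetric_blob_max_at_true_axis(self):
        patch = generate_blob([3, 2], mirror_symmetric=True, axis_deg=0)
        at_axis = dos(patch, 0, 0)
        sampled = max(dos(patch, th, x)
                      for th in range(0, 180, 5) for x in range(-30, 31, 3))
        assert at_axis == pytest.approx(sampled)
        assert at_axis >= sampled

    def test_rigid_cotransform_within_resampling_tolerance(self):
        base = generate_blob([3, 2], mirror_symmetric=True, axis_deg=0)
        rotated = generate_blob([3, 2], mirror_symmetric=True, axis_deg=30)
        assert dos(rotated, 30, 0) == pytest.approx(dos(base, 0, 0), rel=0.25)


class TestOptimalAxis:
    def test_planted_axis_recovery(self):
        res = optimal_axis(generate_blob([3, 2], mirror_symmetric=True, axis_deg=30))
        assert abs(res.theta_star - 30.0) <= 1.0

    def test_full_circle_tiebreak_theta_zero(self):
        # symmetrize the raster about the circle center so the vertical and
        # horizontal axes tie exactly at the perfect-overlap count; the
        # tie-break then returns the smallest theta
        circle = generate_arc(15, 360)
        grid = circle.grid
        grid = np.maximum(grid, grid[::-1, :])  # mirror about row 34
        sub = grid[:, 30:]  # circle spans cols 34..64, center col 49
        grid[:, 30:] = np.maximum(sub, sub[:, ::-1])
        patch = make_patch(grid)
        res = optimal_axis(patch)
        assert res.theta_star == 0.0
        assert res.x_star == -15

    def test_straight_line_axis_collinear(self, vertical_line_patch):
        res = optimal_axis(vertical_line_patch)
        assert res.theta_star == 0.0
        assert res.x_star == 0

    def test_matches_grid_evaluation(self):
        rng = np.random.default_rng(5)
        patch = generate_blob([3, 2, 1], mirror_symmetric=False, seed=2)
        res = optimal_axis(patch)
        assert dos(patch, res.theta_star, res.x_star) == pytest.approx(res.dos_star)
        for _ in range(200):
            th = int(rng.integers(180))
            x = int(rng.integers(-34, 35))
            assert dos(patch, th, x) <= res.dos_star + 1e-12


class TestSymmetryIndex:
    def test_corpus_maximum_patch_has_magnitude_one(self, random_patch_pool):
        sym = generate_blob([3, 2], mirror_symmetric=True, axis_deg=0)
        corpus = [sym] + [p for p, _ in random_patch_pool[:6]]
        searches = [optimal_axis(p) for p in corpus]
        m = max(s.dos_star for s in searches)
        assert searches[0].dos_star == m  # the planted blob attains the max
        value = symmetry_index(sym, local_frame(sym), m, search=searches[0])
        assert abs(value) == pytest.approx(1.0)

    def test_magnitude_bounded_by_one(self, random_patch_pool):
        searches = [optimal_axis(p) for p, _ in random_patch_pool[:8]]
        m = max(s.dos_star for s in searches)
        for (patch, frame), s in zip(random_patch_pool[:8], searches):
            assert abs(symmetry_index(patch, frame, m, search=s)) <= 1.0 + 1e-12

    def test_axis_through_concave_side_gives_negative_sign(self):
        # shallow arc bulging right (convex side = larger columns) plus a
        # strongly symmetric circle on the concave side: the optimal axis is
        # the circle's vertical diameter, lying wholly on the concave side
        arc = generate_arc(30, 90)
        grid = arc.grid.copy()
        rr, cc = np.mgrid[0:69, 0:69]
        ring = np.abs(np.hypot(rr - 24.0, cc - 14.0) - 9.0) < 0.5
        grid[ring] = 1
        patch = make_patch(grid, chain=arc.chain)
        frame = local_frame(patch)
        assert frame.convex_normal[1] > 0  # convex side toward larger columns
        res = optimal_axis(patch)
        m = res.dos_star
        assert symmetry_index(patch, frame, m, search=res) < 0

    def test_invalid_corpus_max(self, vertical_line_patch):
        frame = local_frame(vertical_line_patch)
        with pytest.raises(ValueError):
            symmetry_index(vertical_line_patch, frame, 0.0)


class TestRotationInvariance:
    @pytest.mark.parametrize("k", [1, 2])
    def test_indices_invariant_under_90_degree_rotation(self, k):
        patch = generate_blob([3, 2], mirror_symmetric=True, axis_deg=0)
        frame = local_frame(patch)
        rot = rot90_patch(patch, k)
        rot_frame = local_frame(rot)
        assert convexity(rot_frame) == pytest.approx(convexity(frame), rel=0.05, abs=1e-3)
        assert closure(rot, rot_frame) == closure(patch, frame)
        a = optimal_axis(patch)
        b = optimal_axis(rot)
        assert b.dos_star == pytest.approx(a.dos_star, rel=0.02)
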