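"""Radial-grid DP active contour: geometry, exactness, masks, metrics."""

import itertools

import numpy as np
import pytest

from toothstage import dpac, phantom
from toothstage.dpac import DpConfig


def brute_force_energy(g, grid, delta, sentinel):
    """Exhaustive minimum over all N^M tuples under the DP edge-cost rule."""
    M, N = g.shape
    pts = grid.points()
    best = np.inf
    for tup in itertools.product(range(N), repeat=M):
        e = 0.0
        for i in range(M):
            j, k = tup[i], tup[(i + 1) % M]
            d = np.hypot(*(pts[i, j] - pts[(i + 1) % M, k]))
            e += -g[i, j] if d <= delta + 1e-12 else sentinel
        best = min(best, e)
    return best


class TestRadialGrid:
    def test_recommended_setting_shape(self):
        grid = dpac.build_radial_grid((125, 125), 1200, 100, 1)
        assert (grid.n_lines, grid.n_graduations) == (1200, 100)

    def test_four_axis_aligned_lines(self):
        """M=4, radius 2, spacing 1: points at center +- {1,2} along axes."""
        grid = dpac.build_radial_grid((0.0, 0.0), 4, 2, 1)
        pts = grid.points()
        # angle 0 -> +col, angle pi/2 -> +row, etc.
        np.testing.assert_allclose(pts[0], [[0, 1], [0, 2]], atol=1e-12)
        np.testing.assert_allclose(pts[1], [[1, 0], [2, 0]], atol=1e-12)
        np.testing.assert_allclose(pts[2], [[0, -1], [0, -2]], atol=1e-12)
        np.testing.assert_allclose(pts[3], [[-1, 0], [-2, 0]], atol=1e-12)

    def test_point_matches_polar_formula(self):
        grid = dpac.build_radial_grid((10.0, 20.0), 12, 24, 2)
        i, j = 3, 9
        theta = 2 * np.pi * i / 12
        r = (j + 1) * 2
        np.testing.assert_allclose(
            grid.points()[i, j],
            [10.0 + r * np.sin(theta), 20.0 + r * np.cos(theta)])

    def test_parameter_minima_rejected(self):
        with pytest.raises(ValueError):
            dpac.build_radial_grid((0, 0), 2, 10, 1)
        with pytest.raises(ValueError):
            dpac.build_radial_grid((0, 0), 8, 1.5, 1)


class TestDirectionalGradient:
    def test_constant_image_all_zero(self):
        grid = dpac.build_radial_grid((10, 10), 8, 6, 1)
        g = dpac.directional_gradient(np.full((21, 21), 0.5), grid)
        np.testing.assert_array_equal(g, 0.0)

    def test_column_ramp_gives_cos_theta(self):
        """I(r,c) = c/(w-1): gradient is (0, 1/(w-1)); projection on the
        outward direction of line i is cos(angle_i)/(w-1)."""
        w = 41
        img = np.tile(np.linspace(0, 1, w), (w, 1))
        grid = dpac.build_radial_grid((20, 20), 16, 10, 1)
        g = dpac.directional_gradient(img, grid)
        expected = np.cos(grid.angles)[:, None] / (w - 1)
        np.testing.assert_allclose(g, np.broadcast_to(expected, g.shape), atol=1e-9)

    def test_dark_disk_peak_at_boundary_radius(self):
        side, r0 = 81, 25
        yy, xx = np.indices((side, side)) - side // 2
        img = np.where(yy**2 + xx**2 <= r0**2, 0.1, 0.9)
        grid = dpac.build_radial_grid((side // 2, side // 2), 36, 38, 1)
        g = dpac.directional_gradient(img, grid)
        peak = np.abs(g).argmax(axis=1)
        assert np.all(np.abs(grid.radii[peak] - r0) <= 1.5)


class TestStageCost:
    def test_within_delta_negative_gradient(self):
        cfg = DpConfig(delta=5.0)
        assert dpac.stage_cost(2.5, (0, 0), (3, 4), cfg) == -2.5

    def test_beyond_delta_sentinel(self):
        cfg = DpConfig(delta=4.9, infeasible_cost=1e6)
        assert dpac.stage_cost(2.5, (0, 0), (3, 4), cfg) == 1e6

    def test_zero_gradient_zero_cost(self):
        assert dpac.stage_cost(0.0, (0, 0), (0, 1), DpConfig(delta=2.0)) == 0.0


class TestSolver:
    @pytest.mark.parametrize("trial", range(20))
    def test_exact_closure_equals_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        M = int(rng.integers(3, 6))
        N = int(rng.integers(2, 5))
        grid = dpac.build_radial_grid((0.0, 0.0), M, N, 1.0)
        g = rng.normal(0, 1, (M, N))
        delta = float(rng.uniform(0.5, 3.0))
        sentinel = M * float(np.abs(g).max()) + 1.0
        cfg = DpConfig(delta=delta, closure="exact", bright_object=False,
                       infeasible_cost=sentinel)
        sol = dpac.solve_closed_contour(g, grid, cfg)
        assert sol.energy == pytest.approx(
            brute_force_energy(g, grid, delta, sentinel), abs=1e-9)

    def test_generous_delta_picks_per_line_maximum(self):
        """With every pair within delta the optimum decouples per line."""
        rng = np.random.default_rng(5)
        grid = dpac.build_radial_grid((0.0, 0.0), 4, 3, 1.0)
        g = rng.normal(0, 1, (4, 3))
        cfg = DpConfig(delta=100.0, bright_object=False)
        sol = dpac.solve_closed_contour(g, grid, cfg)
        assert sol.feasible
        np.testing.assert_array_equal(sol.selection, g.argmax(axis=1))
        assert sol.energy == pytest.approx(-g.max(axis=1).sum())

    def test_energy_equals_recomputed_stage_costs(self):
        rng = np.random.default_rng(6)
        grid = dpac.build_radial_grid((0.0, 0.0), 6, 4, 1.0)
        g = rng.normal(0, 1, (6, 4))
        cfg = DpConfig(delta=2.5, bright_object=False, infeasible_cost=50.0)
        sol = dpac.solve_closed_contour(g, grid, cfg)
        pts = grid.points()
        total = sum(
            dpac.stage_cost(g[i, sol.selection[i]],
                            pts[i, sol.selection[i]],
                            pts[(i + 1) % 6, sol.selection[(i + 1) % 6]], cfg)
            for i in range(6))
        assert sol.energy == pytest.approx(total)

    def test_feasible_solutions_satisfy_delta_bound(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            grid = dpac.build_radial_grid((0.0, 0.0), 5, 4, 1.0)
            g = rng.normal(0, 1, (5, 4))
            sol = dpac.solve_closed_contour(
                g, grid, DpConfig(delta=2.0, bright_object=False))
            if sol.feasible:
                d = np.hypot(*(sol.points - np.roll(sol.points, -1, axis=0)).T)
                assert np.all(d <= 2.0 + 1e-9)

    def test_enlarging_delta_never_increases_energy(self):
        rng = np.random.default_rng(8)
        grid = dpac.build_radial_grid((0.0, 0.0), 6, 4, 1.0)
        g = rng.normal(0, 1, (6, 4))
        energies = [
            dpac.solve_closed_contour(
                g, grid, DpConfig(delta=d, bright_object=False,
                                  infeasible_cost=100.0)).energy
            for d in (0.7, 1.2, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(energies) <= 1e-12)

    def test_intensity_scaling_scales_energy_not_contour(self, clean_phantom):
        cfg = DpConfig(delta=3.0)
        grid = dpac.build_radial_grid((124.5, 124.5), 90, 80, 1.0)
        g1 = dpac.directional_gradient(clean_phantom.image, grid)
        g2 = dpac.directional_gradient(clean_phantom.image * 0.5, grid)
        s1 = dpac.solve_closed_contour(g1, grid, cfg)
        s2 = dpac.solve_closed_contour(g2, grid, cfg)
        np.testing.assert_array_equal(s1.selection, s2.selection)
        assert s2.energy == pytest.approx(0.5 * s1.energy, rel=1e-6)

    def test_two_pass_close_to_exact_on_phantom(self, clean_phantom):
        _, m_exact = dpac.segment(clean_phantom.image, config=DpConfig(closure="exact"))
        _, m_two = dpac.segment(clean_phantom.image, config=DpConfig(closure="two_pass"))
        assert dpac.dice(m_exact, m_two) > 0.99

    def test_disk_phantom_recovers_known_radius(self):
        """Noise-free bright disk: selected radii within 1 graduation of r0."""
        side, r0 = 121, 35
        yy, xx = np.indices((side, side)) - side // 2
        img = np.where(yy**2 + xx**2 <= r0**2, 0.9, 0.1)
        grid = dpac.build_radial_grid((side // 2, side // 2), 360, 50, 1.0)
        g = dpac.directional_gradient(img, grid)
        sol = dpac.solve_closed_contour(g, grid, DpConfig(delta=3.0))
        assert sol.feasible
        assert np.all(np.abs(grid.radii[sol.selection] - r0) <= 1.0)


class TestMaskAndMetrics:
    def test_square_polygon_area_inclusive(self):
        pts = np.array([[10, 10], [10, 20], [20, 20], [20, 10]], float)
        mask = dpac.contour_to_mask(pts, (30, 30))
        assert mask.sum() == 121  # 11x11 boundary-inclusive

    def test_orientation_invariance(self):
        tri = np.array([[5, 5], [5, 25], [25, 15]], float)
        m1 = dpac.contour_to_mask(tri, (30, 30))
        m2 = dpac.contour_to_mask(tri[::-1], (30, 30))
        np.testing.assert_array_equal(m1, m2)

    def test_circle_area_within_two_percent(self):
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        pts = np.column_stack([40 + 30 * np.sin(theta), 40 + 30 * np.cos(theta)])
        mask = dpac.contour_to_mask(pts, (81, 81))
        assert abs(mask.sum() - np.pi * 30**2) / (np.pi * 30**2) < 0.02

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            dpac.contour_to_mask(np.array([[0, 0], [1, 1], [2, 2]], float), (10, 10))

    def test_apply_mask_elementwise(self, rng):
        img = rng.random((20, 20))
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[:, 10:] = 1
        np.testing.assert_array_equal(dpac.apply_mask(img, mask), img * mask)
        np.testing.assert_array_equal(dpac.apply_mask(img, np.ones_like(mask)), img)
        assert dpac.apply_mask(img, np.zeros_like(mask)).max() == 0.0

    def test_dice_jaccard_closed_forms(self):
        a = np.zeros((20, 20), dtype=np.uint8)
        b = np.zeros((20, 20), dtype=np.uint8)
        a[:10, :10] = 1          # |A| = 100
        b[5:15, :10] = 1         # |B| = 100, overlap 50
        assert dpac.dice(a, a) == 1.0
        assert dpac.dice(a, 1 - a) == 0.0
        assert dpac.dice(a, b) == pytest.approx(0.5)
        assert dpac.jaccard(a, b) == pytest.approx(1 / 3)
        assert dpac.dice(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_jaccard_dice_identity_random_pairs(self, rng):
        for _ in range(50):
            a = rng.random((15, 15)) > 0.5
            b = rng.random((15, 15)) > 0.5
            d, j = dpac.dice(a, b), dpac.jaccard(a, b)
            assert j == pytest.approx(d / (2 - d), abs=1e-12)

    def test_grading_on_constructed_erosion_dilation(self, clean_phantom):
        from scipy import ndimage as ndi
        truth = clean_phantom.truth_mask
        assert dpac.grade_segmentation(truth, truth) == "well"
        eroded = ndi.binary_erosion(truth, iterations=8)
        assert dpac.grade_segmentation(eroded, truth, tol=0.2) == "under"
        dilated = ndi.binary_dilation(truth, iterations=8)
        assert dpac.grade_segmentation(dilated, truth, tol=0.2) == "over"


class TestParameterSweep:
    def test_single_case_single_setting_consistency(self, clean_phantom):
        center = (124.5, 124.5)
        cases = [(clean_phantom.image, center, clean_phantom.truth_mask)]
        table = dpac.parameter_sweep(cases, radius_lengths=[80], line_counts=[360])
        assert len(table) == 1
        _, mask = dpac.segment(clean_phantom.image, center,
                               n_lines=360, radius_length=80)
        assert table.loc[0, "dice"] == pytest.approx(
            dpac.dice(mask, clean_phantom.truth_mask))

    def test_row_structure_mirrors_reference_grid(self, clean_phantom):
        center = (124.5, 124.5)
        cases = [(clean_phantom.image, center, clean_phantom.truth_mask)]
        table = dpac.parameter_sweep(cases, radius_lengths=[80, 100, 120, 140],
                                     line_counts=[60, 90, 120])
        assert len(table) == 12
        assert list(table.columns) == ["radius_length", "n_lines", "time_s",
                                       "dice", "jaccard", "grade"]

    def test_short_radius_truncates_to_under_segmentation(self):
        """Disk-like phantoms of radius 45 cannot be reached by a 30-px grid."""
        cases = []
        for seed in range(3):
            spec = phantom.PhantomSpec(stage="C", crown_width=90, crown_height=90,
                                       root_length_fraction=0.0, apex_gap=0.0,
                                       clutter_level=0.0, impulse_noise_fraction=0.0,
                                       seed=seed)
            case = phantom.generate_phantom(spec)
            cases.append((case.image, (124.5, 124.5), case.truth_mask))
        table = dpac.parameter_sweep(cases, radius_lengths=[30], line_counts=[360])
        assert table.loc[0, "grade"] == "under"

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError):
            dpac.parameter_sweep([])
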