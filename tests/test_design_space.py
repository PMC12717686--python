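import numpy as np
import pytest

import adhereroi as ar
from adhereroi.design_space import ROISurface


def planted_plane(a=200.0, b=-30.0, c=5.0):
    """Linear ROI field roi = a*delta + b*gamma + c on a small grid."""
    dg = np.linspace(0.0, 0.4, 9)
    gg = np.linspace(0.0, 3.0, 13)
    roi = a * dg[:, None] + b * gg[None, :] + c
    cost = 1000.0 - roi  # arbitrary positive costs
    return ROISurface(dg, gg, roi, cost), (a, b, c)


class TestScanGrid:
    def test_single_cell_matches_single_run(self, scenarios, coarse_params):
        surf = ar.scan_grid([0.3], [1.5], scenarios["early"], coarse_params)
        det = ar.compare_to_baseline(scenarios["early"], coarse_params)
        assert surf.roi_matrix[0, 0] == pytest.approx(det.roi_percent)

    def test_roi_monotone_along_axes(self, scenarios, coarse_params):
        surf = ar.scan_grid(
            np.linspace(0.0, 0.4, 5), np.linspace(0.0, 3.0, 5),
            scenarios["early"], coarse_params,
        )
        assert np.all(np.diff(surf.roi_matrix, axis=1) < 0)  # rising cost
        assert np.all(np.diff(surf.roi_matrix, axis=0) > 0)  # rising gain

    def test_spending_without_benefit_loses(self, scenarios, coarse_params):
        surf = ar.scan_grid([0.0], [0.5, 1.0, 2.0], scenarios["early"], coarse_params)
        assert np.all(surf.roi_matrix < 0)

    def test_stochastic_point_spec_equals_deterministic(self, scenarios, coarse_params):
        det = ar.scan_grid([0.1, 0.3], [0.5, 1.5], scenarios["early"], coarse_params)
        sto = ar.scan_grid(
            [0.1, 0.3], [0.5, 1.5], scenarios["early"], coarse_params,
            spec=ar.DeltaSpec(kind="point", delta=0.3), n=5, seed=0,
        )
        np.testing.assert_array_equal(det.roi_matrix, sto.roi_matrix)
        assert sto.positive_rate_matrix is not None

    def test_empty_grid_rejected(self, scenarios, coarse_params):
        with pytest.raises(ValueError):
            ar.scan_grid([], [1.0], scenarios["early"], coarse_params)

    def test_long_format_export(self, scenarios, coarse_params):
        surf = ar.scan_grid([0.1, 0.3], [0.5, 1.5], scenarios["early"], coarse_params)
        df = surf.to_frame()
        assert len(df) == 4
        assert set(df.columns) == {"delta", "gamma", "roi", "total_cost"}


class TestContours:
    def test_planted_plane_level_set(self):
        surf, (a, b, c) = planted_plane()
        for level, polys in ar.contour_levels(surf, [0.0, 50.0]).items():
            assert polys, f"no contour found at {level}"
            for poly in polys:
                residual = a * poly[:, 0] + b * poly[:, 1] + c - level
                assert np.max(np.abs(residual)) < 1e-8

    def test_constant_surface_has_no_crossing(self):
        dg, gg = np.linspace(0, 0.4, 5), np.linspace(0, 3, 5)
        surf = ROISurface(dg, gg, np.full((5, 5), 10.0), np.ones((5, 5)))
        assert ar.contour_levels(surf, [0.0])[0.0] == []

    def test_level_below_minimum_is_empty(self):
        surf, _ = planted_plane()
        assert ar.contour_levels(surf, [-1e6])[-1e6] == []

    def test_axis_swap_consistency(self):
        surf, (a, b, c) = planted_plane()
        swapped = ROISurface(surf.gamma_grid, surf.delta_grid,
                             surf.roi_matrix.T, surf.cost_matrix.T)
        for poly in ar.contour_levels(swapped, [50.0])[50.0]:
            residual = b * poly[:, 0] + a * poly[:, 1] + c - 50.0
            assert np.max(np.abs(residual)) < 1e-8

    def test_vertices_stay_in_grid_bounds(self):
        surf, _ = planted_plane()
        for poly in ar.contour_levels(surf, [0.0])[0.0]:
            assert poly[:, 0].min() >= surf.delta_grid[0] - 1e-12
            assert poly[:, 0].max() <= surf.delta_grid[-1] + 1e-12
            assert poly[:, 1].min() >= surf.gamma_grid[0] - 1e-12
            assert poly[:, 1].max() <= surf.gamma_grid[-1] + 1e-12

    def test_non_finite_level_rejected(self):
        surf, _ = planted_plane()
        with pytest.raises(ValueError):
            ar.contour_levels(surf, [np.nan])


def brute_force_frontier(points):
    keep = []
    for cost, r in points:
        dominated = any(
            (c2 < cost and r2 >= r) or (c2 <= cost and r2 > r)
            for c2, r2 in points
        )
        if not dominated:
            keep.append((cost, r))
    return np.asarray(sorted(keep))


class TestFrontier:
    def test_single_cell(self):
        surf = ROISurface(np.array([0.3]), np.array([1.5]),
                          np.array([[12.0]]), np.array([[900.0]]))
        front = ar.cost_effectiveness_frontier(surf)["frontier"]
        np.testing.assert_array_equal(front, [[900.0, 12.0]])

    def test_dominated_point_dropped(self):
        surf = ROISurface(np.array([0.1, 0.2]), np.array([1.0]),
                          np.array([[20.0], [5.0]]),
                          np.array([[800.0], [900.0]]))
        front = ar.cost_effectiveness_frontier(surf)["frontier"]
        np.testing.assert_array_equal(front, [[800.0, 20.0]])

    def test_matches_brute_force_on_random_surfaces(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            m, g = rng.integers(2, 5, size=2)
            surf = ROISurface(
                np.sort(rng.uniform(0, 0.4, m)), np.sort(rng.uniform(0, 3, g)),
                rng.normal(0, 50, (m, g)), rng.uniform(500, 1500, (m, g)),
            )
            got = ar.cost_effectiveness_frontier(surf)["frontier"]
            expected = brute_force_frontier(
                list(zip(surf.cost_matrix.ravel(), surf.roi_matrix.ravel()))
            )
            np.testing.assert_allclose(got, expected)
            # along the frontier, paying more must buy strictly more ROI
            assert np.all(np.diff(got[:, 1]) > 0)


class TestRobustness:
    def test_identity_factors_leave_roi_unchanged(self, scenarios, coarse_params):
        table = ar.robustness_suite(
            list(scenarios.values()), coarse_params,
            inflation_factor=1.0, shortening=0.0,
        )
        np.testing.assert_allclose(table.roi_inflated, table.roi_baseline)
        np.testing.assert_allclose(table.roi_accelerated, table.roi_baseline)

    def test_inflation_never_helps(self, scenarios, coarse_params):
        table = ar.robustness_suite(list(scenarios.values()), coarse_params,
                                    inflation_factor=1.2, shortening=0.15)
        assert np.all(table.roi_inflated <= table.roi_baseline + 1e-9)

    def test_early_adherence_survives_inflation(self, scenarios, coarse_params):
        table = ar.robustness_suite([scenarios["early"]], coarse_params,
                                    inflation_factor=1.2, shortening=0.15)
        assert table.loc[0, "roi_inflated"] > 0
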