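"""(delta, gamma) design-space exploration: ROI surfaces, iso-ROI contours,
the cost-effectiveness frontier, and robustness stress tests.

The surface scan evaluates ROI over a rectangular grid of adherence gains
and policy cost scales, deterministically or with per-cell Monte Carlo
draws.  Contours are extracted by marching squares with linear edge
interpolation; the frontier is the Pareto-efficient subset of
(total cost, ROI) pairs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .cost_model import simulate_scenario, inflate_costs
from .disease import accelerate_progression
from .monte_carlo import run_monte_carlo
from .params import ModelParameters, ScenarioConfig, DeltaSpec
from .roi_analysis import roi, _baseline_for

__all__ = [
    "ROISurface",
    "default_delta_grid",
    "default_gamma_grid",
    "scan_grid",
    "contour_levels",
    "cost_effectiveness_frontier",
    "robustness_suite",
]


def default_delta_grid() -> np.ndarray:
    """delta in {0.00, 0.05, ..., 0.40} — covers the scenario-table range."""
    return np.round(np.arange(0.0, 0.40001, 0.05), 10)


def default_gamma_grid() -> np.ndarray:
    """gamma in {0.0, 0.25, ..., 3.0}."""
    return np.round(np.arange(0.0, 3.0001, 0.25), 10)


@dataclass
class ROISurface:
    delta_grid: np.ndarray  # increasing, length m
    gamma_grid: np.ndarray  # increasing, length g
    roi_matrix: np.ndarray  # % , shape (m, g)
    cost_matrix: np.ndarray  # USD, shape (m, g)
    positive_rate_matrix: np.ndarray | None = None  # stochastic scans only

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (delta, gamma) cell."""
        dd, gg = np.meshgrid(self.delta_grid, self.gamma_grid, indexing="ij")
        data = {
            "delta": dd.ravel(),
            "gamma": gg.ravel(),
            "roi": self.roi_matrix.ravel(),
            "total_cost": self.cost_matrix.ravel(),
        }
        if self.positive_rate_matrix is not None:
            data["positive_rate"] = self.positive_rate_matrix.ravel()
        return pd.DataFrame(data)


def scan_grid(
    delta_grid,
    gamma_grid,
    template: ScenarioConfig,
    params: ModelParameters,
    spec: DeltaSpec | None = None,
    n: int = 200,
    seed: int = 0,
) -> ROISurface:
    """Evaluate ROI over a (delta, gamma) grid.

    Deterministic when ``spec`` is None; otherwise each cell runs ``n``
    Monte Carlo draws with a per-cell seed derived from the master seed
    (``seed + row * len(gamma_grid) + col``) and reports mean ROI and the
    positive-ROI rate.
    """
    delta_grid = np.asarray(delta_grid, dtype=float)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    for grid, name in ((delta_grid, "delta"), (gamma_grid, "gamma")):
        if grid.size == 0 or np.any(np.diff(grid) <= 0) and grid.size > 1:
            raise ValueError(f"{name} grid must be non-empty and increasing")

    m, g = delta_grid.size, gamma_grid.size
    roi_mat = np.empty((m, g))
    cost_mat = np.empty((m, g))
    pos_mat = np.empty((m, g)) if spec is not None else None

    base_cost = simulate_scenario(_baseline_for(template), params).total_cost
    for i, d in enumerate(delta_grid):
        for j, gam in enumerate(gamma_grid):
            scen = template.replace(delta=float(d), gamma=float(gam))
            if spec is None:
                cost = simulate_scenario(scen, params).total_cost
                roi_mat[i, j] = roi(base_cost, cost)
                cost_mat[i, j] = cost
            else:
                # the cell's delta is the location of the behavioural
                # distribution (ignored by kinds without a location)
                cell_spec = dataclasses.replace(spec, delta=float(d))
                mc = run_monte_carlo(
                    scen,
                    cell_spec,
                    n=n,
                    seed=seed + i * g + j,
                    params=params,
                )
                roi_mat[i, j] = mc.mean_roi
                cost_mat[i, j] = float(np.mean(mc.total_costs))
                pos_mat[i, j] = mc.positive_rate
    return ROISurface(delta_grid, gamma_grid, roi_mat, cost_mat, pos_mat)


def contour_levels(surface: ROISurface, levels) -> dict[float, list[np.ndarray]]:
    """Iso-ROI polylines in (delta, gamma) coordinates.

    Marching squares with linear interpolation along cell edges; grid-index
    vertices are mapped back onto the (possibly non-uniform) grids by
    per-cell linear interpolation.  Levels entirely outside the surface
    range yield empty polyline lists.
    """
    out: dict[float, list[np.ndarray]] = {}
    idx_d = np.arange(surface.delta_grid.size)
    idx_g = np.arange(surface.gamma_grid.size)
    for level in levels:
        if not np.isfinite(level):
            raise ValueError("contour levels must be finite")
        polylines = []
        for contour in measure.find_contours(surface.roi_matrix, level):
            deltas = np.interp(contour[:, 0], idx_d, surface.delta_grid)
            gammas = np.interp(contour[:, 1], idx_g, surface.gamma_grid)
            polylines.append(np.column_stack([deltas, gammas]))
        out[float(level)] = polylines
    return out


def cost_effectiveness_frontier(surface: ROISurface) -> dict[str, np.ndarray]:
    """All (total cost, ROI) pairs and their Pareto-efficient subset.

    A design is on the frontier if no other design attains at least its ROI
    at lower or equal cost (ties broken toward the cheaper design); sorted
    by cost the frontier therefore has strictly increasing ROI.
    """
    points = np.column_stack([surface.cost_matrix.ravel(), surface.roi_matrix.ravel()])
    order = np.lexsort((-points[:, 1], points[:, 0]))  # cost asc, roi desc
    pts = points[order]
    # scan in cost order: a point survives iff its ROI beats every cheaper
    # (or equally cheap, higher-ROI) design seen so far
    frontier = []
    best = -np.inf
    for cost, r in pts:
        if r > best:
            frontier.append((cost, r))
            best = r
    return {"points": pts, "frontier": np.asarray(frontier)}


def robustness_suite(
    scenarios,
    params: ModelParameters,
    inflation_factor: float = 1.2,
    shortening: float = 0.15,
) -> pd.DataFrame:
    """Stress-test ROI per scenario under cost inflation and accelerated
    disease progression.

    ``inflated`` scales gamma and nudge_cost by ``inflation_factor``;
    ``accelerated`` compresses the disease time axis by ``1 - shortening``
    for both the policy run and its baseline counterfactual.
    """
    fast = accelerate_progression(params, shortening)
    rows = []
    for scen in scenarios:
        if scen.shape == "baseline":
            continue
        base = simulate_scenario(_baseline_for(scen), params).total_cost
        base_fast = simulate_scenario(_baseline_for(scen), fast).total_cost
        nominal = roi(base, simulate_scenario(scen, params).total_cost)
        inflated = roi(
            base, simulate_scenario(inflate_costs(scen, inflation_factor), params).total_cost
        )
        accelerated = roi(base_fast, simulate_scenario(scen, fast).total_cost)
        rows.append(
            {
                "scenario": scen.name,
                "roi_baseline": nominal,
                "roi_inflated": inflated,
                "roi_accelerated": accelerated,
            }
        )
    return pd.DataFrame(rows)
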