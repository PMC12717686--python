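"""Return on investment, payback time, break-even policy cost, and dollar
calibration.

ROI of a policy design relative to the no-intervention counterfactual is

    ROI = 100 * (C_baseline - C_policy) / C_policy

with the policy scenario's own total discounted cost as denominator.
Positive ROI denotes net savings.  The break-even cost ``gamma*`` is the
largest policy cost scale at which ROI stays non-negative for a given
adherence gain; ROI decreases monotonically in gamma, so a bisection
locates it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .adherence import Trajectory
from .cost_model import simulate_scenario
from .params import ModelParameters, ScenarioConfig, scenario_table

__all__ = [
    "ROIResult",
    "roi",
    "payback_time",
    "compare_to_baseline",
    "breakeven_gamma",
    "roi_gamma_slope",
    "calibrate_to_anchors",
]

#: sentinel returned by payback_time when costs never cross within the horizon
NO_PAYBACK = math.inf


@dataclass
class ROIResult:
    roi_percent: float
    savings: float  # USD, C_baseline - C_policy
    payback_years: float  # NO_PAYBACK if never


def roi(c_baseline: float, c_policy: float) -> float:
    """Percent relative cost savings versus baseline; positive = net savings."""
    if c_policy <= 0:
        raise ValueError("c_policy must be positive")
    return 100.0 * (c_baseline - c_policy) / c_policy


def payback_time(c_baseline: Trajectory, c_policy: Trajectory) -> float:
    """First grid time t > 0 at which cumulative policy cost drops strictly
    below cumulative baseline cost; ``NO_PAYBACK`` if that never happens."""
    if len(c_baseline) != len(c_policy) or not np.allclose(
        c_baseline.times, c_policy.times, atol=1e-9
    ):
        raise ValueError("trajectories do not share a common grid")
    below = (c_policy.values < c_baseline.values) & (c_baseline.times > 0)
    idx = np.argmax(below)
    if not below[idx]:
        return NO_PAYBACK
    return float(c_baseline.times[idx])


def _baseline_for(template: ScenarioConfig) -> ScenarioConfig:
    """No-intervention counterfactual matched to the template's baseline
    adherence (and decaying-baseline assumption, if any)."""
    return ScenarioConfig(
        name="Baseline",
        shape="baseline",
        tau=0.0,
        delta=0.0,
        gamma=0.0,
        A0=template.A0,
        baseline_decay_rate=template.baseline_decay_rate,
    )


def compare_to_baseline(
    scenario: ScenarioConfig,
    params: ModelParameters,
    baseline: ScenarioConfig | None = None,
) -> ROIResult:
    """Simulate a policy against its counterfactual and summarise ROI."""
    if baseline is None:
        baseline = _baseline_for(scenario)
    base = simulate_scenario(baseline, params)
    pol = simulate_scenario(scenario, params)
    return ROIResult(
        roi_percent=roi(base.total_cost, pol.total_cost),
        savings=base.total_cost - pol.total_cost,
        payback_years=payback_time(base.cumulative_cost, pol.cumulative_cost),
    )


def _roi_of_gamma(
    delta: float,
    template: ScenarioConfig,
    params: ModelParameters,
    base_cost: float,
) -> Callable[[float], float]:
    def f(gamma: float) -> float:
        scen = template.replace(delta=delta, gamma=gamma)
        return roi(base_cost, simulate_scenario(scen, params).total_cost)

    return f


def breakeven_gamma(
    delta: float,
    template: ScenarioConfig,
    params: ModelParameters,
    gamma_max: float = 10.0,
    tol: float = 1e-4,
) -> tuple[float, bool]:
    """Break-even policy cost scale gamma* for a given adherence gain.

    Bisects ROI(gamma) = 0 on [0, gamma_max], exploiting that ROI decreases
    monotonically in gamma.  Returns ``(gamma_star, bounded)``; ``bounded``
    is False when ROI is still positive at ``gamma_max`` (break-even lies
    beyond the search bound and gamma_max is returned).

    Raises
    ------
    ValueError
        If ROI at zero cost is already negative (no break-even exists).
    """
    base = simulate_scenario(_baseline_for(template), params)
    f = _roi_of_gamma(delta, template, params, base.total_cost)
    lo, hi = 0.0, gamma_max
    roi_lo = f(lo)
    if roi_lo < 0:
        raise ValueError("no break-even exists: ROI < 0 even at zero policy cost")
    roi_hi = f(hi)
    if roi_hi > 0:
        return gamma_max, False
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = f(mid)
        if abs(r) <= tol:
            return mid, True
        if r > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), True


def roi_gamma_slope(
    delta: float,
    gamma: float,
    template: ScenarioConfig,
    params: ModelParameters,
    h: float = 0.05,
    roi_fn: Callable[[float, float], float] | None = None,
) -> float:
    """d(ROI)/d(gamma) by central finite difference (forward at the gamma=0
    boundary).  ``roi_fn(delta, gamma)`` may override the simulated ROI, e.g.
    for analytic cross-checks."""
    if h <= 0:
        raise ValueError("finite-difference step h must be positive")
    if roi_fn is None:
        base = simulate_scenario(_baseline_for(template), params)
        g = _roi_of_gamma(delta, template, params, base.total_cost)
        roi_fn = lambda d, gam: g(gam)  # noqa: E731 - delta fixed by closure
    if gamma - h < 0:
        return (roi_fn(delta, gamma + h) - roi_fn(delta, gamma)) / h
    return (roi_fn(delta, gamma + h) - roi_fn(delta, gamma - h)) / (2.0 * h)


def calibrate_to_anchors(
    anchor_baseline: float,
    anchor_policy: float,
    template: ScenarioConfig,
    params: ModelParameters,
) -> ModelParameters:
    """Solve for (C0, omega) so that the baseline and template simulations
    reproduce two published dollar totals exactly.

    With model-unit discounted integrals I_base and I_policy (computed under
    ``C0 = 0, omega = 1``), solves the linear system::

        C0 + omega * I_base   = anchor_baseline
        C0 + omega * I_policy = anchor_policy

    Raises
    ------
    ValueError
        If the system is singular (equal integrals) or yields a
        non-positive currency scale.
    """
    if anchor_baseline <= 0 or anchor_policy <= 0:
        raise ValueError("anchors must be positive")
    raw = params.replace(C0=0.0, omega=1.0)
    i_base = simulate_scenario(_baseline_for(template), raw).total_cost
    i_policy = simulate_scenario(template, raw).total_cost
    denom = i_base - i_policy
    if abs(denom) < 1e-12:
        raise ValueError("singular calibration: baseline and policy integrals equal")
    omega = (anchor_baseline - anchor_policy) / denom
    if omega <= 0:
        raise ValueError(
            f"calibration yields non-positive currency scale omega={omega:.6g}; "
            "anchors disagree with the model's cost ordering"
        )
    c0 = (anchor_baseline - omega * i_base) / omega
    return params.replace(C0=c0, omega=omega)
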