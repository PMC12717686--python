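"""Instantaneous cost decomposition, policy expenditure, and the discounted
cumulative cost integral.

Instantaneous model cost at time s combines four components:

    c(s) = alpha * D(s) + beta * A(s)^2 + gamma * P(s) + lam * H(s)

where D is (adherence-coupled) disease severity, A adherence, P the policy
expenditure rate, and H an optional health-outcome term (zero in the primary
analysis).  Cumulative cost is the discounted integral

    C(t) = omega * (C0 + int_0^t exp(-rho s) c(s) ds + discounted impulses)

evaluated by the trapezoid rule on the uniform grid; adaptive-nudge
activations add impulse costs ``gamma * nudge_cost`` discounted at their
event times. ``omega`` converts model-cost units to USD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .adherence import Trajectory, AdaptiveRecord, adherence_trajectory, _indicator
from .disease import severity_coupled
from .params import ModelParameters, ScenarioConfig, validate

__all__ = [
    "CostBreakdown",
    "SimulationResult",
    "policy_expenditure",
    "cost_decomposition",
    "cumulative_cost",
    "monetize_health_outcomes",
    "inflate_costs",
    "simulate_scenario",
]


@dataclass
class CostBreakdown:
    """Per-component instantaneous cost on the grid (model-cost/yr).

    ``impulse_times`` / ``impulse_amounts`` carry adaptive-nudge event costs
    (already scaled by gamma) that enter the cumulative integral as
    discounted point masses rather than rates.

    ``jump_times`` / ``jump_sizes`` record known step discontinuities of the
    total instantaneous cost (policy starts, adaptive resets).  The sampled
    grid value at such a time is the post-jump level, so a plain trapezoid
    rule would smear the jump across the preceding interval; the quadrature
    subtracts ``h/2 * exp(-rho t) * jump`` per event to keep convergence at
    second order.
    """

    times: np.ndarray
    disease: np.ndarray
    adherence: np.ndarray
    policy: np.ndarray
    health: np.ndarray
    impulse_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    impulse_amounts: np.ndarray = field(default_factory=lambda: np.empty(0))
    jump_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    jump_sizes: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def total(self) -> np.ndarray:
        return self.disease + self.adherence + self.policy + self.health

    def discounted_total(self, rho: float) -> np.ndarray:
        return np.exp(-rho * self.times) * self.total


@dataclass
class SimulationResult:
    """Full decomposed output of one scenario run."""

    scenario: ScenarioConfig
    adherence: Trajectory
    severity: Trajectory
    policy: Trajectory
    breakdown: CostBreakdown
    cumulative_cost: Trajectory  # USD
    activations: int

    @property
    def total_cost(self) -> float:
        """C(horizon) in USD."""
        return self.cumulative_cost.at_end()

    def to_frame(self):
        """Tabular export: one row per grid point."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.adherence.times,
                "adherence": self.adherence.values,
                "severity": self.severity.values,
                "policy_rate": self.policy.values,
                "cost_disease": self.breakdown.disease,
                "cost_adherence": self.breakdown.adherence,
                "cost_policy": self.breakdown.policy,
                "cost_total": self.breakdown.total,
                "cumulative_cost": self.cumulative_cost.values,
            }
        )


def policy_expenditure(
    scenario: ScenarioConfig,
    activations: AdaptiveRecord,
    params: ModelParameters,
) -> Trajectory:
    """Policy expenditure rate P(s) on the grid.

    Baseline spends nothing; every other shape spends ``p_unit`` per year
    from the start time on.  Adaptive impulse costs are carried separately
    (see :func:`cost_decomposition`), not folded into the rate.
    """
    validate(params, scenario)
    t = params.time_grid()
    if scenario.shape == "baseline":
        return Trajectory(t, np.zeros_like(t))
    return Trajectory(t, params.p_unit * _indicator(t - scenario.tau))


def cost_decomposition(
    severity: Trajectory,
    adherence: Trajectory,
    policy: Trajectory,
    scenario: ScenarioConfig,
    params: ModelParameters,
    activations: AdaptiveRecord | None = None,
    health: Trajectory | None = None,
) -> CostBreakdown:
    """Evaluate each cost component on the shared grid."""
    t = severity.times
    for traj in (adherence, policy) + ((health,) if health is not None else ()):
        if len(traj) != len(severity) or not np.allclose(traj.times, t, atol=1e-9):
            raise ValueError("trajectories do not share the standard grid")
    impulse_times = np.empty(0)
    impulse_amounts = np.empty(0)
    if activations is not None and activations.count:
        impulse_times = activations.activation_times
        impulse_amounts = np.full(
            activations.count, scenario.gamma * scenario.nudge_cost
        )

    # known cost discontinuities: the policy start and adaptive resets
    jump_times, jump_sizes = [], []
    h = float(t[1] - t[0]) if len(t) > 1 else 0.0
    if scenario.shape != "baseline" and scenario.tau > 0 and h > 0:
        i0 = int(np.ceil(scenario.tau / h - 1e-9))
        if 0 < i0 < len(t):
            a_post = adherence.values[i0]
            dc = params.beta * (a_post**2 - scenario.A0**2) \
                + scenario.gamma * policy.values[i0]
            jump_times.append(t[i0])
            jump_sizes.append(dc)
    if activations is not None and activations.count:
        boosted = min(scenario.A0 + scenario.delta, 1.0)
        for t_e, pre in zip(activations.activation_times, activations.pre_values):
            jump_times.append(t_e)
            jump_sizes.append(params.beta * (boosted**2 - pre**2))

    return CostBreakdown(
        times=t,
        disease=params.alpha * severity.values,
        adherence=params.beta * adherence.values**2,
        policy=scenario.gamma * policy.values,
        health=params.lam * (health.values if health is not None else np.zeros_like(t)),
        impulse_times=impulse_times,
        impulse_amounts=impulse_amounts,
        jump_times=np.asarray(jump_times),
        jump_sizes=np.asarray(jump_sizes),
    )


def cumulative_cost(breakdown: CostBreakdown, params: ModelParameters) -> Trajectory:
    """Discounted cumulative cost C(t) in USD, trapezoid rule on the grid."""
    t = breakdown.times
    integrand = breakdown.discounted_total(params.rho)
    integral = cumulative_trapezoid(integrand, t, initial=0.0)
    if breakdown.jump_times.size:
        h = float(t[1] - t[0])
        corr = 0.5 * h * np.exp(-params.rho * breakdown.jump_times) * breakdown.jump_sizes
        integral = integral - np.sum(
            (t[:, None] >= breakdown.jump_times[None, :] - 1e-9) * corr[None, :],
            axis=1,
        )
    if breakdown.impulse_times.size:
        disc = np.exp(-params.rho * breakdown.impulse_times) * breakdown.impulse_amounts
        # each impulse raises C(t) for all t at or after the event
        integral = integral + np.sum(
            (t[:, None] >= breakdown.impulse_times[None, :] - 1e-9) * disc[None, :],
            axis=1,
        )
    return Trajectory(t, params.omega * (params.C0 + integral))


def monetize_health_outcomes(outcomes_averted: float, value_per_outcome: float) -> float:
    """Dollar value of averted health outcomes (e.g. DALYs at $50,000 each)."""
    if value_per_outcome < 0:
        raise ValueError("value_per_outcome must be non-negative")
    return outcomes_averted * value_per_outcome


def inflate_costs(scenario: ScenarioConfig, factor: float) -> ScenarioConfig:
    """Scale per-unit implementation costs (gamma and nudge_cost) by factor."""
    if factor <= 0:
        raise ValueError("inflation factor must be positive")
    return scenario.replace(
        gamma=factor * scenario.gamma, nudge_cost=factor * scenario.nudge_cost
    )


def simulate_scenario(
    scenario: ScenarioConfig, params: ModelParameters
) -> SimulationResult:
    """Run one scenario end to end: adherence -> severity -> costs -> C(t)."""
    validate(params, scenario)
    adherence, record = adherence_trajectory(scenario, params)
    severity = severity_coupled(adherence, params)
    policy = policy_expenditure(scenario, record, params)
    breakdown = cost_decomposition(
        severity, adherence, policy, scenario, params, activations=record
    )
    cumulative = cumulative_cost(breakdown, params)
    return SimulationResult(
        scenario=scenario,
        adherence=adherence,
        severity=severity,
        policy=policy,
        breakdown=breakdown,
        cumulative_cost=cumulative,
        activations=record.count,
    )
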