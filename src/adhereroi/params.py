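"""Model parameters, policy-scenario configurations, and validation.

The simulator works in dimensionless "model-cost" units; ``omega`` (USD per
model-cost unit) and the offset ``C0`` map model totals onto dollar scales.
This keeps the policy cost scale ``gamma`` on the small dimensionless range
used by the scenario table while still allowing calibration to published
dollar anchors (see :mod:`adhereroi.roi_analysis`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "ScenarioConfig",
    "DeltaSpec",
    "ADHERENCE_REFERENCE",
    "SCENARIO_SHAPES",
    "default_parameters",
    "scenario_table",
    "validate",
]

#: Reference adherence level around which the adherence->progression coupling
#: is centred; the flat baseline at this level reproduces the plain logistic
#: severity curve exactly.
ADHERENCE_REFERENCE = 0.5

SCENARIO_SHAPES = ("baseline", "step", "decay", "adaptive", "low_impact")

DELTA_KINDS = ("point", "beta", "truncnorm", "two_point")


@dataclass
class ModelParameters:
    """Global model constants.

    Parameters
    ----------
    C0 : float
        Baseline cost offset (model-cost; USD after currency scaling):
        adherence-independent care cost that keeps total discounted cost
        positive across the admissible policy design space.
    rho : float
        Continuous annual discount rate (1/yr); future costs are weighted
        by ``exp(-rho * s)``.
    alpha : float
        Disease-burden cost weight (model-cost/yr per unit severity).
    D_max : float
        Severity ceiling of the logistic progression curve.
    k : float
        Logistic progression rate (1/yr).
    s0 : float
        Progression midpoint (yr): time at which severity reaches D_max/2
        under reference adherence.
    beta : float
        Adherence cost weight (model-cost/yr); negative values encode
        savings from adherence effort.
    lam : float
        Health-outcome cost weight (USD per outcome unit); 0 in the primary
        analysis, used only for post-hoc monetization.
    eta : float
        Adherence->progression coupling strength; the effective progression
        rate is ``k * (1 - eta * (A - ADHERENCE_REFERENCE))``.
    p_unit : float
        Policy expenditure rate while a policy is active (model-cost/yr).
    omega : float
        Currency scale (USD per model-cost unit).
    horizon : float
        Simulation end time T (yr).
    grid_step : float
        Uniform integration step h (yr); must divide the horizon.
    """

    C0: float = 1.0
    rho: float = 0.03
    alpha: float = 1.0
    D_max: float = 1.0
    k: float = 0.7
    s0: float = 5.0 / 0.7
    beta: float = -0.3
    lam: float = 0.0
    eta: float = 0.8
    p_unit: float = 0.05
    omega: float = 1.0
    horizon: float = 10.0
    grid_step: float = 0.01

    def n_steps(self) -> int:
        return int(round(self.horizon / self.grid_step))

    def time_grid(self) -> np.ndarray:
        """Uniform grid 0 = t_0 < ... < t_M = horizon."""
        return np.linspace(0.0, self.horizon, self.n_steps() + 1)

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScenarioConfig:
    """One policy design: timing, adherence response, and cost intensity.

    ``shape`` selects the adherence trajectory family:

    - ``baseline``: constant A0 (or ``A0 * exp(-baseline_decay_rate * s)``
      when a decaying counterfactual is requested); no policy spend.
    - ``step`` / ``low_impact``: ``A0 + delta * I(s - tau)``.
    - ``decay``: ``A0 + delta * exp(-theta * (s - tau)) * I(s - tau)``.
    - ``adaptive``: the decaying form, reset to ``A0 + delta`` whenever
      adherence would drop below ``A_thresh``; each reset incurs an
      impulse cost ``nudge_cost``.
    """

    name: str
    shape: str
    tau: float = 2.0
    delta: float = 0.0
    gamma: float = 0.0
    A0: float = 0.5
    theta: float = 0.5
    A_thresh: float = 0.75
    nudge_cost: float = 0.25
    baseline_decay_rate: float = 0.0

    def replace(self, **changes) -> "ScenarioConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DeltaSpec:
    """Distributional specification for the adherence gain delta.

    kind:
        ``point`` — degenerate at ``delta``;
        ``beta`` — Beta(a, b) on [0, 1];
        ``truncnorm`` — Normal(delta, sigma^2) truncated to [0, 1];
        ``two_point`` — ``delta_hi`` with probability ``p`` else ``delta_lo``
        (high vs. low responders).
    """

    kind: str = "point"
    delta: float = 0.3
    a: float = 2.0
    b: float = 5.0
    sigma: float = 0.05
    p: float = 0.5
    delta_hi: float = 0.4
    delta_lo: float = 0.1

    def __post_init__(self):
        if self.kind not in DELTA_KINDS:
            raise ValueError(
                f"unknown delta kind {self.kind!r}; expected one of {DELTA_KINDS}"
            )
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("responder probability p must lie in [0, 1]")


def default_parameters() -> ModelParameters:
    """Return the documented default parameter record."""
    return ModelParameters()


def scenario_table() -> list[ScenarioConfig]:
    """The canonical six-scenario policy registry.

    Baseline (no intervention), Early Adherence, Delayed Intervention,
    Regressive Adherence (gain decays), Adaptive Nudges (threshold-triggered
    re-engagement), and a high-cost Low-Impact policy.
    """
    return [
        ScenarioConfig(name="Baseline", shape="baseline", tau=0.0, delta=0.0, gamma=0.0),
        ScenarioConfig(name="Early Adherence", shape="step", tau=2.0, delta=0.3, gamma=1.5),
        ScenarioConfig(name="Delayed Intervention", shape="step", tau=5.0, delta=0.3, gamma=1.5),
        ScenarioConfig(name="Regressive Adherence", shape="decay", tau=2.0, delta=0.3, gamma=1.2),
        ScenarioConfig(name="Adaptive Nudges", shape="adaptive", tau=2.0, delta=0.3, gamma=2.0),
        ScenarioConfig(name="Low-Impact Policy", shape="low_impact", tau=2.0, delta=0.05, gamma=3.0),
    ]


def _check(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


def validate(
    params: ModelParameters, scenario: ScenarioConfig | None = None
) -> tuple[ModelParameters, ScenarioConfig | None]:
    """Check all invariants; return the inputs unchanged if they hold.

    Raises
    ------
    ValueError
        Naming the violated invariant.
    """
    _check(params.rho >= 0, "rho (discount rate) must be non-negative")
    _check(params.D_max > 0, "D_max must be positive")
    _check(params.k > 0, "k (progression rate) must be positive")
    _check(params.horizon > 0, "horizon must be positive")
    _check(params.grid_step > 0, "grid_step must be positive")
    n = params.horizon / params.grid_step
    _check(
        abs(n - round(n)) <= 1e-9 * max(1.0, n),
        "grid_step must divide horizon",
    )
    # Effective progression rate k*(1 - eta*(A - A_ref)) must stay >= 0 for
    # any admissible adherence A in [0, 1].
    _check(
        params.eta * (1.0 - ADHERENCE_REFERENCE) <= 1.0 + 1e-12,
        "eta too large: effective progression rate would go negative "
        "for full adherence",
    )
    _check(params.eta >= 0, "eta (coupling strength) must be non-negative")

    if scenario is not None:
        _check(scenario.shape in SCENARIO_SHAPES,
               f"unknown scenario shape {scenario.shape!r}")
        _check(0.0 <= scenario.A0 <= 1.0, "A0 must lie in [0, 1]")
        _check(scenario.delta >= -scenario.A0 - 1e-12,
               "delta may not push adherence below 0")
        _check(0.0 <= scenario.tau <= params.horizon,
               "tau exceeds horizon" if scenario.tau > params.horizon
               else "tau must be non-negative")
        _check(scenario.gamma >= 0, "gamma (policy cost scale) must be non-negative")
        _check(scenario.theta >= 0, "theta (decay rate) must be non-negative")
        _check(scenario.baseline_decay_rate >= 0,
               "baseline_decay_rate must be non-negative")
        _check(scenario.nudge_cost >= 0, "nudge_cost must be non-negative")
    return params, scenario
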