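"""Adherence trajectories A(s) for every policy shape, and stochastic
sampling of the adherence gain delta.

All trajectories live on the uniform simulation grid. The step indicator
convention is I(x) = 1 for x >= 0, so a policy starting at tau takes effect
at the grid point tau itself. Values are clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .params import ModelParameters, ScenarioConfig, DeltaSpec, validate

__all__ = ["Trajectory", "AdaptiveRecord", "adherence_trajectory", "sample_delta"]


@dataclass
class Trajectory:
    """Values sampled on the uniform time grid (units depend on role)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("time grid must be uniform")

    def __len__(self) -> int:
        return self.times.size

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def at_end(self) -> float:
        return float(self.values[-1])


@dataclass
class AdaptiveRecord:
    """Log of adaptive-nudge activation events.

    ``pre_values`` holds the adherence level each reset interrupted (the
    value the trajectory would have decayed to); the cost quadrature uses it
    to treat the reset as a clean jump.
    """

    activation_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    pre_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.activation_times = np.asarray(self.activation_times, dtype=float)
        self.pre_values = np.asarray(self.pre_values, dtype=float)

    @property
    def count(self) -> int:
        return int(self.activation_times.size)


#: slack for comparing grid times against event times (float round-off)
_T_EPS = 1e-9


def _indicator(x: np.ndarray) -> np.ndarray:
    return (x >= -_T_EPS).astype(float)


def adherence_trajectory(
    scenario: ScenarioConfig, params: ModelParameters
) -> tuple[Trajectory, AdaptiveRecord]:
    """Build A(s) on the simulation grid for one scenario.

    Returns the trajectory together with the record of adaptive activation
    events (empty for non-adaptive shapes). Adaptive crossings are detected
    on the grid: at the first grid point where the decaying adherence would
    fall below ``A_thresh``, adherence is reset to ``A0 + delta`` and the
    event is logged; a one-step refractory period prevents immediate
    re-triggering at the reset point.
    """
    validate(params, scenario)
    t = params.time_grid()
    A0, delta, tau = scenario.A0, scenario.delta, scenario.tau
    record = AdaptiveRecord()

    if scenario.shape == "baseline":
        if scenario.baseline_decay_rate > 0:
            values = A0 * np.exp(-scenario.baseline_decay_rate * t)
        else:
            values = np.full_like(t, A0)
    elif scenario.shape in ("step", "low_impact"):
        values = A0 + delta * _indicator(t - tau)
    elif scenario.shape == "decay":
        values = A0 + delta * np.exp(-scenario.theta * np.maximum(t - tau, 0.0)) \
            * _indicator(t - tau)
    elif scenario.shape == "adaptive":
        if scenario.A_thresh >= A0 + delta:
            raise ValueError("threshold unreachable: A_thresh >= A0 + delta")
        values = np.full_like(t, A0)
        events = []
        pre_values = []
        last_boost = tau  # policy start acts as the first boost
        active = False
        for i, s in enumerate(t):
            if s < tau - _T_EPS:
                continue
            if not active:
                active = True
                values[i] = A0 + delta
                continue
            candidate = A0 + delta * np.exp(-scenario.theta * (s - last_boost))
            # re-trigger only after at least one step of decay has elapsed
            if candidate < scenario.A_thresh and s - last_boost > params.grid_step * 1.5:
                events.append(s)
                pre_values.append(candidate)
                last_boost = s
                values[i] = A0 + delta
            else:
                values[i] = candidate
        record = AdaptiveRecord(np.asarray(events), np.asarray(pre_values))
    else:  # pragma: no cover - guarded by validate
        raise ValueError(f"unknown scenario shape {scenario.shape!r}")

    return Trajectory(t, np.clip(values, 0.0, 1.0)), record


def sample_delta(spec: DeltaSpec, n: int, seed: int) -> np.ndarray:
    """Draw n adherence gains from the given distribution; all in [0, 1].

    Sampling is deterministic given the seed. The truncated normal uses
    inverse-CDF sampling on the truncated interval so that draws are a
    monotone, seed-stable transform of uniforms.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    if spec.kind == "point":
        if not 0.0 <= spec.delta <= 1.0:
            raise ValueError("point delta must lie in [0, 1]")
        return np.full(n, spec.delta)
    if spec.kind == "beta":
        return rng.beta(spec.a, spec.b, size=n)
    if spec.kind == "truncnorm":
        if spec.sigma <= 0:
            return np.full(n, np.clip(spec.delta, 0.0, 1.0))
        a = (0.0 - spec.delta) / spec.sigma
        b = (1.0 - spec.delta) / spec.sigma
        u = rng.uniform(size=n)
        draws = stats.truncnorm.ppf(u, a, b, loc=spec.delta, scale=spec.sigma)
        return np.clip(draws, 0.0, 1.0)
    if spec.kind == "two_point":
        if not (0.0 <= spec.delta_lo <= 1.0 and 0.0 <= spec.delta_hi <= 1.0):
            raise ValueError("two-point values must lie in [0, 1]")
        high = rng.uniform(size=n) < spec.p
        return np.where(high, spec.delta_hi, spec.delta_lo)
    raise ValueError(f"unknown delta kind {spec.kind!r}")
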