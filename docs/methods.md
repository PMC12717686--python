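# Methods

## Model

The simulator tracks one representative patient (equivalently, a cohort
mean) over a horizon of T = 10 years on a uniform grid of step
h = 0.01 yr. Three coupled processes are represented.

**Disease progression.** Severity `D(s)` follows logistic growth

    dD/ds = k_eff(s) · D · (1 − D/D_max),
    k_eff(s) = k · (1 − η · (A(s) − A_ref)),

with ceiling `D_max = 1`, base rate `k = 0.7 /yr`, and initial condition
`D(0) = D_max / (1 + exp(k·s0))` with midpoint `s0 = 5/0.7 ≈ 7.14 yr`, so
that under reference adherence `A_ref = 0.5` the trajectory is exactly the
closed-form logistic `D_max / (1 + exp(−k(s − s0)))`, reaching ≈ 0.88 at
year 10. The coupling is a multiplicative modulation of the growth rate:
adherence above the reference slows progression, below it accelerates it.
This is the minimal mechanism that (a) leaves the untreated baseline on
the closed-form curve and (b) lets policy scenarios separate clinically.
The coupling strength `η = 0.8` is dimensionless; validation enforces
`η·(1 − A_ref) ≤ 1` so the effective rate can never go negative for
admissible adherence. Whether adherence should also affect `D_max`
(severity ceiling) was considered and rejected: rate modulation suffices
to separate the scenario endpoints and keeps one interpretable knob.

**Adherence.** `A(s) ∈ [0, 1]` is scenario-shaped, with step indicator
convention `I(x) = 1 for x ≥ 0` (a policy starting at τ acts at τ):

- baseline: constant `A0 = 0.5`, or `A0·exp(−θ_b·s)` for a decaying
  counterfactual (`θ_b = 0.05 /yr` when enabled; 0 = flat). The
  exponential form is the simplest monotone-erosion model for a
  counterfactual in which engagement wanes without intervention.
- step / low-impact: `A0 + δ·I(s − τ)`.
- regressive decay: `A0 + δ·e^(−θ(s−τ))·I(s − τ)`, `θ = 0.5 /yr`.
- adaptive nudges: the decaying form, reset to `A0 + δ` at the first grid
  point where adherence would fall below the threshold
  `A_thresh = 0.75`; each reset is logged and costed. Reset-to-`A0+δ`
  (rather than adding δ on top of the current level) was chosen because it
  is bounded and makes every inter-nudge cycle identical. Crossings are
  detected on the grid without sub-step root finding — the timing error is
  at most one step and vanishes as h → 0 — and a one-step refractory
  period prevents re-triggering at the reset point itself. A threshold at
  or above `A0 + δ` is rejected as unreachable.

All values are clipped to [0, 1].

**Costs.** Instantaneous model cost
`c(s) = α·D(s) + β·A(s)² + γ·P(s) + λ·H(s)` with disease weight `α = 1`,
adherence weight `β = −0.3` (negative: adherence effort buys savings,
quadratically, so marginal gains matter more at high adherence), policy
cost scale `γ` per scenario, and `λ = 0` by default (health outcomes enter
only through post-hoc monetization, e.g. DALYs averted × dollar value).
The policy expenditure rate is `P(s) = p_unit·I(s − τ)` with
`p_unit = 0.05 model-cost/yr`; adaptive resets additionally cost
`γ·nudge_cost` each (`nudge_cost = 0.25`), entering the cumulative
integral as discounted point masses at the event times — impulses, not
rates, because the spend is proportional to the number of activations.

Cumulative cost is `C(t) = ω·(C0 + ∫₀ᵗ e^(−ρs) c(s) ds + impulses)` with
continuous discount rate `ρ = 0.03 /yr`.

**Units and calibration.** The integral is computed in dimensionless
model-cost units; the offset `C0` (default 1.0) and currency scale `ω`
(USD per model-cost unit, default 1) map totals onto dollar scales. The
positive `C0` represents adherence-independent care cost and keeps the
total positive across the whole admissible design space (δ ≤ 0.4, γ ≥ 0)
— necessary because the ROI ratio divides by the policy scenario's total
cost. `calibrate_to_anchors` solves the 2×2 linear system that makes the
baseline and one policy simulation reproduce two published dollar totals
exactly; with the anchors $3953.07 / $3602.26 the calibrated model returns
ROI = 9.7% for that pair by construction of the exact interpolation.

**ROI conventions.** `ROI = 100·(C_baseline − C_policy)/C_policy`: the
denominator is the policy scenario's *total* cost, not the incremental
policy spend. This is unconventional for a return ratio but is implemented
as stated in the source framework; all monotonicity and break-even results
use it consistently. Payback time is the first grid time with strictly
lower cumulative policy cost, without interpolation between grid points;
an infinite sentinel marks designs that never pay back.

## Numerics

- **Severity integration:** adherence is held at its left-grid-point value
  across each interval (consistent with the indicator convention), making
  the effective rate piecewise constant; a fixed-step classical
  Runge–Kutta update then integrates the logistic within each step. In
  logit space the dynamics are linear, `d logit(D)/ds = k_eff(s)`, which
  provides an exact oracle: the integrator matches it to ~1e−11 for
  piecewise-constant adherence (tested at 1e−5).
- **Cost quadrature:** trapezoid rule on the grid, plus an exact
  correction at known cost discontinuities (policy start, adaptive
  resets). The sampled value at an event time is the post-jump level, so
  a plain trapezoid would smear the jump across the preceding interval —
  an O(h) boundary error; subtracting `h/2·e^(−ρt)·Δc` per event restores
  second-order convergence (grid halving changes ten-year totals by
  < 1e−5 relative). For constant cost the rule matches the closed form
  `c₀(1 − e^(−ρt))/ρ` to better than 1e−6 relative.
- **Break-even:** bisection on γ ∈ [0, γ_max = 10] for ROI(γ) = 0,
  exploiting strict monotone decrease of ROI in γ; tolerance 1e−4 on ROI.
  If ROI is still positive at γ_max the result is flagged unbounded.
- **Finite differences:** ROI slope in γ uses a central difference
  (default step 0.05), falling back to a forward difference at the γ = 0
  boundary.
- **Contours:** marching squares with linear edge interpolation
  (scikit-image), index coordinates mapped onto the δ/γ grids; polylines
  are not smoothed or joined across saddles.
- **Frontier:** a (cost, ROI) design is Pareto-efficient when no design
  achieves at least its ROI at lower or equal cost; along the frontier,
  ROI is therefore strictly increasing with cost.
- **Randomness:** one `numpy` generator per seed, consumed in draw order.
  The truncated normal uses inverse-CDF sampling so draws are a monotone,
  seed-stable transform of uniforms. Grid scans seed each cell as
  `master_seed + row·|γ-grid| + col` so cells are reproducible
  individually. Identical seeds give bit-identical outputs.

## Stochastic behaviour model

Behavioural heterogeneity enters only through the adherence gain δ:
Beta(2, 5) (mean ≈ 0.29, right-skewed — most patients respond modestly),
a truncated normal N(δ, σ²) on [0, 1] with default σ = 0.05 (a
moderate-heterogeneity placeholder; no published value exists), or a
two-point high/low responder mixture. Monte Carlo propagation re-simulates
the policy per draw against one shared baseline (the baseline carries no
δ). Duplicate draws are cached — results are identical, only faster.

## What the defaults emulate — and what they do not

The default parameter set emulates a calibrated chronic-disease cohort:
3% discounting, a ten-year horizon, a progression curve that leaves an
untreated patient at severity ≈ 0.88 by year 10, and scenario parameters
(τ, δ, γ) from the canonical six-scenario registry. No survey microdata
are ingested; the dollar anchors stand in for an empirical cost
calibration. Consequently, passing tests demonstrate the *structural*
claims — orderings, signs, monotonicities, break-even behaviour,
convergence — not empirical dollar magnitudes. Dollar-scale break-even
thresholds and income-stratified results would require the external
calibration and are out of scope. Under the placeholder nudge cost the
Adaptive Nudges scenario re-triggers every ≈ 0.37 yr and is ROI-negative;
its economics are dominated by `A_thresh`, `θ`, and `nudge_cost`, which is
precisely the tuning sensitivity the adaptive design is known for — users
should treat those three defaults as knobs, not findings.

## Problem sizes

Default analyses use the 1001-point grid (h = 0.01 over 10 yr);
design-space scans use a 9 × 13 (δ, γ) grid; Monte Carlo examples use
2,000 draws. These sizes were chosen so severity endpoints are converged
to ~1e−11 and Monte Carlo means have standard errors well under one ROI
percentage point, while a full analysis suite runs in seconds on one core.

## Limitations

- Deterministic disease dynamics: no random clinical events,
  multimorbidity, or mortality.
- One behavioural parameter (δ); no within-patient adherence dynamics
  beyond the scenario shapes.
- No time-varying discounting or macro-level inflation indexing (cost
  inflation is modelled as a one-off scaling stress test).
- The adherence → progression coupling is an assumption; only its
  reference-level behaviour is anchored to the closed-form curve.
- ROI covers direct modelled costs only; health outcomes enter solely via
  post-hoc monetization.
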