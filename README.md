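# adhereroi

Simulation framework for evaluating the return on investment (ROI) of
adherence-enhancing chronic-disease policies.

Chronic conditions such as diabetes and cardiovascular disease generate
costs that compound over decades, and interventions that improve medication
adherence (reminder programmes, counselling, behavioural nudges) are
promoted with little ex-ante economic justification. `adhereroi` couples
three processes in continuous time over a multi-year horizon —
logistic disease progression, time-varying patient adherence, and policy
expenditure — and asks, for any policy design, whether the discounted
savings justify the spend. It is aimed at health economists and policy
modellers who want a transparent, fully scriptable alternative to
black-box cost projections.

## Model

Instantaneous per-patient cost at time *s* is

```
c(s) = α·D(s) + β·A(s)² + γ·P(s) + λ·H(s)
```

where `D(s)` is disease severity, `A(s) ∈ [0, 1]` adherence,
`P(s)` the policy expenditure rate with cost scale `γ`, and `H(s)` an
optional health-outcome term (`λ = 0` in the primary analysis; averted
DALYs can be monetized post hoc). `β < 0` encodes savings from adherence
effort. Severity follows a logistic curve whose growth rate is slowed by
adherence above the reference level A_ref = 0.5:

```
dD/ds = k · (1 − η·(A(s) − A_ref)) · D · (1 − D/D_max)
```

Cumulative discounted cost and ROI are

```
C(t) = C₀ + ∫₀ᵗ e^(−ρs) c(s) ds        ROI = 100 · (C_baseline − C_policy) / C_policy
```

with continuous discount rate ρ = 3%/yr. Six canonical policy scenarios
are built in — no-intervention baseline, early and delayed step
interventions, a regressive (decaying) gain, threshold-triggered adaptive
nudges, and a high-cost low-impact design — plus break-even analysis
(γ\*(δ)), Monte Carlo propagation of behavioural heterogeneity in the
adherence gain δ, (δ, γ) design-space scans with iso-ROI contours and a
cost-effectiveness frontier, and robustness stress tests (cost inflation,
accelerated progression).

## Worked example

```python
import adhereroi as ar

params = ar.default_parameters()            # 10-yr horizon, ρ=0.03, k=0.7
scenarios = {s.name: s for s in ar.scenario_table()}

early = ar.compare_to_baseline(scenarios["Early Adherence"], params)
print(f"ROI = {early.roi_percent:.1f}%, payback at {early.payback_years:.2f} yr")
# ROI = 66.3%, payback at 2.01 yr

res = ar.simulate_scenario(scenarios["Early Adherence"], params)
print(f"year-10 severity = {res.severity.at_end():.4f}")   # 0.6584
# vs. 0.8808 for the untreated baseline

for delta in (0.10, 0.15, 0.25):
    gstar, _ = ar.breakeven_gamma(delta, scenarios["Early Adherence"], params)
    print(f"δ = {delta:.2f}: break-even cost scale γ* = {gstar:.3f}")
# δ = 0.10: γ* = 1.455   δ = 0.15: γ* = 2.241   δ = 0.25: γ* = 3.911
```

An early adherence gain of +0.3 (starting year 2, policy cost scale
γ = 1.5) repays its spend the first grid step after launch, returns 66%
of its total discounted cost as net savings over ten years in model
units, and keeps year-10 severity at 0.66 versus 0.88 untreated. The
break-even table shows how steeply the affordable cost scale grows with
behavioural impact: a gain of 0.25 tolerates ~2.7× the unit cost that a
gain of 0.10 does.

Model-unit costs are mapped to dollars by calibrating the offset `C₀` and
currency scale `ω` to two published cost anchors:

```python
cal = ar.calibrate_to_anchors(3953.07, 3602.26, scenarios["Early Adherence"], params)
base = ar.simulate_scenario(scenarios["Baseline"], cal).total_cost        # 3953.07
pol  = ar.simulate_scenario(scenarios["Early Adherence"], cal).total_cost # 3602.26
print(f"{ar.roi(base, pol):.1f}%")                                         # 9.7%
```

The same analyses are available from the shell:

```sh
adhereroi simulate --scenario early --out out/
adhereroi scan --stochastic --n 200 --seed 1 --out out/
adhereroi breakeven --deltas 0.10,0.15,0.25 --out out/
adhereroi montecarlo --n 2000 --seed 1 --out out/
adhereroi robustness --out out/
```

Every command writes CSV/JSON results plus a `run_meta.json` sidecar with
the resolved parameters, seed, and package version.

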