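# Methods

This note documents the model, the numerical choices, and the limits of what
the synthetic experiments can show. Symbols: `d` baseline and `d'`
post-policy deforestation (ha/yr) in a grid cell; `p` the cell's enforcement
probability; `B` the agency budget (BRL); `F` the per-hectare disincentive
and `PES` the per-hectare conditional payment (BRL/ha); `f(·)` the cell's
total profit of deforestation.

## Opportunity-cost disaggregation

District-level mean per-hectare profits of deforestation are disaggregated
to cells by assuming per-hectare profits within a cell are spatially
Normal(μᵢ, σ) and that baseline clearing occupies exactly the
positive-profit land:

    Φ(μᵢ/σ) = rateᵢ = d0ᵢ / areaᵢ.

One equation per cell cannot identify two parameters per cell, so σ is taken
**common within a district** and pinned by the district constraint that the
deforestation-area-weighted average of E[X | X > 0] over its cells equals
the district mean profit. Writing μᵢ = σ·zᵢ with zᵢ = Φ⁻¹(rateᵢ), the
constraint is linear in σ:

    σ_D = mean_profit_D · Σ d0ᵢ / Σ d0ᵢ·(zᵢ + φ(zᵢ)/Φ(zᵢ)),

which is strictly positive because the bracket is E[X|X>0] in σ units.
Alternatives (a per-cell σ tied functionally to μ, or a region-wide σ) would
need extra structure the data cannot identify; the common-σ choice is the
minimal assumption that delivers both stated identities exactly, and it
makes calibration exactly invertible (parameter-recovery is tested to 1e-6).

Numerical details: rates are clamped to [1e-6, 1−1e-6] before the probit
transform (Φ⁻¹ diverges at the ends) and clamped cells are flagged; cells
with d0 = 0 get no distribution — they are "never profitable", contribute
zero weight to the district constraint, and never respond to any incentive.
The rate denominator is total cell area by default; a column of remaining
forest area can be supplied instead.

Derived quantities are closed-form: marginal profit f′(d) is the (1 −
d/area) quantile of Normal(μ, σ) (zero exactly at d = d0); total profit uses
the antiderivative of the quantile, f(d) = μd + σ·area·φ(Φ⁻¹(1 − d/area)),
cross-checked against adaptive quadrature in the tests; the
avoided-deforestation cost curve at delivered incentive s is
Σ [d0ᵢ − area·Φ((μᵢ − s)/σ)], capped at d0 per cell so clamped rates cannot
produce negative avoidance.

## Land-user behavior

Risk-neutral land users maximize f(d′) − d′pF + PES(d − d′p) subject to
d′ ≤ d. The first-order condition equates marginal profit to the expected
policy incentive p(F+PES), giving d′ = area·Φ((μ − p(F+PES))/σ); decreasing
returns guarantee this is the global optimum and that d′ never exceeds the
baseline, so payments cannot reward inflated baselines inside the model.
Only the product p(F+PES) matters for behavior — the fine and the payment
are behaviorally interchangeable and differ only in who bears the cost.
The payment term PES(d − d′p) reads literally as payment on undetected
residual clearing; the alternative reading (pay on d − d′, claw back with
probability p) has the same expectation, so the printed form is used.

## Enforcement and equilibrium

The agency allocates inspections to maximize inspected deforestation,
max Σ d′ᵢpᵢ s.t. Σ pᵢ·costᵢ ≤ B with costᵢ = TCᵢ + ndᵢ·TC′ᵢ (first-patch
travel cost plus expected within-cell patch costs; patch counts are kept
fractional as expected values to avoid sweep discontinuities). The
continuous optimum is a fractional knapsack: fund cells by d′/cost
descending (ties broken by cell id), at most one fractional cell.

**Equilibrium concept.** The knapsack best response is piecewise constant in
p, and a pure fixed point of the alternating best responses generically
does not exist: funding a cell deters its deforestation, which pushes it
back out of the funded set. The economically meaningful object is the
stationary state of the repeated yearly interaction in which land users
expect the *historical frequency* of inspections. That state is
characterized by a shadow ratio θ (deforestation inspected per marginal
real): cells whose d′/cost exceeds θ even at p = 1 are always inspected,
cells below θ at p = 0 never are, and marginal cells are held at the
frequency that pins their ratio to θ, with θ set by budget exhaustion.
`solve_equilibrium` first runs the damped best-response iteration (step
0.5, halved once on oscillation), which terminates immediately in the easy
regimes (B = 0, saturated budgets, zero incentive, naive agency); if the
iteration cycles or stalls it switches to the exact stationary solution by
bisection on θ (budget matched to 1e-12 relative). The solver is validated
against an independent simulation of the repeated interaction (running-
frequency best-response play, 5–6k rounds): total equilibrium deforestation
agrees to < 0.01% on random 4-cell instances.

**Logistic spatialization.** Observed enforcement is smoother than a
knapsack; the package fits p ≈ logistic(a + b₁·log(1+d′) − b₂·log(1+cost))
to the knapsack plan by maximum likelihood (fractional probabilities enter
as weighted binary outcomes). Because a knapsack plan's funding threshold
typically separates the data perfectly, the fit falls back to a weakly
L2-penalized likelihood (C = 1) when the unpenalized coefficients diverge;
on non-separated plans plain ML is used, and refitting on its own predicted
probabilities is then exactly stationary. In logistic mode the slopes are
fitted once against baseline deforestation and only the intercept moves: it
is recalibrated by bisection so spending equals B. The logistic equilibrium
is computed by nested bisection — inner: each cell's scalar fixed point
p = expit(a + b₁log(1+d′(p)) − b₂log(1+cost)), unique because the
right-hand side is non-increasing in p; outer: the intercept a, since
spending is increasing in a — and it is a true fixed point of the
best-response map.

A `naive_epa` flag makes the agency target baseline deforestation d0
instead of anticipating d′ (its allocation is then a constant map and the
iteration converges in two passes).

## Outcome metrics

CE divides avoided deforestation by B plus payment outlays (minus collected
fines when the disincentive is a true fine rather than in-situ coercion);
the budget B, not realized inspection spending, enters the denominator —
the agency's budget is institutionally separate from the payment budget —
and realized spending is reported separately. A denominator ≤ 0 (fines
cover all outlays) is flagged "self-financing" rather than reported as a
negative ratio. Exact accounting identities hold by construction and are
asserted in tests: total payments = PES·avoided + PES loss, and with fines
collected the full circuit W + Δf + agency net revenue + inspection
spending sums to zero (transfers cancel between agency and land users).

## Synthetic landscapes

The generator emulates the structure of the study-region inputs rather than
any particular year of data. Cells sit on a regular 20 km grid; remoteness
is distance from an access corner. Defaults (all overridable in
`SyntheticConfig`):

- **Inspection costs**: tc_first = 25,000·exp(0.8·remoteness + 0.3·ε) BRL —
  tens of thousands of BRL per field mission, rising with remoteness, sized
  so that the total cost of inspecting the whole 50×50 landscape (~120 M
  BRL) well exceeds the simulated budget range (0–50 M BRL): enforcement
  must ration, as in the real policy setting. tc_within = 600 BRL per
  additional patch; patch counts 0.035 per hectare of clearing.
- **Deforestation rates**: expit(−5.5 + 0.8·profit latent + 1.5·ε), clipped
  to [1e-5, 0.9] — median ~0.4%/yr with a heavy upper tail; the 50×50
  default totals ~1.5 Mha/yr of baseline clearing, the same order as the
  region the model targets. More profitable, more accessible cells deforest
  more.
- **Opportunity costs**: district means mapped into 300–1200 BRL/ha, loaded
  negatively on remoteness with the loading tuned by bisection so the
  realized correlation between district mean profit (broadcast to cells)
  and tc_first hits the target (−0.33 by default; achievable range is
  checked and an explicit error raised otherwise).

Everything is drawn once from a seeded generator, so landscapes are
bit-reproducible and the correlation tuning is deterministic.

**What the synthetic experiments do and do not show.** They exercise every
identity, solver, and qualitative mechanism: monotone cost curves with the
correct asymptote, the carrot/stick substitution tradeoff (constant avoided
deforestation, falling cost-effectiveness, rising land-user income),
budget responses (pure command-and-control CE falling in B, pure-PES CE
rising at low B because higher p makes payments conditional in practice),
and shrinking payment leakage in B. They do not reproduce the real region's
magnitudes, and one per-hectare normalization is sensitive to the
opportunity-cost tail: on the synthetic landscape, income change per
avoided hectare *rises* with the budget at small PES (≤ ~100 BRL/ha),
because near-total deterrence collapses the fine bill faster than forgone
profits grow along the gentle normal-tail cost curve, and the leakage
mechanism is too small at low payment levels to dominate. Aggregate income
always falls with the budget, at every payment level, and the per-hectare
decline reappears once payments are substantial (PES ≥ 500). On data with a
steeply convex cost curve near its asymptote the per-hectare decline would
extend to lower PES.

## Problem sizes and runtime

Default analyses use the 50×50-cell landscape (2500 cells, 25 districts);
a single equilibrium solve takes milliseconds, a full sweep seconds, and
the complete test suite under a minute on one CPU. Tolerances: equilibrium
1e-6 on probabilities; budget bisection 1e-12 (knapsack θ) / 1e-9
(logistic intercept) relative; calibration identities hold to machine
precision.

## Known limitations

Single-period, partial-equilibrium, risk-neutral: no moral hazard or
legal-additionality payment design, no leakage between cells, no adverse
selection into contracts, no commodity-price feedback, no preemptive
patrolling, and uniform (untargeted) payments only. The agency's empirical
inspection behavior is represented only through the functional family of
the logistic surface, not through any particular fitted coefficients.
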