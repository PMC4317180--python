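# policymix

A spatial simulator of mixed **"carrots and sticks"** forest-conservation
policy: per-hectare conditional payments for environmental services (PES)
combined with fines or in-situ coercion under imperfect, budget-constrained
law enforcement. It is built for ex-ante policy analysis of deforestation
frontiers such as the Brazilian Amazon, where an environmental protection
agency (EPA) with a fixed budget inspects remotely sensed deforestation
patches, and land users weigh the profit of clearing against the expected
penalty and forgone payments.

## The model

The landscape is a table of 20×20 km grid cells nested in districts. In cell
*i*, per-hectare profits of deforestation are spatially distributed as
Normal(μᵢ, σ); land with positive profit is cleared at baseline, so the
observed deforestation rate identifies Φ(μᵢ/σ) and the district's mean
opportunity cost (deforestation-weighted average of E[profit | profit > 0])
identifies the common district scale σ in closed form. The marginal profit
of the *d*-th cleared hectare is the (1 − d/area) quantile of that
distribution — decreasing returns, zero exactly at the baseline optimum.

A policy mix is (B, F, PES): the EPA budget, the per-hectare disincentive,
and the per-hectare payment conditional on avoided deforestation, with
conditionality enforced by the same inspections as the fine. A risk-neutral
land user facing inspection probability *p* clears up to

  f′(d′) = p·(F + PES),  so  d′ = area·Φ((μ − p(F+PES))/σ) ≤ d.

The EPA maximizes inspected illegal deforestation, max_p Σ d′ᵢ pᵢ subject to
Σ pᵢ(TCᵢ + ndᵢ·TC′ᵢ) ≤ B — a fractional knapsack in deforestation per real
of inspection cost — or, optionally, a smooth logistic spatialization of
that allocation. Land users' expectations and the agency's allocation are
solved to a joint stationary state (see `docs/methods.md` for the
equilibrium concept and solvers). Outcomes per mix:

- **Cost-effectiveness** CE = Σ Δdᵢ / (B + Σ PES(dᵢ − d′ᵢpᵢ) − collected
  fines), reported in ha per 1000 BRL;
- **Income change** W = Σ PES(dᵢ − d′ᵢpᵢ) − pᵢFd′ᵢ − Δfᵢ;
- **PES loss** Σ PES·d′ᵢ(1 − pᵢ): payments that buy no conservation because
  conditionality goes unenforced (an imperfect-enforcement rent);
- per-cell **net revenue** maps (fine revenue minus costs and payments).

Because the paper-scale input data (deforestation rasters, district
opportunity costs, travel-cost surfaces) are not distributable, the package
ships a seeded synthetic-landscape generator that emulates their structure:
district opportunity costs negatively correlated with inspection costs
(target Pearson r = −0.33), inspection costs rising with remoteness, and
strongly heterogeneous deforestation rates.

## Worked example

```
$ policymix synth --nx 20 --ny 20 --districts 10 --seed 3 --out-prefix demo
wrote 400 cells, 10 districts (realized cost-profit r = -0.330)

$ policymix simulate --cells demo_cells.csv --districts demo_districts.csv \
    --budget 10000000 --fine 5000 --pes 500 --out run.csv
avoided 216544.9 ha, CE 1.830 ha/1000 BRL, income change -85994919 BRL
```

The summary line says: with a 10 M BRL inspection budget, a 5000 BRL/ha
fine and a 500 BRL/ha payment, equilibrium deforestation falls by ~217,000
ha; each 1000 BRL of implementation cost (budget plus payment outlays) buys
1.83 ha of avoided deforestation; and land users are collectively worse off
by ~86 M BRL than under laissez-faire. `run.csv` holds the per-cell table
(`p, d_prime, income_change, net_revenue, pes_paid, pes_loss, fines_paid`)
and `run.csv.summary.json` the aggregates, e.g.:

```
"avoided_total_ha": 216544.9158450067,
"ce_ha_per_1000brl": 1.8303397344532577,
"pes_loss_total_brl": 36133.52032570175,
"income_change_total_brl": -85994919.46041745
```

Other subcommands: `policymix costcurve` (avoided-deforestation cost curve
with per-cell percentile bands) and `policymix sweep --kind
tradeoff|budget|income` (tidy tables for carrot/stick substitution at
constant total incentive, budget response of cost-effectiveness, and
income/leakage effects; presets `fig4` … `fig8` mirror standard scenario
settings). Everything is also available as a library:

```python
import policymix as pm

land = pm.generate_synthetic_landscape(pm.SyntheticConfig(seed=0))
model = pm.calibrate_cell_distributions(land)
res = pm.run_scenario(land, pm.PolicyMix(B=5e7, F=5000, PES=500), model=model)
print(res.ce_per_1000, res.W_total, res.pes_loss_total)
```

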