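# codfishsim

A hybrid simulator of a two-gear demersal cod fishery, built to ask a policy
question: **how should the annual catch quota be split between bottom trawlers
and longliners** when the outcome is judged simultaneously on profit, on
greenhouse-gas emissions, and on jobs at sea?

The package is aimed at fisheries modellers and bioeconomists who want a
transparent, fully scripted desk model: every input is either a documented
default or a small CSV/YAML file, and every figure in an analysis can be
regenerated from a seed.

## The model

**Stock.** Fishable biomass `x` (thousand tonnes, kt) follows the logistic
surplus-production model

```
dx/dt = r x (1 − x/K)
```

with intrinsic growth rate `r = 0.47 /yr` and carrying capacity
`K = 2654.44 kt` by default (estimates obtained by linear regression of
per-capita surplus production on biomass; the package re-derives such
estimates from any annual `year,biomass_kt,catch_kt` series via
`fit_logistic`).

**Management.** Each fishing year the total allowable catch follows the
averaged harvest control rule

```
TAC_{y+1} = (a · B_{y+1} + TAC_y) / 2,        a = 0.2
```

whose fixed point under full uptake is `B* = K (1 − a/r) ≈ 1524.9 kt`,
`TAC* = a B* ≈ 305.0 kt`.

**Fleet.** A discrete-event model simulates individual fishing trips of four
vessel classes (one bottom trawler, three longliner sizes). The TAC is split
`q : (1 − q)` between trawl and longline gear. Before each departure a vessel
queries the quota ledger; quota is reserved at departure, the last trip of a
year may be partial, so a fleet with sufficient capacity always lands exactly
its allocation. Landings are withdrawn from the stock at their landing
instants, with RK4 integration of the growth equation in between.

**Impacts.** Each trip is accounted in three dimensions:
profit = value-of-fish × catch × PR (PR = net profit / revenue, per vessel
class); CO₂-equivalents at the gear-resolved life-cycle factors
**5.14 kg CO₂-eq per kg** of trawled cod and **1.58 kg CO₂-eq per kg** of
longlined cod; and jobs as the crews of all vessels active in the year.

A sweep over `q ∈ [0, 1]` scores each dimension as a proportion of its best
outcome on the grid and locates the crossover of the economic and
environmental curves. In 2011, 46% of the cod TAC was taken by bottom trawls
and 32% by longlines (78% coverage), which puts the current-policy marker at
`q ≈ 0.59`.

## Worked example

```python
import numpy as np
from codfishsim import ScenarioConfig, default_fleet, sweep_q, normalize, find_crossover

base = ScenarioConfig(q=0.5, horizon=10, fleet=default_fleet(), seed=0)
results = sweep_q(np.linspace(0, 1, 21), base)
scores = normalize(results)
print(round(results[-1].total_profit / 1e9, 2))   # 229.31  (profit at q=1, billions)
print(round(results[0].total_co2_kg / 1e9, 2))    # 4.82    (CO2 at q=0, Mt CO2-eq)
print([round(c, 3) for c in find_crossover(scores)])  # [0.248]
```

Profit is maximal when the whole quota goes to trawlers (`q = 1`) and
emissions are minimal at the opposite end (`q = 0`); with the default
economics the two normalized curves intersect at `q ≈ 0.25` — the allocation
that equalises the two criteria if they are weighted equally. The current
policy (`q ≈ 0.59`) leans toward profitability.

The same analysis from the shell:

```
codfishsim sweep --out results/       # sweep.csv + sweep_summary.json + manifest
codfishsim report --out results/      # adds the normalized-score figure
codfishsim fit --input series.csv     # surplus-production (r, K) estimates
codfishsim playback --input series.csv --out results/   # forced-catch validation
```

## Layout

- `codfishsim.stock_dynamics` — logistic growth, harvest control rule, equilibrium, regression fitting
- `codfishsim.fleet_des` — vessel classes, quota ledger, one-year trip event loop
- `codfishsim.impact_accounting` — profit, CO₂-eq, jobs per year and gear
- `codfishsim.scenario_engine` — multi-year hybrid runs, q-sweeps, normalization, playback
- `codfishsim.synthetic_data` — assessment-series generator, default/bulk fleets
- `codfishsim.cli_io` — YAML config validation, CSV writers, manifests, the CLI

See `docs/methods.md` for model assumptions, parameter choices, and known
limitations.
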