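# Methods

## Model structure

The simulator couples two submodels over a shared fishing-year clock.

The **biological submodel** is the unstructured logistic (Schaefer)
surplus-production model, `dx/dt = r x (1 − x/K)`, with the fishable biomass
`x` as its single state. There is no age structure, no recruitment process,
and no environmental stochasticity in growth: variability in the simulated
system comes entirely from management (the TAC path) and from fishing
activity. Management is the averaged harvest control rule
`TAC_{y+1} = (a·B + TAC_y)/2`, applied once per year with `B` read at the
TAC-setting instant — the start of the new fishing year. Iterating the rule
at fixed biomass converges geometrically (ratio 1/2) to `a·B`; combined with
the growth equation under full uptake the joint fixed point is
`B* = K(1 − a/r)`, `TAC* = a·B*`.

The **fleet submodel** is a discrete-event loop over individual vessels. Each
vessel cycles request → trip → turnaround. Quota is held per gear in a
ledger; a grant reserves `min(catch_per_trip, remaining)` at departure, so
landings can never overshoot an allocation, and the final grant of a year may
be partial so that an amply sized fleet lands its allocation exactly. A
vessel is denied when its gear's pool is empty and then idles until the next
year; a trip that could not land before year end is not started (its
reservation is returned). Events are ordered on a heap with a stable
insertion-order tie-break, so a configuration with fixed durations produces a
bit-reproducible, hand-checkable schedule. Trip durations may instead be
drawn per trip from a uniform or lognormal distribution; all draws come from
one seeded generator per fishing year, spawned from the scenario seed.

**Coupling.** The two submodels interact at exactly two surfaces: the annual
TAC (biology → fleet, via the ledger) and landed catches (fleet → biology),
which are subtracted from the stock as impulses at their landing times.
Between impulses the growth ODE is integrated with explicit fixed-step RK4 at
an internal step of 1/365 yr. RK4 at daily resolution reproduces the
logistic closed form to ~1e−10 relative error over a decade, so integration
error is negligible against any other modelling choice.

## Impact accounting

* **Profit** per trip is `value-of-fish × catch × PR`, with the value (per
  kg) and `PR` (net profit over net revenue) fixed per vessel class. PR may
  be negative, representing structurally loss-making classes.
* **CO₂-equivalents** use gear-resolved life-cycle factors per kg of landed
  catch: 5.14 (bottom trawl) and 1.58 (longline). The factors are applied to
  landed mass directly; any distinction between landed and processed mass is
  outside the model boundary.
* **Jobs** count the summed crews of vessels that completed at least one trip
  in the year — activity-based, not FTE-weighted. Onshore employment (e.g.
  baiting for longliners without baiting machines) is excluded, which
  understates the social contrast between the gears.

Because full uptake makes per-gear annual catch equal its allocation, a
year's total CO₂ is exactly `TAC_kg · (q·5.14 + (1−q)·1.58)` — linear and
strictly increasing in the trawl share `q`. This identity is the closed-form
oracle the event model is tested against.

## Scenario engine and normalization

A sweep runs one independent scenario per `q` on a grid (default step 0.05),
with the same seed and initial conditions everywhere, so differences across
the grid are attributable to the allocation alone. Horizon totals per
category are normalized to "proportion of the best outcome on the grid":
profit and jobs by `value/max`, CO₂ (lower is better) by `min/value`, so the
best q in each category scores exactly 1. If no grid point earns a positive
profit the ratio is meaningless and an affine min–max rescaling is used and
flagged. The economic and environmental score curves are interpolated
piecewise-linearly and their sign-change abscissae reported as crossovers;
under the default economics (trawler profit per kg strictly highest, both
gears profitable) the curves are monotone in opposite directions and cross
exactly once.

The current-policy marker is computed from configurable gear shares of the
TAC (defaults 46% trawl, 32% longline, i.e. 78% coverage), giving
`q = 0.46/0.78 ≈ 0.59`; it is a display marker, not a constraint.

## Parameter estimation

`fit_logistic` uses the standard linearisation of the surplus-production
model: annual surplus `S_t = x_{t+1} − x_t + C_t`, per-capita surplus
`S_t/x_t` regressed on `x_t` by OLS. The intercept estimates `r`, the slope
`−r/K`. The t-statistic of `K̂ = −b₀/b₁` is obtained by the delta method on
the coefficient covariance. A constant biomass series raises a
degenerate-design error; a non-negative slope (implying `K̂ ≤ 0`) returns the
estimates flagged invalid with a warning.

**Known estimator limitation.** With multiplicative observation noise on
biomass, the noise enters both the regressor `x_t` and the response
`(x_{t+1} − x_t + C_t)/x_t`, producing correlated errors-in-variables. The
resulting bias (upward in `r̂`, downward in `K̂`) is systematic: at a log-sd
of 0.05 on a 57-point series it amounts to roughly 3–10% on `r̂` depending on
how widely the trajectory ranges, and no admissible catch path removes it —
it scales with (noise variance)/(regressor variance). The package documents
this rather than hiding it: noiseless series are recovered to 1e−8 relative
error (the fitter is exact on its own generating map), the Monte-Carlo bias
test in the acceptance suite asserts unbiasedness and fails, deliberately,
as a faithful record of the naive estimator's behaviour. Users fitting noisy
indices should treat the OLS estimates as biased or substitute an
errors-in-variables estimator.

## Synthetic data

The generator iterates the annual discrete map
`x_{t+1} = x_t + r x_t (1 − x_t/K) − C_t` under one of three catch rules
(the control rule, a fixed fraction, or a supplied series), capping catch at
the available stock. Observed biomass multiplies the truth by
lognormal(0, sd) draws; catches are observed without error. Defaults — 57
annual points, the default `(r, K, a)`, start at `K/4` — are the package's
standing study conditions. A continuous mode integrates the ODE within the
year instead of the map, for quantifying the discretisation gap (transiently
up to ~6–10% of biomass, vanishing near equilibrium).

Because a control-rule trajectory settles at `B*` within ~15 years, leaving
the regressor nearly constant thereafter, estimator studies use an
oscillating forced catch path (`wandering_catch_series`) that keeps biomass
traversing a wide range; this measures the estimator rather than a
degenerate design.

The **default fleet** (one trawler class, three longliner classes) is
synthetic: public accounts aggregate fleet economics, so per-class figures
are package choices. They are set so that (i) each gear alone can absorb the
equilibrium TAC (~305 kt/yr) — the standing full-uptake assumption; (ii)
trawler profit per landed kg (75 currency units) strictly exceeds every
longliner class (57.6/38.4/16.5), making the economic optimum `q = 1`;
(iii) every longliner class carries more crew per landed tonne than the
trawler. A `bulk_fleet` variant with few large vessels trades trip-level
granularity for speed in long-horizon runs where only aggregate uptake
matters.

What passing tests on synthetic data do **not** show: that the logistic map
is an adequate description of a real assessed stock, that the LCA factors
transfer across years and fleets, or that per-class economics resemble any
real operator. The synthetic generator has no assessment-model error, no
catch misreporting, and no autocorrelated noise.

## Numerical and design choices

* Biomass, catch, TAC in thousand tonnes throughout; conversion to kg
  (×1e6) happens only in impact accounting.
* Initial TAC defaults to `a·x₀`, the rule's fixed point at the starting
  stock, so an undisturbed run starts in steady management.
* The hybrid equilibrium is a within-year cycle, not a point: year-start
  biomass sits ~1.5% above the analytic `B*` because withdrawals are spread
  over the year while `B*` balances them continuously. Convergence checks
  therefore bound biomass by 1% of K and the TAC by `a` times that.
* Withdrawals exceeding the stock clamp biomass to zero with a logged
  warning; simulations continue (zero growth) rather than aborting, so a
  collapse is visible in the outputs instead of an exception.
* Playback (forced catch histories, control rule bypassed) defaults to the
  discrete annual map so a generated series replays exactly; a continuous
  mode applies each year's catch as a mid-year impulse.
* Horizons: scenario analyses use 10 years (the policy-relevant window
  before the stationary cycle dominates); equilibrium checks 100 years; the
  default q-grid has 21 points, enough to resolve the single crossover to
  ±0.025 before interpolation.
* One root seed per scenario, spawned per fishing year; identical seed and
  configuration give bit-identical results, including output CSVs.
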