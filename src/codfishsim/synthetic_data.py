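"""Synthetic inputs: assessment series, catch histories and a default fleet.

No stock-assessment tables or fleet microdata are shipped with the package;
everything needed to exercise the model is generated here.  The assessment
generator iterates the annual discrete logistic map

    x_{t+1} = x_t + r x_t (1 - x_t / K) - C_t

under a chosen catch rule, and reports the truth alongside an observed series
with multiplicative lognormal noise on biomass (the standard error structure
for survey-type stock indices; catches are treated as known exactly).  Because
the surplus-production fitter linearises exactly this map, a noiseless series
round-trips to the generating (r, K) at machine precision — which is what
makes the generator usable as an oracle.  An alternate continuous mode
integrates the growth ODE within the year instead, for studying the
discretisation bias of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fleet_des import Fleet, Gear, TripDurationSpec, VesselClass
from .stock_dynamics import (
    AssessmentSeries,
    StockParameters,
    StockState,
    compute_tac,
    step_biomass,
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a synthetic annual stock-assessment series.

    Defaults mirror the study conditions: 57 annual points with the
    regression-estimated stock parameters (r=0.47, K=2654.44 kt) and the
    a=0.2 harvest control rule, starting from a depleted stock (K/4) so the
    trajectory actually traverses part of the state space.

    catch_rule is one of:

    * ``"hcr"`` — catches follow the averaged harvest control rule;
    * ``"fixed_fraction"`` — C_t = fraction * x_t;
    * ``"series"`` — catches supplied explicitly (length >= n).

    noise_sd is the log-sd of multiplicative lognormal observation noise on
    biomass; 0 disables noise.
    """

    r: float = 0.47
    K: float = 2654.44
    a: float = 0.2
    n: int = 57
    x0: Optional[float] = None  # defaults to K/4
    catch_rule: str = "hcr"
    fraction: float = 0.15
    catches: Optional[Sequence[float]] = None
    noise_sd: float = 0.0
    seed: int = 0
    mode: str = "discrete"  # or "continuous"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3 annual points")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.catch_rule not in ("hcr", "fixed_fraction", "series"):
            raise ValueError(f"unknown catch rule {self.catch_rule!r}")
        if self.catch_rule == "series" and (
            self.catches is None or len(self.catches) < self.n
        ):
            raise ValueError("catch_rule='series' needs >= n supplied catches")
        if self.mode not in ("discrete", "continuous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.x0 is not None and self.x0 <= 0:
            raise ValueError("initial biomass must be positive")


def generate_assessment_series(
    spec: GeneratorSpec,
) -> tuple[AssessmentSeries, AssessmentSeries]:
    """Generate (observed, truth) assessment series from the spec.

    The truth series is the noiseless trajectory; the observed one multiplies
    biomass by lognormal(0, noise_sd) draws from a generator seeded with
    ``spec.seed``.  Catch each year is capped so the stock cannot go negative.
    """
    params = StockParameters(r=spec.r, K=spec.K, a=spec.a)
    x0 = spec.x0 if spec.x0 is not None else spec.K / 4.0
    rng = np.random.default_rng(spec.seed)

    years = np.arange(spec.n)
    truth_x = np.empty(spec.n)
    catches = np.empty(spec.n)

    x = x0
    tac = spec.a * x0
    for i in range(spec.n):
        truth_x[i] = x
        if spec.catch_rule == "hcr":
            c = tac
        elif spec.catch_rule == "fixed_fraction":
            c = spec.fraction * x
        else:
            c = float(spec.catches[i])  # type: ignore[index]
        if spec.mode == "discrete":
            grown = x + params.r * x * (1.0 - x / params.K)
        else:
            grown = step_biomass(StockState(x=x, t=0.0), params, dt=1.0).x
        c = min(c, grown)  # cannot land more than is there
        catches[i] = c
        x = grown - c
        tac = compute_tac(x, tac, spec.a)

    obs_x = truth_x * rng.lognormal(0.0, spec.noise_sd, size=spec.n) \
        if spec.noise_sd > 0 else truth_x.copy()

    truth = AssessmentSeries(years, truth_x, catches)
    observed = AssessmentSeries(years, obs_x, catches)
    return observed, truth


def wandering_catch_series(
    n: int,
    params: StockParameters | None = None,
    x0: float | None = None,
    period: float = 16.0,
    amplitude: float = 0.5,
) -> np.ndarray:
    """A forced catch path that keeps biomass moving over a wide range.

    Catches oscillate around the equilibrium-sustaining level,
    C_t = (1 + amplitude * sin(2 pi t / period)) * a * x_t, which drives the
    stock through repeated build-up and draw-down phases.  Useful for
    estimator studies where a trajectory parked at equilibrium would leave
    the regressor with almost no variance.
    """
    params = params or StockParameters()
    x = x0 if x0 is not None else params.K / 4.0
    out = np.empty(n)
    for t in range(n):
        c = (1.0 + amplitude * np.sin(2.0 * np.pi * t / period)) * params.a * x
        grown = x + params.r * x * (1.0 - x / params.K)
        c = min(c, grown)
        out[t] = c
        x = grown - c
    return out


def default_fleet() -> Fleet:
    """The documented default fleet: three longliner classes and one trawler.

    Counts and per-trip figures are synthetic but scaled so each gear alone
    can absorb the equilibrium TAC of the default stock parameters
    (about 305 kt/yr), reflecting the assumption that the fleet always has
    the capacity to take its full quota.  Profit per landed kg is strictly
    highest for the trawler class (value x PR: 75 vs 57.6/38.4/16.5 per kg),
    while the longline classes carry more crew per landed tonne — the two
    asymmetries that shape the quota-sweep trade-off.
    """
    trawler = VesselClass(
        name="bottom_trawler",
        gear=Gear.BOTTOM_TRAWL,
        catch_per_trip=0.120,
        trip_duration=TripDurationSpec(kind="fixed", days=5.0),
        turnaround_days=2.0,
        crew_jobs=15,
        fish_value_per_kg=300.0,
        profit_ratio=0.25,
    )
    ll_large = VesselClass(
        name="longliner_large",
        gear=Gear.LONGLINE,
        catch_per_trip=0.045,
        trip_duration=TripDurationSpec(kind="fixed", days=3.0),
        turnaround_days=1.0,
        crew_jobs=14,
        fish_value_per_kg=320.0,
        profit_ratio=0.18,
    )
    ll_medium = VesselClass(
        name="longliner_medium",
        gear=Gear.LONGLINE,
        catch_per_trip=0.020,
        trip_duration=TripDurationSpec(kind="fixed", days=2.0),
        turnaround_days=1.0,
        crew_jobs=9,
        fish_value_per_kg=320.0,
        profit_ratio=0.12,
    )
    ll_small = VesselClass(
        name="longliner_small",
        gear=Gear.LONGLINE,
        catch_per_trip=0.008,
        trip_duration=TripDurationSpec(kind="fixed", days=1.0),
        turnaround_days=1.0,
        crew_jobs=5,
        fish_value_per_kg=330.0,
        profit_ratio=0.05,
    )
    return Fleet(
        units=(
            (trawler, 60),
            (ll_large, 30),
            (ll_medium, 45),
            (ll_small, 70),
        )
    )


def bulk_fleet() -> Fleet:
    """A coarse-grained ample fleet: same two gears, few large vessels.

    Trades realism for event count — handy for long-horizon runs where only
    aggregate quota uptake matters, not trip-level granularity.
    """
    trawler = VesselClass(
        name="bulk_trawler",
        gear=Gear.BOTTOM_TRAWL,
        catch_per_trip=5.0,
        trip_duration=TripDurationSpec(kind="fixed", days=5.0),
        turnaround_days=2.0,
        crew_jobs=15,
        fish_value_per_kg=300.0,
        profit_ratio=0.25,
    )
    longliner = VesselClass(
        name="bulk_longliner",
        gear=Gear.LONGLINE,
        catch_per_trip=2.0,
        trip_duration=TripDurationSpec(kind="fixed", days=3.0),
        turnaround_days=1.0,
        crew_jobs=12,
        fish_value_per_kg=320.0,
        profit_ratio=0.18,
    )
    return Fleet(units=((trawler, 8), (longliner, 10)))
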