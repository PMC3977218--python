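"""Multi-year hybrid simulations, quota sweeps, and playback validation.

A scenario couples the continuous stock model and the event-driven fleet
year by year: at the start of each fishing year the harvest control rule sets
the TAC from the current biomass and last year's TAC, the TAC is split
between the gears by the trawl share ``q``, the fleet fishes the year out
against that ledger, and every landing is subtracted from the stock at its
landing instant before growth resumes.

A sweep runs an independent scenario per value of ``q`` with identical seed
and initial conditions, so any difference between results is attributable to
the allocation alone.  Horizon totals of profit, CO2 and job-years are then
normalised per category as a proportion of the best outcome on the grid
(for CO2, lower is better, so the score is min/value), and the crossing point
of the economic and environmental curves is located by piecewise-linear
interpolation.

Playback mode bypasses the control rule entirely and forces a historical (or
synthetic) catch series through the stock model, for validation against the
series' own biomass record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fleet_des import Fleet, Gear, TripRecord, allocate_quota, run_fishing_year
from .impact_accounting import AnnualImpacts, ImpactFactors, aggregate_annual
from .stock_dynamics import (
    AssessmentSeries,
    StockParameters,
    StockState,
    compute_tac,
    growth_rate,
    step_biomass,
)
from .synthetic_data import default_fleet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything one hybrid run needs.

    q is the bottom-trawl share of each year's TAC; horizon is in years.
    initial_tac defaults to a * initial_biomass, the control rule's fixed
    point at the starting stock.  The seed drives stochastic trip durations
    (the default fleet is deterministic, so it only matters when a duration
    distribution is configured).
    """

    q: float
    horizon: int = 10
    params: StockParameters = field(default_factory=StockParameters)
    fleet: Fleet = field(default_factory=default_fleet)
    factors: ImpactFactors = field(default_factory=ImpactFactors)
    initial_biomass: float = 1524.89
    initial_tac: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.q <= 1:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if self.horizon < 1:
            raise ValueError("horizon must be at least 1 year")
        if self.initial_biomass <= 0:
            raise ValueError("initial biomass must be positive")

    @property
    def tac0(self) -> float:
        if self.initial_tac is not None:
            return self.initial_tac
        return self.params.a * self.initial_biomass


@dataclass(frozen=True)
class ScenarioResult:
    """Per-year impacts plus horizon totals for one value of q."""

    q: float
    annual: tuple[AnnualImpacts, ...]
    tac_by_year: tuple[float, ...]
    biomass_by_year: tuple[float, ...]  # biomass at each year start, + final
    trip_records: tuple[TripRecord, ...]

    @property
    def total_profit(self) -> float:
        return sum(a.total_profit for a in self.annual)

    @property
    def total_co2_kg(self) -> float:
        return sum(a.total_co2_kg for a in self.annual)

    @property
    def total_jobs_years(self) -> int:
        return sum(a.total_jobs for a in self.annual)

    @property
    def total_catch_kt(self) -> float:
        return sum(a.total_catch_kt for a in self.annual)

    @property
    def final_biomass(self) -> float:
        return self.biomass_by_year[-1]


@dataclass(frozen=True)
class NormalizedScores:
    """Per-q scores in (0, 1]; each category attains 1 at its best q."""

    q: tuple[float, ...]
    economic: tuple[float, ...]
    environmental: tuple[float, ...]
    social: tuple[float, ...]
    economic_affine: bool = False  # min-max fallback used (profits <= 0 everywhere)


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run one multi-year hybrid simulation.

    Year 0 fishes against the configured initial TAC; each subsequent year's
    TAC follows the control rule from the biomass at that year's start.  A
    collapsed stock (biomass 0) does not abort the run: TACs shrink toward
    zero and the simulation logs a warning.
    """
    params = config.params
    state = StockState(x=config.initial_biomass, t=0.0)
    tac = config.tac0
    seeds = np.random.SeedSequence(config.seed).generate_state(config.horizon)

    annual: list[AnnualImpacts] = []
    tacs: list[float] = []
    biomass: list[float] = [state.x]
    all_records: list[TripRecord] = []

    for year in range(config.horizon):
        if state.x == 0.0:
            logger.warning("stock collapsed at start of year %d", year)
        ledger = allocate_quota(tac, config.q, fishing_year=year)
        withdrawals: list[tuple[float, float]] = []
        records = run_fishing_year(
            config.fleet,
            ledger,
            withdrawal_sink=lambda t, c: withdrawals.append((t, c)),
            seed=int(seeds[year]),
            year_start=float(year),
            year_length=1.0,
        )
        state = step_biomass(state, params, dt=1.0, withdrawals=withdrawals)
        annual.append(
            aggregate_annual(records, config.fleet, config.factors, year=year)
        )
        tacs.append(tac)
        biomass.append(state.x)
        all_records.extend(records)
        tac = compute_tac(state.x, tac, params.a)

    return ScenarioResult(
        q=config.q,
        annual=tuple(annual),
        tac_by_year=tuple(tacs),
        biomass_by_year=tuple(biomass),
        trip_records=tuple(all_records),
    )


def sweep_q(
    q_grid: Sequence[float], base_config: ScenarioConfig
) -> list[ScenarioResult]:
    """One independent scenario per q, identical seed and initial conditions."""
    if len(q_grid) == 0:
        raise ValueError("q grid must be non-empty")
    return [run_scenario(replace(base_config, q=float(q))) for q in q_grid]


def default_q_grid(step: float = 0.05) -> np.ndarray:
    n = round(1.0 / step)
    return np.linspace(0.0, 1.0, n + 1)


def normalize(results: Sequence[ScenarioResult]) -> NormalizedScores:
    """Score each category as a proportion of the best outcome on the grid.

    Profit and jobs are higher-is-better: score = value / max.  CO2 is
    lower-is-better: score = min / value, so the cleanest allocation scores 1.
    If no q yields positive profit the ratio is meaningless and an affine
    min-max rescaling is used instead, flagged on the output.
    """
    if len(results) == 0:
        raise ValueError("need at least one scenario result")
    qs = tuple(r.q for r in results)
    profit = np.array([r.total_profit for r in results], dtype=float)
    co2 = np.array([r.total_co2_kg for r in results], dtype=float)
    jobs = np.array([r.total_jobs_years for r in results], dtype=float)
    if np.any(co2 <= 0):
        raise ValueError("CO2 totals must be positive to normalise")

    affine = False
    if profit.max() > 0:
        econ = profit / profit.max()
    else:
        affine = True
        span = profit.max() - profit.min()
        econ = (profit - profit.min()) / span if span > 0 else np.ones_like(profit)
        logger.warning(
            "no positive profit on the grid; economic scores use min-max rescaling"
        )
    env = co2.min() / co2
    social = jobs / jobs.max() if jobs.max() > 0 else np.ones_like(jobs)

    return NormalizedScores(
        q=qs,
        economic=tuple(econ),
        environmental=tuple(env),
        social=tuple(social),
        economic_affine=affine,
    )


def find_crossover(scores: NormalizedScores) -> list[float]:
    """q values where the economic and environmental curves intersect.

    The two score curves are treated as piecewise linear over the q grid;
    every sign change of their difference yields one interpolated crossing.
    Returns an empty list when the curves do not cross.
    """
    q = np.asarray(scores.q, dtype=float)
    if len(q) < 2:
        raise ValueError("need at least two grid points")
    order = np.argsort(q)
    q = q[order]
    d = (
        np.asarray(scores.economic, dtype=float)
        - np.asarray(scores.environmental, dtype=float)
    )[order]

    crossings: list[float] = []
    for i in range(len(q) - 1):
        d0, d1 = d[i], d[i + 1]
        if d0 == 0.0:
            crossings.append(float(q[i]))
        elif d0 * d1 < 0:
            crossings.append(float(q[i] + (q[i + 1] - q[i]) * d0 / (d0 - d1)))
    if len(d) and d[-1] == 0.0:
        crossings.append(float(q[-1]))
    # dedupe while preserving order
    out: list[float] = []
    for c in crossings:
        if not out or abs(c - out[-1]) > 1e-12:
            out.append(c)
    return out


@dataclass(frozen=True)
class PlaybackResult:
    """Stock trajectory under a forced catch history."""

    year: np.ndarray
    biomass_sim_kt: np.ndarray  # biomass at each year start
    catch_applied_kt: np.ndarray
    clamped_years: tuple[int, ...]  # years where forced catch exceeded stock

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "biomass_sim_kt": self.biomass_sim_kt,
                "catch_applied_kt": self.catch_applied_kt,
            }
        )


def playback_validation(
    catches: AssessmentSeries | Sequence[float],
    params: StockParameters,
    x0: Optional[float] = None,
    mode: str = "discrete",
) -> PlaybackResult:
    """Force a catch history through the stock model, bypassing the HCR.

    ``catches`` may be an assessment series (its catch column is used, and its
    first biomass value is the default starting stock) or a bare catch
    sequence (then ``x0`` is required).  ``mode='discrete'`` iterates the
    annual logistic map — the same map the synthetic generator uses, so a
    noiseless generated series replays exactly; ``mode='continuous'``
    integrates the growth ODE with each year's catch as a mid-year impulse.
    A forced catch larger than the available stock is clamped and the year
    recorded.
    """
    if mode not in ("discrete", "continuous"):
        raise ValueError(f"unknown playback mode {mode!r}")
    if isinstance(catches, AssessmentSeries):
        catch_arr = np.asarray(catches.catch_kt, dtype=float)
        years = np.asarray(catches.year, dtype=int)
        if x0 is None:
            x0 = float(catches.biomass_kt[0])
    else:
        catch_arr = np.asarray(catches, dtype=float)
        years = np.arange(len(catch_arr))
        if x0 is None:
            raise ValueError("x0 required when catches is a bare sequence")
    if x0 <= 0:
        raise ValueError("initial biomass must be positive")

    n = len(catch_arr)
    biomass = np.empty(n)
    applied = np.empty(n)
    clamped: list[int] = []
    x = float(x0)
    for i in range(n):
        biomass[i] = x
        c = catch_arr[i]
        if mode == "discrete":
            grown = x + growth_rate(x, params)
            if c > grown:
                logger.warning(
                    "forced catch %.3f kt exceeds available stock %.3f kt in "
                    "year %d; clamped",
                    c,
                    grown,
                    int(years[i]),
                )
                clamped.append(int(years[i]))
                c = grown
            x = grown - c
        else:
            mid = step_biomass(StockState(x=x, t=0.0), params, dt=0.5).x
            if c > mid:
                logger.warning(
                    "forced catch %.3f kt exceeds available stock %.3f kt in "
                    "year %d; clamped",
                    c,
                    mid,
                    int(years[i]),
                )
                clamped.append(int(years[i]))
                c = mid
            x = step_biomass(StockState(x=mid - c, t=0.5), params, dt=0.5).x
        applied[i] = c

    return PlaybackResult(
        year=years,
        biomass_sim_kt=biomass,
        catch_applied_kt=applied,
        clamped_years=tuple(clamped),
    )


def sweep_frame(
    results: Sequence[ScenarioResult], scores: NormalizedScores
) -> pd.DataFrame:
    """Per-q sweep table with raw totals and normalized scores."""
    return pd.DataFrame(
        {
            "q": [r.q for r in results],
            "total_catch_kt": [r.total_catch_kt for r in results],
            "total_profit": [r.total_profit for r in results],
            "total_co2_kg": [r.total_co2_kg for r in results],
            "total_jobs_years": [r.total_jobs_years for r in results],
            "final_biomass_kt": [r.final_biomass for r in results],
            "score_economic": list(scores.economic),
            "score_environmental": list(scores.environmental),
            "score_social": list(scores.social),
        }
    )
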