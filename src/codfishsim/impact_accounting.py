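"""Economic, environmental and social accounting of fishing activity.

Converts trip records into the three sustainability dimensions:

* profit = fish value (per kg) x landed catch (kg) x PR, where PR is the
  vessel class's net-profit-to-revenue ratio;
* CO2-equivalents from gear-specific life-cycle factors applied per kg of
  landed cod — defaults 5.14 kg CO2-eq/kg for bottom-trawled and 1.58 for
  longlined fish;
* jobs as the summed crew of every vessel that completed at least one trip
  in the year (onshore jobs such as baiting are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fleet_des import Fleet, Gear, TripRecord

#: thousand tonnes -> kilograms
KG_PER_KT = 1.0e6

DEFAULT_CO2_PER_KG: dict[Gear, float] = {
    Gear.BOTTOM_TRAWL: 5.14,
    Gear.LONGLINE: 1.58,
}


@dataclass(frozen=True)
class ImpactFactors:
    """Gear-resolved emission intensities, kg CO2-eq per kg of landed cod."""

    co2_per_kg: Mapping[Gear, float] = field(
        default_factory=lambda: dict(DEFAULT_CO2_PER_KG)
    )

    def __post_init__(self) -> None:
        for gear, f in self.co2_per_kg.items():
            if f <= 0:
                raise ValueError(f"CO2 factor for {gear} must be positive")


@dataclass(frozen=True)
class AnnualImpacts:
    """Per-gear and total impacts of one fishing year.

    catch in kt, profit in currency units, co2 in kg CO2-eq, jobs in persons.
    Totals are exact sums over gears; profit may be negative.
    """

    year: int
    catch_kt: Mapping[Gear, float]
    profit: Mapping[Gear, float]
    co2_kg: Mapping[Gear, float]
    jobs: Mapping[Gear, int]

    @property
    def total_catch_kt(self) -> float:
        return sum(self.catch_kt.values())

    @property
    def total_profit(self) -> float:
        return sum(self.profit.values())

    @property
    def total_co2_kg(self) -> float:
        return sum(self.co2_kg.values())

    @property
    def total_jobs(self) -> int:
        return sum(self.jobs.values())


def profit_of(catch_kt: float, fish_value_per_kg: float, pr: float) -> float:
    """Profit = value-of-fish x catch x PR, catch converted from kt to kg."""
    if catch_kt < 0:
        raise ValueError("catch must be non-negative")
    return fish_value_per_kg * catch_kt * KG_PER_KT * pr


def co2_of(catch_kt: float, gear: Gear, factors: ImpactFactors | None = None) -> float:
    """CO2-equivalents (kg) of a landed catch with the gear's LCA factor."""
    if catch_kt < 0:
        raise ValueError("catch must be non-negative")
    factors = factors or ImpactFactors()
    try:
        per_kg = factors.co2_per_kg[gear]
    except KeyError:
        raise KeyError(f"no CO2 factor configured for gear {gear!r}") from None
    return catch_kt * KG_PER_KT * per_kg


def jobs_of(fleet: Fleet, records: Sequence[TripRecord]) -> int:
    """Jobs on board: summed crew of vessels with >= 1 completed trip.

    A vessel that never left port contributes no jobs that year.
    """
    active: dict[int, str] = {}
    for rec in records:
        active.setdefault(rec.vessel_id, rec.vessel_class)
    return sum(fleet.class_by_name(name).crew_jobs for name in active.values())


def aggregate_annual(
    records: Sequence[TripRecord],
    fleet: Fleet,
    factors: ImpactFactors | None = None,
    year: int | None = None,
) -> AnnualImpacts:
    """Roll one year's trip records up into per-gear impact sums."""
    factors = factors or ImpactFactors()
    years = {r.year for r in records}
    if len(years) > 1:
        raise ValueError(f"records span multiple years: {sorted(years)}")
    if year is None:
        year = years.pop() if years else 0

    catch = {g: 0.0 for g in Gear}
    profit = {g: 0.0 for g in Gear}
    co2 = {g: 0.0 for g in Gear}
    active_by_gear: dict[Gear, dict[int, str]] = {g: {} for g in Gear}

    for rec in records:
        cls = fleet.class_by_name(rec.vessel_class)
        catch[rec.gear] += rec.catch_kt
        profit[rec.gear] += profit_of(
            rec.catch_kt, cls.fish_value_per_kg, cls.profit_ratio
        )
        co2[rec.gear] += co2_of(rec.catch_kt, rec.gear, factors)
        active_by_gear[rec.gear].setdefault(rec.vessel_id, rec.vessel_class)

    jobs = {
        g: sum(fleet.class_by_name(name).crew_jobs for name in vs.values())
        for g, vs in active_by_gear.items()
    }
    return AnnualImpacts(year=year, catch_kt=catch, profit=profit, co2_kg=co2, jobs=jobs)


def impacts_frame(impacts: Iterable[AnnualImpacts]) -> pd.DataFrame:
    """Long-format annual impact table: one row per (year, gear)."""
    rows = []
    for imp in impacts:
        for g in Gear:
            rows.append(
                {
                    "year": imp.year,
                    "gear": g.value,
                    "catch_kt": imp.catch_kt[g],
                    "profit": imp.profit[g],
                    "co2_kg": imp.co2_kg[g],
                    "jobs": imp.jobs[g],
                }
            )
    return pd.DataFrame(
        rows, columns=["year", "gear", "catch_kt", "profit", "co2_kg", "jobs"]
    )


def write_impacts(impacts: Iterable[AnnualImpacts], path: str | Path) -> None:
    impacts_frame(impacts).to_csv(path, index=False)
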