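"""Discrete-event submodel of fishing trips drawing on a gear-split quota.

The fleet consists of vessel classes using one of two gears — bottom trawl or
longline — each with a per-trip catch capacity, a trip duration (fixed or
sampled), a port turnaround, a crew size, and per-kg economics.  The annual
TAC is split between the gears by the allocation fraction ``q`` (trawl share)
and held in a :class:`QuotaLedger`.

Vessels alternate trips and turnarounds.  Before every departure the vessel
queries the ledger; quota is *reserved at departure*, so the per-gear landings
can never overshoot the allocation, and the final trip of a gear may be
partial so that the allocation is met exactly — the model's standing
assumption is that the fleet always takes its full quota when it has the
capacity to do so.  The event queue is a simple time-ordered heap with a
stable tie-break, so a fully deterministic configuration yields a
hand-checkable schedule.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.0


class Gear(str, Enum):
    BOTTOM_TRAWL = "bottom_trawl"
    LONGLINE = "longline"


@dataclass(frozen=True)
class TripDurationSpec:
    """Trip duration in days: fixed, uniform(days±spread) or lognormal.

    ``kind='fixed'`` ignores ``spread_days``; ``'uniform'`` samples from
    [days - spread, days + spread]; ``'lognormal'`` samples with median
    ``days`` and log-sd ``spread_days`` (interpreted as a relative sd).
    """

    kind: str = "fixed"
    days: float = 1.0
    spread_days: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "uniform", "lognormal"):
            raise ValueError(f"unknown duration kind {self.kind!r}")
        if self.days <= 0:
            raise ValueError("trip duration must be positive")
        if self.spread_days < 0:
            raise ValueError("duration spread must be non-negative")

    @property
    def stochastic(self) -> bool:
        return self.kind != "fixed" and self.spread_days > 0

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed" or self.spread_days == 0:
            return self.days
        if self.kind == "uniform":
            lo = max(self.days - self.spread_days, 1e-6)
            return float(rng.uniform(lo, self.days + self.spread_days))
        return float(self.days * rng.lognormal(0.0, self.spread_days / self.days))


@dataclass(frozen=True)
class VesselClass:
    """One class of fishing vessel.

    catch_per_trip is in thousand tonnes; fish_value is currency per kg of
    landed catch; profit_ratio is net profit over net revenue (may be
    negative for structurally unprofitable classes).
    """

    name: str
    gear: Gear
    catch_per_trip: float
    trip_duration: TripDurationSpec
    turnaround_days: float
    crew_jobs: int
    fish_value_per_kg: float
    profit_ratio: float

    def __post_init__(self) -> None:
        if self.catch_per_trip <= 0:
            raise ValueError("catch_per_trip must be positive")
        if self.turnaround_days < 0:
            raise ValueError("turnaround must be non-negative")
        if self.crew_jobs < 0:
            raise ValueError("crew_jobs must be non-negative")

    def trips_per_year(self) -> int:
        """Trips a vessel can complete in one year at the mean cycle length."""
        cycle = self.trip_duration.days + self.turnaround_days
        # last trip needs only the trip itself to fit before year end
        return int((DAYS_PER_YEAR - self.trip_duration.days) // cycle) + 1


@dataclass(frozen=True)
class Fleet:
    """Vessel classes with their counts."""

    units: tuple[tuple[VesselClass, int], ...]

    def __post_init__(self) -> None:
        for cls, count in self.units:
            if count < 0:
                raise ValueError(f"vessel count for {cls.name} must be >= 0")

    def vessels(self) -> list[tuple[int, VesselClass]]:
        """Expand to individual vessels as (vessel_id, class), deterministic order."""
        out = []
        vid = 0
        for cls, count in self.units:
            for _ in range(count):
                out.append((vid, cls))
                vid += 1
        return out

    def class_by_name(self, name: str) -> VesselClass:
        for cls, _ in self.units:
            if cls.name == name:
                return cls
        raise KeyError(name)

    def annual_capacity(self) -> dict[Gear, float]:
        """Upper bound on annual landings per gear, kt (mean durations)."""
        cap: dict[Gear, float] = {g: 0.0 for g in Gear}
        for cls, count in self.units:
            cap[cls.gear] += count * cls.trips_per_year() * cls.catch_per_trip
        return cap


@dataclass
class QuotaLedger:
    """Per-gear allocated and remaining quota (kt) for one fishing year.

    This is the contract between the biological model (which sets the TAC)
    and the event model (which draws trips against it).
    """

    fishing_year: int
    allocated: dict[Gear, float]
    remaining: dict[Gear, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.remaining:
            self.remaining = dict(self.allocated)
        for g, alloc in self.allocated.items():
            if alloc < 0:
                raise ValueError("allocated quota must be non-negative")
            if not 0 <= self.remaining[g] <= alloc + 1e-12:
                raise ValueError("remaining quota outside [0, allocated]")


@dataclass(frozen=True)
class TripRecord:
    """One completed fishing trip."""

    year: int
    vessel_class: str
    gear: Gear
    vessel_id: int
    departure: float  # years, absolute simulation time
    landing: float  # years
    catch_kt: float


def allocate_quota(tac: float, q: float, fishing_year: int = 0) -> QuotaLedger:
    """Split a year's TAC: fraction ``q`` to bottom trawl, 1-q to longline."""
    if not 0 <= q <= 1:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if tac < 0:
        raise ValueError("TAC must be non-negative")
    return QuotaLedger(
        fishing_year=fishing_year,
        allocated={Gear.BOTTOM_TRAWL: q * tac, Gear.LONGLINE: (1.0 - q) * tac},
    )


def request_trip(vessel: VesselClass, ledger: QuotaLedger) -> Optional[float]:
    """Pre-departure quota query.

    Returns the granted catch, min(catch_per_trip, remaining quota for the
    vessel's gear), reserving it in the ledger; returns None (denial) when the
    gear's quota is exhausted.  The final grant of a year may therefore be a
    partial trip, which is what lets the fleet meet its allocation exactly.
    """
    rem = ledger.remaining.get(vessel.gear, 0.0)
    if rem <= 0.0:
        return None
    grant = min(vessel.catch_per_trip, rem)
    ledger.remaining[vessel.gear] = rem - grant
    return grant


def run_fishing_year(
    fleet: Fleet,
    ledger: QuotaLedger,
    withdrawal_sink: Optional[Callable[[float, float], None]] = None,
    seed: Optional[int] = None,
    year_start: float = 0.0,
    year_length: float = 1.0,
) -> list[TripRecord]:
    """Simulate one fishing year of trips for the whole fleet.

    Every vessel starts in port at ``year_start`` and cycles
    request -> trip -> turnaround.  A denial retires the vessel until next
    year.  A trip departs only if it can land before the year ends; otherwise
    the reservation is returned and the vessel idles out the year.  Landed
    catch is pushed to ``withdrawal_sink(landing_time, catch_kt)`` so the
    biological model can subtract it at the right instant.
    """
    year_end = year_start + year_length
    rng = np.random.default_rng(seed)
    records: list[TripRecord] = []
    counter = itertools.count()

    heap: list[tuple[float, int, int, VesselClass]] = []
    for vid, cls in fleet.vessels():
        heapq.heappush(heap, (year_start, next(counter), vid, cls))

    while heap:
        t, _, vid, cls = heapq.heappop(heap)
        if t >= year_end:
            continue
        grant = request_trip(cls, ledger)
        if grant is None:
            continue  # quota exhausted: no further trips this year
        duration = cls.trip_duration.sample(rng) / DAYS_PER_YEAR
        landing = t + duration
        if landing > year_end:
            # trip cannot complete this year: undo the reservation
            ledger.remaining[cls.gear] += grant
            continue
        records.append(
            TripRecord(
                year=ledger.fishing_year,
                vessel_class=cls.name,
                gear=cls.gear,
                vessel_id=vid,
                departure=t,
                landing=landing,
                catch_kt=grant,
            )
        )
        if withdrawal_sink is not None:
            withdrawal_sink(landing, grant)
        next_ready = landing + cls.turnaround_days / DAYS_PER_YEAR
        heapq.heappush(heap, (next_ready, next(counter), vid, cls))

    return records


def trip_log_frame(records: Iterable[TripRecord]) -> pd.DataFrame:
    """Trip log with the canonical CSV schema."""
    return pd.DataFrame(
        [
            {
                "year": r.year,
                "vessel_class": r.vessel_class,
                "gear": r.gear.value,
                "departure": r.departure,
                "landing": r.landing,
                "catch_kt": r.catch_kt,
            }
            for r in records
        ],
        columns=["year", "vessel_class", "gear", "departure", "landing", "catch_kt"],
    )


def write_trip_log(records: Iterable[TripRecord], path: str | Path) -> None:
    trip_log_frame(records).to_csv(path, index=False)
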