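import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from codfishsim import (  # noqa: E402
    Fleet,
    Gear,
    ImpactFactors,
    StockParameters,
    TripDurationSpec,
    VesselClass,
)


@pytest.fixture
def default_params() -> StockParameters:
    """Default stock parameters: the regression estimates with a = 0.2."""
    return StockParameters()


@pytest.fixture
def default_factors() -> ImpactFactors:
    return ImpactFactors()


def make_vessel(
    name: str = "v",
    gear: Gear = Gear.BOTTOM_TRAWL,
    catch_per_trip: float = 10.0,
    trip_days: float = 5.0,
    turnaround_days: float = 2.0,
    crew: int = 10,
    value: float = 100.0,
    pr: float = 0.1,
    duration_kind: str = "fixed",
    spread: float = 0.0,
) -> VesselClass:
    return VesselClass(
        name=name,
        gear=gear,
        catch_per_trip=catch_per_trip,
        trip_duration=TripDurationSpec(
            kind=duration_kind, days=trip_days, spread_days=spread
        ),
        turnaround_days=turnaround_days,
        crew_jobs=crew,
        fish_value_per_kg=value,
        profit_ratio=pr,
    )


@pytest.fixture
def two_gear_fleet() -> Fleet:
    """One trawler class and one longliner class, fixed durations."""
    trawler = make_vessel(
        "trawler", Gear.BOTTOM_TRAWL, catch_per_trip=10.0, crew=15, value=300.0, pr=0.25
    )
    longliner = make_vessel(
        "longliner",
        Gear.LONGLINE,
        catch_per_trip=4.0,
        trip_days=3.0,
        turnaround_days=1.0,
        crew=12,
        value=320.0,
        pr=0.18,
    )
    return Fleet(units=((trawler, 3), (longliner, 4)))
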