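"""Continuous biological submodel of the cod stock.

The stock is described by an unstructured logistic (Schaefer surplus-production)
model

    dx/dt = r * x * (1 - x / K)

with ``x`` the fishable biomass in thousand tonnes (kt), ``r`` the intrinsic
growth rate (1/yr) and ``K`` the carrying capacity (kt).  Management acts
through a harvest control rule that averages a fixed harvest rate ``a`` of the
current fishable biomass with last year's total allowable catch:

    TAC_{y+1} = (a * B_y + TAC_y) / 2

Fishing itself is event-driven: landed catches arrive as instantaneous
withdrawals at their landing times, between which the growth equation is
integrated with a fixed-step RK4 scheme.

The module also estimates (r, K) from an annual assessment series by the
standard per-capita surplus-production regression: with surplus
S_t = x_{t+1} - x_t + C_t, regress S_t / x_t on x_t; the intercept estimates
r and the slope estimates -r/K.
"""

from __future__ import annotations

import logging
import math
import warnings as _warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: internal RK4 step, years (one day)
DT_INTERNAL = 1.0 / 365.0


class DegenerateSeriesError(ValueError):
    """Raised when an assessment series cannot support the regression."""


class InvalidFitWarning(UserWarning):
    """Emitted when the fitted slope is non-negative (implies K_hat <= 0)."""


@dataclass(frozen=True)
class StockParameters:
    """Biological and management constants of the stock model.

    Parameters
    ----------
    r : intrinsic growth rate, 1/yr (default: regression estimate 0.47)
    K : carrying capacity, thousand tonnes (default: regression estimate 2654.44)
    a : target harvest rate of the control rule, dimensionless (default 0.2)
    """

    r: float = 0.47
    K: float = 2654.44
    a: float = 0.2

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if not self.K > 0:
            raise ValueError(f"K must be positive, got {self.K}")
        if not 0 <= self.a < 1:
            raise ValueError(f"a must lie in [0, 1), got {self.a}")


@dataclass(frozen=True)
class StockState:
    """Fishable biomass ``x`` (kt) at simulation time ``t`` (years)."""

    x: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError(f"biomass must be non-negative, got {self.x}")


@dataclass(frozen=True)
class HarvestControlState:
    """Current TAC (kt/fishing-year) and the fishing-year index."""

    tac_current: float
    fishing_year: int = 0

    def __post_init__(self) -> None:
        if self.tac_current < 0:
            raise ValueError("TAC must be non-negative")


@dataclass(frozen=True)
class LogisticFit:
    """Result of the surplus-production regression.

    ``valid`` is False when the slope came out non-negative, which implies a
    non-positive carrying capacity; the estimates are still reported.
    """

    r_hat: float
    K_hat: float
    t_r: float
    t_K: float
    n: int
    valid: bool = True


class AssessmentSeries:
    """Ordered annual records of (year, fishable biomass, catch), in kt.

    Thin wrapper over three aligned numpy arrays with the validation the
    fitting routine relies on: consecutive years, finite values.
    """

    def __init__(
        self,
        year: Sequence[int],
        biomass_kt: Sequence[float],
        catch_kt: Sequence[float],
    ) -> None:
        self.year = np.asarray(year, dtype=int)
        self.biomass_kt = np.asarray(biomass_kt, dtype=float)
        self.catch_kt = np.asarray(catch_kt, dtype=float)
        if not (len(self.year) == len(self.biomass_kt) == len(self.catch_kt)):
            raise ValueError("year, biomass and catch must have equal length")
        if len(self.year) >= 2 and not np.all(np.diff(self.year) == 1):
            raise ValueError("years must increase strictly by 1")
        if not np.all(np.isfinite(self.biomass_kt)) or not np.all(
            np.isfinite(self.catch_kt)
        ):
            raise ValueError("biomass and catch must be finite")

    def __len__(self) -> int:
        return len(self.year)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "biomass_kt": self.biomass_kt,
                "catch_kt": self.catch_kt,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AssessmentSeries":
        df = pd.read_csv(path)
        missing = {"year", "biomass_kt", "catch_kt"} - set(df.columns)
        if missing:
            raise ValueError(f"CSV missing columns: {sorted(missing)}")
        return cls(df["year"], df["biomass_kt"], df["catch_kt"])


def growth_rate(x: float, params: StockParameters) -> float:
    """Instantaneous biomass production r*x*(1 - x/K), kt/yr.

    Zero at x = 0 and x = K, maximal (rK/4) at x = K/2.
    """
    if x < 0:
        raise ValueError(f"biomass must be non-negative, got {x}")
    return params.r * x * (1.0 - x / params.K)


def _rk4_segment(x: float, duration: float, params: StockParameters, h: float) -> float:
    """Integrate the unfished logistic ODE over ``duration`` years from ``x``."""
    if duration <= 0:
        return x
    r, K = params.r, params.K

    def f(v: float) -> float:
        return r * v * (1.0 - v / K)

    n = max(1, math.ceil(duration / h))
    hh = duration / n
    for _ in range(n):
        k1 = f(x)
        k2 = f(x + 0.5 * hh * k1)
        k3 = f(x + 0.5 * hh * k2)
        k4 = f(x + hh * k3)
        x += (hh / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if x < 0.0:
            x = 0.0
    return x


def step_biomass(
    state: StockState,
    params: StockParameters,
    dt: float,
    withdrawals: Iterable[tuple[float, float]] = (),
    dt_internal: float = DT_INTERNAL,
) -> StockState:
    """Advance the stock by ``dt`` years, applying catch withdrawals as impulses.

    ``withdrawals`` is an iterable of ``(time, catch_kt)`` with times inside
    ``[state.t, state.t + dt]``; each catch is subtracted instantaneously at
    its event time, with logistic growth integrated (RK4, step ``dt_internal``)
    between events.  A withdrawal exceeding the current biomass clamps the
    stock to zero and logs a warning (an overharvest signal), it does not
    raise.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    t0, t1 = state.t, state.t + dt
    events = sorted(withdrawals, key=lambda ev: ev[0])
    for tw, _ in events:
        if tw < t0 - 1e-12 or tw > t1 + 1e-12:
            raise ValueError(f"withdrawal time {tw} outside [{t0}, {t1}]")

    x = state.x
    t = t0
    for tw, catch in events:
        if catch < 0:
            raise ValueError("withdrawal catch must be non-negative")
        x = _rk4_segment(x, tw - t, params, dt_internal)
        t = tw
        if catch > x:
            logger.warning(
                "withdrawal of %.4f kt exceeds biomass %.4f kt at t=%.4f; "
                "stock clamped to zero",
                catch,
                x,
                t,
            )
            x = 0.0
        else:
            x -= catch
    x = _rk4_segment(x, t1 - t, params, dt_internal)
    return StockState(x=max(x, 0.0), t=t1)


def logistic_closed_form(x0: float, t: float, params: StockParameters) -> float:
    """Analytic unfished solution x(t) = K / (1 + ((K - x0)/x0) e^{-rt})."""
    if x0 <= 0:
        return 0.0
    return params.K / (1.0 + ((params.K - x0) / x0) * math.exp(-params.r * t))


def compute_tac(biomass: float, tac_prev: float, a: float) -> float:
    """Harvest control rule: TAC_{y+1} = (a * B + TAC_y) / 2.

    At fixed biomass, repeated application converges geometrically (ratio 1/2)
    to the fixed point a * B.
    """
    if biomass < 0:
        raise ValueError("biomass must be non-negative")
    if tac_prev < 0:
        raise ValueError("previous TAC must be non-negative")
    return (a * biomass + tac_prev) / 2.0


def equilibrium(params: StockParameters) -> tuple[float, float]:
    """Joint fixed point of the growth equation and the control rule.

    With full quota uptake the harvest removes a*B per year, so at equilibrium
    production r*B*(1 - B/K) = a*B, giving B* = K (1 - a/r) and TAC* = a B*.
    If the harvest rate meets or exceeds the growth rate the stock collapses:
    both are 0.
    """
    if params.a >= params.r:
        return 0.0, 0.0
    b_star = params.K * (1.0 - params.a / params.r)
    return b_star, params.a * b_star


def fit_logistic(series: AssessmentSeries) -> LogisticFit:
    """Estimate (r, K) from an assessment series by linear regression.

    Annual surplus production S_t = x_{t+1} - x_t + C_t is divided by x_t and
    regressed on x_t with OLS:

        S_t / x_t = r - (r/K) x_t + eps_t

    so r_hat is the intercept and K_hat = -intercept/slope.  t-statistics are
    the coefficient estimates over their OLS standard errors; the t-statistic
    of K_hat comes from the delta method on the coefficient covariance.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 annual points to fit")
    x = series.biomass_kt[:-1]
    x_next = series.biomass_kt[1:]
    catch = series.catch_kt[:-1]
    if np.any(series.biomass_kt <= 0):
        raise ValueError("all biomass values must be positive for fitting")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError(
            "biomass series is constant; the regressor has zero variance"
        )

    surplus_pc = (x_next - x + catch) / x
    design = sm.add_constant(x)
    res = sm.OLS(surplus_pc, design).fit()
    b0, b1 = res.params
    t0, t1 = res.tvalues
    cov = res.cov_params()

    valid = b1 < 0
    if not valid:
        _warnings.warn(
            "fitted slope is non-negative, implying non-positive carrying "
            "capacity; estimates returned but flagged invalid",
            InvalidFitWarning,
            stacklevel=2,
        )
    k_hat = -b0 / b1 if b1 != 0 else math.inf

    # delta method for K_hat = -b0/b1: grad = (-1/b1, b0/b1^2)
    if b1 != 0 and math.isfinite(k_hat):
        g = np.array([-1.0 / b1, b0 / b1**2])
        var_k = float(g @ cov @ g)
        t_k = k_hat / math.sqrt(var_k) if var_k > 0 else math.nan
    else:
        t_k = math.nan

    return LogisticFit(
        r_hat=float(b0),
        K_hat=float(k_hat),
        t_r=float(t0),
        t_K=float(t_k),
        n=len(x),
        valid=valid,
    )


def fit_report_frame(fit: LogisticFit) -> pd.DataFrame:
    """Tabular fit report: one row per parameter with estimate and t-statistic."""
    return pd.DataFrame(
        {
            "parameter": ["r", "K"],
            "estimate": [fit.r_hat, fit.K_hat],
            "t_statistic": [fit.t_r, fit.t_K],
        }
    )
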