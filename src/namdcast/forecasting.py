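"""Weekly demand forecasting with additive decomposition and Holt-Winters.

The historical series is weekly counts of treatment-naive patients starting
anti-VEGF therapy at one centre.  The model is classical additive
exponential smoothing with level, trend and a length-``m`` seasonal cycle
(``m`` = 52 weeks by default, one annual cycle of a weekly series):

    l_t = alpha*(y_t - s_{t-m}) + (1-alpha)*(l_{t-1} + b_{t-1})
    b_t = beta*(l_t - l_{t-1}) + (1-beta)*b_{t-1}
    s_t = gamma*(y_t - l_t) + (1-gamma)*s_{t-m}

The h-step point forecast is ``l + h*b + s`` with the matching seasonal
index, truncated at zero because counts cannot be negative; 95% intervals
use the Gaussian one-step residual sd scaled by sqrt(h).

Initial state comes from the additive decomposition of the first two
seasonal cycles: the seasonal indices directly, and level/trend from a
least-squares line through the first cycle's centred-moving-average trend.
On a noiseless trend-plus-seasonal series this initialisation is exact, so
one-step and h-step forecasts reproduce the generating closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.tsa.seasonal import seasonal_decompose

from namdcast import _weeks

Week = _weeks.Week

Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class WeeklySeries:
    """Contiguous weekly count series for one centre."""

    centre: str
    weeks: tuple[Week, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "weeks", tuple(tuple(w) for w in self.weeks))
        if len(self.weeks) != len(counts):
            raise ValueError("weeks and counts differ in length")
        if len(self.weeks) >= 2 and not _weeks.is_contiguous(list(self.weeks)):
            raise ValueError(f"weekly series for {self.centre} is not contiguous")
        if (counts < 0).any():
            raise ValueError("weekly counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, centre: str) -> "WeeklySeries":
        """Build from a (centre, iso_year, iso_week, count) table."""
        sub = frame[frame["centre"] == centre]
        if len(sub) == 0:
            raise ValueError(f"no weekly counts for centre {centre!r}")
        sub = sub.sort_values(["iso_year", "iso_week"])
        weeks = tuple(zip(sub["iso_year"].astype(int), sub["iso_week"].astype(int)))
        return cls(centre=centre, weeks=weeks, counts=sub["count"].to_numpy(float))


@dataclass(frozen=True)
class Decomposition:
    """Additive trend/seasonal/random components; trend (and hence random)
    is NaN in the half-window at each end of the series."""

    trend: np.ndarray
    seasonal: np.ndarray
    random: np.ndarray


@dataclass(frozen=True)
class HoltWintersState:
    """Fitted additive Holt-Winters state at the forecast origin.

    ``seasonal[j]`` is the index for observation times t with t % m == j;
    ``n_obs`` is the number of fitted observations, so the forecast for
    horizon step h uses ``seasonal[(n_obs - 1 + h) % m]``.
    """

    m: int
    level: float
    trend: float
    seasonal: np.ndarray
    alpha: float
    beta: float
    gamma: float
    sigma: float
    n_obs: int
    last_week: Week
    sse: float = field(default=float("nan"))

    def __post_init__(self):
        for name, v in (("alpha", self.alpha), ("beta", self.beta), ("gamma", self.gamma)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if len(self.seasonal) != self.m:
            raise ValueError("seasonal index length must equal the period")


@dataclass(frozen=True)
class Forecast:
    """Point forecasts with 95% intervals over a contiguous horizon.

    ``total`` is the rounded sum of the unrounded weekly points (never a sum
    of rounded points, to avoid accumulating rounding bias).
    """

    centre: str
    table: pd.DataFrame  # iso_year, iso_week, point, lo95, hi95
    total: int


def _require_length(series: WeeklySeries, m: int) -> None:
    if m < 1:
        raise ValueError(f"seasonal period must be positive, got {m}")
    if len(series) < 2 * m:
        raise ValueError(
            f"series for {series.centre} has {len(series)} weeks; "
            f"need at least 2*m = {2 * m}"
        )


def decompose_additive(series: WeeklySeries, m: int) -> Decomposition:
    """Classical additive decomposition: centred moving-average trend,
    period-averaged detrended seasonal re-centred to sum zero, and the
    residual random component."""
    _require_length(series, m)
    res = seasonal_decompose(series.counts, model="additive", period=m, two_sided=True)
    return Decomposition(
        trend=np.asarray(res.trend, dtype=float),
        seasonal=np.asarray(res.seasonal, dtype=float),
        random=np.asarray(res.resid, dtype=float),
    )


def _initial_state(series: WeeklySeries, m: int) -> tuple[float, float, np.ndarray]:
    """Level/trend/seasonal state holding just before the first observation.

    Seasonal indices come from decomposing the first two cycles; level and
    trend from a least-squares line through the first cycle's trend
    component, evaluated at t = -1.
    """
    head = WeeklySeries(series.centre, series.weeks[: 2 * m], series.counts[: 2 * m])
    dec = decompose_additive(head, m)
    seasonal = np.empty(m)
    for j in range(m):
        seasonal[j] = np.nanmean(dec.seasonal[j::m][:2])
    seasonal -= seasonal.mean()

    t = np.arange(2 * m, dtype=float)
    in_first_cycle = (t < m) & ~np.isnan(dec.trend)
    tt, yy = t[in_first_cycle], dec.trend[in_first_cycle]
    slope, intercept = np.polyfit(tt, yy, 1)
    level0 = intercept - slope  # line evaluated at t = -1
    return level0, slope, seasonal


def _run_recursions(
    y: np.ndarray,
    m: int,
    level0: float,
    trend0: float,
    seasonal0: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Apply the smoothing recursions; returns final state and one-step
    residuals."""
    level, trend = level0, trend0
    seasonal = seasonal0.copy()
    resid = np.empty(len(y))
    for t, yt in enumerate(y):
        s_old = seasonal[t % m]
        pred = level + trend + s_old
        resid[t] = yt - pred
        level_new = alpha * (yt - s_old) + (1.0 - alpha) * (level + trend)
        trend = beta * (level_new - level) + (1.0 - beta) * trend
        seasonal[t % m] = gamma * (yt - level_new) + (1.0 - gamma) * s_old
        level = level_new
    return level, trend, seasonal, resid


def fit_holt_winters(
    series: WeeklySeries,
    m: int = 52,
    params: tuple[float, float, float] | None = None,
) -> HoltWintersState:
    """Fit additive Holt-Winters to a weekly series.

    When ``params`` is omitted, (alpha, beta, gamma) minimise the in-sample
    one-step sum of squared errors via bounded numerical optimisation seeded
    from a coarse grid.  The one-step residual sd is stored for prediction
    intervals.
    """
    _require_length(series, m)
    y = series.counts
    level0, trend0, seasonal0 = _initial_state(series, m)

    def sse(theta: np.ndarray) -> float:
        *_, resid = _run_recursions(y, m, level0, trend0, seasonal0, *theta)
        return float(resid @ resid)

    if params is not None:
        alpha, beta, gamma = params
        if not all(0.0 <= p <= 1.0 for p in (alpha, beta, gamma)):
            raise ValueError(f"smoothing parameters {params} outside [0, 1]")
        theta = np.array([alpha, beta, gamma])
    else:
        grid = [0.05, 0.3, 0.7]
        starts = [(a, b, g) for a in grid for b in grid for g in grid]
        best_start = min(starts, key=lambda th: sse(np.array(th)))
        result = minimize(
            sse,
            x0=np.array(best_start),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * 3,
        )
        if not result.success and not np.isfinite(result.fun):
            raise RuntimeError(
                f"Holt-Winters optimiser failed for series {series.centre!r}: "
                f"{result.message}"
            )
        theta = np.clip(result.x, 0.0, 1.0)

    level, trend, seasonal, resid = _run_recursions(y, m, level0, trend0, seasonal0, *theta)
    sigma = float(np.sqrt(np.mean(resid**2)))
    return HoltWintersState(
        m=m,
        level=level,
        trend=trend,
        seasonal=seasonal,
        alpha=float(theta[0]),
        beta=float(theta[1]),
        gamma=float(theta[2]),
        sigma=sigma,
        n_obs=len(y),
        last_week=series.weeks[-1],
        sse=float(resid @ resid),
    )


def one_step_fitted(series: WeeklySeries, state: HoltWintersState) -> np.ndarray:
    """In-sample one-step-ahead predictions under the fitted parameters
    (re-running the recursions from the same initial state)."""
    level0, trend0, seasonal0 = _initial_state(series, state.m)
    *_, resid = _run_recursions(
        series.counts, state.m, level0, trend0, seasonal0,
        state.alpha, state.beta, state.gamma,
    )
    return series.counts - resid


def forecast(
    state: HoltWintersState,
    horizon_weeks: list[Week],
    centre: str = "",
) -> Forecast:
    """Forecast over a horizon contiguous with the fitted series.

    Points are truncated at zero (counts); the 95% interval is
    point +/- 1.96*sigma*sqrt(h) with the lower bound truncated at zero.
    """
    horizon_weeks = [tuple(w) for w in horizon_weeks]
    if not horizon_weeks:
        raise ValueError("empty forecast horizon")
    if _weeks.next_week(state.last_week) != horizon_weeks[0] or not _weeks.is_contiguous(
        horizon_weeks
    ):
        raise ValueError(
            f"forecast horizon must follow the fitted series contiguously "
            f"(series ends at {state.last_week}, horizon starts {horizon_weeks[0]})"
        )
    rows = []
    for h, (year, week) in enumerate(horizon_weeks, start=1):
        raw = state.level + h * state.trend + state.seasonal[(state.n_obs - 1 + h) % state.m]
        point = max(0.0, raw)
        half = Z95 * state.sigma * np.sqrt(h)
        rows.append(
            {
                "iso_year": year,
                "iso_week": week,
                "point": point,
                "lo95": max(0.0, point - half),
                "hi95": point + half,
            }
        )
    table = pd.DataFrame(rows)
    total = int(np.floor(table["point"].sum() + 0.5))
    return Forecast(centre=centre, table=table, total=total)
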