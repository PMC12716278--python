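"""Cumulative chill-injury mortality over a fluctuating temperature record.

Each record of a fixed-resolution temperature series contributes ``x`` hours
(``x`` = resolution in hours) of exposure.  A step at temperature ``T_i`` at
or below the ULCIZ first converts the survival carried in from the previous
step into an *equivalent exposure time* ``t_i`` — the continuous exposure at
``T_i`` that would have produced that survival — then advances it by ``x``:

    t_i = [logit(S_{i-1}) - a] / [b (T_i - c)] + x
    S_i = expit(a + b t_i (T_i - c))
    M_i = S_{i-1} - S_i

which collapses to a pure logit decrement,

    logit(S_i) = logit(S_{i-1}) + b x (T_i - c),

the form used internally (it is exact, has no division by ``T_i - c``, and
makes the cumulative mortality depend only on the degree-hour sum of
injurious records, not their order).  Records warmer than the ULCIZ leave
survival unchanged: injury is assumed cumulative with no recovery between
chill events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model import ChillParams

__all__ = [
    "TemperatureSeries",
    "MortalityTrace",
    "step",
    "accumulate",
    "monthly_mortality",
    "peak_winter_mortality",
    "SURVIVAL_FLOOR",
    "WINTER_MONTH_ORDER",
]

#: survival is clamped here before taking logits so the recursion stays
#: finite once mortality saturates.
SURVIVAL_FLOOR = 1e-12
_LOGIT_FLOOR = float(logit(SURVIVAL_FLOOR))

#: calendar months in winter-year (July .. June) order.
WINTER_MONTH_ORDER = (7, 8, 9, 10, 11, 12, 1, 2, 3, 4, 5, 6)

#: physically plausible surface-temperature bounds, degC.
TEMP_BOUNDS = (-60.0, 60.0)


@dataclass
class TemperatureSeries:
    """Fixed-resolution temperature record for one station.

    ``resolution`` is the spacing in minutes between consecutive records;
    ``x`` (= resolution / 60) is the exposure credited to each record, in
    hours.  Timestamps must be strictly increasing; gaps are permitted and
    contribute neither injury nor time.
    """

    station_id: str
    timestamps: pd.DatetimeIndex
    temps: np.ndarray
    resolution: float  # minutes

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temps = np.asarray(self.temps, dtype=float)
        if len(self.timestamps) != len(self.temps):
            raise ValueError("timestamps and temps differ in length")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if len(self.timestamps) != len(set(self.timestamps)):
            raise ValueError("duplicate timestamps")
        finite = self.temps[np.isfinite(self.temps)]
        if finite.size and (finite.min() < TEMP_BOUNDS[0] or finite.max() > TEMP_BOUNDS[1]):
            raise ValueError(f"temperatures outside physical bounds {TEMP_BOUNDS}")

    def __len__(self) -> int:
        return len(self.temps)

    @property
    def x(self) -> float:
        """Hours of exposure per record."""
        return self.resolution / 60.0

    def slice(self, start, end) -> "TemperatureSeries":
        """Records with start <= timestamp < end."""
        mask = (self.timestamps >= start) & (self.timestamps < end)
        return TemperatureSeries(
            self.station_id, self.timestamps[mask], self.temps[mask], self.resolution
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_id": self.station_id,
                "timestamp": self.timestamps,
                "temp_c": self.temps,
            }
        )


@dataclass
class MortalityTrace:
    """Stepwise output of :func:`accumulate`."""

    table: pd.DataFrame  # timestamp, temp_c, injurious, t_equiv, S, M_inc, M_cum
    S0: float
    params: ChillParams

    @property
    def M_cumulative(self) -> float:
        if self.table.empty:
            return 0.0
        return float(self.table["M_cum"].iloc[-1])

    @property
    def S_final(self) -> float:
        if self.table.empty:
            return self.S0
        return float(self.table["S"].iloc[-1])


def _clamped_logit(s: float) -> float:
    return float(logit(min(max(s, SURVIVAL_FLOOR), 1.0 - SURVIVAL_FLOOR)))


def step(S_prev: float, T_i: float, p: ChillParams, x: float):
    """One record's update: ``(t_i, S_i, M_i)``.

    ``t_i`` is the equivalent exposure (h) *after* adding this record's
    ``x`` hours; it is NaN for non-injurious records (``T_i > c``) and at
    ``T_i == c`` exactly, where the logit decrement is zero and the
    time-form would divide by zero.
    """
    if not 0.0 < S_prev < 1.0:
        raise ValueError("S_prev must lie strictly within (0, 1)")
    if T_i > p.c:
        return math.nan, S_prev, 0.0
    L = _clamped_logit(S_prev)
    if T_i == p.c:
        return math.nan, S_prev, 0.0
    t_i = (L - p.a) / (p.b * (T_i - p.c)) + x
    L_new = max(L + p.b * x * (T_i - p.c), _LOGIT_FLOOR)
    S_i = float(expit(L_new))
    return t_i, S_i, max(S_prev - S_i, 0.0)


def accumulate(series: TemperatureSeries, p: ChillParams) -> MortalityTrace:
    """Run the recursion over a series, starting from the intercept survival
    ``S_0 = expit(a)``; returns a per-record trace.

    Cumulative mortality telescopes: ``M_cumulative = S_0 - S_final``.
    Vectorised via the logit-additive form; the audit columns ``t_equiv``
    are reconstructed per record.
    """
    S0 = float(expit(p.a))
    n = len(series)
    if n == 0:
        empty = pd.DataFrame(
            columns=["timestamp", "temp_c", "injurious", "t_equiv", "S", "M_inc", "M_cum"]
        )
        return MortalityTrace(empty, S0, p)

    T = series.temps
    injurious = T <= p.c
    delta = np.where(injurious, p.b * series.x * (T - p.c), 0.0)
    L = np.maximum(p.a + np.cumsum(delta), _LOGIT_FLOOR)
    S = expit(L)
    L_prev = np.concatenate(([p.a], L[:-1]))
    S_prev = expit(L_prev)
    M_inc = np.maximum(S_prev - S, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_equiv = np.where(
            injurious & (T < p.c),
            (L_prev - p.a) / (p.b * (T - p.c)) + series.x,
            np.nan,
        )
    table = pd.DataFrame(
        {
            "timestamp": series.timestamps,
            "temp_c": T,
            "injurious": injurious,
            "t_equiv": t_equiv,
            "S": S,
            "M_inc": M_inc,
            "M_cum": np.cumsum(M_inc),
        }
    )
    return MortalityTrace(table, S0, p)


def _expected_records(year: int, month: int, resolution: float) -> float:
    days = pd.Period(f"{year}-{month:02d}").days_in_month
    return days * 24.0 * 60.0 / resolution


def monthly_mortality(
    series: TemperatureSeries,
    p: ChillParams,
    completeness_threshold: float = 0.75,
) -> pd.Series:
    """Per-calendar-month cumulative mortality, survival resetting to
    ``S_0`` at each month boundary.

    A month whose record count falls below ``completeness_threshold`` of
    the expected count (from the series resolution) is reported as NaN.
    Index is (year, month); months with no records at all are absent.
    """
    if len(series) == 0:
        return pd.Series(dtype=float)
    frame = pd.DataFrame({"ts": series.timestamps, "temp": series.temps})
    out = {}
    for (yr, mo), grp in frame.groupby([frame.ts.dt.year, frame.ts.dt.month]):
        expected = _expected_records(int(yr), int(mo), series.resolution)
        if len(grp) < completeness_threshold * expected:
            out[(int(yr), int(mo))] = math.nan
            continue
        sub = TemperatureSeries(
            series.station_id,
            pd.DatetimeIndex(grp["ts"]),
            grp["temp"].to_numpy(),
            series.resolution,
        )
        out[(int(yr), int(mo))] = accumulate(sub, p).M_cumulative
    idx = pd.MultiIndex.from_tuples(sorted(out), names=["year", "month"])
    return pd.Series([out[k] for k in sorted(out)], index=idx, name="M_cumulative")


def peak_winter_mortality(monthly: pd.Series) -> float:
    """Highest monthly cumulative mortality of a winter year.

    Ties go to the earliest month in July..June order; NaN if every month
    is missing.
    """
    if len(monthly) == 0 or monthly.isna().all():
        return math.nan
    valid = monthly.dropna()
    # chronological order is already guaranteed by the (year, month) index
    best = -math.inf
    for _, v in valid.sort_index().items():
        if v > best:
            best = v
    return float(best)
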