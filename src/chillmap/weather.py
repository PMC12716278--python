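"""Reading, quality control, and seasonal organisation of station records.

Temperature inputs come either as a canonical long CSV
(``station_id,timestamp,temp_c``) or, best-effort, as NOAA ASOS one-minute
fixed-width pages.  Series are sliced into *winter years* running July 1 to
June 30 so no single winter straddles a file boundary, screened for
completeness over the October-April core months, and summarised per station
as the mean and SD of annual peak winter mortalities.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .accumulator import (
    TemperatureSeries,
    WINTER_MONTH_ORDER,
    monthly_mortality,
    peak_winter_mortality,
)
from .model import ChillParams

__all__ = [
    "StationRecord",
    "QCDecision",
    "read_canonical_series",
    "write_canonical_series",
    "read_asos_onemin",
    "split_winter_years",
    "winter_completeness",
    "station_qc",
    "summarize_station",
    "station_summary_table",
    "CONUS_BBOX",
]

#: contiguous-US bounding box (lat_min, lat_max, lon_min, lon_max);
#: a box, not a polygon — configurable where used.
CONUS_BBOX = (24.0, 50.0, -125.0, -66.0)


@dataclass
class StationRecord:
    """Per-station summary of annual peak winter mortalities."""

    station_id: str
    lat: float
    lon: float
    annual_peaks: dict = field(default_factory=dict)  # winter label -> peak
    mean_peak: float = math.nan
    sd_peak: float = math.nan

    def __post_init__(self) -> None:
        if not -90 <= self.lat <= 90 or not -180 <= self.lon <= 180:
            raise ValueError("coordinates out of range")

    @property
    def n_years(self) -> int:
        return len(self.annual_peaks)


@dataclass
class QCDecision:
    include: bool
    reasons: list
    qualifying_years: list


# ---------------------------------------------------------------------------
# readers


def read_canonical_series(path) -> TemperatureSeries:
    """Read one station's long CSV; rows are sorted, duplicate timestamps
    collapsed by mean, and the fixed resolution inferred as the modal
    spacing (gaps of larger multiples are allowed)."""
    df = pd.read_csv(path)
    required = {"station_id", "timestamp", "temp_c"}
    if not required.issubset(df.columns):
        raise ValueError(f"canonical series CSV needs columns {sorted(required)}")
    stations = df["station_id"].unique()
    if len(stations) != 1:
        raise ValueError(f"expected a single station per file, found {list(stations)}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as e:
        raise ValueError(f"unparseable timestamps in {path}: {e}") from None
    df = pd.DataFrame({"ts": ts, "temp": df["temp_c"].astype(float)})
    df = df.groupby("ts", as_index=False).mean().sort_values("ts")
    return _series_from_frame(str(stations[0]), df["ts"], df["temp"].to_numpy())


def _series_from_frame(station_id, ts, temps) -> TemperatureSeries:
    idx = pd.DatetimeIndex(ts)
    if len(idx) > 1:
        diffs = np.diff(idx.asi8) / 60e9  # minutes
        vals, counts = np.unique(diffs, return_counts=True)
        resolution = float(vals[np.argmax(counts)])
        if resolution <= 0:
            raise ValueError("could not infer a positive time resolution")
    else:
        resolution = 60.0
    return TemperatureSeries(station_id, idx, np.asarray(temps, float), resolution)


def write_canonical_series(series: TemperatureSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


_ASOS_HEAD = re.compile(r"^(\d{5})([A-Z0-9]{4})\s+([A-Z0-9]{3,4})(\d{12})")


def read_asos_onemin(path, max_bad_fraction: float = 0.5) -> TemperatureSeries:
    """Best-effort reader for ASOS one-minute (DSI-6405-style) pages.

    The leading token carries WBAN id, call sign and a local yyyymmddhhmm
    stamp; the dry-bulb temperature (degF) is taken as the second-to-last
    numeric field of the line.  Unparseable lines are counted and skipped;
    the file is rejected if more than ``max_bad_fraction`` of its lines
    fail.
    """
    path = Path(path)
    stamps, temps = [], []
    n_bad = n_lines = 0
    station = None
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        n_lines += 1
        m = _ASOS_HEAD.match(line)
        if m is None:
            n_bad += 1
            continue
        tail = line[m.end():].split()
        try:
            temp_f = float(tail[-2])
            ts = pd.Timestamp(
                year=int(m.group(4)[0:4]), month=int(m.group(4)[4:6]),
                day=int(m.group(4)[6:8]), hour=int(m.group(4)[8:10]),
                minute=int(m.group(4)[10:12]),
            )
        except (IndexError, ValueError):
            n_bad += 1
            continue
        station = station or m.group(2)
        stamps.append(ts)
        temps.append((temp_f - 32.0) * 5.0 / 9.0)
    if n_lines == 0 or n_bad > max_bad_fraction * n_lines:
        raise ValueError(
            f"{path}: {n_bad}/{n_lines} lines unparseable; file rejected"
        )
    order = np.argsort(pd.DatetimeIndex(stamps).asi8)
    idx = pd.DatetimeIndex(stamps)[order]
    return _series_from_frame(station or path.stem, idx, np.asarray(temps)[order])


# ---------------------------------------------------------------------------
# winter years and QC


def winter_year_label(year: int) -> str:
    return f"{year}-{year + 1}"


def split_winter_years(series: TemperatureSeries) -> list[tuple[str, TemperatureSeries]]:
    """Slice a multi-year series at July 1 00:00 boundaries.

    Partial years at either end are emitted as-is and judged later by QC.
    """
    if len(series) == 0:
        return []
    out = []
    first, last = series.timestamps[0], series.timestamps[-1]
    start_year = first.year if first.month >= 7 else first.year - 1
    end_year = last.year if last.month >= 7 else last.year - 1
    for y in range(start_year, end_year + 1):
        sub = series.slice(pd.Timestamp(y, 7, 1), pd.Timestamp(y + 1, 7, 1))
        if len(sub):
            out.append((winter_year_label(y), sub))
    return out


def winter_completeness(winter: TemperatureSeries) -> float:
    """Fraction of expected October 1 - April 30 records present, pooled
    over the core winter months."""
    if len(winter) == 0:
        return 0.0
    start_year = winter.timestamps[0].year
    if winter.timestamps[0].month < 7:
        start_year -= 1
    t0 = pd.Timestamp(start_year, 10, 1)
    t1 = pd.Timestamp(start_year + 1, 5, 1)
    expected = (t1 - t0).total_seconds() / 60.0 / winter.resolution
    observed = len(winter.slice(t0, t1))
    return observed / expected


def station_qc(
    lat: float,
    lon: float,
    winters: list,
    min_years: int = 10,
    max_missing: float = 0.25,
    bbox: tuple = CONUS_BBOX,
) -> QCDecision:
    """Screen a station: inside the study bounding box, with at least
    ``min_years`` winter years each missing no more than ``max_missing`` of
    their October-April records.

    ``winters`` is a list of ``(label, TemperatureSeries)``.  Failing years
    are dropped (with reasons); the station fails if the surviving count is
    below ``min_years``.
    """
    reasons = []
    lat_min, lat_max, lon_min, lon_max = bbox
    if not (lat_min <= lat <= lat_max and lon_min <= lon <= lon_max):
        reasons.append("outside contiguous-US bounding box")
    qualifying = []
    for label, wseries in winters:
        comp = winter_completeness(wseries)
        if 1.0 - comp > max_missing:
            reasons.append(
                f"winter {label}: {100 * (1 - comp):.0f}% of Oct-Apr records missing"
            )
        else:
            qualifying.append(label)
    if len(qualifying) < min_years:
        reasons.append(
            f"fewer than {min_years} yr of qualifying data ({len(qualifying)})"
        )
    include = not reasons or (
        len(qualifying) >= min_years
        and lat_min <= lat <= lat_max
        and lon_min <= lon <= lon_max
    )
    return QCDecision(include=include, reasons=reasons, qualifying_years=qualifying)


# ---------------------------------------------------------------------------
# summaries


def summarize_station(annual_peaks: dict) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of annual peak mortalities.

    SD is NaN with a single year.
    """
    vals = np.array([v for v in annual_peaks.values() if not math.isnan(v)])
    if vals.size == 0:
        raise ValueError("need at least one annual peak")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else math.nan
    return mean, sd


def station_summary_table(
    series_by_station: dict,
    meta: pd.DataFrame,
    params: ChillParams,
    min_years: int = 10,
    max_missing: float = 0.25,
    completeness_threshold: float = 0.75,
    bbox: tuple = CONUS_BBOX,
) -> tuple[pd.DataFrame, dict]:
    """Full station pipeline: split winters, QC, accumulate, summarise.

    Returns ``(summary DataFrame, {station_id: QCDecision})``; the frame has
    one row per included station with columns ``station_id, lat, lon,
    n_years, mean_peak_mortality, sd_peak_mortality``.
    """
    meta = meta.set_index("station_id")
    rows, decisions = [], {}
    for sid, series in series_by_station.items():
        if sid not in meta.index:
            decisions[sid] = QCDecision(False, ["no station metadata"], [])
            continue
        lat, lon = float(meta.loc[sid, "lat"]), float(meta.loc[sid, "lon"])
        winters = split_winter_years(series)
        dec = station_qc(lat, lon, winters, min_years, max_missing, bbox)
        decisions[sid] = dec
        if not dec.include:
            continue
        peaks = {}
        keep = set(dec.qualifying_years)
        for label, wseries in winters:
            if label not in keep:
                continue
            monthly = monthly_mortality(wseries, params, completeness_threshold)
            peak = peak_winter_mortality(monthly)
            if not math.isnan(peak):
                peaks[label] = peak
        if not peaks:
            decisions[sid].include = False
            decisions[sid].reasons.append("no winter produced a reportable peak")
            continue
        mean, sd = summarize_station(peaks)
        rows.append(
            {
                "station_id": sid, "lat": lat, "lon": lon,
                "n_years": len(peaks),
                "mean_peak_mortality": mean, "sd_peak_mortality": sd,
            }
        )
    return pd.DataFrame(rows), decisions
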