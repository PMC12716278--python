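"""Retrospective link between predicted winter mortality and spring
collection success of a redistribution program.

For each program year, peak winter mortality is predicted at the collection
site (nearest qualifying station by default, kriged surface optionally) and
regressed against the number of insects collected the following spring.
The predictor is expressed in *percent* mortality, so the slope reads as
"insects lost per percentage-point increase in predicted winter mortality".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .accumulator import monthly_mortality, peak_winter_mortality
from .model import ChillParams
from .spatial import haversine_km
from .weather import split_winter_years

__all__ = [
    "CollectionYear",
    "annual_site_mortality",
    "regress_collections",
    "logistic_mortality_regression",
]


def logistic_mortality_regression(assays: pd.DataFrame) -> dict:
    """Binomial GLM of assay mortality on exposure time and temperature drop.

    Expects the assay-table columns (``temperature_c, exposure_h,
    n_exposed`` and ``n_dead`` or ``proportion_dead``).  Predictors are
    exposure time in hours and *negated* temperature, so both coefficients
    are positive log-odds increases: per additional hour of exposure and
    per degC drop in temperature.  Cells are weighted by ``n_exposed``.
    """
    df = assays.copy()
    if "proportion_dead" not in df.columns:
        df["proportion_dead"] = df["n_dead"] / df["n_exposed"]
    y = df["proportion_dead"].to_numpy()
    X = sm.add_constant(
        np.column_stack([df["exposure_h"].to_numpy(float), -df["temperature_c"].to_numpy(float)])
    )
    fit = sm.GLM(
        y, X, family=sm.families.Binomial(),
        freq_weights=df["n_exposed"].to_numpy(float),
    ).fit()
    return {
        "coef_time_per_h": float(fit.params[1]),
        "se_time": float(fit.bse[1]),
        "coef_temp_drop_per_degC": float(fit.params[2]),
        "se_temp_drop": float(fit.bse[2]),
        "intercept": float(fit.params[0]),
        "n_cells": int(len(df)),
    }


@dataclass(frozen=True)
class CollectionYear:
    """One program year: spring collection count and the predicted
    mortality of the preceding winter at the collection site."""

    year: int
    lat: float
    lon: float
    collected: float
    predicted_mortality: float = math.nan  # proportion in [0, 1]

    def __post_init__(self) -> None:
        if self.collected < 0:
            raise ValueError("collected count must be >= 0")


def annual_site_mortality(
    series_by_station: dict,
    meta: pd.DataFrame,
    params: ChillParams,
    site: tuple,
    years: list,
    completeness_threshold: float = 0.75,
):
    """Peak mortality of winter ``year-1 -> year`` at the nearest station
    with adequate data, for each requested collection year.

    Returns ``(year -> mortality dict, dropped list)``; a year is dropped
    (with a reason) when no station yields a reportable peak for that
    winter.
    """
    meta = meta.reset_index(drop=True)
    d = haversine_km(site[0], site[1], meta["lat"].to_numpy(), meta["lon"].to_numpy())
    order = np.argsort(d)
    winters_cache = {
        sid: dict(split_winter_years(s)) for sid, s in series_by_station.items()
    }
    out, dropped = {}, []
    for year in years:
        label = f"{year - 1}-{year}"
        got = False
        for j in order:
            sid = meta.loc[j, "station_id"]
            wseries = winters_cache.get(sid, {}).get(label)
            if wseries is None:
                continue
            peak = peak_winter_mortality(
                monthly_mortality(wseries, params, completeness_threshold)
            )
            if not math.isnan(peak):
                out[year] = peak
                got = True
                break
        if not got:
            dropped.append((year, "insufficient weather data"))
    return out, dropped


def regress_collections(data) -> dict:
    """OLS of collection count on predicted winter mortality in percent.

    ``data`` is a sequence of :class:`CollectionYear` (or a DataFrame with
    ``collected`` and ``predicted_mortality`` columns, the latter a
    proportion).  Returns slope (insects per percent mortality), its SE,
    t, two-sided p and r-squared, plus the intercept.
    """
    if isinstance(data, pd.DataFrame):
        df = data[["collected", "predicted_mortality"]].dropna()
    else:
        df = pd.DataFrame(
            {
                "collected": [d.collected for d in data],
                "predicted_mortality": [d.predicted_mortality for d in data],
            }
        ).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 years with both fields")
    x = 100.0 * df["predicted_mortality"].to_numpy()  # percent scale
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor: all mortalities identical")
    X = sm.add_constant(x)
    fit = sm.OLS(df["collected"].to_numpy(), X).fit()
    return {
        "slope": float(fit.params[1]),
        "slope_se": float(fit.bse[1]),
        "t": float(fit.tvalues[1]),
        "p": float(fit.pvalues[1]),
        "r2": float(fit.rsquared),
        "intercept": float(fit.params[0]),
        "n": int(fit.nobs),
    }
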