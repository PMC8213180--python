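"""Per-plot climatic covariates: growing degree-days and cumulative precipitation.

Growing degree-days (GDD) follow the monthly approximation used by the
JABOWA family of forest gap models: each month contributes
``max(0, tmean - base) * days_in_month``, with a base temperature of 4.4 °C
below which tree growth is taken to be negligible.  Annual values are then
averaged over each remeasurement interval, using the convention that an
interval from ``t_prev`` to ``t_curr`` covers calendar years
``t_prev + 1 .. t_curr`` (the interval ends at, and includes, the
remeasurement year).
"""

from __future__ import annotations

import calendar
from collections.abc import Mapping

import numpy as np
import pandas as pd

BASE_TEMP_C = 4.4

#: Expected columns of a monthly climate table.
CLIMATE_COLUMNS = ["plot_id", "year", "month", "tmean_c", "pcp_mm"]


class MissingClimateError(ValueError):
    """A (plot, year, month) needed for a covariate is absent."""


def days_in_month(year: int, month: int) -> int:
    """Calendar-true (leap-aware) number of days in a month."""
    return calendar.monthrange(int(year), int(month))[1]


def gdd_annual(tmean_by_month: Mapping[int, float], year: int,
               base_temp: float = BASE_TEMP_C) -> float:
    """Annual growing degree-days from 12 monthly mean daily temperatures.

    Parameters
    ----------
    tmean_by_month : mapping month (1..12) -> monthly mean of daily mean
        temperature (°C).
    year : calendar year, used for leap-aware month lengths.
    base_temp : base temperature (°C); default 4.4.

    Returns
    -------
    float
        ``sum_m max(0, tmean_m - base_temp) * days_in_month(m)``, in
        degree-day units.
    """
    missing = [m for m in range(1, 13) if m not in tmean_by_month]
    if missing:
        raise MissingClimateError(
            f"missing month(s) {missing} for year {year}")
    total = 0.0
    for m in range(1, 13):
        excess = float(tmean_by_month[m]) - base_temp
        if excess > 0:
            total += excess * days_in_month(year, m)
    return total


def pcp_annual(pcp_by_month: Mapping[int, float]) -> float:
    """Cumulative annual precipitation (mm) from 12 monthly totals."""
    missing = [m for m in range(1, 13) if m not in pcp_by_month]
    if missing:
        raise MissingClimateError(f"missing month(s) {missing}")
    vals = [float(pcp_by_month[m]) for m in range(1, 13)]
    if any(v < 0 for v in vals):
        raise ValueError("monthly precipitation must be non-negative")
    return float(sum(vals))


def annual_climate(climate: pd.DataFrame,
                   base_temp: float = BASE_TEMP_C) -> pd.DataFrame:
    """Collapse a monthly climate table to annual GDD and PCP per plot-year.

    Parameters
    ----------
    climate : DataFrame with columns ``plot_id, year, month, tmean_c, pcp_mm``
        and one row per (plot, year, month).

    Returns
    -------
    DataFrame with columns ``plot_id, year, gdd, pcp``.
    """
    required = set(CLIMATE_COLUMNS)
    if not required.issubset(climate.columns):
        raise ValueError(f"climate table needs columns {sorted(required)}")
    dup = climate.duplicated(subset=["plot_id", "year", "month"])
    if dup.any():
        raise ValueError("duplicate (plot_id, year, month) rows in climate table")

    out = []
    for (plot_id, year), grp in climate.groupby(["plot_id", "year"], sort=True):
        tm = dict(zip(grp["month"].astype(int), grp["tmean_c"].astype(float)))
        pm = dict(zip(grp["month"].astype(int), grp["pcp_mm"].astype(float)))
        try:
            gdd = gdd_annual(tm, int(year), base_temp=base_temp)
            pcp = pcp_annual(pm)
        except MissingClimateError as exc:
            raise MissingClimateError(f"plot {plot_id}: {exc}") from exc
        out.append({"plot_id": plot_id, "year": int(year),
                    "gdd": gdd, "pcp": pcp})
    return pd.DataFrame(out, columns=["plot_id", "year", "gdd", "pcp"])


def interval_average(annual_values: Mapping[int, float],
                     t_prev: int, t_curr: int) -> float:
    """Mean of an annual series over the remeasurement interval.

    The window is ``(t_prev, t_curr]``: calendar years
    ``t_prev + 1 .. t_curr`` inclusive.  All years must be present.
    """
    if t_curr <= t_prev:
        raise ValueError(f"t_curr ({t_curr}) must exceed t_prev ({t_prev})")
    years = range(int(t_prev) + 1, int(t_curr) + 1)
    missing = [y for y in years if y not in annual_values]
    if missing:
        raise MissingClimateError(f"missing annual value(s) for year(s) {missing}")
    vals = np.array([float(annual_values[y]) for y in years])
    return float(vals.mean())
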