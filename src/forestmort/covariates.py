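"""Tree-level and competition covariates for mortality modelling.

Implements the covariate set used by the mortality model:

* ``ΔBA`` — average annual basal-area increment between two measurements
  (cm² yr⁻¹),
* ``BAL`` — basal area of all plot trees larger than the subject
  (m² ha⁻¹), a one-sided competition index,
* ``ERD`` — extended relative density: observed stand density divided by
  the self-thinning maximum ``Nmax = α (DBH / DBH_r)^(−β)`` at the stand's
  quadratic-mean DBH,
* the ``BAL×ERD`` interaction,

together with the quality-control filters that drop outlying observations
before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import climate as _climate

#: The 28 species codes of the source inventory (boreal/temperate Acadian mix).
SPECIES_CODES = [
    "AA", "AB", "AW", "BG", "BW", "BY", "CP", "EC", "EE", "EH", "FB", "IW",
    "KA", "LT", "MM", "MR", "MS", "MT", "OR", "PJ", "PR", "RB", "RL", "RT",
    "SB", "SR", "SW", "XW",
]

AGE_CLASSES = ["young", "immature", "mature", "overmature"]


@dataclass(frozen=True)
class SelfThinningParams:
    """Parameters of the self-thinning line ``Nmax = alpha (DBH/dbh_ref)^-beta``.

    alpha : maximum stems per hectare at the reference DBH (stems ha⁻¹).
    beta : self-thinning exponent (dimensionless); 1.605 is the classical
        Reineke value.
    dbh_ref : reference DBH (cm); 20 cm by convention.
    """

    alpha: float = 500.0
    beta: float = 1.605
    dbh_ref: float = 20.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.dbh_ref <= 0:
            raise ValueError("dbh_ref must be > 0")


@dataclass(frozen=True)
class QCThresholds:
    """Outlier thresholds applied to the covariate table.

    delta_ba_max is expressed in cm² yr⁻¹.  bal_erd_max applies to the
    BAL×ERD interaction and slp_max to plot slope in percent.
    """

    delta_ba_max: float = 20.0
    bal_erd_max: float = 7.0
    slp_max: float = 40.0


def basal_area(dbh):
    """Stem basal area (cm²) from DBH (cm): ``π (dbh/2)²``."""
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh < 0):
        raise ValueError("DBH must be non-negative")
    out = np.pi * (dbh / 2.0) ** 2
    return float(out) if out.ndim == 0 else out


def delta_ba(ba_prev: float, ba_curr: float, t_prev: float, t_curr: float) -> float:
    """Average annual basal-area increment (cm² yr⁻¹) between two measurements.

    Negative values (apparent shrinkage) are retained; they are only
    removed later by the explicit outlier rule.
    """
    if t_curr <= t_prev:
        raise ValueError(
            f"invalid remeasurement order: t_curr ({t_curr}) <= t_prev ({t_prev})")
    return (float(ba_curr) - float(ba_prev)) / (float(t_curr) - float(t_prev))


def bal(subject_dbh: float, plot_dbh_list, plot_area_m2: float,
        ties: str = "strict") -> float:
    """Basal area of larger trees (m² ha⁻¹) for one subject tree.

    Sums the basal area of every plot tree whose DBH exceeds the subject's
    (strictly, by default) and scales from the plot to a hectare by
    ``10000 / plot_area``.  The largest tree in the plot has BAL = 0.

    Parameters
    ----------
    subject_dbh : DBH of the subject tree (cm).
    plot_dbh_list : DBH of every tree in the plot census (cm), subject included.
    plot_area_m2 : plot area (m²).
    ties : "strict" (default) — equal-DBH trees do not compete;
        "inclusive" — ties count (the subject itself never does).
    """
    dbhs = np.asarray(plot_dbh_list, dtype=float)
    if dbhs.size == 0:
        raise ValueError("empty plot tree list")
    if plot_area_m2 <= 0:
        raise ValueError("plot area must be > 0")
    if ties == "strict":
        larger = dbhs[dbhs > subject_dbh]
    elif ties == "inclusive":
        larger = dbhs[dbhs >= subject_dbh]
        # drop one occurrence for the subject itself
        if larger.size and np.any(np.isclose(larger, subject_dbh)):
            idx = int(np.argmax(np.isclose(larger, subject_dbh)))
            larger = np.delete(larger, idx)
    else:
        raise ValueError(f"unknown ties mode {ties!r}")
    ba_m2 = basal_area(larger) / 1e4 if larger.size else np.array([])
    return float(np.sum(ba_m2) * (10000.0 / plot_area_m2))


def n_max(mean_dbh: float, params: SelfThinningParams) -> float:
    """Maximum sustainable stand density (stems ha⁻¹) at a mean DBH (cm)."""
    if mean_dbh <= 0:
        raise ValueError("mean DBH must be > 0")
    return float(params.alpha * (mean_dbh / params.dbh_ref) ** (-params.beta))


def erd(n_stems: float, mean_dbh: float, params: SelfThinningParams) -> float:
    """Extended relative density: stand density over the self-thinning maximum.

    Equals 1 exactly when the stand sits on the self-thinning boundary;
    linear in ``n_stems``.
    """
    if n_stems < 0:
        raise ValueError("stem density must be >= 0")
    return float(n_stems) / n_max(mean_dbh, params)


def quadratic_mean_dbh(dbhs) -> float:
    """Quadratic mean DBH (cm) — the diameter of the tree of mean basal area."""
    dbhs = np.asarray(dbhs, dtype=float)
    if dbhs.size == 0:
        raise ValueError("no stems")
    return float(np.sqrt(np.mean(dbhs**2)))


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

COVARIATE_COLUMNS = [
    "plot_id", "tree_id", "interval_index", "species", "age_class",
    "delta_ba", "bal", "erd", "bal_erd", "slp", "ins", "gdd", "pcp",
]


def build_covariate_table(trees: pd.DataFrame, plots: pd.DataFrame,
                          climate: pd.DataFrame,
                          params: SelfThinningParams | None = None) -> pd.DataFrame:
    """Assemble the record-level covariate table, one row per tree-interval.

    Parameters
    ----------
    trees : per-measurement tree records with columns
        ``plot_id, tree_id, species, year, dbh_cm, status, age_class``.
    plots : per-plot attributes with columns
        ``plot_id, area_m2, slope_pct, ins_wh_m2``.
    climate : monthly climate table (see :mod:`forestmort.climate`).
    params : self-thinning parameters for ERD; defaults used when omitted.

    Notes
    -----
    For each consecutive measurement pair of a tree, ΔBA uses the two
    recorded DBHs; BAL and ERD are evaluated from the live census at the
    start of the interval; GDD and PCP are annual values averaged over the
    interval ``(t_prev, t_curr]``.
    """
    params = params or SelfThinningParams()
    ann = _climate.annual_climate(climate)
    ann_by_plot: dict = {
        pid: dict(zip(grp["year"], grp["gdd"]))
        for pid, grp in ann.groupby("plot_id")
    }
    pcp_by_plot: dict = {
        pid: dict(zip(grp["year"], grp["pcp"]))
        for pid, grp in ann.groupby("plot_id")
    }
    plot_attrs = plots.set_index("plot_id")

    rows = []
    for plot_id, ptrees in trees.groupby("plot_id", sort=True):
        attrs = plot_attrs.loc[plot_id]
        area = float(attrs["area_m2"])
        years = np.sort(ptrees["year"].unique())
        # live census (DBH list) at each measurement year
        live_by_year = {
            y: ptrees.loc[(ptrees["year"] == y) & (ptrees["status"] == 1),
                          "dbh_cm"].to_numpy(dtype=float)
            for y in years
        }
        for tree_id, hist in ptrees.groupby("tree_id", sort=True):
            hist = hist.sort_values("year")
            yr = hist["year"].to_numpy()
            dbh = hist["dbh_cm"].to_numpy(dtype=float)
            status = hist["status"].to_numpy()
            for k in range(len(hist) - 1):
                if status[k] != 1:
                    break  # no intervals start from a dead record
                t0, t1 = int(yr[k]), int(yr[k + 1])
                census = live_by_year[t0]
                qmd = quadratic_mean_dbh(census)
                stems_ha = census.size * (10000.0 / area)
                erd_val = erd(stems_ha, qmd, params)
                bal_val = bal(dbh[k], census, area)
                dba = delta_ba(basal_area(dbh[k]), basal_area(dbh[k + 1]), t0, t1)
                gdd_val = _climate.interval_average(ann_by_plot[plot_id], t0, t1)
                pcp_val = _climate.interval_average(pcp_by_plot[plot_id], t0, t1)
                rows.append({
                    "plot_id": plot_id, "tree_id": tree_id, "interval_index": k,
                    "species": hist["species"].iloc[0],
                    "age_class": hist["age_class"].iloc[0],
                    "delta_ba": dba, "bal": bal_val, "erd": erd_val,
                    "bal_erd": bal_val * erd_val,
                    "slp": float(attrs["slope_pct"]),
                    "ins": float(attrs["ins_wh_m2"]),
                    "gdd": gdd_val, "pcp": pcp_val,
                })
    return pd.DataFrame(rows, columns=COVARIATE_COLUMNS)


def qc_filter(rows: pd.DataFrame,
              thresholds: QCThresholds | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the outlier filters; return (kept rows, rejection log).

    Rules, applied independently (a row may violate several):
    ``delta_ba > delta_ba_max``, ``bal_erd > bal_erd_max``,
    ``slp > slp_max``.  The rejection log has one row per (record, rule)
    violation with the row's keys and the rule name.
    """
    thresholds = thresholds or QCThresholds()
    if rows.empty:
        return rows.copy(), pd.DataFrame(
            columns=["plot_id", "tree_id", "interval_index", "rule", "value"])
    rules = {
        "delta_ba": rows["delta_ba"] > thresholds.delta_ba_max,
        "bal_erd": rows["bal_erd"] > thresholds.bal_erd_max,
        "slp": rows["slp"] > thresholds.slp_max,
    }
    log_rows = []
    any_bad = np.zeros(len(rows), dtype=bool)
    for name, mask in rules.items():
        mask = mask.to_numpy()
        any_bad |= mask
        for idx in np.flatnonzero(mask):
            r = rows.iloc[idx]
            log_rows.append({
                "plot_id": r.get("plot_id"), "tree_id": r.get("tree_id"),
                "interval_index": r.get("interval_index"),
                "rule": name, "value": float(r[name]),
            })
    kept = rows.loc[~any_bad].reset_index(drop=True)
    log = pd.DataFrame(
        log_rows,
        columns=["plot_id", "tree_id", "interval_index", "rule", "value"])
    return kept, log
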