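"""Survival outcomes and five-year mortality rates.

Status histories (1 = alive, 0 = dead at a measurement) are recoded to one
binary survival record per remeasurement interval; repeated dead codes
after a tree's first death are dropped so no tree is counted dead twice.
Interval mortality proportions are put on a common five-year scale with the
compound-survival conversion

    P_m5 = 1 - (1 - P_m3)^(5/3)

which generalises to any pair of interval lengths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SURVIVAL_COLUMNS = ["plot_id", "tree_id", "interval_index",
                    "year_start", "year_end", "interval_years", "outcome"]


def convert_rate(p: float, from_years: float, to_years: float) -> float:
    """Convert a mortality proportion between observation-period lengths.

    ``1 - (1 - p)^(to_years / from_years)``: survival is compounded at a
    constant annualised rate.  Fixed points at 0 and 1; monotone in ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion {p} outside [0, 1]")
    if from_years <= 0 or to_years <= 0:
        raise ValueError("period lengths must be positive")
    return 1.0 - (1.0 - float(p)) ** (float(to_years) / float(from_years))


def recode_status(statuses, years) -> list[dict]:
    """Recode one tree's ordered status history into interval records.

    Parameters
    ----------
    statuses : sequence of 1 (alive) / 0 (dead) codes ordered by year.
    years : measurement years, same length.

    Returns
    -------
    list of dicts with keys ``year_start, year_end, interval_years, outcome``;
    outcome 1 = alive at interval end, 0 = died during the interval.
    Records after the first dead code are dropped.  A history that begins
    dead yields no records (the tree was never observed alive).
    """
    statuses = list(statuses)
    years = list(years)
    if len(statuses) != len(years):
        raise ValueError("statuses and years differ in length")
    records: list[dict] = []
    for k in range(len(statuses) - 1):
        if statuses[k] != 1:
            break  # first dead code reached: later pairs dropped
        outcome = 1 if statuses[k + 1] == 1 else 0
        records.append({
            "year_start": int(years[k]), "year_end": int(years[k + 1]),
            "interval_years": int(years[k + 1]) - int(years[k]),
            "outcome": outcome,
        })
        if outcome == 0:
            break
    return records


def build_survival_records(trees: pd.DataFrame
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recode a full tree-measurement table into survival records.

    Returns (records, skipped) where ``skipped`` logs trees whose history
    begins with a dead code (never observed alive).
    """
    rows, skipped = [], []
    for (plot_id, tree_id), hist in trees.groupby(["plot_id", "tree_id"],
                                                  sort=True):
        hist = hist.sort_values("year")
        statuses = hist["status"].tolist()
        if statuses and statuses[0] != 1:
            skipped.append({"plot_id": plot_id, "tree_id": tree_id,
                            "reason": "never observed alive"})
            continue
        for k, rec in enumerate(recode_status(statuses, hist["year"].tolist())):
            rows.append({"plot_id": plot_id, "tree_id": tree_id,
                         "interval_index": k, **rec})
    records = pd.DataFrame(rows, columns=SURVIVAL_COLUMNS)
    skipped_df = pd.DataFrame(skipped, columns=["plot_id", "tree_id", "reason"])
    return records, skipped_df


def pooled_five_year_rate(outcomes, interval_years) -> float:
    """Five-year mortality proportion from mixed-length interval records.

    Within each interval length the raw proportion of deaths is converted
    to a five-year rate, and lengths are pooled weighted by record count.
    """
    outcomes = np.asarray(outcomes)
    interval_years = np.asarray(interval_years)
    if outcomes.size == 0:
        raise ValueError("no records")
    total_n = 0
    acc = 0.0
    for length in np.unique(interval_years):
        sel = interval_years == length
        n = int(sel.sum())
        raw = float((outcomes[sel] == 0).sum()) / n
        acc += n * convert_rate(raw, float(length), 5.0)
        total_n += n
    return acc / total_n


def group_rates(records: pd.DataFrame, group_cols: list[str],
                min_n: int = 20) -> pd.DataFrame:
    """Grouped observed five-year mortality rates.

    Parameters
    ----------
    records : survival records carrying ``outcome``, ``interval_years`` and
        the grouping columns.
    group_cols : columns forming the group key (species and covariate bins).
    min_n : groups with fewer live-at-start records are eliminated.

    Returns
    -------
    DataFrame with the group key columns plus ``n_start, n_dead, rate_5yr``.
    """
    out = []
    for key, grp in records.groupby(group_cols, sort=True, observed=True,
                                    dropna=False):
        n_start = len(grp)
        if n_start < min_n:
            continue
        n_dead = int((grp["outcome"] == 0).sum())
        rate = pooled_five_year_rate(grp["outcome"].to_numpy(),
                                     grp["interval_years"].to_numpy())
        key = key if isinstance(key, tuple) else (key,)
        out.append({**dict(zip(group_cols, key)),
                    "n_start": n_start, "n_dead": n_dead, "rate_5yr": rate})
    return pd.DataFrame(out, columns=group_cols + ["n_start", "n_dead",
                                                   "rate_5yr"])


def default_group_key(table: pd.DataFrame,
                      quartile_cols: tuple[str, ...] = ("delta_ba", "bal_erd",
                                                        "gdd", "pcp"),
                      n_bins: int = 4) -> pd.Series:
    """Default evaluation grouping: species × quantile bins of key covariates.

    Each listed numeric covariate is cut into ``n_bins`` quantile bins over
    the table; the key is the species code joined with the bin indices.
    Degenerate columns (too few distinct values) collapse to one bin.
    """
    parts = [table["species"].astype(str)]
    for col in quartile_cols:
        if col not in table.columns:
            continue
        try:
            bins = pd.qcut(table[col], q=n_bins, labels=False, duplicates="drop")
        except ValueError:
            bins = pd.Series(0, index=table.index)
        parts.append(bins.fillna(-1).astype(int).astype(str))
    key = parts[0].str.cat(parts[1:], sep="|")
    key.name = "group_key"
    return key


def build_model_table(covariates: pd.DataFrame, records: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join covariates with survival outcomes into the model input table.

    Inner join on ``(plot_id, tree_id, interval_index)``.  Rows missing any
    covariate value are dropped and logged with the offending column.
    Duplicate keys on either side raise.
    """
    keys = ["plot_id", "tree_id", "interval_index"]
    for name, df in (("covariates", covariates), ("records", records)):
        if df.duplicated(subset=keys).any():
            raise ValueError(f"duplicate keys in {name} table")
    merged = covariates.merge(
        records[keys + ["interval_years", "outcome"]], on=keys, how="inner")
    cov_cols = [c for c in covariates.columns if c not in keys]
    rejects = []
    bad = pd.Series(False, index=merged.index)
    for col in cov_cols:
        isna = merged[col].isna()
        for idx in merged.index[isna]:
            rejects.append({**{k: merged.at[idx, k] for k in keys},
                            "column": col})
        bad |= isna
    kept = merged.loc[~bad].reset_index(drop=True)
    log = pd.DataFrame(rejects, columns=keys + ["column"])
    return kept, log
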