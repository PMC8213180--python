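"""Covariate screening, k-fold cross-validation and node-stability reports.

Model quality is judged on grouped five-year mortality rates: held-out
records are grouped (species × covariate quantile bins by default), their
observed five-year rates computed, and compared with the count-weighted
mean predicted rate per group via weighted correlation, MSE and mean bias.
Cross-fold structural stability is summarised by comparing the split
variables and split forms of the fitted trees down to a depth limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ctree as _ctree
from .ctree import CTreeControl, CTreeModel
from .model import MortalityTree
from .response import default_group_key, group_rates

SPEARMAN_BANDS = ((0.50, "significant"), (0.30, "some"), (0.10, "slight"),
                  (0.0, "none"))


@dataclass
class FitMetrics:
    """Observed-vs-predicted agreement on grouped mortality rates."""

    r: float
    r2: float
    mse: float
    bias: float
    n_groups: int
    n_inner: int = 0
    n_terminal: int = 0


def spearman_matrix(table: pd.DataFrame,
                    columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (average-rank tie handling).

    Nominal object columns are ordinal-encoded by sorted level before
    ranking; constant columns give NaN coefficients.  Requires >= 3 rows.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    cols = columns or list(table.columns)
    enc = {}
    for c in cols:
        s = table[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = {v: i for i, v in enumerate(sorted(s.astype(str).unique()))}
            enc[c] = s.astype(str).map(levels).astype(float)
        else:
            enc[c] = s.astype(float)
    df = pd.DataFrame(enc)
    corr = df.corr(method="spearman")
    for c in cols:  # constant columns: undefined, reported missing
        if df[c].nunique() < 2:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def correlation_band(rho: float) -> str:
    """Qualitative association band for a Spearman coefficient."""
    if np.isnan(rho):
        return "undefined"
    a = abs(rho)
    for cut, label in SPEARMAN_BANDS:
        if a >= cut:
            return label
    return "none"


def fit_metrics(observed, predicted, weights=None,
                n_inner: int = 0, n_terminal: int = 0) -> FitMetrics:
    """Count-weighted correlation, MSE and mean bias of grouped rates.

    ``bias`` is mean(predicted - observed).  With zero variance in either
    vector the correlation is undefined (NaN) but MSE/bias are returned.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need >= 2 equal-length groups")
    w = np.ones_like(obs) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mse = float(np.sum(w * (pred - obs) ** 2))
    bias = float(np.sum(w * (pred - obs)))
    mo, mp = np.sum(w * obs), np.sum(w * pred)
    vo = np.sum(w * (obs - mo) ** 2)
    vp = np.sum(w * (pred - mp) ** 2)
    if vo <= 0 or vp <= 0:
        r = float("nan")
    else:
        r = float(np.sum(w * (obs - mo) * (pred - mp)) / np.sqrt(vo * vp))
    return FitMetrics(r=r, r2=r * r if np.isfinite(r) else float("nan"),
                      mse=mse, bias=bias, n_groups=int(obs.size),
                      n_inner=n_inner, n_terminal=n_terminal)


def assign_folds(table: pd.DataFrame, k: int, seed: int,
                 by_plot: bool = True) -> np.ndarray:
    """Deterministic fold assignment (1..k) per record.

    By default whole plots are assigned to folds, so a tree's earlier
    interval never trains the fold that holds out its later interval;
    record-level assignment (``by_plot=False``) is available for literal
    random partitioning.  Unit (plot or record) counts per fold differ by
    at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    if by_plot:
        plots = np.sort(table["plot_id"].unique())
        perm = rng.permutation(len(plots))
        fold_of_plot = {plots[j]: (perm[j] % k) + 1 for j in range(len(plots))}
        return table["plot_id"].map(fold_of_plot).to_numpy()
    perm = rng.permutation(len(table))
    folds = np.empty(len(table), dtype=int)
    folds[perm] = (np.arange(len(table)) % k) + 1
    return folds


def kfold_cv(table: pd.DataFrame, k: int = 5, seed: int = 0,
             control: CTreeControl | None = None,
             covariates: list[str] | None = None,
             nominal: list[str] | None = None,
             by_plot: bool = True, min_group_n: int = 20,
             group_key_func=None
             ) -> tuple[list[FitMetrics], list[CTreeModel]]:
    """k-fold cross-validation of the mortality tree on a model table.

    For each fold: fit on the remaining folds, predict the held-out
    records, group the held-out set (species × covariate quantile bins),
    and compute :func:`fit_metrics` between observed grouped five-year
    rates and count-weighted mean predictions per group.

    ``group_key_func`` maps the held-out table to a group-key Series; the
    default is :func:`forestmort.response.default_group_key`.  With small
    held-out sets a coarser grouping (fewer bins/covariates) keeps enough
    groups above the ``min_group_n`` floor.

    Returns (per-fold metrics, per-fold fitted trees).  A fold whose
    held-out groups are all eliminated by the group floor gets NaN metrics.
    """
    if group_key_func is None:
        group_key_func = default_group_key
    if len(table) < k:
        raise ValueError("table smaller than k")
    folds = assign_folds(table, k, seed, by_plot=by_plot)
    metrics: list[FitMetrics] = []
    models: list[CTreeModel] = []
    for fold in range(1, k + 1):
        train = table.loc[folds != fold]
        test = table.loc[folds == fold].copy()
        res = MortalityTree(train, covariates=covariates, nominal=nominal,
                            control=control).fit()
        models.append(res.tree)
        if test.empty:
            metrics.append(FitMetrics(*(float("nan"),) * 4, 0,
                                      res.n_inner, res.n_terminal))
            continue
        test["predicted"] = res.predict(test)
        test["group_key"] = group_key_func(test)
        grouped = group_rates(test, ["group_key"], min_n=min_group_n)
        if len(grouped) < 2:
            metrics.append(FitMetrics(*(float("nan"),) * 4, len(grouped),
                                      res.n_inner, res.n_terminal))
            continue
        pred_by_group = (test.groupby("group_key")["predicted"].mean())
        grouped["predicted"] = grouped["group_key"].map(pred_by_group)
        metrics.append(fit_metrics(grouped["rate_5yr"], grouped["predicted"],
                                   weights=grouped["n_start"],
                                   n_inner=res.n_inner,
                                   n_terminal=res.n_terminal))
    return metrics, models


def cv_predict(table: pd.DataFrame, k: int = 5, seed: int = 0,
               control: CTreeControl | None = None,
               covariates: list[str] | None = None,
               nominal: list[str] | None = None,
               by_plot: bool = True) -> np.ndarray:
    """Out-of-fold predicted five-year rates for every record.

    Each record is predicted by the tree fitted on the k-1 folds that do
    not contain it, so the returned vector is a genuinely held-out
    prediction for the whole table — the natural input for pooled
    observed-vs-predicted evaluation on grouped rates.
    """
    folds = assign_folds(table, k, seed, by_plot=by_plot)
    out = np.full(len(table), np.nan)
    for fold in np.unique(folds):
        train = table.loc[folds != fold]
        test = table.loc[folds == fold]
        if test.empty:
            continue
        res = MortalityTree(train, covariates=covariates, nominal=nominal,
                            control=control).fit()
        out[folds == fold] = res.predict(test)
    return out


def _split_sequence(model: CTreeModel, depth_limit: int) -> list[list[tuple]]:
    """Per-depth list of (variable, split-form) pairs down to depth_limit."""
    by_depth: list[list[tuple]] = [[] for _ in range(depth_limit)]

    def walk(nid: int, depth: int) -> None:
        node = model.nodes[nid]
        if not isinstance(node, _ctree.SplitNode) or depth >= depth_limit:
            return
        form = (node.threshold if node.kind == "ordered"
                else tuple(sorted(map(str, node.left_levels))))
        by_depth[depth].append((node.var, form))
        walk(node.left_id, depth + 1)
        walk(node.right_id, depth + 1)

    walk(model.root_id, 0)
    return by_depth


def node_stability(models: list[CTreeModel], depth_limit: int = 4,
                   rel_tol: float = 0.10) -> pd.DataFrame:
    """Cross-model agreement of split variables by depth.

    For each depth below ``depth_limit``, reports the split variables used
    by every model and whether all models share the same variable set at
    that depth; ordered thresholds of shared variables are compared with
    relative tolerance ``rel_tol``.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    seqs = [_split_sequence(m, depth_limit) for m in models]
    rows = []
    for depth in range(depth_limit):
        var_sets = [sorted({v for v, _ in s[depth]}) for s in seqs]
        vars_agree = all(vs == var_sets[0] for vs in var_sets)
        thr_agree = vars_agree
        if vars_agree and var_sets[0]:
            for var in var_sets[0]:
                thr_lists = []
                for s in seqs:
                    thr = sorted(f for v, f in s[depth]
                                 if v == var and isinstance(f, float))
                    thr_lists.append(thr)
                if any(len(t) != len(thr_lists[0]) for t in thr_lists):
                    thr_agree = False
                    continue
                for t in thr_lists[1:]:
                    for a, b in zip(thr_lists[0], t):
                        denom = max(abs(a), abs(b), 1e-12)
                        if abs(a - b) / denom > rel_tol:
                            thr_agree = False
        rows.append({"depth": depth + 1,
                     "variables": [";".join(vs) for vs in var_sets],
                     "variables_agree": vars_agree,
                     "thresholds_agree": thr_agree})
    return pd.DataFrame(rows)
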