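"""Conditional inference tree (CTREE) learner, built from first principles.

Recursive binary partitioning in which both variable selection and
stopping are governed by permutation-test p-values:

1. At each node, the association between every candidate covariate and the
   response is measured by a linear statistic ``T = Σ_i w_i g(x_i) h(y_i)``
   whose null distribution under random permutation of the response has
   closed-form conditional mean and covariance (Strasser–Weber moments).
2. Each covariate's p-value is Bonferroni-adjusted by the number of
   candidates; the node splits on the covariate with the smallest adjusted
   p-value, provided it is below ``alpha`` — otherwise the node is terminal.
   This stopping rule is the tree's only pruning and avoids the variable
   selection bias of exhaustive-search trees such as CART.
3. The split point maximises the standardised two-sample statistic over
   admissible cutpoints (ordered covariates) or level subsets (nominal
   covariates).

Terminal nodes store death counts; their mortality proportion is the
model's predicted rate, optionally standardised to a five-year period from
mixed 3/5-year remeasurement records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import pinvh

from .response import pooled_five_year_rate

__all__ = [
    "CTreeControl", "CovariateSchema", "SplitNode", "TerminalNode",
    "CTreeModel", "linear_statistic", "test_pvalue", "select_variable",
    "best_split", "grow", "predict_rate",
]


# ---------------------------------------------------------------------------
# Control parameters and schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CTreeControl:
    """Hyper-parameters of the tree learner.

    alpha : significance level for the (Bonferroni-adjusted) split test.
    test_stat : "quadratic" (chi-squared reference on the quadratic form,
        the default) or "maximum" (max standardised coordinate with a
        normal reference and coordinate-count Bonferroni).
    min_split : smallest node eligible for splitting.
    min_bucket : smallest admissible child node.
    max_depth : optional depth cap (root has depth 0).
    nominal_exhaustive_max_levels : nominal covariates with at most this
        many levels are split by exhaustive subset search; beyond it,
        levels are ordered by mean response and scanned as ordered (exact
        for a binary response).
    score : "identity" scores ordered covariates on their observed values;
        "rank" uses mid-ranks instead.
    """

    alpha: float = 0.05
    test_stat: str = "quadratic"
    min_split: int = 20
    min_bucket: int = 7
    max_depth: Optional[int] = None
    nominal_exhaustive_max_levels: int = 10
    score: str = "identity"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.test_stat not in ("quadratic", "maximum"):
            raise ValueError("test_stat must be 'quadratic' or 'maximum'")
        if self.min_bucket < 1:
            raise ValueError("min_bucket must be >= 1")
        if self.min_split < 2 * self.min_bucket:
            raise ValueError("min_split must be >= 2 * min_bucket")
        if self.score not in ("identity", "rank"):
            raise ValueError("score must be 'identity' or 'rank'")


@dataclass(frozen=True)
class CovariateSchema:
    """Declares each covariate ordered or nominal (with its level list)."""

    names: tuple
    kinds: dict            # name -> "ordered" | "nominal"
    levels: dict           # name -> tuple of levels (nominal only)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariates: list[str],
                       nominal: list[str] | None = None) -> "CovariateSchema":
        nominal = set(nominal or [])
        unknown = nominal - set(covariates)
        if unknown:
            raise ValueError(f"nominal covariates not in covariate list: {unknown}")
        kinds, levels = {}, {}
        for name in covariates:
            if name in nominal or df[name].dtype == object or isinstance(
                    df[name].dtype, pd.CategoricalDtype):
                kinds[name] = "nominal"
                levels[name] = tuple(sorted(pd.unique(df[name].astype(str))))
            else:
                kinds[name] = "ordered"
        return cls(names=tuple(covariates), kinds=kinds, levels=levels)


# ---------------------------------------------------------------------------
# Node types
# ---------------------------------------------------------------------------

@dataclass
class SplitNode:
    node_id: int
    var: str
    kind: str                                   # "ordered" | "nominal"
    threshold: Optional[float] = None           # ordered split
    left_levels: Optional[tuple] = None         # nominal split (left child)
    raw_p: float = np.nan
    adj_p: float = np.nan
    statistic: float = np.nan
    left_id: int = -1
    right_id: int = -1


@dataclass
class TerminalNode:
    node_id: int
    n_records: int
    n_dead: int
    rate_5yr: float                             # interval-standardised

    @property
    def proportion(self) -> float:
        """Raw death proportion in the node: exact ratio of stored counts."""
        return self.n_dead / self.n_records


@dataclass
class CTreeModel:
    """A fitted conditional inference tree."""

    control: CTreeControl
    schema: CovariateSchema
    nodes: dict = field(default_factory=dict)   # node_id -> node
    root_id: int = 1
    unseen_level_log: list = field(default_factory=list)

    @property
    def inner_nodes(self) -> list[SplitNode]:
        return [n for n in self.nodes.values() if isinstance(n, SplitNode)]

    @property
    def terminal_nodes(self) -> list[TerminalNode]:
        return [n for n in self.nodes.values() if isinstance(n, TerminalNode)]

    @property
    def n_inner(self) -> int:
        return len(self.inner_nodes)

    @property
    def n_terminal(self) -> int:
        return len(self.terminal_nodes)

    def depth_of(self, node_id: int) -> int:
        depth = {self.root_id: 0}
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            if isinstance(node, SplitNode):
                for child in (node.left_id, node.right_id):
                    depth[child] = depth[nid] + 1
                    stack.append(child)
        return depth[node_id]

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        nodes = {}
        for nid, node in self.nodes.items():
            if isinstance(node, SplitNode):
                nodes[str(nid)] = {
                    "type": "split", "var": node.var, "kind": node.kind,
                    "threshold": node.threshold,
                    "left_levels": list(node.left_levels or []) or None,
                    "raw_p": node.raw_p, "adj_p": node.adj_p,
                    "statistic": node.statistic,
                    "left_id": node.left_id, "right_id": node.right_id,
                }
            else:
                nodes[str(nid)] = {
                    "type": "terminal", "n_records": node.n_records,
                    "n_dead": node.n_dead, "rate_5yr": node.rate_5yr,
                }
        return {
            "control": {
                "alpha": self.control.alpha,
                "test_stat": self.control.test_stat,
                "min_split": self.control.min_split,
                "min_bucket": self.control.min_bucket,
                "max_depth": self.control.max_depth,
                "nominal_exhaustive_max_levels":
                    self.control.nominal_exhaustive_max_levels,
                "score": self.control.score,
            },
            "schema": {
                "names": list(self.schema.names),
                "kinds": dict(self.schema.kinds),
                "levels": {k: list(v) for k, v in self.schema.levels.items()},
            },
            "root_id": self.root_id,
            "nodes": nodes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CTreeModel":
        control = CTreeControl(**d["control"])
        schema = CovariateSchema(
            names=tuple(d["schema"]["names"]),
            kinds=dict(d["schema"]["kinds"]),
            levels={k: tuple(v) for k, v in d["schema"]["levels"].items()},
        )
        nodes: dict = {}
        for nid_s, nd in d["nodes"].items():
            nid = int(nid_s)
            if nd["type"] == "split":
                nodes[nid] = SplitNode(
                    node_id=nid, var=nd["var"], kind=nd["kind"],
                    threshold=nd["threshold"],
                    left_levels=tuple(nd["left_levels"])
                    if nd["left_levels"] else None,
                    raw_p=nd["raw_p"], adj_p=nd["adj_p"],
                    statistic=nd["statistic"],
                    left_id=nd["left_id"], right_id=nd["right_id"],
                )
            else:
                nodes[nid] = TerminalNode(
                    node_id=nid, n_records=nd["n_records"],
                    n_dead=nd["n_dead"], rate_5yr=nd["rate_5yr"])
        return cls(control=control, schema=schema, nodes=nodes,
                   root_id=d["root_id"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CTreeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- rendering ----------------------------------------------------------

    def render(self) -> str:
        """Text rendering of the tree (N1, N2, ... node notation)."""
        lines: list[str] = []

        def walk(nid: int, indent: int, label: str) -> None:
            node = self.nodes[nid]
            pad = "  " * indent
            if isinstance(node, SplitNode):
                if node.kind == "ordered":
                    desc = f"{node.var} <= {node.threshold:.4g}"
                else:
                    desc = f"{node.var} in {{{', '.join(map(str, node.left_levels))}}}"
                lines.append(f"{pad}[N{nid}]{label} split: {desc} "
                             f"(adj p = {node.adj_p:.3g})")
                walk(node.left_id, indent + 1, " yes")
                walk(node.right_id, indent + 1, " no")
            else:
                lines.append(
                    f"{pad}[N{nid}]{label} terminal: n = {node.n_records}, "
                    f"dead = {node.n_dead}, "
                    f"mortality = {node.proportion:.3f} "
                    f"(5-yr rate = {node.rate_5yr:.3f})")

        walk(self.root_id, 0, "")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Permutation-test machinery
# ---------------------------------------------------------------------------

def _scores(x: np.ndarray, kind: str, levels, control: CTreeControl
            ) -> np.ndarray:
    """Transformation g(x): (n, p) score matrix."""
    if kind == "ordered":
        x = np.asarray(x, dtype=float)
        if control.score == "rank":
            g = stats.rankdata(x, method="average")
        else:
            g = x
        return g.reshape(-1, 1)
    # nominal: one-hot over the declared level order
    codes = _nominal_codes(x, levels)
    g = np.zeros((len(codes), len(levels)))
    g[np.arange(len(codes)), codes] = 1.0
    return g


def _nominal_codes(x, levels) -> np.ndarray:
    lookup = {lev: i for i, lev in enumerate(levels)}
    try:
        return np.array([lookup[str(v)] for v in x], dtype=int)
    except KeyError as exc:
        raise KeyError(f"level {exc} not in declared levels {levels}") from exc


def linear_statistic(g: np.ndarray, h: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear association statistic with its permutation-null moments.

    Parameters
    ----------
    g : (n, p) score matrix of the covariate transformation.
    h : (n,) influence values of the response.
    weights : optional non-negative case weights (default: all one).

    Returns
    -------
    (T, mu, Sigma) : the p-vector statistic ``T = Σ w_i g_i h_i`` and its
    conditional expectation and covariance under random permutation of the
    response against the covariate, by the closed-form moment formulas

        mu    = (Σ w g) * E(h)
        Sigma = V(h) * [ w./(w.-1) Σ w g gᵀ  -  1/(w.-1) (Σ w g)(Σ w g)ᵀ ]

    with E(h), V(h) the weighted response mean and variance and
    ``w. = Σ w``.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    if g.shape[0] == 1 and g.shape[1] > 1:
        g = g.T
    h = np.asarray(h, dtype=float).ravel()
    n = h.shape[0]
    if g.shape[0] != n:
        raise ValueError("g and h disagree on the number of observations")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w_tot = w.sum()
    if w_tot < 2:
        raise ValueError("need total weight >= 2")

    wg = g * w[:, None]
    T = wg.T @ h                       # (p,)
    g1 = wg.sum(axis=0)                # Σ w g
    eh = float((w * h).sum() / w_tot)
    vh = float((w * h**2).sum() / w_tot - eh**2)
    mu = g1 * eh
    g2 = wg.T @ g                      # Σ w g gᵀ
    sigma = vh * (w_tot / (w_tot - 1.0) * g2
                  - np.outer(g1, g1) / (w_tot - 1.0))
    return T, mu, sigma


def test_pvalue(T: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                test_stat: str = "quadratic") -> tuple[float, float]:
    """p-value of the permutation test from the statistic and its moments.

    quadratic : ``c = (T-mu)ᵀ Σ⁺ (T-mu)`` referred to chi-squared with
        rank(Σ) degrees of freedom (Moore–Penrose inverse).
    maximum : max standardised coordinate referred to the standard normal,
        Bonferroni-corrected by the number of non-degenerate coordinates.

    Returns (p, statistic).  A zero-rank covariance gives p = 1.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    d = T - mu
    diag = np.diag(sigma)
    scale = float(diag.max()) if diag.size else 0.0
    if scale <= 0.0 or not np.isfinite(scale):
        return 1.0, 0.0
    if test_stat == "quadratic":
        # rank via eigenvalues relative to the largest
        evals = np.linalg.eigvalsh(sigma)
        tol = max(sigma.shape) * np.finfo(float).eps * max(evals.max(), 0.0)
        rank = int((evals > tol).sum())
        if rank == 0:
            return 1.0, 0.0
        c = float(d @ pinvh(sigma) @ d)
        c = max(c, 0.0)
        return float(stats.chi2.sf(c, df=rank)), c
    if test_stat == "maximum":
        ok = diag > 0
        if not ok.any():
            return 1.0, 0.0
        z = np.abs(d[ok]) / np.sqrt(diag[ok])
        c = float(z.max())
        k = int(ok.sum())
        return float(min(1.0, k * 2.0 * stats.norm.sf(c))), c
    raise ValueError(f"unknown test_stat {test_stat!r}")


def _covariate_pvalue(x, kind, levels, h, control: CTreeControl
                      ) -> tuple[float, float]:
    """Raw p-value and statistic for one covariate at a node."""
    h = np.asarray(h, dtype=float)
    if np.unique(h).size < 2:
        return 1.0, 0.0
    if kind == "ordered":
        if np.unique(np.asarray(x, dtype=float)).size < 2:
            return 1.0, 0.0
    else:
        if np.unique(np.asarray(x)).size < 2:
            return 1.0, 0.0
    g = _scores(x, kind, levels, control)
    T, mu, sigma = linear_statistic(g, h)
    return test_pvalue(T, mu, sigma, control.test_stat)


def select_variable(X: dict, h: np.ndarray, schema: CovariateSchema,
                    control: CTreeControl
                    ) -> Optional[tuple[str, float, float]]:
    """Bonferroni-adjusted variable selection at one node.

    Parameters
    ----------
    X : mapping covariate name -> value array for the node's records.
    h : response influence values (death indicator).

    Returns
    -------
    (variable name, adjusted p, raw p) for the covariate minimising the
    adjusted p-value, or None when no adjusted p-value is below ``alpha``
    (the node becomes terminal).  Ties in adjusted p are broken by the
    larger test statistic, then by schema order.
    """
    m = len(schema.names)
    best = None
    for order, name in enumerate(schema.names):
        raw, stat = _covariate_pvalue(
            X[name], schema.kinds[name], schema.levels.get(name), h, control)
        adj = min(1.0, m * raw)
        key = (adj, -stat, order)
        if best is None or key < best[0]:
            best = (key, name, adj, raw)
    if best is None or best[2] >= control.alpha:
        return None
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------

def _ordered_split_scan(x: np.ndarray, h: np.ndarray, min_bucket: int
                        ) -> Optional[tuple[float, float]]:
    """Best threshold on an ordered covariate.

    Maximises |T - mu| / sd of the two-sample linear statistic over all
    cutpoints between adjacent distinct values, subject to both children
    holding at least ``min_bucket`` records.  Returns (threshold, statistic)
    with the threshold at the midpoint of the straddling observed values.
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    n = x.shape[0]
    order = np.argsort(x, kind="mergesort")
    xs, hs = x[order], h[order]
    csum = np.cumsum(hs)
    hbar = csum[-1] / n
    vh = float(np.mean(hs**2) - hbar**2)
    if vh <= 0:
        return None
    k = np.arange(1, n)                      # left-child sizes
    # admissible cuts: between distinct values, respecting min_bucket
    distinct = xs[1:] > xs[:-1]
    ok = distinct & (k >= min_bucket) & (n - k >= min_bucket)
    if not ok.any():
        return None
    T = csum[:-1]
    mu = k * hbar
    var = vh * k * (n - k) / (n - 1.0)
    z = np.abs(T - mu) / np.sqrt(var)
    z = np.where(ok, z, -np.inf)
    best = int(np.argmax(z))
    threshold = 0.5 * (xs[best] + xs[best + 1])
    return float(threshold), float(z[best])


def _two_sample_z(n_left: int, sum_left: float, n: int, sum_all: float,
                  vh: float) -> float:
    hbar = sum_all / n
    var = vh * n_left * (n - n_left) / (n - 1.0)
    if var <= 0:
        return -np.inf
    return abs(sum_left - n_left * hbar) / np.sqrt(var)


def best_split(x, h, kind: str, levels, control: CTreeControl
               ) -> Optional[Union[float, tuple]]:
    """Best binary split on an already-selected covariate.

    Ordered: the threshold (midpoint between adjacent observed values)
    maximising the standardised two-sample statistic.  Nominal: the binary
    level subset maximising the same statistic — exhaustive over
    ``2^(L-1) - 1`` subsets when the node's observed level count L is at
    most ``nominal_exhaustive_max_levels``, otherwise levels are ordered by
    mean response and scanned as an ordered variable (exact for a binary
    response).

    Returns a float threshold (ordered), a tuple of left-child levels
    (nominal), or None when no admissible split respects ``min_bucket``.
    """
    h = np.asarray(h, dtype=float)
    if kind == "ordered":
        res = _ordered_split_scan(np.asarray(x, dtype=float), h,
                                  control.min_bucket)
        return None if res is None else res[0]

    codes = _nominal_codes(x, levels)
    n = codes.shape[0]
    counts = np.bincount(codes, minlength=len(levels))
    sums = np.bincount(codes, weights=h, minlength=len(levels))
    present = np.flatnonzero(counts)
    if present.size < 2:
        return None
    sum_all = float(h.sum())
    vh = float(np.mean(h**2) - (sum_all / n) ** 2)
    if vh <= 0:
        return None

    if present.size <= control.nominal_exhaustive_max_levels:
        # exhaustive: subsets of present levels never containing the last
        # present level (avoids complement duplicates)
        best_z, best_subset = -np.inf, None
        pool = list(present[:-1])
        for r in range(1, len(pool) + 1):
            for subset in combinations(pool, r):
                idx = np.array(subset)
                n_left = int(counts[idx].sum())
                if n_left < control.min_bucket or n - n_left < control.min_bucket:
                    continue
                z = _two_sample_z(n_left, float(sums[idx].sum()), n,
                                  sum_all, vh)
                if z > best_z:
                    best_z, best_subset = z, idx
        if best_subset is None:
            return None
        return tuple(levels[i] for i in best_subset)

    # many levels: order by mean response, scan as ordered
    means = sums[present] / counts[present]
    ordering = present[np.argsort(means, kind="mergesort")]
    cum_n = np.cumsum(counts[ordering])
    cum_s = np.cumsum(sums[ordering])
    best_z, best_k = -np.inf, None
    for k in range(1, ordering.size):
        n_left = int(cum_n[k - 1])
        if n_left < control.min_bucket or n - n_left < control.min_bucket:
            continue
        z = _two_sample_z(n_left, float(cum_s[k - 1]), n, sum_all, vh)
        if z > best_z:
            best_z, best_k = z, k
    if best_k is None:
        return None
    return tuple(levels[i] for i in sorted(ordering[:best_k]))


# ---------------------------------------------------------------------------
# Tree growth and prediction
# ---------------------------------------------------------------------------

def grow(table: pd.DataFrame, schema: CovariateSchema,
         control: CTreeControl | None = None,
         outcome_col: str = "outcome",
         interval_col: str | None = "interval_years") -> CTreeModel:
    """Fit a conditional inference tree on record-level survival outcomes.

    Parameters
    ----------
    table : model table; ``outcome_col`` codes 1 = alive, 0 = died.
    schema : covariate declaration (ordered / nominal with levels).
    interval_col : optional column of remeasurement lengths (years) used to
        standardise terminal-node rates to five years; when absent the raw
        proportion is stored.

    Returns
    -------
    CTreeModel with pre-order node numbering (root = N1).
    """
    control = control or CTreeControl()
    if table.empty:
        raise ValueError("empty model table")
    for name in schema.names:
        if table[name].isna().any():
            raise ValueError(f"missing values in covariate {name!r}")
    died = (table[outcome_col].to_numpy() == 0).astype(float)
    X = {}
    for name in schema.names:
        if schema.kinds[name] == "ordered":
            X[name] = table[name].to_numpy(dtype=float)
        else:
            X[name] = table[name].astype(str).to_numpy()
    intervals = (table[interval_col].to_numpy(dtype=float)
                 if interval_col and interval_col in table.columns else None)

    model = CTreeModel(control=control, schema=schema)
    counter = {"next": 1}

    def make_terminal(idx: np.ndarray) -> TerminalNode:
        nid = counter["next"]
        counter["next"] += 1
        n = idx.size
        n_dead = int(died[idx].sum())
        if intervals is not None and n > 0:
            rate = pooled_five_year_rate(1.0 - died[idx], intervals[idx])
        else:
            rate = n_dead / n
        node = TerminalNode(node_id=nid, n_records=n, n_dead=n_dead,
                            rate_5yr=rate)
        model.nodes[nid] = node
        return node

    def build(idx: np.ndarray, depth: int) -> int:
        n = idx.size
        h = died[idx]
        stop = (
            n < control.min_split
            or (control.max_depth is not None and depth >= control.max_depth)
            or np.unique(h).size < 2
        )
        selection = None
        if not stop:
            Xn = {name: X[name][idx] for name in schema.names}
            selection = select_variable(Xn, h, schema, control)
        if selection is None:
            return make_terminal(idx).node_id
        var, adj_p, raw_p = selection
        kind = schema.kinds[var]
        split = best_split(X[var][idx], h, kind,
                           schema.levels.get(var), control)
        if split is None:
            return make_terminal(idx).node_id
        nid = counter["next"]
        counter["next"] += 1
        if kind == "ordered":
            go_left = X[var][idx] <= split
            node = SplitNode(node_id=nid, var=var, kind=kind,
                             threshold=float(split),
                             raw_p=raw_p, adj_p=adj_p)
        else:
            left_set = set(split)
            go_left = np.array([v in left_set for v in X[var][idx]])
            node = SplitNode(node_id=nid, var=var, kind=kind,
                             left_levels=tuple(split),
                             raw_p=raw_p, adj_p=adj_p)
        _, stat = _covariate_pvalue(X[var][idx], kind,
                                    schema.levels.get(var), h, control)
        node.statistic = stat
        model.nodes[nid] = node
        node.left_id = build(idx[go_left], depth + 1)
        node.right_id = build(idx[~go_left], depth + 1)
        return nid

    model.root_id = build(np.arange(len(table)), 0)
    return model


def _route(model: CTreeModel, row: dict) -> TerminalNode:
    nid = model.root_id
    while True:
        node = model.nodes[nid]
        if isinstance(node, TerminalNode):
            return node
        val = row[node.var]
        if pd.isna(val):
            raise ValueError(
                f"missing value for {node.var!r} while routing a record")
        if node.kind == "ordered":
            nid = node.left_id if float(val) <= node.threshold else node.right_id
        else:
            sval = str(val)
            if sval in model.schema.levels[node.var]:
                nid = (node.left_id if sval in node.left_levels
                       else node.right_id)
            else:
                # unseen level: follow the majority child and log it
                left_n = _subtree_n(model, node.left_id)
                right_n = _subtree_n(model, node.right_id)
                model.unseen_level_log.append(
                    {"var": node.var, "level": sval, "node_id": node.node_id})
                nid = node.left_id if left_n >= right_n else node.right_id


def _subtree_n(model: CTreeModel, nid: int) -> int:
    node = model.nodes[nid]
    if isinstance(node, TerminalNode):
        return node.n_records
    return _subtree_n(model, node.left_id) + _subtree_n(model, node.right_id)


def predict_rate(model: CTreeModel, rows: pd.DataFrame) -> np.ndarray:
    """Predicted five-year mortality rate for each row (terminal-node rate)."""
    missing = [c for c in model.schema.names if c not in rows.columns]
    if missing:
        raise ValueError(f"rows lack covariate column(s) {missing}")
    out = np.empty(len(rows))
    recs = rows[list(model.schema.names)].to_dict("records")
    for i, row in enumerate(recs):
        out[i] = _route(model, row).rate_5yr
    return out


def predict_node(model: CTreeModel, rows: pd.DataFrame) -> np.ndarray:
    """Terminal node id for each row."""
    recs = rows[list(model.schema.names)].to_dict("records")
    return np.array([_route(model, row).node_id for row in recs], dtype=int)
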