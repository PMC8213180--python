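"""Model / results interface for the mortality tree.

``MortalityTree`` wraps the conditional-inference-tree learner in the
model-object idiom: construct from a model table, call :meth:`fit`, and
work with the returned :class:`MortalityTreeResults` (predictions, node
table, text summary, serialisation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ctree as _ctree
from .ctree import CovariateSchema, CTreeControl, CTreeModel

DEFAULT_COVARIATES = ["delta_ba", "species", "age_class", "bal", "gdd",
                      "pcp", "ins", "slp", "erd"]
DEFAULT_NOMINAL = ["species", "age_class"]


class MortalityTree:
    """Conditional-inference-tree model of tree mortality rates.

    Parameters
    ----------
    data : model table with one row per tree-interval, an outcome column
        (1 = alive at interval end, 0 = died) and the covariate columns.
    covariates : covariate names; defaults to the standard nine-variable
        set (ΔBA, SP, AGE, BAL, GDD, PCP, INS, SLP, ERD) restricted to the
        columns present.
    nominal : which covariates are nominal; the rest are treated as
        ordered numeric.
    outcome : outcome column name.
    interval : column of interval lengths in years, used to standardise
        node rates to a five-year period (optional).
    control : tree hyper-parameters (:class:`CTreeControl`).

    Examples
    --------
    >>> model = MortalityTree(table, control=CTreeControl(alpha=0.05))
    >>> res = model.fit()
    >>> res.predict(new_rows)
    """

    def __init__(self, data: pd.DataFrame,
                 covariates: list[str] | None = None,
                 nominal: list[str] | None = None,
                 outcome: str = "outcome",
                 interval: str | None = "interval_years",
                 control: CTreeControl | None = None):
        if covariates is None:
            covariates = [c for c in DEFAULT_COVARIATES if c in data.columns]
            if not covariates:
                raise ValueError("no recognised covariate columns; pass "
                                 "covariates= explicitly")
        if nominal is None:
            nominal = [c for c in DEFAULT_NOMINAL if c in covariates]
        missing = [c for c in covariates + [outcome] if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks column(s) {missing}")
        self.data = data.reset_index(drop=True)
        self.covariates = list(covariates)
        self.nominal = list(nominal)
        self.outcome = outcome
        self.interval = interval if interval in data.columns else None
        self.control = control or CTreeControl()
        self.schema = CovariateSchema.from_dataframe(
            self.data, self.covariates, self.nominal)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "MortalityTree":
        return cls(data, **kwargs)

    def fit(self) -> "MortalityTreeResults":
        tree = _ctree.grow(self.data, self.schema, self.control,
                           outcome_col=self.outcome,
                           interval_col=self.interval)
        return MortalityTreeResults(self, tree)


class MortalityTreeResults:
    """Fitted mortality tree: node estimates, diagnostics, prediction."""

    def __init__(self, model: MortalityTree | None, tree: CTreeModel):
        self.model = model
        self.tree = tree

    # -- estimates ----------------------------------------------------------

    @property
    def n_inner(self) -> int:
        return self.tree.n_inner

    @property
    def n_terminal(self) -> int:
        return self.tree.n_terminal

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Five-year mortality rate for each row (its terminal-node rate)."""
        return _ctree.predict_rate(self.tree, rows)

    def predict_node(self, rows: pd.DataFrame) -> np.ndarray:
        return _ctree.predict_node(self.tree, rows)

    def node_table(self) -> pd.DataFrame:
        """One row per node: splits with p-values, terminals with rates."""
        rows = []
        for nid in sorted(self.tree.nodes):
            node = self.tree.nodes[nid]
            if isinstance(node, _ctree.SplitNode):
                if node.kind == "ordered":
                    form = f"{node.var} <= {node.threshold:.6g}"
                else:
                    form = (f"{node.var} in "
                            f"{{{','.join(map(str, node.left_levels))}}}")
                rows.append({"node": nid, "type": "inner", "split": form,
                             "raw_p": node.raw_p, "adj_p": node.adj_p,
                             "n": np.nan, "n_dead": np.nan,
                             "mortality": np.nan, "rate_5yr": np.nan})
            else:
                rows.append({"node": nid, "type": "terminal", "split": "",
                             "raw_p": np.nan, "adj_p": np.nan,
                             "n": node.n_records, "n_dead": node.n_dead,
                             "mortality": node.proportion,
                             "rate_5yr": node.rate_5yr})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        terminals = self.tree.terminal_nodes
        n_total = sum(t.n_records for t in terminals)
        n_dead = sum(t.n_dead for t in terminals)
        lines = [
            "Mortality conditional inference tree",
            "=" * 52,
            f"Records:              {n_total}",
            f"Deaths:               {n_dead} "
            f"({n_dead / n_total:.3%} of records)" if n_total else "Deaths: 0",
            f"Inner nodes:          {self.n_inner}",
            f"Terminal nodes:       {self.n_terminal}",
            f"alpha:                {self.tree.control.alpha}",
            f"Test statistic:       {self.tree.control.test_stat}",
            f"min_split/min_bucket: {self.tree.control.min_split}/"
            f"{self.tree.control.min_bucket}",
            "-" * 52,
            self.tree.render(),
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        self.tree.to_json(path)

    @classmethod
    def load(cls, path) -> "MortalityTreeResults":
        return cls(model=None, tree=CTreeModel.from_json(path))
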