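"""Evaluation primitives: average precision, AP tables, tests, correlations.

Average precision is the primary metric because it resists class imbalance
and needs no decision threshold — AUROC inflates badly when negatives
dominate, which is the norm for tail classes. The AP here is the
non-interpolated step-wise variant with tied scores processed as a single
threshold group, so it is invariant to the ordering of tied samples.

A class with zero positives has no defined AP; such entries carry an
undefined marker (NaN) and are excluded from means rather than imputed,
since imputing 0 would fabricate forgetting signal for empty classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import RunPopulation
from .prune import SparsityGrid

__all__ = [
    "APTable",
    "average_precision",
    "build_ap_table",
    "mean_ap",
    "welch_t_test",
    "pearson",
    "spearman",
    "percentile",
]

UNDEFINED = float("nan")


@dataclass
class APTable:
    """AP over (run, sparsity, class): the substrate of every class-level analysis."""

    values: np.ndarray  # (R, K, C), NaN where undefined
    grid: SparsityGrid
    class_names: list[str]
    run_seeds: list[int] = field(default_factory=list)

    def __post_init__(self):
        R, K, C = self.values.shape
        if K != len(self.grid) or C != len(self.class_names):
            raise ValueError("table shape inconsistent with grid/class_names")
        defined = self.values[~np.isnan(self.values)]
        if defined.size and (defined.min() < 0 or defined.max() > 1):
            raise ValueError("defined AP entries must lie in [0, 1]")

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    def k_index(self, k: float) -> int:
        try:
            return self.grid.values.index(float(k))
        except ValueError:
            raise KeyError(f"sparsity {k} not in grid {self.grid.values}") from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format (run, sparsity, class, ap) interchange table."""
        R, K, C = self.values.shape
        runs, ks, cs = np.meshgrid(np.arange(R), np.arange(K), np.arange(C), indexing="ij")
        return pd.DataFrame(
            {
                "run": runs.ravel(),
                "sparsity": np.asarray(self.grid.values)[ks.ravel()],
                "class": np.asarray(self.class_names, dtype=object)[cs.ravel()],
                "ap": self.values.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, run_seeds=None) -> "APTable":
        grid = SparsityGrid(sorted(frame["sparsity"].unique()))
        classes = list(dict.fromkeys(frame["class"]))
        runs = sorted(frame["run"].unique())
        values = np.full((len(runs), len(grid), len(classes)), np.nan)
        kidx = {k: i for i, k in enumerate(grid.values)}
        cidx = {c: i for i, c in enumerate(classes)}
        ridx = {r: i for i, r in enumerate(runs)}
        cols = frame[["run", "sparsity", "class", "ap"]]
        for r, k, c, ap in cols.itertuples(index=False, name=None):
            values[ridx[r], kidx[float(k)], cidx[c]] = ap
        return cls(values, grid, classes, list(run_seeds or []))


def average_precision(scores, labels) -> float:
    """Non-interpolated AP with tied-score grouping.

    Samples are sorted by descending score; each distinct score value forms
    one threshold group, and AP accumulates (recall increment) x (precision
    at the group's cut). Returns NaN (undefined) when there are no positive
    labels, so table assembly can proceed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d and equally long")
    n_pos = int(labels.sum())
    if n_pos == 0:
        return UNDEFINED
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # inclusive end index of each tied-score group
    ends = np.flatnonzero(np.diff(s))
    ends = np.append(ends, s.size - 1)
    tp = np.cumsum(y)[ends]
    precision = tp / (ends + 1)
    recall = tp / n_pos
    d_recall = np.diff(recall, prepend=0.0)
    return float(np.sum(d_recall * precision))


def build_ap_table(pop: RunPopulation, labels: np.ndarray, run_seeds=None) -> APTable:
    """One AP per (run, grid value, class) from population test predictions.

    ``labels`` is the N x C binary test-label matrix in the population's
    row order (all population entries are checked to share that order).
    """
    grid = SparsityGrid(pop.grid)
    labels = np.asarray(labels)
    R = pop.n_runs
    C = labels.shape[1]
    values = np.full((R, len(grid), C), np.nan)
    for (i, k), pm in pop.predictions.items():
        if pm.scores.shape != labels.shape:
            raise ValueError(
                f"prediction shape {pm.scores.shape} does not match labels {labels.shape}"
            )
        ki = grid.values.index(float(k))
        for c in range(C):
            values[i, ki, c] = average_precision(pm.scores[:, c], labels[:, c])
    names = pop.class_names or [f"class_{c:02d}" for c in range(C)]
    return APTable(values, grid, list(names), list(run_seeds or pop.seeds))


def mean_ap(table: APTable, run: int, k: float) -> float:
    """Arithmetic mean AP over classes with defined AP for one (run, k)."""
    row = table.values[run, table.k_index(k), :]
    defined = row[~np.isnan(row)]
    if defined.size == 0:
        raise ValueError(f"no class has defined AP at run={run}, k={k}")
    return float(defined.mean())


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, two-sided p, df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, float(a.size + b.size - 2)
        raise ValueError("both samples have zero variance; t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p; (NaN, NaN) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return UNDEFINED, UNDEFINED
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties), two-sided p.

    Constant input yields the undefined marker (NaN, NaN) rather than an
    exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return UNDEFINED, UNDEFINED
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile of ``values`` at fraction ``q`` in [0,1]."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if not (0 <= q <= 1):
        raise ValueError("q must lie in [0, 1]")
    return float(np.quantile(values, q, method="linear"))
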