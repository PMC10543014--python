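"""Class-level forgettability analytics.

The forgettability curve of a class is, at each sparsity ratio k, the
median across training runs of the relative change in AP between the
unpruned model and its k-sparse counterpart:

    F_c(k) = med_i { (AP_{i,k,c} - AP_{i,0,c}) / AP_{i,0,c} }

Relative (not absolute) change makes the impact of pruning comparable
across classes of different difficulty, and the median across runs damps
run-to-run variance. Two classes' forgetting behavior is compared via the
Forgettability Curve Dissimilarity (FCD): the mean squared error between
their curves over the grid. Pairwise FCD is then modelled by OLS on the
absolute difference in log class frequency, the fourth root of the pairwise
label IoU, and their interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import statsmodels.api as sm

from .metrics import APTable, spearman
from .prune import SparsityGrid

__all__ = [
    "ForgettabilityCurve",
    "PairStats",
    "RegressionFit",
    "BaselineTooLowError",
    "forgettability_curve",
    "forgettability_curves",
    "fcd",
    "first_forgotten_sparsity",
    "tail_impact",
    "class_covariates",
    "build_pair_stats",
    "fit_fcd_regression",
    "frequency_forgettability_correlation",
    "CENSORED",
]

#: Encoding for a class that never reaches the drop criterion: just above
#: the grid maximum, so robust classes stay in rank correlations instead of
#: being dropped.
CENSORED = 1.0

#: Baseline-AP floor below which relative change is considered ill-defined.
BASELINE_FLOOR = 1e-3


class BaselineTooLowError(ValueError):
    """Median baseline AP below the floor: relative change would blow up."""

    def __init__(self, class_name, baseline, floor):
        self.class_name = class_name
        self.baseline = baseline
        super().__init__(
            f"class {class_name!r}: median baseline AP {baseline:.3g} below floor {floor:g}"
        )


@dataclass
class ForgettabilityCurve:
    class_name: str
    grid: SparsityGrid
    values: np.ndarray  # per-grid-point median relative AP change

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("curve length must match grid")
        if self.values[0] != 0.0:
            raise ValueError("curve must be exactly 0 at k=0")


@dataclass(frozen=True)
class PairStats:
    """Pairwise covariates for the FCD regression (symmetric in the pair)."""

    class_a: str
    class_b: str
    fcd: float
    log_freq_diff: float  # |ln f_a - ln f_b|, natural log
    iou: float

    @property
    def iou_q(self) -> float:
        return self.iou ** 0.25


@dataclass
class RegressionFit:
    """OLS fit of FCD ~ 1 + |LogFreqDiff| + IoU^(1/4) + interaction."""

    beta: np.ndarray  # (4,) intercept, log_freq_diff, iou_q, interaction
    stderr: np.ndarray
    p_values: np.ndarray
    n_pairs: int
    term_names: tuple[str, ...] = (
        "intercept",
        "abs_log_freq_diff",
        "iou_quarter_root",
        "interaction",
    )

    def as_dict(self) -> dict:
        return {
            "terms": list(self.term_names),
            "beta": [float(b) for b in self.beta],
            "stderr": [float(s) for s in self.stderr],
            "p_values": [float(p) for p in self.p_values],
            "n_pairs": int(self.n_pairs),
            "log_base": "e",
        }


def forgettability_curve(table: APTable, c: int | str, floor: float = BASELINE_FLOOR) -> ForgettabilityCurve:
    """Median-across-runs relative AP change for one class over the grid.

    For even run counts the median is the mean of the two middle order
    statistics. The k=0 point is exactly 0 by construction. Raises
    :class:`BaselineTooLowError` when the median unpruned AP is below
    ``floor``; callers assembling many curves should use
    :func:`forgettability_curves`, which converts that into a structured
    warning and exclusion.
    """
    if isinstance(c, str):
        c = table.class_names.index(c)
    name = table.class_names[c]
    ap = table.values[:, :, c]  # (R, K)
    baseline = ap[:, 0]
    if np.all(np.isnan(baseline)):
        raise BaselineTooLowError(name, float("nan"), floor)
    med_base = np.nanmedian(baseline)
    if not (med_base > floor):
        raise BaselineTooLowError(name, med_base, floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = (ap - baseline[:, None]) / baseline[:, None]
        values = np.nanmedian(rel, axis=0)
    values[0] = 0.0
    return ForgettabilityCurve(name, table.grid, values)


def forgettability_curves(table: APTable, floor: float = BASELINE_FLOOR) -> dict[str, ForgettabilityCurve]:
    """All class curves, excluding (with a warning) undefined-baseline classes."""
    curves = {}
    for c, name in enumerate(table.class_names):
        try:
            curves[name] = forgettability_curve(table, c, floor=floor)
        except BaselineTooLowError as exc:
            warnings.warn(f"excluding class from curves: {exc}", UserWarning, stacklevel=2)
    return curves


def fcd(a: ForgettabilityCurve, b: ForgettabilityCurve) -> float:
    """Forgettability Curve Dissimilarity: MSE between two curves."""
    if a.grid.values != b.grid.values:
        raise ValueError("curves must share the sparsity grid")
    return float(np.mean((a.values - b.values) ** 2))


def first_forgotten_sparsity(curve: ForgettabilityCurve, drop: float = 0.20) -> float:
    """Smallest grid k with a median relative drop of at least ``drop``.

    Returns :data:`CENSORED` (1.0, just above the grid maximum) when the
    drop is never reached.
    """
    hit = np.flatnonzero(curve.values <= -drop)
    if hit.size == 0:
        return CENSORED
    return float(curve.grid.values[hit[0]])


def tail_impact(curve: ForgettabilityCurve) -> float:
    """Median relative AP change at the maximum grid sparsity (default 0.95)."""
    return float(curve.values[-1])


def class_covariates(labels: np.ndarray) -> dict:
    """Per-class frequency and pairwise IoU / |log frequency difference|.

    ``labels`` is an N x C binary matrix (typically the test split).
    Classes with zero positives are excluded from log-based quantities
    (their pairwise entries are NaN). Natural log is used.
    """
    labels = np.asarray(labels).astype(bool)
    C = labels.shape[1]
    freq = labels.sum(axis=0).astype(float)
    inter = (labels.T.astype(np.int64) @ labels.astype(np.int64)).astype(float)
    union = freq[:, None] + freq[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / np.maximum(union, 1e-300), np.nan)
        logf = np.where(freq > 0, np.log(np.maximum(freq, 1e-300)), np.nan)
    log_freq_diff = np.abs(logf[:, None] - logf[None, :])
    np.fill_diagonal(iou, 1.0)
    np.fill_diagonal(log_freq_diff, 0.0)
    return {"frequency": freq, "iou": iou, "log_freq_diff": log_freq_diff, "n_classes": C}


def build_pair_stats(curves: dict[str, ForgettabilityCurve], labels: np.ndarray, class_names: list[str]) -> list[PairStats]:
    """Assemble PairStats for every unordered pair of classes with curves.

    Pairs involving a class without a curve (excluded baseline) or with an
    undefined covariate are skipped.
    """
    cov = class_covariates(labels)
    pairs = []
    for a, b in combinations(range(len(class_names)), 2):
        na, nb = class_names[a], class_names[b]
        if na not in curves or nb not in curves:
            continue
        lfd = cov["log_freq_diff"][a, b]
        iou = cov["iou"][a, b]
        if np.isnan(lfd) or np.isnan(iou):
            continue
        pairs.append(PairStats(na, nb, fcd(curves[na], curves[nb]), float(lfd), float(iou)))
    return pairs


def fit_fcd_regression(pairs: list[PairStats]) -> RegressionFit:
    """OLS of FCD on {1, |LogFreqDiff|, IoU^(1/4), interaction}."""
    if len(pairs) < 5:
        raise ValueError("need at least 5 pairs to fit the interaction model")
    x1 = np.array([p.log_freq_diff for p in pairs])
    x2 = np.array([p.iou_q for p in pairs])
    y = np.array([p.fcd for p in pairs])
    X = np.column_stack([np.ones_like(x1), x1, x2, x1 * x2])
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        names = ("intercept", "abs_log_freq_diff", "iou_quarter_root", "interaction")
        raise ValueError(
            f"design matrix rank {rank} < 4; columns {names} are collinear for these pairs"
        )
    fit = sm.OLS(y, X).fit()
    return RegressionFit(
        beta=np.asarray(fit.params),
        stderr=np.asarray(fit.bse),
        p_values=np.asarray(fit.pvalues),
        n_pairs=len(pairs),
    )


def frequency_forgettability_correlation(statistic, frequency) -> tuple[float, float]:
    """Spearman correlation of a per-class statistic against class frequency.

    Censored first-forgotten values (encoded 1.0) are included as-is, so
    robust classes count as "forgotten last".
    """
    statistic = np.asarray(statistic, dtype=float)
    frequency = np.asarray(frequency, dtype=float)
    if statistic.size < 3:
        raise ValueError("need at least 3 classes")
    return spearman(statistic, frequency)
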