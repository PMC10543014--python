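"""Pruning-identified exemplars (PIEs) for multi-label populations.

A PIE is a test image on which the uncompressed and heavily pruned model
populations disagree the most. Agreement for an image is the Spearman rank
correlation between its C class scores under the population-average
unpruned prediction and the population-average prediction at the
comparator sparsity (0.9 by default). Images in the bottom 5% of
agreement are flagged.

"Bottom 5th percentile" is operationalized as a rank rule — exactly
floor(0.05 * N_defined) lowest correlations, ties at the boundary broken
by image index — which guarantees a deterministic, exact flag rate; the
interpolated percentile threshold is still reported for transparency.
Images whose prediction rows are constant (undefined rank correlation) are
excluded from ranking rather than assigned 0, which would force them into
the PIE set artifactually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .classifier import PredictionMatrix, RunPopulation

__all__ = [
    "PIEReport",
    "average_prediction",
    "image_agreement",
    "identify_pies",
    "pie_class_ratio",
    "pie_disease_count_ratio",
    "build_pie_report",
]

COUNT_BUCKETS = ("0", "1", "2", "3", "4+")


@dataclass
class PIEReport:
    per_image_corr: np.ndarray  # (N,), NaN where undefined
    pie_mask: np.ndarray  # (N,) bool
    threshold: float
    class_ratio: np.ndarray  # (C,), NaN where undefined
    count_ratio: dict[str, float]  # bucket -> ratio (NaN where undefined)
    comparator_sparsity: float
    fraction: float


def average_prediction(pop: RunPopulation, k: float) -> PredictionMatrix:
    """Elementwise mean of per-run test predictions at sparsity k."""
    if float(k) not in [float(g) for g in pop.grid]:
        raise ValueError(f"sparsity {k} not in population grid {pop.grid}")
    mats = [pop.predictions[(i, float(k))] for i in range(pop.n_runs)]
    scores = np.mean([m.scores for m in mats], axis=0)
    return PredictionMatrix(scores=scores, sample_ids=mats[0].sample_ids, class_names=mats[0].class_names)


def image_agreement(p0: PredictionMatrix, p1: PredictionMatrix) -> np.ndarray:
    """Per-image Spearman correlation between the two score vectors.

    Average ranks on ties. A constant row in either matrix yields NaN for
    that image.
    """
    a, b = p0.scores, p1.scores
    if a.shape != b.shape:
        raise ValueError("prediction matrices must share shape")
    if a.shape[1] < 3:
        raise ValueError("need at least 3 classes for rank correlation")
    ra = rankdata(a, axis=1)
    rb = rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return corr


def identify_pies(corr: np.ndarray, fraction: float = 0.05) -> tuple[np.ndarray, float]:
    """Flag the floor(fraction * N_defined) lowest-agreement images.

    Returns (pie_mask, threshold) where threshold is the highest flagged
    correlation. Undefined (NaN) correlations are never flagged.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    corr = np.asarray(corr, dtype=float)
    defined = np.flatnonzero(~np.isnan(corr))
    if defined.size < 20:
        raise ValueError("need at least 20 defined correlations")
    m = int(np.floor(fraction * defined.size))
    order = defined[np.lexsort((defined, corr[defined]))]  # corr, then index
    flagged = order[:m]
    mask = np.zeros(corr.size, dtype=bool)
    mask[flagged] = True
    threshold = float(corr[flagged].max()) if m else float("nan")
    return mask, threshold


def pie_class_ratio(pie_mask: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-class prevalence ratio, PIEs relative to non-PIEs.

    NaN where the class never appears among non-PIEs (ratio undefined).
    """
    pie_mask = np.asarray(pie_mask, dtype=bool)
    labels = np.asarray(labels)
    if pie_mask.sum() == 0 or (~pie_mask).sum() == 0:
        raise ValueError("need at least one PIE and one non-PIE")
    prev_pie = labels[pie_mask].mean(axis=0)
    prev_non = labels[~pie_mask].mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(prev_non > 0, prev_pie / np.maximum(prev_non, 1e-300), np.nan)


def pie_disease_count_ratio(pie_mask: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Ratio of bucket frequency (d = 0,1,2,3,4+ simultaneous findings),
    PIEs relative to non-PIEs; NaN where the non-PIE bucket is empty."""
    pie_mask = np.asarray(pie_mask, dtype=bool)
    labels = np.asarray(labels)
    if pie_mask.sum() == 0 or (~pie_mask).sum() == 0:
        raise ValueError("need at least one PIE and one non-PIE")
    counts = np.minimum(labels.sum(axis=1), 4)  # pool at 4+
    ratios = {}
    for d, name in enumerate(COUNT_BUCKETS):
        f_pie = float(np.mean(counts[pie_mask] == d))
        f_non = float(np.mean(counts[~pie_mask] == d))
        ratios[name] = f_pie / f_non if f_non > 0 else float("nan")
    return ratios


def build_pie_report(
    pop: RunPopulation,
    labels: np.ndarray,
    comparator_k: float = 0.9,
    fraction: float = 0.05,
) -> PIEReport:
    """End-to-end PIE analysis: average predictions at k=0 and the
    comparator sparsity, per-image agreement, flagging, and enrichment."""
    p0 = average_prediction(pop, 0.0)
    p1 = average_prediction(pop, comparator_k)
    corr = image_agreement(p0, p1)
    mask, threshold = identify_pies(corr, fraction)
    return PIEReport(
        per_image_corr=corr,
        pie_mask=mask,
        threshold=threshold,
        class_ratio=pie_class_ratio(mask, labels),
        count_ratio=pie_disease_count_ratio(mask, labels),
        comparator_sparsity=float(comparator_k),
        fraction=float(fraction),
    )
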