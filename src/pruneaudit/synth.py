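"""Synthetic long-tailed multi-label datasets and prediction fixtures.

This module stands in for large chest-X-ray-style benchmarks: a few head
classes are common, most classes are rare (prevalence spanning orders of
magnitude), each sample carries at least one label, labels co-occur, and
samples are grouped by synthetic "patient" so splits can be leakage-free.

Labels are drawn from a correlated-latent-Gaussian (multivariate probit)
model: a latent vector z ~ N(0, R) is thresholded per class at the quantile
matching the requested marginal prevalence, so marginals and pairwise
association are controlled independently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import norm

__all__ = [
    "ClassStructure",
    "LabeledDataset",
    "sample_class_structure",
    "generate_dataset",
    "split_dataset",
    "generate_prediction_fixture",
    "save_dataset",
    "load_dataset",
    "load_scenario_config",
]

SPLITS = ("train", "val", "test")


class CorrelationRepairError(ValueError):
    """Requested pairwise associations cannot be repaired to a valid PSD matrix."""

    def __init__(self, pairs, message):
        self.pairs = pairs
        super().__init__(message)


@dataclass
class ClassStructure:
    """Generative description of a long-tailed multi-label class system.

    Attributes
    ----------
    class_names : list of str
        C class identifiers, ordered head (most prevalent) to tail.
    prevalence : ndarray, shape (C,)
        Marginal positive probability per class, each in (0, 1).
    latent_corr : ndarray, shape (C, C)
        Symmetric PSD correlation matrix of the latent Gaussian driving
        label co-occurrence; unit diagonal.
    signal_strength : ndarray, shape (C,)
        Nonnegative per-class scale of the class prototype in feature
        space; smaller values make a class harder to separate.
    """

    class_names: list[str]
    prevalence: np.ndarray
    latent_corr: np.ndarray
    signal_strength: np.ndarray

    def __post_init__(self):
        C = len(self.class_names)
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        self.signal_strength = np.asarray(self.signal_strength, dtype=float)
        if self.prevalence.shape != (C,):
            raise ValueError(f"prevalence must have shape ({C},)")
        if not np.all((self.prevalence > 0) & (self.prevalence < 1)):
            raise ValueError("prevalence entries must lie in (0, 1)")
        if self.latent_corr.shape != (C, C):
            raise ValueError(f"latent_corr must have shape ({C}, {C})")
        if not np.allclose(self.latent_corr, self.latent_corr.T):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(self.latent_corr), 1.0):
            raise ValueError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(self.latent_corr).min() < -1e-8:
            raise ValueError("latent_corr must be positive semidefinite")
        if self.signal_strength.shape != (C,):
            raise ValueError(f"signal_strength must have shape ({C},)")
        if np.any(self.signal_strength < 0):
            raise ValueError("signal_strength must be nonnegative")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class LabeledDataset:
    """Features, binary labels, patient grouping and split assignment."""

    features: np.ndarray  # (N, D) float
    labels: np.ndarray  # (N, C) {0,1}
    group_id: np.ndarray  # (N,) int patient identifier
    split: np.ndarray  # (N,) str in {train, val, test}
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        N = self.features.shape[0]
        if self.labels.shape[0] != N or self.group_id.shape != (N,) or self.split.shape != (N,):
            raise ValueError("features, labels, group_id and split must agree on N")
        if np.any(self.labels.sum(axis=1) < 1):
            raise ValueError("every sample must carry at least one positive label")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_classes(self) -> int:
        return self.labels.shape[1]

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (features, labels) restricted to one split."""
        mask = self.split == split
        return self.features[mask], self.labels[mask]

    def class_counts(self, split: str | None = None) -> np.ndarray:
        """Positive count per class, optionally within one split."""
        labels = self.labels if split is None else self.labels[self.split == split]
        return labels.sum(axis=0).astype(int)


def _nearest_psd_correlation(R: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a PSD correlation matrix.

    Eigenvalues are clipped at a small positive floor and the diagonal is
    rescaled back to 1. Not the Higham alternating projection, but adequate
    for the mild repairs a few conflicting pair requests need.
    """
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2


def sample_class_structure(
    C: int,
    head_prevalence: float,
    tail_prevalence: float,
    cooccur_pairs: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
    head_signal: float = 1.0,
    tail_signal: float = 1.0,
) -> ClassStructure:
    """Build a long-tailed class structure with requested co-occurrence.

    Prevalence interpolates log-linearly from ``head_prevalence`` (class 0)
    down to ``tail_prevalence`` (class C-1), so a head/tail ratio of a few
    hundred emulates imbalance spanning orders of magnitude. Requested
    off-diagonal latent correlations are installed and, if the result is not
    PSD, projected to the nearest PSD correlation matrix; a projection that
    moves a requested strength by more than 0.1 raises
    :class:`CorrelationRepairError` naming the offending pairs.

    ``head_signal``/``tail_signal`` interpolate per-class separability the
    same way, letting a scenario make rare classes harder to learn.
    Deterministic given ``seed`` (held for interface stability; the current
    construction is seed-free).
    """
    if C < 2:
        raise ValueError("need at least 2 classes")
    if not (0 < tail_prevalence <= head_prevalence < 1):
        raise ValueError("require 0 < tail_prevalence <= head_prevalence < 1")
    cooccur_pairs = list(cooccur_pairs or [])
    for i, j, s in cooccur_pairs:
        if not (0 <= s < 1):
            raise ValueError(f"co-occurrence strength for pair ({i},{j}) must be in [0,1)")
        if i == j or not (0 <= i < C and 0 <= j < C):
            raise ValueError(f"invalid class pair ({i},{j})")

    t = np.arange(C) / (C - 1)
    prevalence = np.exp(np.log(head_prevalence) + t * (np.log(tail_prevalence) - np.log(head_prevalence)))
    signal = np.exp(np.log(head_signal) + t * (np.log(tail_signal) - np.log(head_signal)))

    R = np.eye(C)
    for i, j, s in cooccur_pairs:
        R[i, j] = R[j, i] = s
    if np.linalg.eigvalsh(R).min() < -1e-10:
        R = _nearest_psd_correlation(R)
        bad = [(i, j) for i, j, s in cooccur_pairs if abs(R[i, j] - s) > 0.1]
        if bad:
            raise CorrelationRepairError(
                bad, f"requested correlations not PSD-repairable; offending pairs: {bad}"
            )

    names = [f"class_{c:02d}" for c in range(C)]
    return ClassStructure(names, prevalence, R, signal)


def generate_dataset(
    structure: ClassStructure,
    N: int,
    D: int,
    noise_sd: float,
    seed: int,
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    prototype_overlap: list[tuple[int, int, float]] | None = None,
) -> LabeledDataset:
    """Draw a labelled dataset from a class structure.

    Labels come from thresholding a correlated latent Gaussian at per-class
    quantiles matching the marginal prevalence. Rows left with no positive
    label are backfilled on class 0, the "no finding" head class, keeping N
    fixed and every row non-empty. Features are a noisy superposition of
    fixed class prototypes::

        x_n = sum_c labels[n, c] * signal_strength[c] * mu_c + eps,
        eps ~ N(0, noise_sd^2 I)

    with prototypes ``mu_c ~ N(0, I_D)`` drawn once from ``seed``. Samples
    are grouped into synthetic patients of 1-3 consecutive images and split
    70/10/20 at the patient level (see :func:`split_dataset`).

    ``prototype_overlap`` is a list of ``(class, partner, cos)`` triples:
    the prototype of ``class`` is rebuilt as ``cos`` times the unit
    prototype of ``partner`` plus an orthogonal remainder, at the same
    overall norm. This emulates a finding that visually resembles another
    (e.g. a rare disease mimicking a common one), so that telling the two
    apart rests on a fine feature component rather than a dedicated one.
    """
    C = structure.n_classes
    if N < 10 * C:
        raise ValueError(f"N must be >= 10*C = {10 * C}")
    if D < C:
        raise ValueError("feature dimension D must be >= C")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    thin = [structure.class_names[c] for c in range(C) if structure.prevalence[c] * N < 1]
    if thin:
        warnings.warn(
            f"expected positive count below 1 for classes {thin}; they may have zero positives",
            UserWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(structure.latent_corr + 1e-9 * np.eye(C))
    z = rng.standard_normal((N, C)) @ L.T
    thresholds = norm.ppf(1 - structure.prevalence)
    labels = (z > thresholds).astype(np.int8)
    labels[labels.sum(axis=1) == 0, 0] = 1  # "no finding" backfill on head class

    prototypes = rng.standard_normal((C, D))
    for c, partner, cos in prototype_overlap or []:
        if not (0 <= cos < 1) or c == partner:
            raise ValueError(f"invalid prototype overlap ({c}, {partner}, {cos})")
        unit = prototypes[partner] / np.linalg.norm(prototypes[partner])
        resid = rng.standard_normal(D)
        resid -= (resid @ unit) * unit
        resid /= np.linalg.norm(resid)
        prototypes[c] = np.sqrt(D) * (cos * unit + np.sqrt(1 - cos**2) * resid)
    weighted = labels * structure.signal_strength
    features = weighted @ prototypes
    if noise_sd > 0:
        features = features + noise_sd * rng.standard_normal((N, D))

    group_sizes = rng.integers(1, 4, size=N)  # patients of 1-3 images
    group_id = np.repeat(np.arange(N), group_sizes)[:N]

    ds = LabeledDataset(
        features=features,
        labels=labels,
        group_id=group_id,
        split=np.full(N, "train", dtype=object),
        class_names=list(structure.class_names),
    )
    return split_dataset(ds, split_fractions, seed=seed)


def split_dataset(
    ds: LabeledDataset,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> LabeledDataset:
    """Assign train/val/test splits at the patient level.

    Groups are shuffled by ``seed`` and assigned greedily, each to the split
    with the largest remaining sample deficit (ties broken in train, val,
    test order), so no patient straddles splits and achieved fractions are
    within one group's size of the targets.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three values summing to 1")
    groups = np.unique(ds.group_id)
    if len(groups) < 3:
        raise ValueError("need at least 3 patient groups to split")

    rng = np.random.default_rng(seed)
    order = rng.permutation(groups)
    N = ds.n_samples
    targets = np.array(fractions) * N
    assigned = np.zeros(3)
    split = np.empty(N, dtype=object)
    for g in order:
        mask = ds.group_id == g
        which = int(np.argmax(targets - assigned))
        split[mask] = SPLITS[which]
        assigned[which] += mask.sum()

    return LabeledDataset(
        features=ds.features,
        labels=ds.labels,
        group_id=ds.group_id,
        split=split,
        class_names=list(ds.class_names),
    )


def generate_prediction_fixture(
    N: int,
    C: int,
    agreement: float,
    seed: int,
    return_mask: bool = False,
):
    """Generate a pair of score matrices with a controlled agreement level.

    The first matrix holds uniform random scores. For ``ceil(agreement*N)``
    rows the second matrix is a strictly increasing (rank-preserving)
    transform of the first, giving per-row Spearman correlation exactly 1;
    the remaining rows are independent redraws. With ``return_mask=True`` a
    boolean vector marking the redrawn rows is returned as a third element,
    which planted-anomaly tests use as ground truth.
    """
    if C < 3:
        raise ValueError("need C >= 3 classes for non-degenerate rank correlation")
    if not (0 <= agreement <= 1):
        raise ValueError("agreement must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(size=(N, C))
    n_keep = int(np.ceil(agreement * N))
    keep = np.zeros(N, dtype=bool)
    keep[rng.permutation(N)[:n_keep]] = True
    p1 = np.where(keep[:, None], p0**2, rng.uniform(size=(N, C)))

    from .classifier import PredictionMatrix  # local import avoids a cycle

    ids = np.arange(N)
    names = [f"class_{c:02d}" for c in range(C)]
    m0 = PredictionMatrix(scores=p0, sample_ids=ids, class_names=names)
    m1 = PredictionMatrix(scores=p1, sample_ids=ids.copy(), class_names=names)
    if return_mask:
        return m0, m1, ~keep
    return m0, m1


def save_dataset(ds: LabeledDataset, npz_path, json_path=None) -> None:
    """Write a dataset as NPZ (/features /labels /group_id /split) + JSON sidecar."""
    np.savez_compressed(
        npz_path,
        features=ds.features,
        labels=ds.labels,
        group_id=ds.group_id,
        split=np.asarray(ds.split, dtype=str),
    )
    if json_path is not None:
        meta = {
            "class_names": list(ds.class_names),
            "n_samples": int(ds.n_samples),
            "n_classes": int(ds.n_classes),
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def load_dataset(npz_path, json_path=None) -> LabeledDataset:
    with np.load(npz_path, allow_pickle=False) as data:
        class_names = []
        if json_path is not None:
            with open(json_path) as fh:
                class_names = json.load(fh)["class_names"]
        return LabeledDataset(
            features=data["features"],
            labels=data["labels"],
            group_id=data["group_id"],
            split=data["split"].astype(object),
            class_names=class_names,
        )


def load_scenario_config(path) -> dict:
    """Read a YAML scenario config with keys C, N, D, head_prevalence,
    tail_prevalence, cooccur_pairs, noise_sd, seed (missing keys defaulted)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    defaults = {
        "C": 20,
        "N": 5000,
        "D": 64,
        "head_prevalence": 0.3,
        "tail_prevalence": 0.002,
        "cooccur_pairs": [],
        "noise_sd": 1.0,
        "seed": 0,
    }
    defaults.update(cfg)
    return defaults
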