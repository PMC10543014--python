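"""Population training of small multi-label classifiers.

The backbone is deliberately tiny: a one-hidden-layer dense network with
elementwise sigmoid outputs, trained by plain minibatch gradient descent on
mean binary cross-entropy. The analysis machinery downstream (pruning
sweeps, AP tables, forgettability curves, PIEs) is the point; the network
only needs to be overparameterized enough that moderate pruning is harmless
and heavy pruning is not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .synth import LabeledDataset

__all__ = [
    "WeightSet",
    "PredictionMatrix",
    "RunPopulation",
    "train_classifier",
    "predict",
    "train_population",
    "save_weights",
    "load_weights",
]


@dataclass
class WeightSet:
    """Named parameter tensors partitioned into prunable and non-prunable.

    Prunable names are the weight matrices; biases are non-prunable,
    following standard magnitude-pruning practice.
    """

    tensors: dict[str, np.ndarray]
    prunable: tuple[str, ...]
    non_prunable: tuple[str, ...]

    def __post_init__(self):
        names = set(self.tensors)
        if set(self.prunable) | set(self.non_prunable) != names:
            raise ValueError("prunable and non_prunable must partition tensor names")
        if set(self.prunable) & set(self.non_prunable):
            raise ValueError("prunable and non_prunable must be disjoint")
        if self.prunable_count() < 1:
            raise ValueError("need at least one prunable element")

    def prunable_count(self) -> int:
        return int(sum(self.tensors[n].size for n in self.prunable))

    def copy(self) -> "WeightSet":
        return WeightSet(
            {k: v.copy() for k, v in self.tensors.items()},
            tuple(self.prunable),
            tuple(self.non_prunable),
        )


@dataclass
class PredictionMatrix:
    """N x C sigmoid scores for one model on one sample set."""

    scores: np.ndarray
    sample_ids: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")
        if self.scores.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match score rows")


@dataclass
class RunPopulation:
    """Test-set predictions indexed by (run, sparsity) over a seed population."""

    predictions: dict[tuple[int, float], PredictionMatrix]
    seeds: list[int]
    grid: list[float]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        grid = list(self.grid)
        if grid != sorted(grid) or grid[0] != 0.0:
            raise ValueError("sparsity grid must be ascending and start at 0")
        ids0 = None
        for pm in self.predictions.values():
            if ids0 is None:
                ids0 = pm.sample_ids
            elif not np.array_equal(pm.sample_ids, ids0):
                raise ValueError("all prediction matrices must share the test-set ordering")

    @property
    def n_runs(self) -> int:
        return len(self.seeds)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _forward(tensors: dict[str, np.ndarray], X: np.ndarray) -> np.ndarray:
    h = np.maximum(X @ tensors["W1"] + tensors["b1"], 0.0)
    return h @ tensors["W2"] + tensors["b2"]


def train_classifier(
    ds: LabeledDataset,
    hidden_units: int = 256,
    epochs: int = 30,
    learning_rate: float = 3.0,
    seed: int = 0,
    batch_size: int = 128,
    weight_decay: float = 0.0,
) -> WeightSet:
    """Train a one-hidden-layer sigmoid-output network on the train split.

    Minibatch gradient descent with a fixed learning rate on the mean (over
    samples and classes) binary cross-entropy. An optional L2 penalty
    (``weight_decay``, off by default) on the weight matrices — not biases —
    shrinks weights the task does not use toward zero, which concentrates
    the magnitude distribution and makes the model markedly more robust to
    magnitude pruning. Deterministic given ``seed``:
    initialization and minibatch order both come from one generator.
    ``epochs=0`` returns the untouched initialization.

    Raises ``FloatingPointError`` with the learning rate and epoch if the
    loss goes non-finite.
    """
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    X, y = ds.subset("train")
    if X.shape[0] == 0:
        raise ValueError("train split is empty")
    y = y.astype(float)
    N, D = X.shape
    C = y.shape[1]

    rng = np.random.default_rng(seed)
    tensors = {
        "W1": rng.normal(0.0, np.sqrt(2.0 / D), size=(D, hidden_units)),
        "b1": np.zeros(hidden_units),
        "W2": rng.normal(0.0, np.sqrt(2.0 / hidden_units), size=(hidden_units, C)),
        "b2": np.zeros(C),
    }

    loss_first = None
    for epoch in range(epochs):
        order = rng.permutation(N)
        epoch_loss = 0.0
        for start in range(0, N, batch_size):
            idx = order[start : start + batch_size]
            Xb, yb = X[idx], y[idx]
            B = len(idx)
            pre = Xb @ tensors["W1"] + tensors["b1"]
            h = np.maximum(pre, 0.0)
            p = _sigmoid(h @ tensors["W2"] + tensors["b2"])
            epoch_loss += _bce(p, yb) * B

            dz = (p - yb) / (B * C)  # grad of mean BCE wrt logits
            gW2 = h.T @ dz
            gb2 = dz.sum(axis=0)
            dh = dz @ tensors["W2"].T
            dh[pre <= 0] = 0.0
            gW1 = Xb.T @ dh
            gb1 = dh.sum(axis=0)
            tensors["W1"] -= learning_rate * (gW1 + weight_decay * tensors["W1"])
            tensors["b1"] -= learning_rate * gb1
            tensors["W2"] -= learning_rate * (gW2 + weight_decay * tensors["W2"])
            tensors["b2"] -= learning_rate * gb2
        epoch_loss /= N
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch + 1} (learning_rate={learning_rate})"
            )
        if loss_first is None:
            loss_first = epoch_loss

    return WeightSet(tensors, prunable=("W1", "W2"), non_prunable=("b1", "b2"))


def predict(w: WeightSet, features: np.ndarray, sample_ids=None, class_names=None) -> PredictionMatrix:
    """Sigmoid network outputs for a feature matrix; pure function of (w, X)."""
    if features.ndim != 2 or features.shape[1] != w.tensors["W1"].shape[0]:
        raise ValueError(
            f"feature dimension {features.shape} does not match weights "
            f"(expect D={w.tensors['W1'].shape[0]})"
        )
    scores = _sigmoid(_forward(w.tensors, features))
    if sample_ids is None:
        sample_ids = np.arange(features.shape[0])
    if class_names is None:
        class_names = [f"class_{c:02d}" for c in range(scores.shape[1])]
    return PredictionMatrix(scores=scores, sample_ids=np.asarray(sample_ids), class_names=list(class_names))


def train_population(
    ds: LabeledDataset,
    R: int = 30,
    grid: list[float] | None = None,
    base_seed: int = 0,
    hidden_units: int = 256,
    epochs: int = 30,
    learning_rate: float = 3.0,
    weight_decay: float = 0.0,
) -> RunPopulation:
    """Train R independently initialized models and sweep the sparsity grid.

    Each run i trains once with seed ``base_seed + i``; the trained weights
    are then pruned (one-shot, no fine-tuning) at every grid value and test
    predictions recorded. The k=0 entry is the unpruned model.
    """
    from .prune import SparsityGrid, l1_global_prune

    if R < 2:
        raise ValueError("population size R must be >= 2")
    grid = SparsityGrid(grid if grid is not None else DEFAULT_GRID).values
    X_test, _ = ds.subset("test")
    test_ids = np.nonzero(ds.split == "test")[0]

    predictions: dict[tuple[int, float], PredictionMatrix] = {}
    seeds = []
    for i in range(R):
        seed = base_seed + i
        seeds.append(seed)
        try:
            w = train_classifier(
                ds, hidden_units=hidden_units, epochs=epochs,
                learning_rate=learning_rate, seed=seed,
                weight_decay=weight_decay,
            )
        except Exception as exc:
            raise RuntimeError(f"training failed for run {i} (seed {seed}): {exc}") from exc
        for k in grid:
            wk = l1_global_prune(w, k)
            predictions[(i, k)] = predict(wk, X_test, sample_ids=test_ids, class_names=ds.class_names)
    return RunPopulation(predictions=predictions, seeds=seeds, grid=list(grid), class_names=list(ds.class_names))


#: Sparsity sweep used throughout: k from 0 to 0.95 in steps of 0.05.
DEFAULT_GRID = [round(0.05 * i, 2) for i in range(20)]


def save_weights(w: WeightSet, npz_path, json_path=None) -> None:
    np.savez_compressed(npz_path, **w.tensors)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({"prunable": list(w.prunable), "non_prunable": list(w.non_prunable)}, fh)


def load_weights(npz_path, json_path) -> WeightSet:
    with np.load(npz_path) as data:
        tensors = {k: data[k] for k in data.files}
    with open(json_path) as fh:
        meta = json.load(fh)
    return WeightSet(tensors, tuple(meta["prunable"]), tuple(meta["non_prunable"]))
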