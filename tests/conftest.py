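import numpy as np
import pytest

from pruneaudit.classifier import PredictionMatrix, RunPopulation, WeightSet
from pruneaudit.synth import generate_dataset, sample_class_structure


def random_weightset(rng, n_tensors=None, with_ties=False):
    """Small random WeightSet; optionally with duplicated magnitudes."""
    n_tensors = n_tensors or rng.integers(1, 4)
    tensors, prunable = {}, []
    for t in range(n_tensors):
        shape = tuple(rng.integers(2, 6, size=rng.integers(1, 3)))
        vals = rng.normal(size=shape)
        if with_ties:
            flat = vals.ravel()
            k = max(1, flat.size // 3)
            flat[rng.integers(0, flat.size, size=k)] = 0.25  # planted ties
            vals = flat.reshape(shape)
        name = f"W{t}"
        tensors[name] = vals
        prunable.append(name)
    tensors["bias"] = rng.normal(size=3)
    return WeightSet(tensors, tuple(prunable), ("bias",))


@pytest.fixture(scope="session")
def small_dataset():
    """C=4 long-tailed dataset, big enough for stable per-class AP."""
    structure = sample_class_structure(4, 0.4, 0.05, seed=7)
    return generate_dataset(structure, N=600, D=16, noise_sd=0.5, seed=7)


@pytest.fixture(scope="session")
def toy_population():
    """Hand-built 2-run population on a fixed grid, for assembly tests."""
    rng = np.random.default_rng(0)
    N, C = 40, 4
    grid = [0.0, 0.5, 0.9]
    ids = np.arange(N)
    names = [f"class_{c:02d}" for c in range(C)]
    preds = {
        (i, k): PredictionMatrix(rng.uniform(size=(N, C)), ids, names)
        for i in range(2)
        for k in grid
    }
    labels = (rng.uniform(size=(N, C)) < 0.3).astype(int)
    labels[labels.sum(axis=1) == 0, 0] = 1
    pop = RunPopulation(preds, seeds=[0, 1], grid=grid, class_names=names)
    return pop, labels
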