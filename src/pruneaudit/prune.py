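"""Global unstructured L1 (magnitude) pruning and weight diagnostics.

Pruning at sparsity ratio k zeros the floor(k*P) prunable weights of
smallest absolute value, ranked jointly across all prunable tensors rather
than per layer. Ties at the threshold are broken by a fixed total order
(tensor name order, then flat index) so results are bit-reproducible;
pre-existing zeros sort first, which makes pruning idempotent and the
zero-sets nested across an increasing grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import WeightSet

__all__ = ["SparsityGrid", "l1_global_prune", "sparsity_of", "magnitude_histogram"]


@dataclass(frozen=True)
class SparsityGrid:
    """Ascending sparsity ratios in [0, 1), containing 0."""

    values: tuple[float, ...]

    def __init__(self, values):
        values = tuple(float(v) for v in values)
        if not values or values[0] != 0.0:
            raise ValueError("grid must start at 0")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError("grid must be strictly increasing")
        if values[-1] >= 1.0:
            raise ValueError("grid values must be < 1")
        object.__setattr__(self, "values", values)

    def __iter__(self):
        return iter(self.values)

    def __len__(self):
        return len(self.values)

    @property
    def max(self) -> float:
        return self.values[-1]


def _global_order(w: WeightSet):
    """Total order over prunable elements: (|value|, tensor rank, flat index)."""
    abs_vals, ranks, idxs = [], [], []
    for rank, name in enumerate(w.prunable):
        flat = np.abs(w.tensors[name]).ravel()
        abs_vals.append(flat)
        ranks.append(np.full(flat.size, rank))
        idxs.append(np.arange(flat.size))
    abs_vals = np.concatenate(abs_vals)
    ranks = np.concatenate(ranks)
    idxs = np.concatenate(idxs)
    # lexsort: last key is primary
    return np.lexsort((idxs, ranks, abs_vals)), ranks, idxs


def l1_global_prune(w: WeightSet, k: float) -> WeightSet:
    """Zero the floor(k*P) smallest-magnitude prunable weights, globally.

    Non-prunable tensors (biases) are untouched; the input is not mutated.
    """
    if not (0 <= k < 1):
        raise ValueError(f"sparsity ratio k={k} must lie in [0, 1)")
    out = w.copy()
    P = w.prunable_count()
    m = int(np.floor(k * P))
    if m == 0:
        return out
    order, ranks, idxs = _global_order(w)
    chosen = order[:m]
    for rank, name in enumerate(out.prunable):
        sel = idxs[chosen[ranks[chosen] == rank]]
        if sel.size:
            flat = out.tensors[name].ravel()
            flat[sel] = 0.0
            out.tensors[name] = flat.reshape(out.tensors[name].shape)
    return out


def sparsity_of(w: WeightSet) -> float:
    """Fraction of prunable elements that are exactly zero."""
    P = w.prunable_count()
    zeros = sum(int(np.count_nonzero(w.tensors[n] == 0.0)) for n in w.prunable)
    return zeros / P


def magnitude_histogram(w: WeightSet, bin_edges) -> np.ndarray:
    """Counts of |prunable weights| per half-open bin [e_j, e_{j+1}).

    Values outside [e_0, e_last) are not counted, so the counts sum to P
    only when the edges cover the full magnitude range.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly ascending")
    mags = np.concatenate([np.abs(w.tensors[n]).ravel() for n in w.prunable])
    which = np.searchsorted(edges, mags, side="right") - 1
    in_range = (which >= 0) & (mags < edges[-1])
    return np.bincount(which[in_range], minlength=edges.size - 1)[: edges.size - 1]
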