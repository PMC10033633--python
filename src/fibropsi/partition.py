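"""Deterministic Kennard–Stone train/test partitioning.

Kennard–Stone picks a representative training subset by max-min Euclidean
distance: the first two members are the most distant pair, and each
subsequent member is the sample whose minimum distance to the already
selected set is largest.  The split is deterministic; distance ties are
broken by the lowest sample index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitIndices", "kennard_stone", "write_split", "random_split"]


@dataclass
class SplitIndices:
    train_idx: list[int]
    test_idx: list[int]
    train_frac: float = 0.7

    def __post_init__(self) -> None:
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError("train and test indices overlap")


def _train_size(n: int, train_frac: float) -> int:
    # round half up; the seed pair forces at least two training samples
    return min(n, max(2, int(np.floor(train_frac * n + 0.5))))


def kennard_stone(X: np.ndarray, train_frac: float = 0.7) -> SplitIndices:
    """Split rows of ``X`` into training/test sets by Kennard–Stone.

    Distances are Euclidean on the rows as given (no internal scaling).
    ``|train| = round(train_frac * n)``, floored at 2 because the seeding
    step needs the maximum-distance pair.  With ``n == 2`` both samples
    are assigned to training and a warning is emitted.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("Kennard-Stone needs at least two samples")
    n_train = _train_size(n, train_frac)
    if n_train >= n:
        warnings.warn(
            f"Kennard-Stone training size {n_train} consumes all {n} samples; "
            "test set is empty"
        )
    D = squareform(pdist(X, metric="euclidean"))
    # seed: maximum-distance pair; np.argmax returns the first (lowest-index)
    # occurrence, which implements the documented tie-break
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_train:
        cand = remaining[int(np.argmax(min_dist[remaining]))]
        selected.append(cand)
        remaining.remove(cand)
        min_dist = np.minimum(min_dist, D[cand])
    return SplitIndices(train_idx=selected, test_idx=sorted(remaining), train_frac=train_frac)


def random_split(
    n: int, train_frac: float = 0.7, seed: int = 0
) -> SplitIndices:
    """Seeded random split (experimentation only; the pipeline default is
    Kennard–Stone)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    k = _train_size(n, train_frac)
    return SplitIndices(sorted(order[:k].tolist()), sorted(order[k:].tolist()), train_frac)


def write_split(split: SplitIndices, sample_ids: list[str], path: str | Path) -> None:
    rows = [(sample_ids[i], "train") for i in split.train_idx] + [
        (sample_ids[i], "test") for i in split.test_idx
    ]
    pd.DataFrame(rows, columns=["sample_id", "role"]).to_csv(path, index=False)
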