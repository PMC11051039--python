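"""Synthetic minority oversampling (SMOTE) for the cross-validation loop.

Every non-majority class is upsampled to the majority count by linear
interpolation between a random minority sample and one of its k nearest
same-class neighbors (Euclidean): x_new = x + r · (z − x), r ~ U(0, 1).
Original rows are preserved unchanged and flagged; only the training folds
of the evaluation loop are ever balanced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class BalancedSet:
    values: np.ndarray
    labels: np.ndarray
    synthetic_flags: np.ndarray

    def class_counts(self) -> dict:
        classes, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))


def smote_balance(values, labels, k_neighbors: int = 5, seed: int = 0) -> BalancedSet:
    """Oversample every minority class to the majority count.

    ``k_neighbors`` is clamped (with a logged warning) to minority-class
    size − 1 when the class is too small; a class with a single sample has
    no neighbor to interpolate toward and raises.
    """
    X = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=object)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("values must be 2-D with one label per row")
    if int(k_neighbors) < 1:
        raise ValueError(f"k_neighbors must be >= 1, got {k_neighbors}")
    classes, counts = np.unique(y.astype(str), return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to balance")
    majority = int(counts.max())
    rng = np.random.default_rng(seed)

    new_rows: list[np.ndarray] = []
    new_labels: list[object] = []
    for cls, count in sorted(zip(classes.tolist(), counts.tolist())):
        deficit = majority - int(count)
        if deficit == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {cls!r} has a single sample; SMOTE needs >= 2 "
                "samples per class"
            )
        k = int(k_neighbors)
        if k > count - 1:
            logger.warning(
                "smote: k_neighbors=%d clamped to %d for class %r (size %d)",
                k, count - 1, cls, count,
            )
            k = count - 1
        members = np.flatnonzero(y.astype(str) == cls)
        Xc = X[members]
        # k+1 neighbors because each point is its own nearest neighbor
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        neighbor_idx = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, len(members), size=deficit)
        pick = rng.integers(0, k, size=deficit)
        r = rng.random(deficit)
        for b, p, ri in zip(base, pick, r):
            x = Xc[b]
            z = Xc[neighbor_idx[b, p]]
            new_rows.append(x + ri * (z - x))
            new_labels.append(cls)

    n_orig = X.shape[0]
    if new_rows:
        out_X = np.vstack([X, np.array(new_rows)])
        out_y = np.concatenate([y, np.array(new_labels, dtype=object)])
    else:
        out_X, out_y = X.copy(), y.copy()
    flags = np.zeros(out_X.shape[0], dtype=bool)
    flags[n_orig:] = True
    logger.info(
        "smote_balance n=%d -> %d (synthetic=%d, classes=%d)",
        n_orig, out_X.shape[0], int(flags.sum()), len(classes),
    )
    return BalancedSet(values=out_X, labels=out_y, synthetic_flags=flags)
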