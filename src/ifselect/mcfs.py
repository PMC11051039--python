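"""Monte Carlo feature selection (MCFS), implemented from scratch.

Importance of a gene g is aggregated over many decision trees grown on
random feature subsets and random train/test splits:

    RI(g) = sum over trees tau  (wAcc_tau)^u
            * sum over nodes nd in tau splitting on g
                IG(nd) * (coverage(nd) / coverage(root))^v

where wAcc is the tree's class-balanced accuracy on its held-out split,
IG is the information gain of the split (entropy impurity decrease), and
coverage is the number of training samples reaching the node. Genes never
sampled into any subset score exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from ._seeding import derive_seed

logger = logging.getLogger(__name__)


@dataclass
class MCFSParams:
    """Monte Carlo sampling scheme: s feature subsets of size m, each
    evaluated on t random stratified train/test splits."""

    s: int = 100
    m: int | None = None  # default: ceil(0.1 * n_genes), capped at 500
    t: int = 5
    train_fraction: float = 0.66
    u: float = 1.0
    v: float = 1.0
    seed: int = 0

    def validate(self, n_genes: int) -> int:
        if self.s < 1 or self.t < 1:
            raise ValueError("s and t must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.u < 0 or self.v < 0:
            raise ValueError("u and v must be nonnegative")
        m = self.m if self.m is not None else min(500, int(np.ceil(0.1 * n_genes)))
        if m < 1 or m > n_genes:
            raise ValueError(f"m={m} out of range [1, {n_genes}]")
        return m


def _tree_contributions(tree: DecisionTreeClassifier, v: float) -> dict[int, float]:
    """Per-feature sum of IG(nd) * coverage_ratio^v over a fitted tree."""
    t = tree.tree_
    out: dict[int, float] = {}
    root_cov = float(t.n_node_samples[0])
    for nd in range(t.node_count):
        left, right = t.children_left[nd], t.children_right[nd]
        if left == -1:  # leaf
            continue
        n_nd = float(t.n_node_samples[nd])
        ig = t.impurity[nd] - (
            t.n_node_samples[left] / n_nd * t.impurity[left]
            + t.n_node_samples[right] / n_nd * t.impurity[right]
        )
        feat = int(t.feature[nd])
        out[feat] = out.get(feat, 0.0) + max(ig, 0.0) * (n_nd / root_cov) ** v
    return out


def mcfs_scores(
    X: np.ndarray,
    y: np.ndarray,
    params: MCFSParams,
    collect_trees: bool = False,
):
    """Raw per-column MCFS relative importances.

    With ``collect_trees`` the fitted trees, their sampled columns and
    held-out weighted accuracies are also returned so the aggregation can
    be audited externally.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object).astype(str)
    n, d = X.shape
    m = params.validate(d)
    scores = np.zeros(d)
    rng = np.random.default_rng(derive_seed(params.seed, "mcfs", "subsets"))
    trees: list[tuple[DecisionTreeClassifier, np.ndarray, float]] = []

    for si in range(params.s):
        cols = rng.choice(d, size=m, replace=False)
        for ti in range(params.t):
            split_seed = derive_seed(params.seed, "mcfs", si, ti)
            Xtr, Xte, ytr, yte = train_test_split(
                X[:, cols], y,
                train_size=params.train_fraction,
                stratify=y,
                random_state=split_seed,
            )
            tree = DecisionTreeClassifier(
                criterion="entropy", random_state=split_seed
            ).fit(Xtr, ytr)
            wacc = balanced_accuracy_score(yte, tree.predict(Xte))
            contrib = _tree_contributions(tree, params.v)
            weight = wacc ** params.u  # 0**0 == 1: u=0 keeps every tree
            for local_feat, val in contrib.items():
                scores[cols[local_feat]] += weight * val
            if collect_trees:
                trees.append((tree, cols.copy(), float(wacc)))
    logger.info("mcfs: s=%d m=%d t=%d -> %d trees", params.s, m, params.t,
                params.s * params.t)
    if collect_trees:
        return scores, trees
    return scores
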