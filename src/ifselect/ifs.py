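"""Incremental feature selection: sweep nested prefixes of a ranked list.

For each prefix size k the matrix is restricted to the list's top-k genes
and evaluated with stratified k-fold cross-validation: the training fold is
SMOTE-balanced, a decision tree or random forest is fit, and held-out
predictions are pooled over folds before scoring, so every cell is
predicted exactly once per curve point and no synthetic sample ever reaches
an evaluation fold.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._seeding import derive_seed
from .balancing import smote_balance
from .data import LabeledExpressionMatrix
from .metrics import MetricReport, evaluate
from .ranking import RankedFeatureList, top_prefix

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("DT", "RF")


@dataclass
class IFSRecord:
    k: int
    classifier_name: str
    report: MetricReport

    def to_dict(self) -> dict:
        return {"k": self.k, "classifier": self.classifier_name,
                **self.report.to_dict()}


@dataclass
class IFSCurve:
    ranker_name: str
    classifier_name: str
    records: list[IFSRecord]
    gene_ids: list[str] | None = None  # the ranked prefix the sweep used

    def __post_init__(self) -> None:
        ks = [r.k for r in self.records]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("record k values must be strictly increasing")

    @property
    def ks(self) -> list[int]:
        return [r.k for r in self.records]

    def scores(self, metric: str = "weighted_f1") -> list[float]:
        return [getattr(r.report, metric) for r in self.records]

    def record_at(self, k: int) -> IFSRecord:
        for r in self.records:
            if r.k == k:
                return r
        raise KeyError(f"no record at k={k}")


def build_subset_sizes(top_n: int, step: int) -> list[int]:
    """Prefix sizes step, 2·step, … up to top_n (top_n appended if it is
    not a multiple of step)."""
    if top_n < 1 or step < 1:
        raise ValueError("top_n and step must be positive")
    if step > top_n:
        return [top_n]
    sizes = list(range(step, top_n + 1, step))
    if sizes[-1] != top_n:
        sizes.append(top_n)
    return sizes


def make_classifier(classifier_name: str, seed: int):
    """Pinned classifier defaults: DT = CART/Gini, unlimited depth;
    RF = 100 trees with sqrt(d) features per split."""
    if classifier_name == "DT":
        from sklearn.tree import DecisionTreeClassifier
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if classifier_name == "RF":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(
            n_estimators=100, max_features="sqrt", random_state=seed, n_jobs=1
        )
    raise ValueError(
        f"unknown classifier {classifier_name!r}; valid: {CLASSIFIER_NAMES}"
    )


def evaluate_subset(
    matrix: LabeledExpressionMatrix,
    gene_subset: list[str],
    classifier_name: str,
    folds: int = 10,
    smote_k: int = 5,
    seed: int = 0,
    return_predictions: bool = False,
):
    """Cross-validated evaluation of one gene subset.

    Returns an :class:`IFSRecord`; with ``return_predictions`` also the
    pooled prediction vector (aligned with ``matrix`` rows).
    """
    if not gene_subset:
        raise ValueError("gene_subset must be nonempty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    cols = matrix.gene_index(list(gene_subset))
    X = matrix.values[:, cols]
    y = matrix.labels.astype(str)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"{folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=derive_seed(seed, "cv")
    )
    pooled = np.empty(len(y), dtype=object)
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        balanced = smote_balance(
            X[train_idx], y[train_idx],
            k_neighbors=smote_k,
            seed=derive_seed(seed, "smote", fold_i),
        )
        clf = make_classifier(classifier_name, derive_seed(seed, "clf", fold_i))
        clf.fit(balanced.values, balanced.labels.astype(str))
        pooled[test_idx] = clf.predict(X[test_idx])
    report = evaluate(y, pooled, matrix.class_names)
    record = IFSRecord(
        k=len(gene_subset), classifier_name=classifier_name, report=report
    )
    if return_predictions:
        return record, pooled
    return record


def run_ifs(
    matrix: LabeledExpressionMatrix,
    ranked_list: RankedFeatureList,
    classifier_name: str,
    top_n: int = 200,
    step: int = 5,
    folds: int = 10,
    smote_k: int = 5,
    seed: int = 0,
) -> IFSCurve:
    """Evaluate every prefix size of the grid on one ranked list."""
    if len(ranked_list) < top_n:
        raise ValueError(
            f"ranked list has {len(ranked_list)} genes, fewer than top_n={top_n}"
        )
    records = []
    t0 = time.perf_counter()
    for k in build_subset_sizes(top_n, step):
        subset = top_prefix(ranked_list, k)
        records.append(
            evaluate_subset(
                matrix, subset, classifier_name,
                folds=folds, smote_k=smote_k,
                seed=derive_seed(seed, "ifs", ranked_list.ranker_name, k),
            )
        )
    logger.info(
        "run_ifs ranker=%s clf=%s points=%d cells=%d elapsed=%.1fs",
        ranked_list.ranker_name, classifier_name, len(records),
        matrix.n_cells, time.perf_counter() - t0,
    )
    return IFSCurve(
        ranker_name=ranked_list.ranker_name,
        classifier_name=classifier_name,
        records=records,
        gene_ids=top_prefix(ranked_list, records[-1].k),
    )
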