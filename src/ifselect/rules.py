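"""Decision-tree rule extraction.

A single CART tree is trained on the SMOTE-balanced dataset restricted to
an essential gene subset; every root-to-leaf path becomes one quantitative
rule — a conjunction of expression-threshold predicates predicting one
class. Because the paths tile the tree's feature space, the rule set is
mutually exclusive and exhaustive: every expression vector satisfies
exactly one rule. Redundant bounds on the same gene along a path are merged
into the tightest interval.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._seeding import derive_seed
from .balancing import smote_balance
from .data import LabeledExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Predicate:
    gene_id: str
    operator: str  # "<=" | ">"
    threshold: float

    def __post_init__(self) -> None:
        if self.operator not in ("<=", ">"):
            raise ValueError(f"bad operator {self.operator!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def matches(self, value: float) -> bool:
        return value <= self.threshold if self.operator == "<=" else value > self.threshold

    def __str__(self) -> str:
        return f"expr({self.gene_id}) {self.operator} {self.threshold:.4g}"


@dataclass
class Rule:
    predicates: list[Predicate]
    predicted_class: str
    training_support: dict[str, int]
    purity: float

    def matches(self, values: dict[str, float]) -> bool:
        return all(p.matches(values.get(p.gene_id, 0.0)) for p in self.predicates)

    def __str__(self) -> str:
        cond = " AND ".join(str(p) for p in self.predicates) or "TRUE"
        return f"IF {cond} THEN {self.predicted_class}"


def merge_predicates(predicates: list[Predicate]) -> list[Predicate]:
    """Collapse same-gene same-side bounds into the tightest one, keeping
    first-occurrence order of (gene, side) pairs."""
    best: dict[tuple[str, str], Predicate] = {}
    order: list[tuple[str, str]] = []
    for p in predicates:
        key = (p.gene_id, p.operator)
        if key not in best:
            best[key] = p
            order.append(key)
        else:
            cur = best[key]
            if p.operator == "<=":
                if p.threshold < cur.threshold:
                    best[key] = p
            else:
                if p.threshold > cur.threshold:
                    best[key] = p
    return [best[key] for key in order]


def extract_rules(
    matrix: LabeledExpressionMatrix,
    gene_subset: list[str],
    smote_k: int = 5,
    seed: int = 0,
    max_depth: int | None = None,
    return_model: bool = False,
):
    """Fit one decision tree on balanced data and read off its rules.

    With ``return_model`` the fitted tree and the balanced training set are
    also returned, so rule-set fidelity to the tree can be audited.
    """
    if not gene_subset:
        raise ValueError("gene_subset must be nonempty")
    from sklearn.tree import DecisionTreeClassifier

    cols = matrix.gene_index(list(gene_subset))
    balanced = smote_balance(
        matrix.values[:, cols], matrix.labels,
        k_neighbors=smote_k, seed=derive_seed(seed, "rules", "smote"),
    )
    y = balanced.labels.astype(str)
    clf = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        random_state=derive_seed(seed, "rules", "tree"),
    ).fit(balanced.values, y)

    tree = clf.tree_
    leaf_of_sample = clf.apply(balanced.values)
    support_by_leaf: dict[int, Counter] = {}
    for leaf, label in zip(leaf_of_sample, y):
        support_by_leaf.setdefault(int(leaf), Counter())[label] += 1

    class_order = [c for c in matrix.class_names]
    rules: list[Rule] = []

    def walk(node: int, path: list[Predicate]) -> None:
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1:
            support = support_by_leaf.get(node, Counter())
            total = sum(support.values())
            counts = {c: int(support.get(c, 0)) for c in class_order}
            # argmax over tree_.value reproduces the tree's own tie-break,
            # so rule predictions are exactly the tree's predictions
            best = str(clf.classes_[int(np.argmax(tree.value[node]))])
            rules.append(Rule(
                predicates=merge_predicates(path),
                predicted_class=best,
                training_support=counts,
                purity=(counts[best] / total) if total else 0.0,
            ))
            return
        gene = gene_subset[int(tree.feature[node])]
        thr = float(tree.threshold[node])
        walk(left, path + [Predicate(gene, "<=", thr)])
        walk(right, path + [Predicate(gene, ">", thr)])

    walk(0, [])
    logger.info(
        "extract_rules genes=%d leaves=%d depth=%s",
        len(gene_subset), len(rules), clf.get_depth(),
    )
    if return_model:
        return rules, clf, balanced
    return rules


def apply_rules(rules: list[Rule], values: dict[str, float]) -> str:
    """Class of the unique rule matched by an expression vector."""
    matched = [r for r in rules if r.matches(values)]
    if len(matched) != 1:
        raise ValueError(f"expected exactly one matching rule, got {len(matched)}")
    return matched[0].predicted_class


def rule_counts(rules: list[Rule]) -> dict[str, int]:
    """Number of rules predicting each class."""
    if not rules:
        raise ValueError("empty rule list")
    out: dict[str, int] = {}
    for r in rules:
        out[r.predicted_class] = out.get(r.predicted_class, 0) + 1
    return out
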