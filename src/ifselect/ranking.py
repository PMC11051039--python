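"""Feature ranking: eight importance criteria producing ordered gene lists.

Seven rankers extract importances from established model implementations
(scikit-learn ensembles, XGBoost, LightGBM, L1-penalized one-vs-rest
logistic models); Monte Carlo feature selection is implemented in
:mod:`ifselect.mcfs`. Hyperparameters are pinned explicitly (100 trees for
every forest/booster) so rankings are stable across library versions.
Ties are broken by ascending gene id for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seeding import derive_seed
from .data import LabeledExpressionMatrix
from .mcfs import MCFSParams, mcfs_scores

logger = logging.getLogger(__name__)

RANKER_NAMES = (
    "Adaboost", "CatBoost", "ExtraTrees", "LASSO",
    "LightGBM", "MCFS", "RF", "XGBoost",
)


@dataclass
class RankedFeatureList:
    """One ranker's genes ordered by non-increasing importance score."""

    ranker_name: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")
        ids = [g for g, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def scores(self) -> list[float]:
        return [s for _, s in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def top_prefix(ranked: RankedFeatureList, k: int) -> list[str]:
    """First k gene ids of a ranked list (nested across k)."""
    if not (1 <= k <= len(ranked)):
        raise ValueError(f"k={k} out of range [1, {len(ranked)}]")
    return ranked.gene_ids[:k]


def _order_entries(gene_ids: list[str], scores: np.ndarray) -> list[tuple[str, float]]:
    order = sorted(range(len(gene_ids)), key=lambda i: (-scores[i], gene_ids[i]))
    return [(gene_ids[i], float(scores[i])) for i in order]


def _check_matrix(matrix: LabeledExpressionMatrix) -> None:
    if len(set(matrix.labels.tolist())) < 2:
        raise ValueError("ranking needs a matrix with at least 2 classes")


# ---------------------------------------------------------------------------
# individual score functions (raw per-column importances)

def _scores_adaboost(X, y, seed):
    from sklearn.ensemble import AdaBoostClassifier
    model = AdaBoostClassifier(n_estimators=100, random_state=seed).fit(X, y)
    return model.feature_importances_


def _scores_extratrees(X, y, seed):
    from sklearn.ensemble import ExtraTreesClassifier
    model = ExtraTreesClassifier(
        n_estimators=100, random_state=seed, n_jobs=1
    ).fit(X, y)
    return model.feature_importances_


def _scores_rf(X, y, seed):
    from sklearn.ensemble import RandomForestClassifier
    model = RandomForestClassifier(
        n_estimators=100, random_state=seed, n_jobs=1
    ).fit(X, y)
    return model.feature_importances_


def _scores_lasso(X, y, seed):
    """One-vs-rest L1 logistic models; importance = max |coefficient| over
    classes, with the regularization strength picked from a small internal
    grid by cross-validated accuracy."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.multiclass import OneVsRestClassifier

    def make(C):
        return OneVsRestClassifier(LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=C,
            random_state=seed, max_iter=200,
        ))

    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    grid = [0.01, 0.1, 1.0]
    cv_acc = [
        cross_val_score(make(C), X, y, cv=cv, scoring="accuracy").mean()
        for C in grid
    ]
    best_c = grid[int(np.argmax(cv_acc))]  # ties -> smallest C
    model = make(best_c).fit(X, y)
    coef = np.vstack([est.coef_.ravel() for est in model.estimators_])
    return np.max(np.abs(coef), axis=0)


def _scores_lightgbm(X, y, seed):
    from lightgbm import LGBMClassifier
    model = LGBMClassifier(
        n_estimators=100,
        random_state=seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        importance_type="gain",
        verbosity=-1,
    ).fit(X, y)
    return model.feature_importances_


def _scores_xgboost(X, y, seed):
    from xgboost import XGBClassifier
    from sklearn.preprocessing import LabelEncoder
    yi = LabelEncoder().fit_transform(y)
    model = XGBClassifier(
        n_estimators=100,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    ).fit(X, yi)
    return model.feature_importances_


def _scores_catboost(X, y, seed):
    try:
        from catboost import CatBoostClassifier
    except ImportError as err:
        raise RuntimeError(
            "the CatBoost ranker requires the optional 'catboost' package "
            "(pip install ifselect[catboost]); available rankers: "
            f"{sorted(available_rankers())}"
        ) from err
    model = CatBoostClassifier(
        iterations=100, random_seed=seed, verbose=False, allow_writing_files=False
    ).fit(X, y)
    return np.asarray(model.get_feature_importance())


def _scores_mcfs(X, y, seed):
    return mcfs_scores(X, y, MCFSParams(seed=seed))


_SCORERS = {
    "Adaboost": _scores_adaboost,
    "CatBoost": _scores_catboost,
    "ExtraTrees": _scores_extratrees,
    "LASSO": _scores_lasso,
    "LightGBM": _scores_lightgbm,
    "MCFS": _scores_mcfs,
    "RF": _scores_rf,
    "XGBoost": _scores_xgboost,
}

_CANONICAL = {name.lower(): name for name in RANKER_NAMES}


def canonical_ranker_name(name: str) -> str:
    key = str(name).lower()
    if key not in _CANONICAL:
        raise ValueError(
            f"unknown ranker {name!r}; valid rankers: {list(RANKER_NAMES)}"
        )
    return _CANONICAL[key]


def available_rankers() -> list[str]:
    """Rankers whose backing library is importable in this environment."""
    out = []
    for name in RANKER_NAMES:
        if name == "CatBoost":
            try:
                import catboost  # noqa: F401
            except ImportError:
                continue
        out.append(name)
    return out


def rank_features(
    matrix: LabeledExpressionMatrix, ranker_name: str, seed: int = 0
) -> RankedFeatureList:
    """Rank every gene of ``matrix`` by one importance criterion.

    Ranking always uses the full dataset (lists are produced once, upstream
    of the incremental evaluation loop). Deterministic given ``seed``.
    """
    _check_matrix(matrix)
    name = canonical_ranker_name(ranker_name)
    X = matrix.values
    y = matrix.labels.astype(str)
    child = derive_seed(seed, "rank", name)
    scores = np.asarray(_SCORERS[name](X, y, child), dtype=float)
    logger.info("rank_features ranker=%s genes=%d seed=%d", name, len(scores), seed)
    return RankedFeatureList(
        ranker_name=name, entries=_order_entries(matrix.gene_ids, scores)
    )


def mcfs_rank(
    matrix: LabeledExpressionMatrix, params: MCFSParams
) -> RankedFeatureList:
    """Monte Carlo feature selection ranking with explicit parameters."""
    _check_matrix(matrix)
    scores = mcfs_scores(matrix.values, matrix.labels, params)
    return RankedFeatureList(
        ranker_name="MCFS", entries=_order_entries(matrix.gene_ids, scores)
    )
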