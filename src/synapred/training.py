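"""Subsample splits and grid-search-tuned classifier training.

The training scheme repeatedly subsamples the labeled genes: the positive and
negative classes are each split into five fifths, and each of five rounds
leaves a different fifth of both classes out as that round's test set.  On
every training subsample three algorithm families are tuned and fit — kNN,
RBF-kernel SVM and random forest — giving 3 x 5 = 15 classifiers under the
defaults.  Hyperparameters are chosen per classifier by exhaustive grid
search with stratified cross-validation on the training subsample only; the
held-out fifth is never touched during tuning, so it supports an unbiased
per-classifier evaluation.

Class imbalance is deliberately preserved: no reweighting is applied by
default, so the fitted probabilities reflect the skewed positive:negative
ratio of the labeled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, ParameterGrid, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "ALGORITHMS",
    "LabeledGeneSet",
    "SubsampleSplit",
    "TrainedClassifier",
    "default_grids",
    "derive_seed",
    "make_subsample_splits",
    "tune_and_train",
    "train_all",
    "train_full",
]

ALGORITHMS: tuple[str, ...] = ("kNN", "SVM", "RF")


def default_grids() -> dict[str, dict[str, list[Any]]]:
    """Hyperparameter search grids per algorithm family.

    Small, standard grids over the knobs that matter for 24-dimensional
    profile vectors; fully overridable by the caller.
    """
    return {
        "kNN": {
            "n_neighbors": [1, 3, 5, 7, 9, 15, 21],
            "weights": ["uniform", "distance"],
        },
        "SVM": {
            "C": [0.1, 1.0, 10.0, 100.0],
            "gamma": [1e-3, 1e-2, 1e-1, 1.0, 10.0],
        },
        "RF": {
            "n_estimators": [100, 300, 500],
            "max_depth": [None, 5, 10],
        },
    }


def derive_seed(master_seed: int, *context: int) -> int:
    """Deterministically derive an independent 31-bit sub-seed from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, context)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class LabeledGeneSet:
    """Disjoint positive and negative training gene IDs."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"genes labeled both positive and negative: {sorted(overlap)[:5]}")

    def require_in(self, features: pd.DataFrame) -> None:
        missing = (self.positives | self.negatives) - set(features.index)
        if missing:
            raise ValueError(
                f"{len(missing)} labeled genes absent from the feature matrix, "
                f"e.g. {sorted(missing)[:5]}"
            )


@dataclass(frozen=True)
class SubsampleSplit:
    """One train/test partition: test holds one fifth of each class."""

    fold_index: int
    train: LabeledGeneSet
    test: LabeledGeneSet


def make_subsample_splits(
    labeled: LabeledGeneSet, k: int = 5, seed: int = 0
) -> list[SubsampleSplit]:
    """Partition each class into ``k`` fifths and leave a different one out per fold.

    Assignment is a seeded random permutation per class sliced into ``k``
    nearly equal blocks (sizes differ by at most one), so the union of the
    test sets is exactly the labeled set and folds never overlap.
    """
    rng = np.random.default_rng(seed)

    def blocks(ids: frozenset[str]) -> list[frozenset[str]]:
        arr = np.array(sorted(ids))
        if len(arr) < k:
            raise ValueError(f"class of size {len(arr)} cannot be split into {k} fifths")
        return [frozenset(chunk) for chunk in np.array_split(rng.permutation(arr), k)]

    pos_blocks = blocks(labeled.positives)
    neg_blocks = blocks(labeled.negatives)
    splits = []
    for fold in range(k):
        test = LabeledGeneSet(pos_blocks[fold], neg_blocks[fold])
        train = LabeledGeneSet(
            labeled.positives - pos_blocks[fold], labeled.negatives - neg_blocks[fold]
        )
        splits.append(SubsampleSplit(fold_index=fold, train=train, test=test))
    return splits


@dataclass
class TrainedClassifier:
    """A tuned, fitted classifier with its identity and provenance.

    ``fold_index`` is -1 for a classifier trained on the full labeled set
    (the single-model baseline the subsampling scheme is compared against).
    """

    algorithm: str
    fold_index: int
    hyperparameters: dict[str, Any]
    estimator: Any = field(repr=False)
    feature_names: tuple[str, ...] = field(repr=False)
    cv_score: float = float("nan")
    seed: int = 0

    @property
    def name(self) -> str:
        return f"{self.algorithm}_full" if self.fold_index < 0 else (
            f"{self.algorithm}_fold{self.fold_index}"
        )

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        """Positive-class probability for every gene in ``features``."""
        if tuple(features.columns) != self.feature_names:
            raise ValueError(
                "feature columns do not match the classifier's training columns"
            )
        proba = self.estimator.predict_proba(features.to_numpy())
        pos_col = list(self.estimator.classes_).index(1)
        return pd.Series(proba[:, pos_col], index=features.index, name=self.name)


def _build_estimator(algorithm: str, seed: int) -> Any:
    if algorithm == "kNN":
        return KNeighborsClassifier()
    if algorithm == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def _finalize_estimator(algorithm: str, best: dict[str, Any], seed: int,
                        min_class: int) -> Any:
    """Estimator refit on the full training subsample with the chosen point.

    The SVM gets Platt-style sigmoid calibration fit by cross-validation
    inside the training data, since the ensemble rule needs probabilities in
    [0, 1] from all three families (kNN and RF provide them natively).
    """
    est = clone(_build_estimator(algorithm, seed))
    est.set_params(**best)
    if algorithm == "SVM":
        cv = StratifiedKFold(n_splits=max(2, min(5, min_class)),
                             shuffle=True, random_state=seed)
        return CalibratedClassifierCV(est, method="sigmoid", cv=cv, ensemble=False)
    return est


def _design(
    genes_pos: frozenset[str], genes_neg: frozenset[str], features: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ids = sorted(genes_pos) + sorted(genes_neg)
    X = features.loc[ids].to_numpy()
    y = np.r_[np.ones(len(genes_pos), dtype=int), np.zeros(len(genes_neg), dtype=int)]
    return X, y, ids


def _tune_and_fit(
    algorithm: str,
    pos: frozenset[str],
    neg: frozenset[str],
    features: pd.DataFrame,
    grid: dict[str, list[Any]],
    cv_folds: int,
    seed: int,
    fold_index: int,
    scoring: str,
) -> TrainedClassifier:
    if not pos or not neg:
        raise ValueError("training set must contain both classes")
    if not grid:
        raise ValueError(f"empty hyperparameter grid for {algorithm}")
    LabeledGeneSet(pos, neg).require_in(features)
    if min(len(pos), len(neg)) < cv_folds:
        raise ValueError(
            f"smallest training class ({min(len(pos), len(neg))}) is below "
            f"cv_folds={cv_folds}; stratified cross-validation is impossible"
        )
    X, y, _ = _design(pos, neg, features)

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _build_estimator(algorithm, seed),
        param_grid=grid,
        scoring=scoring,
        cv=cv,
        refit=False,
        n_jobs=1,
    )
    search.fit(X, y)
    # GridSearchCV's best index resolves ties by first occurrence in
    # ParameterGrid iteration order, keeping the choice deterministic
    best = dict(ParameterGrid(grid)[int(search.best_index_)])

    final = _finalize_estimator(algorithm, best, seed, min(len(pos), len(neg)))
    final.fit(X, y)
    return TrainedClassifier(
        algorithm=algorithm,
        fold_index=fold_index,
        hyperparameters=best,
        estimator=final,
        feature_names=tuple(features.columns),
        cv_score=float(search.best_score_),
        seed=seed,
    )


def tune_and_train(
    algorithm: str,
    split: SubsampleSplit,
    features: pd.DataFrame,
    grid: dict[str, list[Any]] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    scoring: str = "accuracy",
) -> TrainedClassifier:
    """Grid-search ``algorithm`` on ``split.train`` only and refit on it.

    The split's test set is never seen here; the returned classifier exposes
    probabilities in [0, 1] via :meth:`TrainedClassifier.predict_proba`.
    """
    if grid is None:
        grid = default_grids()[algorithm]
    sub_seed = derive_seed(seed, ALGORITHMS.index(algorithm), split.fold_index)
    return _tune_and_fit(
        algorithm, split.train.positives, split.train.negatives, features,
        grid, cv_folds, sub_seed, split.fold_index, scoring,
    )


def train_full(
    algorithm: str,
    labeled: LabeledGeneSet,
    features: pd.DataFrame,
    grid: dict[str, list[Any]] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    scoring: str = "accuracy",
) -> TrainedClassifier:
    """Tune and fit one classifier on the *full* labeled set (no subsampling).

    This is the single-model baseline that the subsampled ensemble is
    compared against; its fold_index is -1.
    """
    if grid is None:
        grid = default_grids()[algorithm]
    sub_seed = derive_seed(seed, ALGORITHMS.index(algorithm), 2**20)
    return _tune_and_fit(
        algorithm, labeled.positives, labeled.negatives, features,
        grid, cv_folds, sub_seed, -1, scoring,
    )


def train_all(
    labeled: LabeledGeneSet,
    features: pd.DataFrame,
    grids: dict[str, dict[str, list[Any]]] | None = None,
    k: int = 5,
    cv_folds: int = 10,
    seed: int = 0,
    algorithms: tuple[str, ...] = ALGORITHMS,
    scoring: str = "accuracy",
) -> tuple[list[TrainedClassifier], list[SubsampleSplit]]:
    """Train every (algorithm, fold) combination: 3 x 5 = 15 under defaults.

    Returns the classifiers together with the subsample splits that produced
    them, so each classifier can later be evaluated on its own held-out fifth.
    """
    if grids is None:
        grids = default_grids()
    labeled.require_in(features)
    splits = make_subsample_splits(labeled, k=k, seed=derive_seed(seed, 2**20 + 1))
    classifiers = [
        tune_and_train(alg, split, features, grid=grids[alg],
                       cv_folds=cv_folds, seed=seed, scoring=scoring)
        for split in splits
        for alg in algorithms
    ]
    return classifiers, splits
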