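"""Train/test splitting, tuned base classifiers, and the majority-vote hybrid.

Three base learners are tuned by exhaustive search minimizing mean 5-fold
stratified cross-validation misclassification, then refit on the full
training split:

* kNN — k in {3, 5, 7} crossed with euclidean, manhattan (cityblock) and
  minkowski (p = 3) distances;
* SVM — RBF kernel, log-spaced box constraint C and kernel width gamma;
* ensemble tree — bootstrap-aggregated decision trees, 50/100/200 trees.

Features are z-scored with training-split statistics inside every model
(distance- and margin-based learners are scale-sensitive, and the epoch
descriptors span orders of magnitude). Zero-variance training columns are
dropped with a warning.

The hybrid model is a majority vote over the three members' hard labels;
its score (used only for AUC) is the mean of the member scores.

Two split protocols are provided. The epoch-random 50/50 split shuffles
*epochs*, so both halves contain epochs of every subject — subject-level
traits leak across the split and inflate apparent accuracy. Leave-one-
subject-out keeps each subject's epochs entirely in one test fold and is
the honest generalization estimate; both are exposed so the contrast is
measurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ConfigError, SchemaError, SingleClassError
from .features import FeatureMatrix

MODEL_KINDS = ("knn", "svm", "ensemble_tree")

DEFAULT_GRIDS = {
    "knn": [
        {"clf__n_neighbors": [3, 5, 7],
         "clf__metric": ["euclidean", "manhattan"]},
        {"clf__n_neighbors": [3, 5, 7],
         "clf__metric": ["minkowski"], "clf__p": [3]},
    ],
    "svm": [
        {"clf__C": [1.0, 10.0, 100.0],
         "clf__gamma": ["scale", 0.01, 0.1]},
    ],
    "ensemble_tree": [
        {"clf__n_estimators": [50, 100, 200]},
    ],
}


@dataclass
class SplitSpec:
    mode: str = "epoch_random_50_50"
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.mode not in ("epoch_random_50_50", "leave_one_subject_out"):
            raise ConfigError(f"unknown split mode {self.mode!r}")


def split(matrix: FeatureMatrix, spec: SplitSpec):
    """Row indices for the requested protocol.

    epoch_random_50_50 returns ``(train_idx, test_idx)`` with a per-class
    seeded shuffle split half/half (|train| and |test| differ by at most 1
    per class). leave_one_subject_out returns an iterator of
    ``(subject_id, train_idx, test_idx)`` folds in cohort order.
    """
    y = matrix.labels
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise SingleClassError("need at least 2 rows per class to split")
    if spec.mode == "epoch_random_50_50":
        rng = np.random.default_rng(spec.seed)
        train, test = [], []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            half = (idx.size + 1) // 2
            train.append(idx[:half])
            test.append(idx[half:])
        return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))
    return _loso_folds(matrix)


def _loso_folds(matrix: FeatureMatrix) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
    sids = matrix.subject_ids
    seen = list(dict.fromkeys(sids))  # first-appearance order
    for sid in seen:
        test = np.flatnonzero(sids == sid)
        train = np.flatnonzero(sids != sid)
        if np.unique(matrix.labels[train]).size < 2:
            raise SingleClassError(
                f"LOSO fold for {sid!r} leaves single-class training data")
        yield sid, train, test


@dataclass
class ClassifierSpec:
    kind: str
    hyper_grid: list | None = None
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ConfigError(f"unknown classifier kind {self.kind!r}")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.hyper_grid is None:
            self.hyper_grid = DEFAULT_GRIDS[self.kind]
        if not self.hyper_grid:
            raise ConfigError("empty hyperparameter grid")


def _base_estimator(spec: ClassifierSpec):
    if spec.kind == "knn":
        return KNeighborsClassifier()
    if spec.kind == "svm":
        return SVC(kernel="rbf")
    return RandomForestClassifier(random_state=spec.seed)


@dataclass
class FittedModel:
    """A tuned, refit classifier bound to its training columns."""

    spec: ClassifierSpec
    columns: list[str]
    pipeline: Pipeline
    chosen_hypers: dict
    cv_loss: float
    dropped_columns: list[str] = field(default_factory=list)

    def _check(self, rows):
        missing = [c for c in self.columns if c not in rows.columns]
        if missing:
            raise SchemaError(f"prediction rows lack columns {missing[:5]}")

    def predict(self, rows) -> tuple[np.ndarray, np.ndarray]:
        """Hard 0/1 labels and probability-like scores in [0, 1].

        kNN scores are the neighbor vote fraction; ensemble-tree scores the
        tree vote fraction; SVM scores a logistic squash of the decision
        function (monotone in the margin, so AUC is unaffected). Labels are
        score >= 0.5 in every case.
        """
        self._check(rows)
        X = rows[self.columns].to_numpy(dtype=float)
        if self.spec.kind == "svm":
            margin = self.pipeline.decision_function(X)
            scores = 1.0 / (1.0 + np.exp(-margin))
        else:
            proba = self.pipeline.predict_proba(X)
            cls = list(self.pipeline.classes_)
            scores = proba[:, cls.index(1)]
        labels = (scores >= 0.5).astype(int)
        return labels, scores


def tune_and_fit(rows, labels, spec: ClassifierSpec) -> FittedModel:
    """Grid-search the spec's hyperparameters by 5-fold CV, refit on all rows.

    *rows* is a DataFrame of feature columns; *labels* a 0/1 vector.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise SingleClassError("training rows contain a single class")
    X = rows.to_numpy(dtype=float)
    variances = X.var(axis=0)
    keep = variances > 0
    dropped = [c for c, k in zip(rows.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): "
                      f"{dropped[:5]}", stacklevel=2)
        rows = rows.loc[:, keep]
        X = X[:, keep]
    columns = list(rows.columns)

    pipe = Pipeline([("scale", StandardScaler()),
                     ("clf", _base_estimator(spec))])
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                         random_state=spec.seed)
    search = GridSearchCV(pipe, spec.hyper_grid, scoring="accuracy",
                          cv=cv, refit=True, n_jobs=1)
    search.fit(X, y)
    chosen = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
    return FittedModel(spec=spec, columns=columns,
                       pipeline=search.best_estimator_,
                       chosen_hypers=chosen,
                       cv_loss=1.0 - float(search.best_score_),
                       dropped_columns=dropped)


@dataclass
class HybridModel:
    """Majority vote over exactly three fitted base models."""

    members: list[FittedModel]

    def __post_init__(self):
        if len(self.members) != 3:
            raise ConfigError("hybrid model needs exactly 3 members")

    def predict(self, rows) -> tuple[np.ndarray, np.ndarray]:
        member_labels = []
        member_scores = []
        for m in self.members:
            lab, sc = m.predict(rows)
            member_labels.append(lab)
            member_scores.append(sc)
        votes = np.sum(member_labels, axis=0)
        labels = (votes >= 2).astype(int)
        scores = np.mean(member_scores, axis=0)
        return labels, scores


def hybrid_predict(model: HybridModel, rows):
    return model.predict(rows)


def majority_vote(labels_triplet) -> int:
    """Majority of three hard 0/1 labels."""
    a, b, c = labels_triplet
    return int(a + b + c >= 2)


def fit_all(rows, labels, seed: int = 0,
            kinds=MODEL_KINDS) -> dict[str, FittedModel | HybridModel]:
    """Tune and fit the three base models plus the hybrid on one train split."""
    models: dict[str, FittedModel | HybridModel] = {}
    for kind in kinds:
        models[kind] = tune_and_fit(rows, labels, ClassifierSpec(kind=kind, seed=seed))
    if all(k in models for k in MODEL_KINDS):
        models["hybrid"] = HybridModel([models[k] for k in MODEL_KINDS])
    return models
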