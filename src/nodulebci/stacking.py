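"""Two-tier stacked generalisation with out-of-fold level-2 training.

Five heterogeneous base families — RBF support-vector classifier, random
forest, L2 logistic regression, k-nearest neighbours, and AdaBoost on
depth-1 stumps — are each trained five times over a stratified 5-fold split
of the training set.  Every training sample's level-2 feature is the
positive-class score of the one base model that did *not* see that sample
(out-of-fold integrity), giving an n_train x 5 matrix on which a logistic
meta-learner is fitted.  Test-set level-2 features are the average of the
five fold models' scores per family.
"""
from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import DataError, ValidationError

__all__ = [
    "StackedModel",
    "default_base_specs",
    "split_train_test",
    "build_level2_matrix",
    "average_test_predictions",
    "fit_stacking",
    "predict",
    "cross_validated_auc",
    "save_model",
    "load_model",
]

_BUNDLE_VERSION = 1


class AnovaScreen(BaseEstimator, TransformerMixin):
    """Keep the k features with the largest ANOVA F score against the label.

    k is capped at the number of available columns, so the screen is a
    no-op on low-dimensional inputs; constant columns score lowest.
    """

    def __init__(self, k: int = 32):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores, _ = f_classif(X, y)
        scores = np.nan_to_num(scores, nan=-np.inf)
        k = min(self.k, X.shape[1])
        self.support_ = np.sort(np.argsort(-scores, kind="stable")[:k])
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]


def default_base_specs(seed: int = 0, screen_k: int = 16) -> list[tuple[str, object]]:
    """The five base-learner families with their default hyperparameters.

    Scale-sensitive learners (SVC, KNN, logistic) are wrapped with a
    standardiser and an ANOVA feature screen, both fitted inside each fold:
    epoch feature vectors are high-dimensional relative to the number of
    classification units typical of an oddball session, and distance- and
    margin-based learners dilute badly without screening.  ``screen_k``
    caps the number of features kept (disabled when <= 0).  All
    hyperparameters are overridable by passing a custom spec list.
    """
    def scaled(est, screened=True):
        steps = [("scale", StandardScaler())]
        if screened and screen_k > 0:
            steps.append(("screen", AnovaScreen(k=screen_k)))
        steps.append(("clf", est))
        return Pipeline(steps)

    return [
        ("svc", scaled(CalibratedClassifierCV(
            SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
            ensemble=False))),
        ("random_forest", RandomForestClassifier(n_estimators=200,
                                                 random_state=seed)),
        ("logreg", scaled(LogisticRegression(C=1.0, max_iter=2000))),
        ("knn", scaled(KNeighborsClassifier(n_neighbors=5))),
        ("adaboost", AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=100, random_state=seed)),
    ]


@dataclass
class StackedModel:
    """Fitted two-tier model: 5 families x 5 folds plus the meta-learner."""

    base_names: list[str]
    fitted_base: dict[str, list[object]]
    meta: object
    fold_assignment: np.ndarray
    n_features: int
    seed: int
    n_folds: int = 5
    version: int = _BUNDLE_VERSION
    meta_name: str = "logreg"
    extra: dict = field(default_factory=dict)


def _positive_score(est, X: np.ndarray) -> np.ndarray:
    """Positive-class probability of a fitted binary classifier."""
    if not hasattr(est, "predict_proba"):
        raise ValidationError("base learners must expose predict_proba")
    proba = est.predict_proba(X)
    classes = getattr(est, "classes_", np.array([0, 1]))
    pos = int(np.where(classes == 1)[0][0]) if 1 in classes else proba.shape[1] - 1
    return np.asarray(proba)[:, pos]


def split_train_test(
    X: np.ndarray, y: np.ndarray, ratio: float = 0.5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test split; the protocol uses a 1:1 ratio."""
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    if len(X) < 10:
        raise ValidationError("need at least 10 samples to split")
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=ratio, stratify=y, random_state=seed, shuffle=True
    )
    return X_tr, X_te, y_tr, y_te


def build_level2_matrix(
    X_train: np.ndarray,
    y_train: np.ndarray,
    base_specs: list[tuple[str, object]] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict[str, list[object]]]:
    """Out-of-fold level-2 training matrix Z (n_train x n_families).

    Z[i, j] is family j's positive-class score for sample i, produced by the
    fold model whose training part excluded i.  Each family is fitted
    exactly ``n_folds`` times; the fitted fold models are returned for
    test-set averaging.
    """
    if base_specs is None:
        base_specs = default_base_specs(seed)
    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train).astype(int)
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    counts = np.bincount(y_train, minlength=2)
    if counts.min() < n_folds:
        raise DataError(
            f"a fold would lose a class (class counts {counts.tolist()}, "
            f"n_folds={n_folds}); increase data or reduce folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    n = len(X_train)
    Z = np.zeros((n, len(base_specs)))
    fold_assignment = np.full(n, -1, dtype=int)
    fitted: dict[str, list[object]] = {name: [] for name, _ in base_specs}
    splits = list(skf.split(X_train, y_train))
    for fold_i, (_, held) in enumerate(splits):
        fold_assignment[held] = fold_i
    for j, (name, spec) in enumerate(base_specs):
        for fold_i, (tr, held) in enumerate(splits):
            est = clone(spec)
            est.fit(X_train[tr], y_train[tr])
            Z[held, j] = _positive_score(est, X_train[held])
            fitted[name].append(est)
    return Z, fold_assignment, fitted


def average_test_predictions(
    fitted_base: dict[str, list[object]], X: np.ndarray
) -> np.ndarray:
    """Level-2 features for unseen data: per-family mean of fold scores."""
    X = np.asarray(X)
    names = list(fitted_base)
    n_folds = {len(models) for models in fitted_base.values()}
    if len(n_folds) != 1 or 0 in n_folds:
        raise ValidationError("every family needs the same non-zero fold count")
    Z = np.zeros((len(X), len(names)))
    for j, name in enumerate(names):
        Z[:, j] = np.mean(
            [_positive_score(m, X) for m in fitted_base[name]], axis=0
        )
    return Z


def fit_stacking(
    X_train: np.ndarray,
    y_train: np.ndarray,
    base_specs: list[tuple[str, object]] | None = None,
    meta_spec: object | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> StackedModel:
    """Fit the full two-tier model on a training set.

    The meta-learner (logistic regression by default, pluggable) is trained
    on the out-of-fold matrix with the original labels unchanged.
    """
    if base_specs is None:
        base_specs = default_base_specs(seed)
    Z, fold_assignment, fitted = build_level2_matrix(
        X_train, y_train, base_specs, n_folds=n_folds, seed=seed
    )
    if np.any(Z.std(axis=0) == 0):
        warnings.warn("level-2 matrix has constant column(s); proceeding")
    meta = meta_spec if meta_spec is not None else LogisticRegression(max_iter=2000)
    meta = clone(meta)
    meta.fit(Z, np.asarray(y_train).astype(int))
    return StackedModel(
        base_names=[name for name, _ in base_specs],
        fitted_base=fitted,
        meta=meta,
        fold_assignment=fold_assignment,
        n_features=np.asarray(X_train).shape[1],
        seed=seed,
        n_folds=n_folds,
        meta_name=type(meta).__name__,
    )


def predict(model: StackedModel, X: np.ndarray) -> np.ndarray:
    """Meta-learner positive-class score in [0, 1] for each row of X."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature layout mismatch: expected {model.n_features} columns"
        )
    Z = average_test_predictions(model.fitted_base, X)
    return _positive_score(model.meta, Z)


def cross_validated_auc(
    X: np.ndarray,
    y: np.ndarray,
    base_specs: list[tuple[str, object]] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated AUC of the stack on one data set.

    Base scores are already out-of-fold; the meta-learner's scores are made
    out-of-fold as well via an inner stratified cross_val_predict, so the
    AUC carries no training optimism.
    """
    from sklearn.model_selection import cross_val_predict

    from .evaluation import roc_auc

    y = np.asarray(y).astype(int)
    Z, _, _ = build_level2_matrix(X, y, base_specs, n_folds=n_folds, seed=seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + 1)
    meta_scores = cross_val_predict(
        LogisticRegression(max_iter=2000), Z, y, cv=skf, method="predict_proba"
    )[:, 1]
    return roc_auc(meta_scores, y).auc


def save_model(model: StackedModel, path: str | Path) -> None:
    """Versioned on-disk bundle: JSON manifest + per-learner pickle blobs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": model.version,
        "base_names": model.base_names,
        "n_folds": model.n_folds,
        "n_features": model.n_features,
        "seed": model.seed,
        "meta_name": model.meta_name,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.save(path / "fold_assignment.npy", model.fold_assignment)
    with open(path / "learners.pkl", "wb") as fh:
        pickle.dump({"base": model.fitted_base, "meta": model.meta}, fh)


def load_model(path: str | Path) -> StackedModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest["version"] != _BUNDLE_VERSION:
        raise DataError(f"unsupported model bundle version {manifest['version']}")
    with open(path / "learners.pkl", "rb") as fh:
        learners = pickle.load(fh)
    return StackedModel(
        base_names=manifest["base_names"],
        fitted_base=learners["base"],
        meta=learners["meta"],
        fold_assignment=np.load(path / "fold_assignment.npy"),
        n_features=manifest["n_features"],
        seed=manifest["seed"],
        n_folds=manifest["n_folds"],
        meta_name=manifest["meta_name"],
    )
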