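"""Gini-criterion classification trees and their gradient-boosted ensemble.

The base learner is a CART-style binary classification tree whose splits
minimize the size-weighted Gini impurity of the child nodes; the boosted
model is an XGBoost ensemble of such trees under a logistic objective with
shrinkage and L2 regularization. The impurity arithmetic is exposed as
standalone, tested operations (:func:`gini_index`, :func:`branch_purity`);
training delegates to scikit-learn's ``DecisionTreeClassifier`` configured
for the Gini criterion and to ``xgboost.XGBClassifier``.

Throughout the package, essential = 1 is the positive class, and the
canonical model output is the positive-class probability; hard labels are
derived by thresholding at 0.5.
"""

from __future__ import annotations

import os
from pathlib import Path

import joblib
import numpy as np
import sklearn
import xgboost
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

from . import __version__ as _pkg_version
from .encoders import FeatureMatrix

MODEL_SCHEMA_VERSION = 1


class ProvenanceError(ValueError):
    """Feature provenance of the input does not match the fitted model's."""


class ModelArtifactError(ValueError):
    """A persisted model artifact is missing, corrupt, or incompatible."""


def gini_index(class_proportions) -> float:
    """Gini impurity 1 − Σ pᵢ² of a class-proportion vector.

    Zero for a pure node; maximal (1 − 1/k) at the uniform distribution
    over k classes.
    """
    p = np.asarray(class_proportions, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("class proportions must be a non-empty 1-d vector")
    if np.any(p < 0):
        raise ValueError("class proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {p.sum()!r}")
    return float(1.0 - np.sum(p * p))


def branch_purity(subset_sizes, subset_proportions) -> float:
    """Size-weighted mean Gini impurity over the subsets of a split."""
    sizes = np.asarray(subset_sizes, dtype=float)
    if sizes.ndim != 1 or sizes.size == 0:
        raise ValueError("subset sizes must be a non-empty 1-d vector")
    if np.any(sizes <= 0):
        raise ValueError("every subset must be non-empty")
    if len(subset_proportions) != sizes.size:
        raise ValueError("one proportion vector is required per subset")
    weights = sizes / sizes.sum()
    return float(sum(w * gini_index(p) for w, p in zip(weights, subset_proportions)))


def _unwrap(X):
    """Split a FeatureMatrix into (values, provenance); pass arrays through."""
    if isinstance(X, FeatureMatrix):
        return X.values, dict(X.provenance)
    return X, None


class _ProvenancedClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict plumbing: validation + feature-provenance checks."""

    def _validate_fit(self, X, y):
        X, provenance = _unwrap(X)
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                f"training labels contain a single class ({classes.tolist()}); "
                "both essential (1) and non-essential (0) examples are required"
            )
        if classes.size > 2 or not set(classes) <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got classes {classes.tolist()}")
        self.feature_provenance_ = provenance
        self.n_features_in_ = X.shape[1]
        return X, y

    def _validate_predict(self, X):
        check_is_fitted(self)
        X, provenance = _unwrap(X)
        if provenance is not None and self.feature_provenance_ is not None:
            if provenance != self.feature_provenance_:
                raise ProvenanceError(
                    "feature provenance mismatch: model was fitted on "
                    f"{self.feature_provenance_!r} but input carries {provenance!r}"
                )
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got array of shape {X.shape}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        """Hard labels: positive-class probability thresholded at 0.5."""
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_scores(self, X) -> np.ndarray:
        """Positive-class (essential) probabilities in [0, 1]."""
        return self.predict_proba(X)[:, 1]


class GiniTreeClassifier(_ProvenancedClassifier):
    """A single CART-style binary tree with the Gini split criterion.

    Parameters
    ----------
    splitter : {"best", "random"}
        Branching randomness S: best split vs. best random split.
    max_depth : int
        Maximum tree depth D.
    max_features : int or None
        Number of features M examined per split; None means all.
    random_state : int
        Seed; it matters when ``splitter="random"`` or M < n.
    """

    def __init__(self, splitter="best", max_depth=6, max_features=None, random_state=0):
        self.splitter = splitter
        self.max_depth = max_depth
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._validate_fit(X, y)
        if self.max_features is not None and self.max_features > X.shape[1]:
            raise ValueError(
                f"max_features={self.max_features} exceeds the feature "
                f"dimension n={X.shape[1]}"
            )
        self.tree_ = DecisionTreeClassifier(
            criterion="gini",
            splitter=self.splitter,
            max_depth=self.max_depth,
            max_features=self.max_features,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = self.tree_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate_predict(X)
        return self.tree_.predict_proba(X)

    @property
    def depth_(self) -> int:
        check_is_fitted(self)
        return int(self.tree_.get_depth())


class BoostedTreesClassifier(_ProvenancedClassifier):
    """Gradient-boosted Gini trees under a logistic objective (XGBoost).

    Parameters
    ----------
    n_trees : int
        Ensemble size T.
    learning_rate : float
        Shrinkage R applied to each tree's contribution.
    max_depth : int
        Per-tree depth D.
    reg_lambda : float
        L2 regularization λ on leaf weights.
    random_state : int
        Seed for column/row subsampling reproducibility.
    """

    def __init__(
        self, n_trees=100, learning_rate=0.3, max_depth=6, reg_lambda=1.0, random_state=0
    ):
        self.n_trees = n_trees
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.reg_lambda = reg_lambda
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._validate_fit(X, y)
        self.booster_ = xgboost.XGBClassifier(
            n_estimators=self.n_trees,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            reg_lambda=self.reg_lambda,
            random_state=self.random_state,
            objective="binary:logistic",
            eval_metric="logloss",
            tree_method="exact",
            n_jobs=1,
        ).fit(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate_predict(X)
        return self.booster_.predict_proba(X)


def train_tree(X, y, params: dict | None = None, seed: int = 0) -> GiniTreeClassifier:
    """Fit a single Gini tree; thin wrapper over :class:`GiniTreeClassifier`."""
    return GiniTreeClassifier(**(params or {}), random_state=seed).fit(X, y)


def train_boosted(X, y, params: dict | None = None, seed: int = 0) -> BoostedTreesClassifier:
    """Fit the boosted ensemble; thin wrapper over :class:`BoostedTreesClassifier`."""
    return BoostedTreesClassifier(**(params or {}), random_state=seed).fit(X, y)


def predict_proba(model, X) -> np.ndarray:
    """Positive-class scores of a fitted model on a feature matrix."""
    return model.decision_scores(X)


def save_model(model, path: str | os.PathLike) -> None:
    """Persist a fitted model with provenance and library versions."""
    check_is_fitted(model)
    bundle = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "model": model,
        "feature_provenance": getattr(model, "feature_provenance_", None),
        "versions": {
            "essmir": _pkg_version,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        },
    }
    joblib.dump(bundle, path)


def load_model(path: str | os.PathLike):
    """Load a persisted model, refusing incompatible artifacts."""
    path = Path(path)
    if not path.exists():
        raise ModelArtifactError(f"model artifact {path} does not exist")
    try:
        bundle = joblib.load(path)
    except Exception as exc:
        raise ModelArtifactError(f"cannot read model artifact {path}: {exc}") from exc
    if not isinstance(bundle, dict) or "schema_version" not in bundle:
        raise ModelArtifactError(f"{path} is not an essmir model artifact")
    if bundle["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ModelArtifactError(
            f"model artifact schema version {bundle['schema_version']} is not "
            f"supported (expected {MODEL_SCHEMA_VERSION})"
        )
    model = bundle["model"]
    model.feature_provenance_ = bundle.get("feature_provenance")
    return model
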