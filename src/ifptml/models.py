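"""Data splitting, classifier suite, tuning and cross-validation.

The linear model is an LDA whose decision function is an explicit linear
score over the feature columns (intercept a0, weight a1 on f_ref, weights
on raw and Δ descriptors) — the fitted coefficients are exposed so the
score can be audited term by term.  The nonlinear suite covers random
forest, RBF-SVM, decision tree, KNN, gradient boosting and a histogram
gradient-boosting model standing in for XGBoost (same algorithm family;
hyperparameter names are translated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import (
    GridSearchCV,
    RandomizedSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.model_selection import cross_validate as _sk_cross_validate
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .pt_engine import FeatureMatrix

DEFAULT_SEED = 42

#: hyperparameters the original study reports for its final XGBoost model
#: (grid-refined: depth 12, 160 estimators, learning rate 0.267, subsample 1).
STUDY_XGB_PARAMS = {
    "n_estimators": 160,
    "max_depth": 12,
    "learning_rate": 0.267,
    "subsample": 1.0,
}

FAMILIES = ("LDA", "RF", "SVM", "DT", "KNN", "GB", "XGB")


class ModelConfigError(ValueError):
    pass


class ColumnContractError(ValueError):
    pass


@dataclass
class SplitPlan:
    strategy: str = "random_stratified"  # or "kmeans_within_cluster"
    train_fraction: float = 0.8
    k: int = 5
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.strategy not in ("random_stratified", "kmeans_within_cluster"):
            raise ModelConfigError(f"unknown split strategy {self.strategy!r}")
        if not 0 < self.train_fraction < 1:
            raise ModelConfigError("train_fraction must be in (0, 1)")


def _as_frame(fm) -> pd.DataFrame:
    return fm.df if isinstance(fm, FeatureMatrix) else pd.DataFrame(fm)


def make_split(fm, labels, plan: SplitPlan) -> np.ndarray:
    """Boolean train mask over rows (True = training partition)."""
    X = _as_frame(fm)
    y = np.asarray(labels)
    n = len(X)
    idx = np.arange(n)
    mask = np.zeros(n, dtype=bool)

    if plan.strategy == "random_stratified":
        strat = y if len(np.unique(y)) > 1 else None
        tr, _ = train_test_split(
            idx, train_size=plan.train_fraction, stratify=strat,
            random_state=plan.seed,
        )
        mask[tr] = True
        return mask

    # K-Means split: cluster on the standardized feature space, then split
    # 80/20 inside each cluster (stratified where both classes occur).
    Xs = StandardScaler().fit_transform(X.to_numpy(float))
    km = KMeans(n_clusters=plan.k, random_state=plan.seed, n_init=10)
    clusters = km.fit_predict(Xs)
    for c in np.unique(clusters):
        rows = idx[clusters == c]
        if len(rows) < 5:
            warnings.warn(
                f"cluster {c} has {len(rows)} rows (<5); all assigned to train"
            )
            mask[rows] = True
            continue
        yc = y[rows]
        strat = yc if len(np.unique(yc)) > 1 else None
        try:
            tr, _ = train_test_split(
                rows, train_size=plan.train_fraction, stratify=strat,
                random_state=plan.seed,
            )
        except ValueError:  # a class with a single member in this cluster
            tr, _ = train_test_split(
                rows, train_size=plan.train_fraction, random_state=plan.seed
            )
        mask[tr] = True
    return mask


@dataclass
class ModelSpec:
    family: str = "XGB"
    params: dict = field(default_factory=dict)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelConfigError(
                f"unknown model family {self.family!r}; choose from {FAMILIES}"
            )
        est = build_estimator(self)  # validates hyperparameter names
        del est


def _translate_xgb_params(params: dict) -> dict:
    """Map XGBoost-style names onto HistGradientBoostingClassifier."""
    out = {}
    for k, v in params.items():
        if k == "n_estimators":
            out["max_iter"] = int(v)
        elif k == "subsample":
            if float(v) != 1.0:
                warnings.warn(
                    "subsample != 1.0 is not supported by the histogram "
                    "gradient-boosting backend; ignoring"
                )
        else:
            out[k] = v
    return out


def build_estimator(spec: ModelSpec):
    """Instantiate the sklearn estimator behind a model spec."""
    p = dict(spec.params)
    try:
        if spec.family == "LDA":
            return LinearDiscriminantAnalysis(**{"solver": "lsqr", **p})
        if spec.family == "RF":
            return RandomForestClassifier(random_state=spec.seed, **p)
        if spec.family == "SVM":
            return SVC(kernel="rbf", probability=True,
                       random_state=spec.seed, **p)
        if spec.family == "DT":
            return DecisionTreeClassifier(random_state=spec.seed, **p)
        if spec.family == "KNN":
            return KNeighborsClassifier(**p)
        if spec.family == "GB":
            return GradientBoostingClassifier(random_state=spec.seed, **p)
        if spec.family == "XGB":
            return HistGradientBoostingClassifier(
                random_state=spec.seed, **_translate_xgb_params(p)
            )
    except TypeError as exc:
        raise ModelConfigError(
            f"invalid hyperparameters for {spec.family}: {exc}"
        ) from exc
    raise ModelConfigError(spec.family)


@dataclass
class LDACoefficients:
    """The linear scoring form: intercept plus one weight per feature."""

    intercept: float
    weights: pd.Series

    def score(self, X: pd.DataFrame) -> np.ndarray:
        X = X[self.weights.index]
        return self.intercept + X.to_numpy(float) @ self.weights.to_numpy()


class PTMLClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style wrapper over the model suite with a column contract.

    Refuses prediction on feature matrices whose columns differ from the
    training snapshot.  For the LDA family the fitted linear coefficients
    are exposed as :attr:`coefficients_`.
    """

    def __init__(self, family: str = "XGB", params: dict | None = None,
                 seed: int = DEFAULT_SEED):
        self.family = family
        self.params = params
        self.seed = seed

    def _spec(self) -> ModelSpec:
        return ModelSpec(self.family, dict(self.params or {}), self.seed)

    def fit(self, fm, y) -> "PTMLClassifier":
        X = _as_frame(fm)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ModelConfigError("training labels are single-class")
        self.feature_names_ = list(X.columns)
        self.feature_std_ = X.std(ddof=0)
        self.estimator_ = build_estimator(self._spec())
        self.estimator_.fit(X.to_numpy(float), y)
        self.classes_ = self.estimator_.classes_
        if self.family == "LDA":
            est = self.estimator_
            self.coefficients_ = LDACoefficients(
                intercept=float(est.intercept_[0]),
                weights=pd.Series(est.coef_[0], index=self.feature_names_),
            )
        return self

    def _check_columns(self, X: pd.DataFrame) -> None:
        if list(X.columns) != self.feature_names_:
            extra = sorted(set(X.columns) - set(self.feature_names_))
            missing = sorted(set(self.feature_names_) - set(X.columns))
            raise ColumnContractError(
                f"feature columns differ from the training snapshot "
                f"(missing: {missing}; unexpected: {extra}; order matters)"
            )

    def predict_proba(self, fm) -> np.ndarray:
        X = _as_frame(fm)
        self._check_columns(X)
        return self.estimator_.predict_proba(X.to_numpy(float))

    def predict(self, fm) -> np.ndarray:
        # class = P(active) > 0.5, consistent across the suite
        return (self.predict_proba(fm)[:, 1] > 0.5).astype(int)

    def decision_function(self, fm) -> np.ndarray:
        X = _as_frame(fm)
        self._check_columns(X)
        return self.estimator_.decision_function(X.to_numpy(float))


def train(spec: ModelSpec, fm_train, labels_train) -> PTMLClassifier:
    """Fit one model from a spec (functional form)."""
    clf = PTMLClassifier(spec.family, dict(spec.params), spec.seed)
    return clf.fit(fm_train, labels_train)


# -- hyperparameter search -------------------------------------------------

DEFAULT_RANDOM_ITERS = {"XGB": 45, "LDA": 15}

_SEARCH_SPACES = {
    "LDA": [
        {"solver": ["svd"]},
        {"solver": ["lsqr", "eigen"],
         "shrinkage": [None, "auto", 0.0, 0.1, 0.25, 0.5, 0.75, 0.9]},
    ],
    "XGB": {
        "max_iter": randint(50, 300),
        "learning_rate": loguniform(0.01, 0.5),
        "max_depth": randint(3, 15),
    },
    "GB": {
        "n_estimators": randint(50, 300),
        "learning_rate": loguniform(0.01, 0.5),
        "max_depth": randint(2, 8),
    },
    "RF": {"n_estimators": randint(100, 500), "max_depth": randint(3, 20)},
    "SVM": {"C": loguniform(0.01, 100), "gamma": loguniform(1e-4, 1)},
    "DT": {"max_depth": randint(2, 20)},
    "KNN": {"n_neighbors": randint(3, 30)},
}


def _neighborhood(value, grid_step=0.25):
    """±1-step grid around a randomized optimum, type-preserving."""
    if isinstance(value, (int, np.integer)):
        return sorted({max(1, value - 1), value, value + 1})
    if isinstance(value, (float, np.floating)):
        return sorted({round(value * (1 - grid_step), 6), value,
                       round(value * (1 + grid_step), 6)})
    return [value]


@dataclass
class SearchResult:
    best_spec: ModelSpec
    log: pd.DataFrame


def tune(
    spec: ModelSpec,
    fm_train,
    labels_train,
    random_iters: int | None = None,
    cv: int = 5,
    refine: bool = True,
) -> SearchResult:
    """Randomized search then a ±1-neighborhood grid refinement.

    Selection is by mean CV accuracy; the full search log is returned.
    """
    X = _as_frame(fm_train).to_numpy(float)
    y = np.asarray(labels_train).astype(int)
    space = _SEARCH_SPACES.get(spec.family)
    if not space:
        raise ModelConfigError(f"empty search space for {spec.family}")
    iters = random_iters or DEFAULT_RANDOM_ITERS.get(spec.family, 20)
    base = build_estimator(ModelSpec(spec.family, {}, spec.seed))
    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=spec.seed)
    rs = RandomizedSearchCV(
        base, space, n_iter=iters, scoring="accuracy", cv=folds,
        random_state=spec.seed, n_jobs=1,
    )
    rs.fit(X, y)
    logs = [pd.DataFrame(rs.cv_results_)[["params", "mean_test_score"]]
            .assign(stage="random")]
    best_params = dict(rs.best_params_)

    if refine and best_params:
        grid = {k: _neighborhood(v) for k, v in best_params.items()}
        gs = GridSearchCV(base, grid, scoring="accuracy", cv=folds, n_jobs=1)
        gs.fit(X, y)
        logs.append(pd.DataFrame(gs.cv_results_)[["params", "mean_test_score"]]
                    .assign(stage="grid"))
        best_params = dict(gs.best_params_)

    log = pd.concat(logs, ignore_index=True)
    return SearchResult(ModelSpec(spec.family, best_params, spec.seed), log)


@dataclass
class CVResult:
    fold_accuracy: np.ndarray
    fold_auc: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def mean_auc(self) -> float:
        return float(self.fold_auc.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.fold_accuracy.std(ddof=1))


def cross_validate(
    spec: ModelSpec, fm, labels, folds: int = 10, seed: int | None = None
) -> CVResult:
    """Stratified k-fold accuracy and ROC AUC."""
    X = _as_frame(fm).to_numpy(float)
    y = np.asarray(labels).astype(int)
    if folds > len(y):
        raise ModelConfigError("more folds than samples")
    cv = StratifiedKFold(
        n_splits=folds, shuffle=True,
        random_state=spec.seed if seed is None else seed,
    )
    res = _sk_cross_validate(
        build_estimator(spec), X, y, cv=cv,
        scoring=("accuracy", "roc_auc"), n_jobs=1,
    )
    return CVResult(
        fold_accuracy=res["test_accuracy"], fold_auc=res["test_roc_auc"]
    )
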