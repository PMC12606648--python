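"""Splits, model suite, LDA scoring form, tuning, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from ifptml import (
    STUDY_XGB_PARAMS,
    ModelSpec,
    PTMLClassifier,
    SplitPlan,
    cross_validate,
    make_split,
    train,
    tune,
)
from ifptml.models import (
    ColumnContractError,
    LDACoefficients,
    ModelConfigError,
    build_estimator,
)


@pytest.fixture(scope="module")
def blobs():
    """Linearly separable 2-D toy problem."""
    rng = np.random.default_rng(0)
    n = 200
    X = pd.DataFrame({
        "x1": np.r_[rng.normal(-3, 0.5, n // 2), rng.normal(3, 0.5, n // 2)],
        "x2": rng.normal(0, 1, n),
    })
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    return X, y


@pytest.fixture(scope="module")
def noisy():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(600, 8)),
                     columns=[f"f{i}" for i in range(8)])
    y = (X["f0"] + 0.7 * X["f1"] + rng.normal(0, 1, 600) > 0).astype(int)
    return X, y.to_numpy()


class TestSplit:
    def test_stratified_fractions_and_balance(self, noisy):
        X, y = noisy
        mask = make_split(X, y, SplitPlan(seed=42))
        assert mask.sum() == round(0.8 * len(y))
        # class ratio preserved within one row per stratum
        for cls in (0, 1):
            n_cls = (y == cls).sum()
            assert abs(mask[y == cls].sum() - 0.8 * n_cls) <= 1

    def test_single_class_toy(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        y = np.ones(20, dtype=int)
        mask = make_split(X, y, SplitPlan(seed=0))
        assert 0 < mask.sum() < 20

    def test_kmeans_split_within_cluster(self, noisy):
        X, y = noisy
        plan = SplitPlan(strategy="kmeans_within_cluster", seed=42)
        mask = make_split(X, y, plan)
        frac = mask.mean()
        assert 0.75 <= frac <= 0.85
        # deterministic under the same seed
        np.testing.assert_array_equal(mask, make_split(X, y, plan))

    def test_tiny_cluster_goes_to_train(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({
            "x": np.r_[rng.normal(0, 0.1, 40), rng.normal(100, 0.1, 3)],
            "y": np.r_[rng.normal(0, 0.1, 40), rng.normal(100, 0.1, 3)],
        })
        y = rng.integers(0, 2, 43)
        plan = SplitPlan(strategy="kmeans_within_cluster", k=2, seed=1)
        with pytest.warns(UserWarning, match="<5"):
            mask = make_split(X, y, plan)
        assert mask[-3:].all()


class TestTrainPredict:
    def test_lda_perfect_separation(self, blobs):
        X, y = blobs
        clf = train(ModelSpec("LDA"), X, y)
        assert (clf.predict(X) == y).all()

    def test_lda_score_equals_explicit_expansion(self, noisy):
        """predict_proba threshold agrees with the explicit linear score
        a0 + Σ w_k x_k to 1e-10."""
        X, y = noisy
        clf = train(ModelSpec("LDA"), X, y)
        manual = clf.coefficients_.score(X)
        np.testing.assert_allclose(
            clf.decision_function(X), manual, atol=1e-10
        )
        assert ((manual > 0).astype(int) == clf.predict(X)).all()

    def test_hand_set_coefficients_toy(self):
        """3-row toy scored by hand arithmetic."""
        coef = LDACoefficients(
            intercept=0.5,
            weights=pd.Series({"f_ref": 2.0, "D1": -1.0}),
        )
        X = pd.DataFrame({"f_ref": [0.0, 0.5, 1.0], "D1": [1.0, 0.0, -2.0]})
        np.testing.assert_allclose(coef.score(X), [-0.5, 1.5, 4.5])

    def test_all_zero_coefficients_positive_intercept(self):
        coef = LDACoefficients(0.7, pd.Series({"a": 0.0, "b": 0.0}))
        X = pd.DataFrame({"a": [1, -5, 9.0], "b": [0, 2, -3.0]})
        assert ((coef.score(X) > 0).astype(int) == 1).all()

    def test_rf_deterministic_under_seed(self, noisy):
        X, y = noisy
        p1 = train(ModelSpec("RF", seed=7), X, y).predict_proba(X)
        p2 = train(ModelSpec("RF", seed=7), X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_study_xgb_hyperparameters_train(self, noisy):
        """The reported final boosting setting (subsample 1.0, 160 trees,
        depth 12, learning rate 0.267) fits without error."""
        X, y = noisy
        clf = train(ModelSpec("XGB", dict(STUDY_XGB_PARAMS)), X, y)
        proba = clf.predict_proba(X)[:, 1]
        assert ((proba >= 0) & (proba <= 1)).all()

    def test_every_family_fits_and_bounds_probability(self, blobs):
        X, y = blobs
        for fam in ("LDA", "RF", "SVM", "DT", "KNN", "GB", "XGB"):
            p = train(ModelSpec(fam), X, y).predict_proba(X)[:, 1]
            assert ((p >= 0) & (p <= 1)).all(), fam

    def test_column_contract(self, noisy):
        X, y = noisy
        clf = train(ModelSpec("DT"), X, y)
        with pytest.raises(ColumnContractError, match="f7"):
            clf.predict(X.drop(columns=["f7"]))

    def test_single_class_labels_rejected(self, blobs):
        X, _ = blobs
        with pytest.raises(ModelConfigError):
            train(ModelSpec("LDA"), X, np.zeros(len(X), dtype=int))

    def test_unknown_family_and_params_rejected(self):
        with pytest.raises(ModelConfigError):
            ModelSpec("MLP")
        with pytest.raises(ModelConfigError):
            ModelSpec("RF", {"not_a_param": 3})


class TestTune:
    def test_grid_over_single_point(self, noisy):
        X, y = noisy
        res = tune(ModelSpec("DT"), X, y, random_iters=1, cv=3, refine=False)
        assert len(res.log) == 1
        assert res.best_spec.family == "DT"

    def test_lda_search_logs_requested_samples(self, noisy):
        X, y = noisy
        res = tune(ModelSpec("LDA"), X, y, random_iters=15, cv=3, refine=False)
        assert (res.log["stage"] == "random").sum() == 15

    def test_depth_sensitive_signal_recovered(self):
        """An interaction signal needs depth ≥ 2; tuning should not pick a
        stump."""
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(500, 4)),
                         columns=list("abcd"))
        y = ((X["a"] * X["b"]) > 0).astype(int).to_numpy()
        res = tune(ModelSpec("DT", seed=0), X, y, random_iters=8, cv=3)
        assert res.best_spec.params["max_depth"] >= 2


class TestCrossValidate:
    def test_perfect_separation(self, blobs):
        X, y = blobs
        cv = cross_validate(ModelSpec("LDA"), X, y, folds=5)
        assert cv.mean_accuracy == pytest.approx(1.0)
        assert cv.mean_auc == pytest.approx(1.0)

    def test_permuted_labels_null(self, noisy):
        X, y = noisy
        rng = np.random.default_rng(0)
        yp = y.copy()
        rng.shuffle(yp)
        cv = cross_validate(ModelSpec("LDA"), X, yp, folds=10, seed=1)
        assert cv.mean_auc == pytest.approx(0.5, abs=0.05)

    def test_too_many_folds_rejected(self, blobs):
        X, y = blobs
        with pytest.raises(ModelConfigError):
            cross_validate(ModelSpec("LDA"), X, y, folds=len(y) + 1)
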