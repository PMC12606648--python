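"""End-to-end estimator: assay table in, trained classifier out.

Chains labelling → perturbation featurisation → variance and correlation
filtering → standardisation → train/test split → model fit, under a single
*scope* switch:

* ``scope="full"`` (the historical protocol): moving-average and reference
  tables, filters and scaler are fitted on the whole dataset before
  splitting.  This leaks test-set information through f_ref and is kept to
  mirror the original workflow.
* ``scope="train_only"`` (leakage-safe): everything after labelling is
  fitted on the training partition only and merely applied to the test
  rows.

Labels are always computed on the full table first (they are data
curation, and the stratified split needs them); the scope governs every
fitted statistic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assay_data import Dataset
from .evaluation import MetricsReport, evaluate
from .feature_prep import CorrelationFilter, FeatureScaler, VarianceFilter
from .labeling import ActivityLabeler, LabelingPolicy
from .models import DEFAULT_SEED, PTMLClassifier, SplitPlan, make_split
from .pt_engine import PTFeaturizer
from .screening import (
    enumerate_conditions,
    predict_new,
    relative_outcome,
    success_summary,
)


@dataclass
class PipelineResult:
    train_report: MetricsReport
    test_report: MetricsReport
    train_mask: np.ndarray


class IFPTMLPipeline:
    """The whole modelling workflow as one fit/predict object.

    Parameters
    ----------
    model_family, model_params, seed : model suite selection.
    policy : optional explicit labelling policy.
    scope : "full" | "train_only" — see module docstring.
    variance_threshold, r_max : feature-filter thresholds.
    split : SplitPlan; defaults to the random stratified 80/20 split.
    """

    def __init__(
        self,
        model_family: str = "XGB",
        model_params: dict | None = None,
        policy: LabelingPolicy | None = None,
        scope: str = "full",
        variance_threshold: float = 0.01,
        r_max: float = 0.97,
        split: SplitPlan | None = None,
        seed: int = DEFAULT_SEED,
    ):
        if scope not in ("full", "train_only"):
            raise ValueError(f"unknown scope {scope!r}")
        self.model_family = model_family
        self.model_params = model_params
        self.policy = policy
        self.scope = scope
        self.variance_threshold = variance_threshold
        self.r_max = r_max
        self.split = split or SplitPlan(seed=seed)
        self.seed = seed

    # -- fitting -----------------------------------------------------------
    def fit(self, ds: Dataset, y=None) -> "IFPTMLPipeline":
        self.labeler_ = ActivityLabeler(policy=self.policy)
        labeled = self.labeler_.fit_transform(ds)
        labels = labeled.labels.to_numpy(int)

        self.featurizer_ = PTFeaturizer(scope=self.scope)
        self.vfilter_ = VarianceFilter(self.variance_threshold)
        self.cfilter_ = CorrelationFilter(self.r_max)
        self.scaler_ = FeatureScaler()

        if self.scope == "full":
            fm = self.featurizer_.fit(labeled).transform(labeled)
            fm = self.vfilter_.fit(fm).transform(fm)
            fm = self.cfilter_.fit(fm).transform(fm)
            X = self.scaler_.fit(fm).transform(fm)
            mask = make_split(X, labels, self.split)
            X_train, y_train = X.df[mask], labels[mask]
            X_test, y_test = X.df[~mask], labels[~mask]
        else:
            # split first (on labels only), then fit every statistic on train
            mask = make_split(labeled.descriptors.fillna(0.0), labels, self.split)
            train_ds = Dataset(labeled.df[mask].reset_index(drop=True),
                               labeled.schema)
            test_ds = Dataset(labeled.df[~mask].reset_index(drop=True),
                              labeled.schema)
            fm_train = self.featurizer_.fit(train_ds).transform(train_ds)
            fm_train = self.vfilter_.fit(fm_train).transform(fm_train)
            fm_train = self.cfilter_.fit(fm_train).transform(fm_train)
            X_train = self.scaler_.fit(fm_train).transform(fm_train).df
            y_train = labels[mask]
            fm_test = self.featurizer_.transform(test_ds)
            fm_test = self.cfilter_.transform(self.vfilter_.transform(fm_test))
            X_test = self.scaler_.transform(fm_test).df
            y_test = labels[~mask]

        self.model_ = PTMLClassifier(
            self.model_family, dict(self.model_params or {}), self.seed
        ).fit(X_train, y_train)

        self.train_mask_ = mask
        self.labels_ = labels
        self.result_ = PipelineResult(
            train_report=evaluate(
                y_train, self.model_.predict(X_train),
                scores=self.model_.predict_proba(X_train)[:, 1],
            ),
            test_report=evaluate(
                y_test, self.model_.predict(X_test),
                scores=self.model_.predict_proba(X_test)[:, 1],
            ),
            train_mask=mask,
        )
        self._train_dataset_ = ds
        return self

    # -- application -------------------------------------------------------
    def transform(self, ds: Dataset):
        """Feature matrix for new records under the fitted tables."""
        fm = self.featurizer_.transform(ds)
        fm = self.cfilter_.transform(self.vfilter_.transform(fm))
        return self.scaler_.transform(fm)

    def predict(self, ds: Dataset) -> np.ndarray:
        return self.model_.predict(self.transform(ds))

    def predict_proba(self, ds: Dataset) -> np.ndarray:
        return self.model_.predict_proba(self.transform(ds))

    # -- screening ---------------------------------------------------------
    def predict_grid(self, queries, condition_filter=None):
        """Score query compounds over all matching condition tuples of the
        training data; see :mod:`ifptml.screening`."""
        tuples = enumerate_conditions(self._train_dataset_, condition_filter)
        return predict_new(
            self.model_,
            self.featurizer_.ma_,
            self.featurizer_.ref_,
            queries,
            tuples,
            self._train_dataset_.schema,
            column_selector=self.cfilter_.retained_,
            scaler=self.scaler_,
        )

    def screen(self, queries, reference_id: str,
               aggregation_filter: dict | None = None,
               condition_filter=None):
        """Predict, then aggregate relative to a reference compound."""
        grid = self.predict_grid(queries, condition_filter)
        return (
            grid,
            relative_outcome(grid, reference_id, aggregation_filter),
            success_summary(grid),
        )
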