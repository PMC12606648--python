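"""Confusion matrices, classification statistics and ROC analysis.

Specificity, sensitivity and accuracy are reported as percentages (the
convention of the assay-efficacy tables this package mirrors); precision /
recall / F1 are reported both for the positive class and label-weighted;
MCC and unweighted Cohen's kappa come from the same 2×2 table.  AUC is the
Mann–Whitney rank statistic, which equals the trapezoidal integral of the
ROC staircase.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score, roc_curve

from .models import PTMLClassifier


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise EvaluationError("confusion-matrix counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


def confusion(y_obs, y_pred) -> ConfusionMatrix:
    """Exact 2×2 cross-tabulation of observed vs predicted {0,1}."""
    y_obs = np.asarray(y_obs)
    y_pred = np.asarray(y_pred)
    if y_obs.shape != y_pred.shape:
        raise EvaluationError("y_obs and y_pred lengths differ")
    if not (set(np.unique(y_obs)) <= {0, 1} and set(np.unique(y_pred)) <= {0, 1}):
        raise EvaluationError("labels must be binary 0/1")
    return ConfusionMatrix(
        tn=int(np.sum((y_obs == 0) & (y_pred == 0))),
        fp=int(np.sum((y_obs == 0) & (y_pred == 1))),
        fn=int(np.sum((y_obs == 1) & (y_pred == 0))),
        tp=int(np.sum((y_obs == 1) & (y_pred == 1))),
    )


@dataclass
class MetricsReport:
    cm: ConfusionMatrix
    specificity: float          # Sp, %
    sensitivity: float          # Sn, %
    accuracy: float             # Ac, %
    precision: float            # positive class, fraction
    recall: float
    f1: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    mcc: float
    kappa: float
    auc: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_per_class(self) -> dict[int, int]:
        return {0: self.cm.tn + self.cm.fp, 1: self.cm.tp + self.cm.fn}

    def to_dict(self) -> dict:
        return {
            "confusion": {"tn": self.cm.tn, "fp": self.cm.fp,
                          "fn": self.cm.fn, "tp": self.cm.tp},
            "Sp_pct": self.specificity, "Sn_pct": self.sensitivity,
            "Ac_pct": self.accuracy,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
            "mcc": self.mcc, "kappa": self.kappa, "auc": self.auc,
            "flags": self.flags,
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    def format_table(self) -> str:
        """Sp/Sn/Ac block in the layout of the assay-efficacy tables."""
        cm = self.cm
        lines = [
            "observed     stat        n     pred=0  pred=1",
            f"obs=0        Sp {self.specificity:6.2f}%  {cm.tn + cm.fp:5d}  "
            f"{cm.tn:6d}  {cm.fp:6d}",
            f"obs=1        Sn {self.sensitivity:6.2f}%  {cm.tp + cm.fn:5d}  "
            f"{cm.fn:6d}  {cm.tp:6d}",
            f"total        Ac {self.accuracy:6.2f}%  {cm.n:5d}  "
            f"{cm.tn + cm.fn:6d}  {cm.fp + cm.tp:6d}",
        ]
        return "\n".join(lines)


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(f"{name}: zero denominator, reported 0")
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix, y_obs=None, scores=None) -> MetricsReport:
    """All closed-form statistics of a 2×2 table; AUC when scores given."""
    if cm.n == 0:
        raise EvaluationError("empty confusion matrix")
    tn, fp, fn, tp = cm.tn, cm.fp, cm.fn, cm.tp
    n = cm.n
    flags: list[str] = []
    sp = 100.0 * _safe_div(tn, tn + fp, flags, "Sp")
    sn = 100.0 * _safe_div(tp, tp + fn, flags, "Sn")
    ac = 100.0 * (tn + tp) / n
    prec = _safe_div(tp, tp + fp, flags, "precision")
    rec = _safe_div(tp, tp + fn, flags, "recall")
    f1 = _safe_div(2 * prec * rec, prec + rec, flags, "f1")
    prec0 = _safe_div(tn, tn + fn, flags, "precision_neg")
    rec0 = _safe_div(tn, tn + fp, flags, "recall_neg")
    f10 = _safe_div(2 * prec0 * rec0, prec0 + rec0, flags, "f1_neg")
    w0, w1 = (tn + fp) / n, (tp + fn) / n

    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, flags, "mcc")

    po = (tn + tp) / n
    pe = ((tn + fp) * (tn + fn) + (tp + fn) * (tp + fp)) / n**2
    kappa = _safe_div(po - pe, 1 - pe, flags, "kappa")

    auc = None
    if scores is not None:
        if y_obs is None:
            raise EvaluationError("AUC needs y_obs alongside scores")
        auc = float(roc_auc_score(np.asarray(y_obs), np.asarray(scores)))

    return MetricsReport(
        cm=cm, specificity=sp, sensitivity=sn, accuracy=ac,
        precision=prec, recall=rec, f1=f1,
        precision_weighted=w0 * prec0 + w1 * prec,
        recall_weighted=w0 * rec0 + w1 * rec,
        f1_weighted=w0 * f10 + w1 * f1,
        mcc=mcc, kappa=kappa, auc=auc, flags=flags,
    )


def evaluate(y_obs, y_pred, scores=None) -> MetricsReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(y_obs, y_pred), y_obs=y_obs, scores=scores)


def roc_points(y_obs, scores) -> tuple[pd.DataFrame, float]:
    """Monotone ROC staircase from (0,0) to (1,1) plus its AUC.

    The trapezoidal integral of the returned points equals the
    Mann–Whitney formulation of the AUC.
    """
    y_obs = np.asarray(y_obs)
    if len(np.unique(y_obs)) < 2:
        raise EvaluationError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y_obs, np.asarray(scores))
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), auc


def passes_acceptability(report: MetricsReport, threshold: float = 70.0) -> bool:
    """Model-acceptability gate: accuracy AND sensitivity above threshold %."""
    return report.accuracy > threshold and report.sensitivity > threshold


def feature_importance(
    model: PTMLClassifier,
    top_n: int = 20,
    X=None,
    y=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Ranked (feature, weight) list.

    LDA → |coefficient × training-column std| (importance on the
    standardized scale); impurity-based families → gain importances; the
    histogram-gradient-boosting family has no analytic importances, so
    permutation importance on (X, y) is used.  Ties break by registry order.
    """
    names = model.feature_names_
    est = model.estimator_
    if model.family == "LDA":
        weights = np.abs(
            model.coefficients_.weights.to_numpy()
            * model.feature_std_.to_numpy()
        )
    elif hasattr(est, "feature_importances_"):
        weights = np.asarray(est.feature_importances_, dtype=float)
    elif model.family == "XGB":
        if X is None or y is None:
            raise EvaluationError(
                "permutation importance for XGB needs X and y"
            )
        Xdf = X.df if hasattr(X, "df") else X
        res = permutation_importance(
            est, Xdf.to_numpy(float), np.asarray(y), n_repeats=3,
            random_state=seed, n_jobs=1,
        )
        weights = res.importances_mean
    else:
        raise EvaluationError(
            f"feature importance unsupported for family {model.family}"
        )
    order = np.lexsort((np.arange(len(names)), -weights))
    ranked = pd.DataFrame(
        {"feature": [names[i] for i in order],
         "weight": weights[order]}
    )
    return ranked.head(top_n).reset_index(drop=True)
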