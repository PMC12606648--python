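"""Binarising heterogeneous activity readouts into a single objective label.

Assays report activity on incompatible scales (IC50 in nM, % inhibition,
Km, ...).  Each activity-measure class c0 gets a *desirability* d(c0) ∈
{+1, −1} saying whether a desirable compound maximises (+1, e.g. %
inhibition) or minimises (−1, e.g. IC50) the readout, and a *cut-off* in the
measure's own units.  The objective label is then

    d = +1 : f_obj = 1  iff  v > cutoff
    d = −1 : f_obj = 1  iff  v < cutoff

with strict inequalities (a value sitting exactly on the cut-off is
inactive).  Censored readouts (standard relation ``>`` or ``<``) are
labelled active only when the censoring direction *guarantees* the
criterion; ambiguous censorings are conservatively inactive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .assay_data import Dataset

#: substrings identifying concentration-type measures (d = −1, 100 nM).
CONCENTRATION_KEYWORDS = ("ic50", "ki ", "ki(", "ki_", "potency", "kd", "km")

#: substrings identifying percentage-type measures (d = +1, 70 %).
PERCENT_KEYWORDS = ("residual activity", "inhibition", "metabolism", "activity")

DEFAULT_CONCENTRATION_CUTOFF_NM = 100.0
DEFAULT_PERCENT_CUTOFF = 70.0


class PolicyError(ValueError):
    """A c0 level has no desirability rule and no applicable default."""


@dataclass
class DesirabilityRule:
    measure: str
    d: int
    cutoff_kind: str = "fixed"  # "fixed" | "dataset_mean"
    cutoff_value: float | None = None

    def __post_init__(self) -> None:
        if self.d not in (+1, -1):
            raise PolicyError(f"desirability must be ±1, got {self.d}")
        if self.cutoff_kind not in ("fixed", "dataset_mean"):
            raise PolicyError(f"unknown cutoff_kind {self.cutoff_kind!r}")

    @property
    def resolved(self) -> bool:
        return self.cutoff_value is not None


@dataclass
class LabelingPolicy:
    """One rule per activity-measure class."""

    rules: dict[str, DesirabilityRule] = field(default_factory=dict)

    def rule_for(self, measure: str) -> DesirabilityRule:
        if measure not in self.rules:
            raise PolicyError(f"no desirability rule for measure {measure!r}")
        return self.rules[measure]

    def to_yaml(self, path) -> None:
        data = [
            {
                "measure": str(r.measure),
                "d": int(r.d),
                "cutoff_kind": str(r.cutoff_kind),
                "cutoff_value": None if r.cutoff_value is None
                else float(r.cutoff_value),
            }
            for r in self.rules.values()
        ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LabelingPolicy":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            {d["measure"]: DesirabilityRule(**d) for d in data}
        )


def classify_measure(measure: str) -> str:
    """Heuristic family of a measure label: percent / concentration / other."""
    m = measure.lower()
    if "%" in m or any(k in m for k in PERCENT_KEYWORDS):
        return "percent"
    if "nm" in m or any(m.startswith(k.strip()) or k in m
                        for k in CONCENTRATION_KEYWORDS):
        return "concentration"
    return "other"


def default_policy(ds: Dataset, other_d: int = +1) -> LabelingPolicy:
    """Build the standard policy over every c0 level present in ``ds``.

    Percentage measures → d=+1, cut-off 70 %; concentration measures →
    d=−1, cut-off 100 nM; anything else → ``other_d`` with the dataset mean
    of its own activity values as cut-off (resolved here).
    """
    c0_col = ds.schema.condition_columns[0]
    rules: dict[str, DesirabilityRule] = {}
    for measure in ds.df[c0_col].unique():
        fam = classify_measure(measure)
        if fam == "percent":
            rules[measure] = DesirabilityRule(
                measure, +1, "fixed", DEFAULT_PERCENT_CUTOFF
            )
        elif fam == "concentration":
            rules[measure] = DesirabilityRule(
                measure, -1, "fixed", DEFAULT_CONCENTRATION_CUTOFF_NM
            )
        else:
            mean = float(
                ds.df.loc[ds.df[c0_col] == measure, ds.schema.activity_column].mean()
            )
            rules[measure] = DesirabilityRule(measure, other_d, "dataset_mean", mean)
    return LabelingPolicy(rules)


def objective_function(v: float, rule: DesirabilityRule, relation: str = "=") -> int:
    """Binarise a single readout under a resolved rule.

    ``relation`` is the standard relation c9: the reported number ``v``
    bounds the true value from below (``>``) or above (``<``).  A censored
    record is active only when the bound guarantees the criterion.
    """
    if not rule.resolved:
        raise PolicyError(
            f"dataset_mean cutoff for {rule.measure!r} not resolved"
        )
    cut = rule.cutoff_value
    if relation == "=":
        return int(v > cut) if rule.d == +1 else int(v < cut)
    if relation == ">":
        # true value exceeds v: certifies only "maximise" criteria
        return int(rule.d == +1 and v >= cut)
    if relation == "<":
        return int(rule.d == -1 and v <= cut)
    raise PolicyError(f"unknown standard relation {relation!r}")


@dataclass
class LabelReport:
    counts: dict[int, int]
    per_measure: dict[str, dict[int, int]]

    @property
    def prevalence(self) -> float:
        n = self.counts.get(0, 0) + self.counts.get(1, 0)
        return self.counts.get(1, 0) / n if n else float("nan")


class ActivityLabeler(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer assigning the binary objective label.

    Parameters
    ----------
    policy : LabelingPolicy or None
        Explicit policy; if None, the default policy is built at fit time
        from the fitted dataset (dataset-mean cut-offs resolved on it).
    other_d : int
        Desirability assigned to measures outside the two standard families.
    """

    def __init__(self, policy: LabelingPolicy | None = None, other_d: int = +1):
        self.policy = policy
        self.other_d = other_d

    def fit(self, ds: Dataset, y=None) -> "ActivityLabeler":
        if self.policy is not None:
            # resolve any unresolved dataset_mean cut-offs on the fit data
            c0_col = ds.schema.condition_columns[0]
            for rule in self.policy.rules.values():
                if rule.cutoff_kind == "dataset_mean" and not rule.resolved:
                    sel = ds.df[c0_col] == rule.measure
                    rule.cutoff_value = float(
                        ds.df.loc[sel, ds.schema.activity_column].mean()
                    )
            self.policy_ = self.policy
        else:
            self.policy_ = default_policy(ds, other_d=self.other_d)
        return self

    def transform(self, ds: Dataset) -> Dataset:
        c0_col = ds.schema.condition_columns[0]
        c9_col = ds.schema.condition_columns[9]
        labels = []
        for i, (measure, v, rel) in enumerate(
            zip(ds.df[c0_col], ds.df[ds.schema.activity_column], ds.df[c9_col])
        ):
            try:
                rule = self.policy_.rule_for(measure)
                labels.append(objective_function(float(v), rule, rel))
            except PolicyError as exc:
                raise PolicyError(f"row {i}: {exc}") from exc
        labeled = ds.with_labels(pd.Series(labels, index=ds.df.index))
        self.report_ = _label_report(labeled)
        return labeled

    def fit_transform(self, ds: Dataset, y=None, **kw) -> Dataset:
        return self.fit(ds).transform(ds)


def _label_report(ds: Dataset) -> LabelReport:
    lab = ds.labels
    c0_col = ds.schema.condition_columns[0]
    counts = {k: int(v) for k, v in lab.value_counts().items()}
    per = {}
    for measure, grp in ds.df.groupby(c0_col):
        vc = grp[ds.schema.label_column].value_counts()
        per[measure] = {int(k): int(v) for k, v in vc.items()}
    return LabelReport(
        counts={0: counts.get(0, 0), 1: counts.get(1, 0)}, per_measure=per
    )


def label_dataset(
    ds: Dataset, policy: LabelingPolicy | None = None
) -> tuple[Dataset, LabelReport]:
    """Label every record; returns the labeled dataset and a class-balance
    report."""
    labeler = ActivityLabeler(policy=policy)
    labeled = labeler.fit_transform(ds)
    return labeled, labeler.report_
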