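"""Screening new compounds against enumerated assay conditions.

A *query compound* is a full drug-descriptor block with no measured
activity.  Screening crosses each query with condition tuples observed in
the reference dataset (each tuple carries its target's protein-domain
descriptors), recomputes the perturbation features against the *fitted*
moving-average tables — never refitting them — looks up f_ref through the
fallback chain, and scores the trained model.  Predictions are summarised
two ways:

* a *relative outcome* matrix Δf(target × compound): mean difference of
  the predicted class between each compound and a named reference compound
  over a filtered slice of conditions (by default binding assays on
  *Homo sapiens* targets), bounded in [−1, +1];
* *success summaries*: mean predicted probability per compound and per
  assay type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay_data import Dataset
from .pt_engine import FeatureMatrix, MATable, ReferenceTable, assemble_features
from .schema import CONDITION_FIELDS, DatasetSchema


class ScreeningError(ValueError):
    pass


@dataclass
class QueryCompound:
    """One candidate: id + complete drug-descriptor block (+ optional
    assay-variable overrides)."""

    compound_id: str
    descriptors: pd.Series
    variables: dict[str, float] = field(default_factory=dict)

    def validate(self, schema: DatasetSchema) -> None:
        missing = [c for c in schema.drug_descriptor_columns
                   if c not in self.descriptors.index]
        if missing:
            raise ScreeningError(
                f"query {self.compound_id!r} missing descriptors: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        vals = self.descriptors[schema.drug_descriptor_columns].to_numpy(float)
        if not np.isfinite(vals).all():
            raise ScreeningError(
                f"query {self.compound_id!r} has non-finite descriptors"
            )


def queries_from_frame(df: pd.DataFrame, schema: DatasetSchema) -> list[QueryCompound]:
    """Read query compounds from a table with the drug-descriptor header."""
    out = []
    for _, row in df.iterrows():
        q = QueryCompound(
            compound_id=str(row[schema.compound_column]),
            descriptors=row.drop(schema.compound_column),
            variables={c: float(row[c]) for c in schema.variable_columns
                       if c in row.index and pd.notna(row[c])},
        )
        q.validate(schema)
        out.append(q)
    return out


def _condition_filter(df: pd.DataFrame, flt) -> pd.Series:
    if flt is None:
        return pd.Series(True, index=df.index)
    if callable(flt):
        return df.apply(flt, axis=1).astype(bool)
    mask = pd.Series(True, index=df.index)
    for fld, value in flt.items():
        mask &= df[fld] == value
    return mask


def enumerate_conditions(ds: Dataset, condition_filter=None) -> pd.DataFrame:
    """Distinct condition tuples (with their protein descriptors) present in
    the dataset and passing the filter; deterministic order.

    ``condition_filter`` is either a mapping {canonical field -> level}
    (e.g. ``{"c10": "B", "c4": "Homo sapiens"}``) or a row predicate.
    """
    s = ds.schema
    cmap = s.condition_map
    cond_cols = list(cmap.values())
    prot_cols = list(s.protein_descriptor_columns)
    var_cols = list(s.variable_columns)
    tup = ds.df[cond_cols + prot_cols + var_cols].copy()
    tup[var_cols] = tup[var_cols].fillna(0.0)
    tup = tup.rename(columns={v: k for k, v in cmap.items()})
    tup = tup.drop_duplicates(subset=list(CONDITION_FIELDS))
    mask = _condition_filter(tup, condition_filter)
    tup = tup[mask].sort_values(list(CONDITION_FIELDS), kind="mergesort")
    if tup.empty:
        import warnings

        warnings.warn("condition filter matched no tuples")
    return tup.reset_index(drop=True)


def _grid_dataset(
    queries: list[QueryCompound], tuples: pd.DataFrame, schema: DatasetSchema
) -> Dataset:
    """Cross queries × tuples into a synthetic-activity Dataset for
    featurisation (activity column is a placeholder, never used)."""
    rows = []
    for q in queries:
        q.validate(schema)
        for _, t in tuples.iterrows():
            row = {schema.compound_column: q.compound_id,
                   schema.activity_column: 0.0}
            for f, col in schema.condition_map.items():
                row[col] = t[f]
            for c in schema.drug_descriptor_columns:
                row[c] = float(q.descriptors[c])
            for c in schema.protein_descriptor_columns:
                row[c] = float(t[c])
            for c in schema.variable_columns:
                row[c] = float(q.variables.get(c, t.get(c, 0.0)))
            rows.append(row)
    return Dataset(pd.DataFrame(rows), schema)


def predict_new(
    model,
    ma: MATable,
    ref: ReferenceTable,
    queries: list[QueryCompound],
    tuples: pd.DataFrame,
    schema: DatasetSchema,
    column_selector=None,
    scaler=None,
) -> pd.DataFrame:
    """Score every (query, tuple) pair; returns the prediction grid.

    ``column_selector`` is the ordered list of retained feature columns
    (from the fitted filters) and ``scaler`` the fitted
    :class:`~ifptml.feature_prep.FeatureScaler`; both default to identity.
    Each output row records the predicted class, probability, the condition
    tuple, and whether the f_ref lookup was exact or a fallback.
    """
    if not queries:
        raise ScreeningError("no query compounds")
    grid_ds = _grid_dataset(queries, tuples, schema)
    fm = assemble_features(grid_ds, ma, ref)
    if column_selector is not None:
        fm = fm.select(list(column_selector))
    X: FeatureMatrix | pd.DataFrame = fm
    if scaler is not None:
        X = scaler.transform(fm)
    proba = model.predict_proba(X)[:, 1]

    out = grid_ds.df[[schema.compound_column]].copy()
    cmap = schema.condition_map
    for f, col in cmap.items():
        out[f] = grid_ds.df[col].to_numpy()
    out["probability"] = proba
    out["f_calc"] = (proba > 0.5).astype(int)
    out["f_ref_source"] = fm.fallback_flags["f_ref_source"].to_numpy()
    return out.rename(columns={schema.compound_column: "compound_id"})


@dataclass
class RelativeOutcome:
    """Δf matrix (targets × compounds) with per-cell support counts."""

    delta: pd.DataFrame
    support: pd.DataFrame
    reference_id: str
    aggregation_filter: dict | None


def relative_outcome(
    grid: pd.DataFrame,
    reference_id: str,
    aggregation_filter: dict | None = None,
) -> RelativeOutcome:
    """Mean per (target, compound) of f_calc(compound) − f_calc(reference)
    over the filtered tuples; cells with no shared tuple stay NaN."""
    if aggregation_filter is None:
        aggregation_filter = {"c10": "B"}
    mask = _condition_filter(grid, aggregation_filter)
    sub = grid[mask]
    ref_rows = sub[sub["compound_id"] == reference_id]
    if ref_rows.empty:
        raise ScreeningError(
            f"reference compound {reference_id!r} absent from the "
            "filtered grid"
        )
    key_cols = list(CONDITION_FIELDS)
    ref_pred = ref_rows.groupby(key_cols)["f_calc"].first()

    others = sub.set_index(key_cols)
    aligned = ref_pred.reindex(others.index)
    diff = others["f_calc"].to_numpy(float) - aligned.to_numpy(float)
    tmp = pd.DataFrame({
        "target": others.index.get_level_values("c1").to_numpy(),
        "compound": others["compound_id"].to_numpy(),
        "diff": diff,
    }).dropna(subset=["diff"])

    delta = tmp.pivot_table(index="target", columns="compound",
                            values="diff", aggfunc="mean")
    support = tmp.pivot_table(index="target", columns="compound",
                              values="diff", aggfunc="count")
    return RelativeOutcome(
        delta=delta.sort_index(),
        support=support.reindex_like(delta).fillna(0).astype(int),
        reference_id=reference_id,
        aggregation_filter=aggregation_filter,
    )


@dataclass
class SuccessSummary:
    by_compound: pd.Series
    by_assay_type: pd.Series


def success_summary(grid: pd.DataFrame) -> SuccessSummary:
    """Mean predicted success probability per compound and per assay type,
    ordered by value (descending) then id."""
    if grid.empty:
        raise ScreeningError("empty prediction grid")

    def ordered(s: pd.Series) -> pd.Series:
        df = s.rename("p").reset_index()
        df = df.sort_values(["p", df.columns[0]],
                            ascending=[False, True], kind="mergesort")
        return df.set_index(df.columns[0])["p"]

    return SuccessSummary(
        by_compound=ordered(grid.groupby("compound_id")["probability"].mean()),
        by_assay_type=ordered(grid.groupby("c10")["probability"].mean()),
    )
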