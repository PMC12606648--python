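"""Perturbation-theory feature engine.

The core idea: a record's descriptors are re-expressed as *deviations from
the expectation under its own assay conditions*.  For each descriptor D_k
and each of two condition groupings —

* ``c_assay`` = (c1..c5): target, cell type, tissue, organisms,
* ``c_dat``   = (c6..c10): target type, fraction, buffer, relation, assay type

— the moving-average (MA) expectation ⟨D_k(c_j)⟩ is the mean of D_k over all
records sharing the grouping's full level tuple, and the perturbation
operator is the Box–Jenkins-style delta

    ΔD_k(c_j) = D_k − ⟨D_k(c_j)⟩.

A conditional *reference function* f_ref gives the empirical probability of
activity among records sharing the full condition tuple (c0..c10); at
prediction time unseen tuples fall back to the (c0, c10) pair and finally to
the global prevalence.

The assembled feature matrix is  [f_ref | raw descriptors | Δ_assay | Δ_dat],
i.e. ``1 + p + 2p`` columns for ``p`` raw descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .assay_data import Dataset
from .schema import ASSAY_GROUP, DAT_GROUP, CONDITION_FIELDS

GROUP_FIELDS = {"assay": ASSAY_GROUP, "dat": DAT_GROUP, "ref": CONDITION_FIELDS}


class FitError(RuntimeError):
    pass


class TupleLookupError(KeyError):
    pass


def _group_columns(ds: Dataset, group: str) -> list[str]:
    cmap = ds.schema.condition_map
    return [cmap[f] for f in GROUP_FIELDS[group]]


def _descriptor_frame(ds: Dataset) -> pd.DataFrame:
    """Descriptor block with missing assay variables imputed as 0 μM."""
    desc = ds.df[ds.schema.descriptor_columns].astype(float).copy()
    for col in ds.schema.variable_columns:
        desc[col] = desc[col].fillna(0.0)
    return desc


@dataclass
class MATable:
    """Group-conditional descriptor expectations ⟨D_k(c_j)⟩.

    ``means[group]`` is a DataFrame indexed by the group's level tuple with
    one column per descriptor; ``support[group]`` the per-tuple record
    count; ``global_means`` the scope-wide fallback.
    """

    means: dict[str, pd.DataFrame]
    support: dict[str, pd.Series]
    global_means: pd.Series
    scope: str = "full"

    def lookup(self, group: str, key: tuple, fallback: str = "global"):
        """Return (means row, used_fallback) for one tuple."""
        tab = self.means[group]
        try:
            return tab.loc[key], False
        except KeyError:
            if fallback == "global":
                return self.global_means, True
            raise TupleLookupError(
                f"unseen {group} tuple {key!r} and fallback disabled"
            ) from None

    def to_frame(self, group: str) -> pd.DataFrame:
        out = self.means[group].copy()
        out["__support__"] = self.support[group]
        return out.reset_index()


@dataclass
class ReferenceTable:
    """Conditional activity prevalence f_ref keyed by the full c-tuple."""

    table: pd.Series           # index: full condition tuple -> f_ref
    support: pd.Series
    pair_table: pd.Series      # (c0, c10) fallback
    fallback_value: float      # global prevalence of the fit scope
    scope: str = "full"

    def lookup(self, key: tuple) -> tuple[float, str]:
        """f_ref with fallback chain: exact tuple → (c0,c10) → global."""
        try:
            return float(self.table.loc[key]), "exact"
        except KeyError:
            pass
        try:
            return float(self.pair_table.loc[(key[0], key[-1])]), "pair"
        except KeyError:
            return self.fallback_value, "global"

    def to_frame(self) -> pd.DataFrame:
        out = self.table.rename("f_ref").reset_index()
        out["__support__"] = self.support.to_numpy()
        return out


@dataclass
class FeatureMatrix:
    """Model-ready rows plus per-column provenance."""

    df: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    fallback_flags: pd.DataFrame | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def select(self, columns) -> "FeatureMatrix":
        return FeatureMatrix(
            self.df[list(columns)].copy(),
            {c: self.provenance[c] for c in columns},
            self.fallback_flags,
        )


def delta_column(descriptor: str, group: str) -> str:
    return f"{descriptor}__d_{group}"


def fit_moving_averages(ds: Dataset, scope: str = "full") -> MATable:
    """Mean of every descriptor over each c_assay and c_dat level tuple."""
    if len(ds) == 0:
        raise FitError("cannot fit moving averages on an empty dataset")
    desc = _descriptor_frame(ds)
    means, support = {}, {}
    for group in ("assay", "dat"):
        cols = _group_columns(ds, group)
        grouped = desc.groupby([ds.df[c] for c in cols], sort=True)
        means[group] = grouped.mean()
        support[group] = grouped.size()
    return MATable(
        means=means,
        support=support,
        global_means=desc.mean(),
        scope=scope,
    )


def apply_deltas(
    ds: Dataset, ma: MATable, unseen_rule: str = "global"
) -> FeatureMatrix:
    """Populate ΔD_k(c_assay) and ΔD_k(c_dat) for every descriptor."""
    desc = _descriptor_frame(ds)
    blocks = []
    prov: dict[str, str] = {}
    for group in ("assay", "dat"):
        cols = _group_columns(ds, group)
        keys = pd.MultiIndex.from_frame(ds.df[cols])
        tab = ma.means[group]
        expected = tab.reindex(keys)
        missing = expected.iloc[:, 0].isna().to_numpy()
        if missing.any():
            if unseen_rule != "global":
                bad = keys[np.flatnonzero(missing)[0]]
                raise TupleLookupError(
                    f"unseen {group} tuple {tuple(bad)!r} and fallback disabled"
                )
            expected.loc[missing, :] = ma.global_means.to_numpy()
        delta = desc.to_numpy() - expected.to_numpy()
        block = pd.DataFrame(
            delta,
            index=ds.df.index,
            columns=[delta_column(c, group) for c in desc.columns],
        )
        blocks.append(block)
        prov.update({c: f"delta_{group}" for c in block.columns})
    out = pd.concat(blocks, axis=1)
    if not np.isfinite(out.to_numpy()).all():
        raise FitError("non-finite delta feature after assembly")
    return FeatureMatrix(out, prov)


def fit_reference(ds: Dataset, scope: str = "full") -> ReferenceTable:
    """Empirical activity prevalence per full condition tuple."""
    labels = ds.labels
    if labels is None or labels.isna().any():
        raise FitError("fit_reference requires a fully labeled dataset")
    cols = _group_columns(ds, "ref")
    lab = labels.astype(float)
    grouped = lab.groupby([ds.df[c] for c in cols], sort=True)
    table = grouped.mean()
    support = grouped.size()
    cmap = ds.schema.condition_map
    pair = lab.groupby([ds.df[cmap["c0"]], ds.df[cmap["c10"]]], sort=True).mean()
    return ReferenceTable(
        table=table,
        support=support,
        pair_table=pair,
        fallback_value=float(lab.mean()),
        scope=scope,
    )


def reference_column(ds: Dataset, ref: ReferenceTable) -> tuple[pd.Series, pd.Series]:
    """Per-row f_ref values and the fallback level used ('exact'/'pair'/'global')."""
    cols = _group_columns(ds, "ref")
    keys = pd.MultiIndex.from_frame(ds.df[cols])
    vals = ref.table.reindex(keys)
    source = pd.Series(np.where(vals.notna(), "exact", ""), index=ds.df.index)
    if vals.isna().any():
        cmap = ds.schema.condition_map
        pair_keys = pd.MultiIndex.from_frame(ds.df[[cmap["c0"], cmap["c10"]]])
        pair_vals = ref.pair_table.reindex(pair_keys)
        missing = vals.isna().to_numpy()
        from_pair = missing & pair_vals.notna().to_numpy()
        arr = vals.to_numpy()
        arr[from_pair] = pair_vals.to_numpy()[from_pair]
        source.iloc[np.flatnonzero(from_pair)] = "pair"
        still = np.isnan(arr)
        arr[still] = ref.fallback_value
        source.iloc[np.flatnonzero(still)] = "global"
        vals = pd.Series(arr, index=ds.df.index)
    else:
        vals = pd.Series(vals.to_numpy(), index=ds.df.index)
    return vals.rename("f_ref"), source.rename("f_ref_source")


def assemble_features(
    ds: Dataset,
    ma: MATable,
    ref: ReferenceTable,
    unseen_rule: str = "global",
) -> FeatureMatrix:
    """[f_ref | raw D/V | Δ_assay | Δ_dat] with a complete provenance map."""
    f_ref, src = reference_column(ds, ref)
    raw = _descriptor_frame(ds)
    deltas = apply_deltas(ds, ma, unseen_rule=unseen_rule)
    df = pd.concat([f_ref, raw, deltas.df], axis=1)
    if not np.isfinite(df.to_numpy()).all():
        raise FitError("non-finite entry in assembled feature matrix")
    prov = {"f_ref": "ref"}
    s = ds.schema
    for c in raw.columns:
        if c in s.drug_descriptor_columns:
            prov[c] = "raw_drug"
        elif c in s.protein_descriptor_columns:
            prov[c] = "raw_protein"
        else:
            prov[c] = "raw_variable"
    prov.update(deltas.provenance)
    return FeatureMatrix(df, prov, fallback_flags=src.to_frame())


class PTFeaturizer(BaseEstimator, TransformerMixin):
    """Fits the MA and reference tables; transforms datasets into the
    perturbation-theory feature matrix.

    Parameters
    ----------
    unseen_rule : "global" | "error"
        How to resolve condition tuples unseen at fit time.
    scope : str
        Metadata tag recorded on the fitted tables ("full" or
        "train_only"); the caller decides which rows to fit on.
    """

    def __init__(self, unseen_rule: str = "global", scope: str = "full"):
        self.unseen_rule = unseen_rule
        self.scope = scope

    def fit(self, ds: Dataset, y=None) -> "PTFeaturizer":
        self.ma_ = fit_moving_averages(ds, scope=self.scope)
        self.ref_ = fit_reference(ds, scope=self.scope)
        return self

    def transform(self, ds: Dataset) -> FeatureMatrix:
        return assemble_features(ds, self.ma_, self.ref_,
                                 unseen_rule=self.unseen_rule)
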