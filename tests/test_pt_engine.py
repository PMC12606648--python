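"""Moving-average tables, Δ-operators and the reference function."""

import numpy as np
import pandas as pd
import pytest

from ifptml import (
    Dataset,
    PTFeaturizer,
    apply_deltas,
    assemble_features,
    fit_moving_averages,
    fit_reference,
)
from ifptml.pt_engine import (
    FitError,
    TupleLookupError,
    _group_columns,
    delta_column,
    reference_column,
)

from conftest import tiny_dataset


def brute_force_ma(ds, group):
    """Nested-loop oracle: mean per (group tuple, descriptor)."""
    cols = _group_columns(ds, group)
    desc_cols = ds.schema.descriptor_columns
    desc = ds.df[desc_cols].astype(float).copy()
    for c in ds.schema.variable_columns:
        desc[c] = desc[c].fillna(0.0)
    out = {}
    tuples = [tuple(r) for r in ds.df[cols].itertuples(index=False)]
    for key in set(tuples):
        rows = [i for i, t in enumerate(tuples) if t == key]
        for d in desc_cols:
            vals = [desc[d].iloc[i] for i in rows]
            out[(key, d)] = sum(vals) / len(vals)
    return out


class TestMovingAverages:
    def test_two_record_group_mean(self, tiny_schema):
        ds = tiny_dataset(tiny_schema)
        df = ds.df.copy()
        df["D1"] = [4.0, 6.0, 4.0, 6.0, 4.0, 6.0]
        ds = Dataset(df, tiny_schema)
        ma = fit_moving_averages(ds)
        # first three rows share the assay tuple (T1, x, x, x, x)
        key = tuple(df.loc[0, _group_columns(ds, "assay")])
        assert ma.means["assay"].loc[key, "D1"] == pytest.approx(14.0 / 3)

    def test_singleton_group_delta_zero(self, tiny_schema):
        ds = tiny_dataset(tiny_schema, n=6)
        df = ds.df.copy()
        df.loc[0, "c1"] = "LONER"  # its assay tuple is now unique
        ds = Dataset(df, tiny_schema)
        ma = fit_moving_averages(ds)
        fm = apply_deltas(ds, ma)
        assert fm.df.loc[0, delta_column("D1", "assay")] == pytest.approx(0.0)

    def test_empty_dataset_fit_error(self, tiny_schema):
        ds = tiny_dataset(tiny_schema)
        with pytest.raises(FitError):
            fit_moving_averages(Dataset(ds.df.iloc[0:0], tiny_schema))

    def test_matches_nested_loop_oracle(self, oracle_world):
        """MA table equals brute-force group-by means to 1e-12 on 500 rows."""
        _, ds, _ = oracle_world
        ma = fit_moving_averages(ds)
        for group in ("assay", "dat"):
            oracle = brute_force_ma(ds, group)
            tab = ma.means[group]
            for (key, d), val in oracle.items():
                assert tab.loc[key, d] == pytest.approx(val, abs=1e-12)

    def test_row_order_invariance(self, oracle_world):
        _, ds, _ = oracle_world
        ma1 = fit_moving_averages(ds)
        shuffled = Dataset(
            ds.df.sample(frac=1.0, random_state=3).reset_index(drop=True),
            ds.schema,
        )
        ma2 = fit_moving_averages(shuffled)
        for g in ("assay", "dat"):
            pd.testing.assert_frame_equal(ma1.means[g], ma2.means[g])


class TestDeltas:
    def test_arithmetic(self, tiny_schema):
        ds = tiny_dataset(tiny_schema)
        df = ds.df.copy()
        df["D1"] = [5.0, 3.0, 1.0, 2.0, 2.0, 2.0]
        ds = Dataset(df, tiny_schema)
        fm = apply_deltas(ds, fit_moving_averages(ds))
        # group mean of first assay tuple is 3 → Δ of row 0 is 5 − 3 = 2
        assert fm.df.loc[0, delta_column("D1", "assay")] == pytest.approx(2.0)

    def test_zero_mean_within_fitted_groups(self, oracle_world):
        """Direct summation oracle: Δ columns average to 0 per group."""
        _, ds, _ = oracle_world
        ma = fit_moving_averages(ds)
        fm = apply_deltas(ds, ma)
        for group in ("assay", "dat"):
            cols = _group_columns(ds, group)
            keys = [ds.df[c] for c in cols]
            for d in ["D001", "MW", "P_I_1", "V1"]:
                means = fm.df[delta_column(d, group)].groupby(keys).mean()
                assert np.abs(means.to_numpy()).max() < 1e-9

    def test_unseen_tuple_fallback_and_error(self, tiny_schema):
        ds = tiny_dataset(tiny_schema)
        ma = fit_moving_averages(ds)
        new = Dataset(ds.df.assign(c1="UNSEEN"), tiny_schema)
        fm = apply_deltas(new, ma, unseen_rule="global")
        expected = new.df["D1"] - ds.df["D1"].mean()
        np.testing.assert_allclose(
            fm.df[delta_column("D1", "assay")], expected, atol=1e-12
        )
        with pytest.raises(TupleLookupError, match="UNSEEN"):
            apply_deltas(new, ma, unseen_rule="error")


class TestReference:
    def test_arithmetic_and_bounds(self, tiny_schema):
        ds = tiny_dataset(tiny_schema, n=5)
        labels = pd.Series([1, 1, 1, 0, 1])
        # single shared tuple for first 2 rows? use one uniform tuple:
        df = ds.df.copy()
        for c in [f"c{i}" for i in range(11)]:
            df[c] = "u"
        ref = fit_reference(Dataset(df, tiny_schema).with_labels(labels))
        assert ref.table.iloc[0] == pytest.approx(4 / 5)
        assert ref.fallback_value == pytest.approx(4 / 5)

    def test_all_active_group_is_one(self, tiny_schema):
        ds = tiny_dataset(tiny_schema).with_labels(pd.Series([1] * 6))
        ref = fit_reference(ds)
        assert (ref.table == 1.0).all()

    def test_unlabeled_state_error(self, tiny_ds):
        with pytest.raises(FitError):
            fit_reference(tiny_ds)

    def test_values_bounded_and_weighted_mean_is_prevalence(self, oracle_world):
        _, ds, _ = oracle_world
        ref = fit_reference(ds)
        assert ref.table.between(0, 1).all()
        vals, src = reference_column(ds, ref)
        assert (src == "exact").all()
        assert vals.mean() == pytest.approx(ds.labels.mean(), abs=1e-12)

    def test_matches_brute_force(self, oracle_world):
        _, ds, _ = oracle_world
        ref = fit_reference(ds)
        cols = _group_columns(ds, "ref")
        tuples = [tuple(r) for r in ds.df[cols].itertuples(index=False)]
        y = ds.labels.to_numpy(float)
        for key in set(tuples):
            rows = [i for i, t in enumerate(tuples) if t == key]
            assert ref.table.loc[key] == pytest.approx(
                y[rows].mean(), abs=1e-12
            )

    def test_fallback_chain(self, oracle_world):
        _, ds, _ = oracle_world
        ref = fit_reference(ds)
        seen = next(iter(ref.table.index))
        # unseen full tuple sharing (c0, c10) with data → pair fallback
        novel = tuple(["__nope__" if 0 < i < 10 else seen[i]
                      for i in range(11)])
        val, how = ref.lookup(novel)
        assert how == "pair"
        assert val == pytest.approx(ref.pair_table.loc[(seen[0], seen[10])])
        # fully unseen → global prevalence
        val, how = ref.lookup(tuple(["__nope__"] * 11))
        assert how == "global"
        assert val == pytest.approx(ref.fallback_value)


class TestAssemble:
    def test_column_count_formula(self, oracle_world):
        """108 drug + 15 protein + 2 variable descriptors → 1 + 125 + 250."""
        _, ds, _ = oracle_world
        fm = PTFeaturizer().fit(ds).transform(ds)
        p = len(ds.schema.descriptor_columns)
        assert p == 125
        assert fm.df.shape[1] == 1 + p + 2 * p == 376
        assert fm.columns[0] == "f_ref"
        assert set(fm.provenance) == set(fm.columns)

    def test_row_alignment_and_finiteness(self, oracle_world):
        _, ds, _ = oracle_world
        fm = assemble_features(
            ds, fit_moving_averages(ds), fit_reference(ds)
        )
        assert list(fm.df.index) == list(ds.df.index)
        assert np.isfinite(fm.df.to_numpy()).all()
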