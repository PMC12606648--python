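"""Condition enumeration, query prediction, reference-relative outcomes."""

import numpy as np
import pandas as pd
import pytest

from ifptml import (
    Dataset,
    IFPTMLPipeline,
    QueryCompound,
    SplitPlan,
    SynthConfig,
    enumerate_conditions,
    generate,
    relative_outcome,
    success_summary,
)
from ifptml.screening import ScreeningError

from conftest import tiny_dataset


@pytest.fixture(scope="module")
def fitted():
    """A pipeline fitted on a 1500-row synthetic world."""
    ds, truth = generate(SynthConfig(n_rows=1500, seed=21))
    pipe = IFPTMLPipeline(
        model_family="XGB", split=SplitPlan(seed=0), seed=0
    ).fit(ds)
    return ds, truth, pipe


def make_query(ds, qid, like_compound=None, rng=None):
    s = ds.schema
    if like_compound is not None:
        row = ds.df[ds.df[s.compound_column] == like_compound].iloc[0]
        desc = row[s.drug_descriptor_columns].astype(float)
    else:
        desc = pd.Series(
            rng.normal(size=len(s.drug_descriptor_columns)),
            index=s.drug_descriptor_columns,
        )
    return QueryCompound(qid, desc)


class TestEnumerate:
    def test_assay_type_filter(self, tiny_schema):
        ds = tiny_dataset(tiny_schema)  # 1 binding tuple + 1 functional
        tup = enumerate_conditions(ds, {"c10": "B"})
        assert len(tup) == 1 and (tup["c10"] == "B").all()

    def test_empty_filter_returns_all_distinct(self, fitted):
        ds, _, _ = fitted
        tup = enumerate_conditions(ds)
        cond_cols = list(ds.schema.condition_map.values())
        assert len(tup) == ds.df[cond_cols].drop_duplicates().shape[0]

    def test_filter_matches_group_by_oracle(self, fitted):
        ds, _, _ = fitted
        flt = {"c10": "B", "c4": "org1"}
        tup = enumerate_conditions(ds, flt)
        cond_cols = list(ds.schema.condition_map.values())
        sub = ds.df[(ds.df["c10"] == "B") & (ds.df["c4"] == "org1")]
        assert len(tup) == sub[cond_cols].drop_duplicates().shape[0]

    def test_no_match_warns_and_is_empty(self, fitted):
        ds, _, _ = fitted
        with pytest.warns(UserWarning):
            tup = enumerate_conditions(ds, {"c10": "Z"})
        assert tup.empty


class TestPredictNew:
    def test_training_compound_reproduces_in_sample_prediction(self, fitted):
        """A query with a training compound's descriptors, scored under a
        tuple that compound was measured in, matches the in-sample
        prediction for that row."""
        ds, _, pipe = fitted
        s = ds.schema
        row = ds.df.iloc[0]
        cid = row[s.compound_column]
        q = make_query(ds, "probe", like_compound=cid)
        grid = pipe.predict_grid([q])
        in_sample = pipe.predict_proba(ds)[0, 1]
        key = {f: row[c] for f, c in s.condition_map.items()}
        m = np.ones(len(grid), bool)
        for f, v in key.items():
            m &= (grid[f] == v).to_numpy()
        hit = grid[m]
        assert len(hit) >= 1
        assert hit["probability"].iloc[0] == pytest.approx(in_sample, abs=1e-9)

    def test_unseen_tuple_flagged_global(self, fitted):
        ds, _, pipe = fitted
        rng = np.random.default_rng(0)
        q = make_query(ds, "newmol", rng=rng)
        tup = enumerate_conditions(ds).head(3).copy()
        tup["c0"] = "Mystery"
        from ifptml.screening import predict_new

        grid = predict_new(
            pipe.model_, pipe.featurizer_.ma_, pipe.featurizer_.ref_,
            [q], tup, ds.schema,
            column_selector=pipe.cfilter_.retained_, scaler=pipe.scaler_,
        )
        assert (grid["f_ref_source"] != "exact").all()

    def test_probabilities_bounded(self, fitted):
        ds, _, pipe = fitted
        rng = np.random.default_rng(1)
        qs = [make_query(ds, f"q{i}", rng=rng) for i in range(3)]
        grid = pipe.predict_grid(qs, condition_filter={"c10": "B"})
        assert grid["probability"].between(0, 1).all()
        assert grid["f_calc"].isin([0, 1]).all()


class TestRelativeOutcome:
    def grid(self):
        rows = []
        for comp, preds in [("ref", [0, 0]), ("hit", [1, 0]), ("same", [0, 0])]:
            for i, p in enumerate(preds):
                rows.append({
                    "compound_id": comp,
                    **{f"c{k}": "u" for k in range(11)},
                    "c1": "T1", "c10": "B",
                    "c2": f"tuple{i}",   # distinguishes the two tuples
                    "probability": 0.2 + 0.6 * p, "f_calc": p,
                    "f_ref_source": "exact",
                })
        return pd.DataFrame(rows)

    def test_reference_against_itself_zero(self):
        out = relative_outcome(self.grid(), "ref")
        assert out.delta["ref"].to_numpy() == pytest.approx([0.0])

    def test_mixed_average_half(self):
        """Active on 1 of 2 tuples where reference is inactive on both →
        +0.5."""
        out = relative_outcome(self.grid(), "ref")
        assert out.delta.loc["T1", "hit"] == pytest.approx(0.5)
        assert out.support.loc["T1", "hit"] == 2

    def test_full_bounds(self):
        g = self.grid()
        g.loc[g["compound_id"] == "hit", "f_calc"] = 1
        out = relative_outcome(g, "ref")
        assert out.delta.loc["T1", "hit"] == pytest.approx(1.0)
        assert out.delta.to_numpy().min() >= -1.0
        assert out.delta.to_numpy().max() <= 1.0

    def test_antisymmetry(self):
        g = self.grid()
        a = relative_outcome(g, "ref").delta.loc["T1", "hit"]
        b = relative_outcome(g, "hit").delta.loc["T1", "ref"]
        assert a == pytest.approx(-b)

    def test_missing_reference_raises(self):
        with pytest.raises(ScreeningError, match="ghost"):
            relative_outcome(self.grid(), "ghost")


class TestSuccessSummary:
    def test_single_row(self):
        g = pd.DataFrame({
            "compound_id": ["a"], "c10": ["B"], "probability": [0.73],
        })
        s = success_summary(g)
        assert s.by_compound["a"] == pytest.approx(0.73)
        assert s.by_assay_type["B"] == pytest.approx(0.73)

    def test_mean_of_two(self):
        g = pd.DataFrame({
            "compound_id": ["a", "a"], "c10": ["B", "F"],
            "probability": [0.2, 0.8],
        })
        assert success_summary(g).by_compound["a"] == pytest.approx(0.5)

    def test_group_means_match_brute_force(self, fitted):
        ds, _, pipe = fitted
        rng = np.random.default_rng(4)
        qs = [make_query(ds, f"q{i}", rng=rng) for i in range(2)]
        grid = pipe.predict_grid(qs, condition_filter={"c10": "B"})
        s = success_summary(grid)
        for comp in grid["compound_id"].unique():
            manual = grid.loc[grid["compound_id"] == comp, "probability"].mean()
            assert s.by_compound[comp] == pytest.approx(manual)
        # descending by value
        assert list(s.by_compound) == sorted(s.by_compound, reverse=True)
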