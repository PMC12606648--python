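import numpy as np
import pandas as pd
import pytest

from ifptml import Dataset, DatasetSchema, SynthConfig, generate, label_dataset


@pytest.fixture(scope="session")
def small_world():
    """400-row synthetic dataset with planted signal, plus ground truth."""
    cfg = SynthConfig(n_rows=400, seed=7)
    ds, truth = generate(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def small_labeled(small_world):
    _, ds, _ = small_world
    labeled, report = label_dataset(ds)
    return labeled, report


@pytest.fixture(scope="session")
def oracle_world():
    """500-row instance used for brute-force oracle comparisons."""
    cfg = SynthConfig(n_rows=500, seed=11)
    ds, truth = generate(cfg)
    labeled, _ = label_dataset(ds)
    return cfg, labeled, truth


@pytest.fixture()
def tiny_schema():
    """Minimal hand-written schema: 2 drug, 1 protein, 1 variable column."""
    return DatasetSchema(
        compound_column="cid",
        activity_column="act",
        condition_columns=[f"c{i}" for i in range(11)],
        drug_descriptor_columns=["D1", "D2"],
        protein_descriptor_columns=["P1"],
        variable_columns=["V1"],
    )


def tiny_dataset(schema, n=6, seed=0):
    """Small handmade dataset over two condition tuples."""
    rng = np.random.default_rng(seed)
    half = n // 2
    df = pd.DataFrame({
        "cid": [f"M{i}" for i in range(n)],
        "act": rng.uniform(10.0, 200.0, n),
        "c0": ["IC50 (nM)"] * n,
        "c1": ["T1"] * half + ["T2"] * (n - half),
        **{f"c{i}": ["x"] * n for i in range(2, 9)},
        "c9": ["="] * n,
        "c10": ["B"] * half + ["F"] * (n - half),
        "D1": rng.normal(size=n),
        "D2": rng.normal(size=n),
        "P1": rng.normal(size=n),
        "V1": rng.uniform(1.0, 10.0, n),
    })
    return Dataset(df, schema)


@pytest.fixture()
def tiny_ds(tiny_schema):
    return tiny_dataset(tiny_schema)
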