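"""Synthetic assay tables with planted, known structure.

The generator emulates the shape of a curated ChEMBL extract for a
signalling-pathway target family: ~10³ compounds measured on ~10² targets
under a finite pool of assay contexts (each context = one combination of
the 11 boundary conditions plus the target's protein-domain descriptors).
Activity is driven by a latent logistic model

    p = expit( β·D_drug + γ·D_prot + effect(c0) + effect(c10) + b )

with the intercept b solved so that mean activity equals the configured
prevalence.  The binary label is a Bernoulli draw from p, and the raw
activity value is back-mapped onto the row's measure scale so that the
desirability/cut-off labelling recovers the latent class exactly
(concentrations are log-normal around the 100 nM cut-off, percentages
straddle 70 %, unit-less measures straddle their dataset mean with a
guard gap).

Deliberately planted pathologies — duplicated descriptor columns and
near-constant columns — exercise the correlation and variance filters; the
per-row true probability is returned so recovery tests have a Bayes
ceiling to compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .assay_data import Dataset
from .schema import C10_LEVELS, NA_LEVEL, DatasetSchema

#: the 13 activity-measure classes: 5 concentration-type, 4 percentage-type,
#: 4 unit-less (dataset-mean cut-off).
MEASURE_CLASSES = (
    "IC50 (nM)", "Ki (nM)", "Potency (nM)", "Kd (nM)", "Km (nM)",
    "Residual activity (%)", "Inhibition (%)", "Metabolism (%)",
    "Activity (%)",
    "Fold change", "Selectivity ratio", "Binding score", "Response index",
)

CONCENTRATION_MEASURES = MEASURE_CLASSES[:5]
PERCENT_MEASURES = MEASURE_CLASSES[5:9]
OTHER_MEASURES = MEASURE_CLASSES[9:]

_DRUG_NAMED = ["MW", "Ro5", "AlogP"]
_N_DRUG_D = 105
_N_PROT = 15

#: columns carrying the planted linear effect (fixed pattern × beta_scale).
_INFORMATIVE = ["D001", "D002", "D003", "D004", "D005"]
_BETA_PATTERN = np.array([1.0, -1.0, 0.75, -0.75, 0.5])

#: planted redundancies: exact copies and near-constant columns.
_DUPLICATES = {"D101": "D001", "D102": "D050"}
_NEAR_CONSTANT = ["D103", "D104", "D105"]


class ConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Stated world of the synthetic benchmark.

    Cardinalities default to roughly a 1/5 scale of the curated dataset's
    composition (which keeps desk-scale runs fast) except the 13
    activity-measure classes, which are kept in full so all three cut-off
    families are exercised.
    """

    n_rows: int = 5000
    n_compounds: int = 1000
    n_targets: int = 20
    n_contexts: int = 150
    cardinalities: dict = field(default_factory=lambda: {
        "c2": 3, "c3": 2, "c4": 4, "c5": 5, "c6": 2, "c7": 2, "c8": 2,
    })
    concentration_fraction: float = 0.5   # share of contexts on conc. measures
    percent_fraction: float = 0.3         # share on percentage measures
    missing_rate: float = 0.3             # NA rate for sparse fields c2/c3/c7/c8
    censored_rate: float = 0.1            # share of rows with c9 in {<, >}
    beta_scale: float = 1.0               # multiplies the planted β pattern
    gamma: float = 0.5                    # effect of the first protein descriptor
    cond_sd: float = 0.75                 # sd of per-level c0/c10 effects
    prevalence: float = 0.5
    variable_missing_rate: float = 0.2    # missing V1/V2 concentrations
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ConfigError("prevalence must be in (0, 1)")
        if min(self.cardinalities.values()) < 1:
            raise ConfigError("condition cardinalities must be >= 1")
        if self.n_rows < 1 or self.n_compounds < 1 or self.n_targets < 1:
            raise ConfigError("sizes must be positive")

    def null(self) -> "SynthConfig":
        """The no-signal world: β = 0 and no condition effects."""
        return replace(self, beta_scale=0.0, cond_sd=0.0)


@dataclass
class GroundTruth:
    p_true: np.ndarray
    beta: pd.Series
    gamma: float
    condition_effects: dict[str, dict[str, float]]
    duplicate_columns: dict[str, str]
    near_constant_columns: list[str]
    intercept: float


def synthetic_schema() -> DatasetSchema:
    drug_cols = _DRUG_NAMED + [f"D{i:03d}" for i in range(1, _N_DRUG_D + 1)]
    prot_cols = [f"P_{dom}_{lvl}" for dom in ("I", "II", "III")
                 for lvl in range(1, 6)]
    return DatasetSchema(
        compound_column="compound_id",
        activity_column="activity_value",
        condition_columns=[f"c{i}" for i in range(11)],
        drug_descriptor_columns=drug_cols,
        protein_descriptor_columns=prot_cols,
        variable_columns=["V1", "V2"],
    )


def _draw_level(rng, prefix: str, k: int, missing_rate: float = 0.0):
    levels = [f"{prefix}{i + 1}" for i in range(k)]

    def draw(n):
        out = np.array(levels, dtype=object)[rng.integers(0, k, n)]
        if missing_rate > 0:
            out = np.where(rng.random(n) < missing_rate, NA_LEVEL, out)
        return out

    return draw


def _backmap_activity(rng, y, measure):
    """Raw value on the measure's own scale whose binarisation equals y."""
    if measure in CONCENTRATION_MEASURES:
        # log-normal around the 100 nM cut-off; active ⇒ strictly below it
        mag = np.abs(rng.normal(0.0, 1.0)) + 0.05
        return 100.0 * np.exp(-mag if y == 1 else mag)
    if measure in PERCENT_MEASURES:
        off = np.abs(rng.normal(0.0, 10.0)) + 0.5
        v = 70.0 + off if y == 1 else 70.0 - off
        return float(np.clip(v, 0.0, 100.0)) if y == 0 else float(min(v, 100.0))
    # unit-less: clusters at 50 ± (5 + |N|), so any dataset mean in the
    # guard band (45, 55) reproduces the latent class
    off = 5.0 + np.abs(rng.normal(0.0, 5.0))
    return 50.0 + off if y == 1 else 50.0 - off


def generate(cfg: SynthConfig) -> tuple[Dataset, GroundTruth]:
    """Draw one synthetic dataset plus its ground truth; seed-reproducible."""
    rng = np.random.default_rng(cfg.seed)
    schema = synthetic_schema()

    # -- compounds ---------------------------------------------------------
    comp_ids = [f"C{i + 1:05d}" for i in range(cfg.n_compounds)]
    drug = pd.DataFrame(index=comp_ids, columns=schema.drug_descriptor_columns,
                        dtype=float)
    drug["MW"] = rng.normal(380.0, 80.0, cfg.n_compounds)
    drug["Ro5"] = rng.poisson(0.6, cfg.n_compounds).clip(0, 4).astype(float)
    drug["AlogP"] = rng.normal(2.5, 1.5, cfg.n_compounds)
    dcols = [f"D{i:03d}" for i in range(1, _N_DRUG_D + 1)]
    drug[dcols] = rng.normal(0.0, 1.0, (cfg.n_compounds, len(dcols)))
    for dup, src in _DUPLICATES.items():
        drug[dup] = drug[src]
    for j, col in enumerate(_NEAR_CONSTANT):
        drug[col] = float(j) + rng.normal(0.0, 0.05, cfg.n_compounds)

    # -- targets -----------------------------------------------------------
    targets = [f"T{i + 1:03d}" for i in range(cfg.n_targets)]
    prot = pd.DataFrame(
        rng.normal(0.0, 1.0, (cfg.n_targets, _N_PROT)),
        index=targets, columns=schema.protein_descriptor_columns,
    )

    # -- condition effects ---------------------------------------------------
    eff_c0 = {m: float(rng.normal(0.0, cfg.cond_sd)) for m in MEASURE_CLASSES}
    eff_c10 = {lv: float(rng.normal(0.0, cfg.cond_sd)) for lv in C10_LEVELS}

    # -- assay contexts ------------------------------------------------------
    n_conc = int(round(cfg.concentration_fraction * cfg.n_contexts))
    n_pct = int(round(cfg.percent_fraction * cfg.n_contexts))
    measures = (
        list(rng.choice(CONCENTRATION_MEASURES, n_conc))
        + list(rng.choice(PERCENT_MEASURES, n_pct))
        + list(rng.choice(OTHER_MEASURES, cfg.n_contexts - n_conc - n_pct))
    )
    rng.shuffle(measures)
    card = cfg.cardinalities
    draws = {
        "c2": _draw_level(rng, "cell", card["c2"], cfg.missing_rate),
        "c3": _draw_level(rng, "tissue", card["c3"], cfg.missing_rate),
        "c4": _draw_level(rng, "org", card["c4"]),
        "c5": _draw_level(rng, "aorg", card["c5"]),
        "c6": _draw_level(rng, "ttype", card["c6"]),
        "c7": _draw_level(rng, "frac", card["c7"], cfg.missing_rate),
        "c8": _draw_level(rng, "buf", card["c8"], cfg.missing_rate),
    }
    ctx = pd.DataFrame({
        "c0": measures,
        "c1": np.array(targets, dtype=object)[
            rng.integers(0, cfg.n_targets, cfg.n_contexts)],
        **{f: draws[f](cfg.n_contexts) for f in
           ("c2", "c3", "c4", "c5", "c6", "c7", "c8")},
        "c10": np.array(C10_LEVELS, dtype=object)[
            rng.integers(0, len(C10_LEVELS), cfg.n_contexts)],
    })

    # -- rows ----------------------------------------------------------------
    row_comp = rng.integers(0, cfg.n_compounds, cfg.n_rows)
    row_ctx = rng.integers(0, cfg.n_contexts, cfg.n_rows)

    beta = pd.Series(cfg.beta_scale * _BETA_PATTERN, index=_INFORMATIVE)
    x_info = drug.loc[np.array(comp_ids, dtype=object)[row_comp],
                      _INFORMATIVE].to_numpy()
    tgt = ctx["c1"].to_numpy(object)[row_ctx]
    p1 = prot.iloc[:, 0].reindex(tgt).to_numpy()
    z = (
        x_info @ beta.to_numpy()
        + cfg.gamma * cfg.beta_scale * p1
        + np.array([eff_c0[m] for m in ctx["c0"]])[row_ctx]
        + np.array([eff_c10[m] for m in ctx["c10"]])[row_ctx]
    )

    def mean_p(b):
        return expit(z + b).mean() - cfg.prevalence

    intercept = 0.0 if abs(mean_p(0.0)) < 1e-12 else brentq(
        mean_p, -30.0, 30.0
    )
    p_true = expit(z + intercept)
    y = (rng.random(cfg.n_rows) < p_true).astype(int)

    c0_rows = ctx["c0"].to_numpy(object)[row_ctx]
    activity = np.array([
        _backmap_activity(rng, y[i], c0_rows[i]) for i in range(cfg.n_rows)
    ])
    # censored relations only in directions that preserve the label under
    # the conservative rule
    c9 = np.full(cfg.n_rows, "=", dtype=object)
    cens = rng.random(cfg.n_rows) < cfg.censored_rate
    for i in np.flatnonzero(cens):
        m = c0_rows[i]
        if y[i] == 1:
            c9[i] = "<" if m in CONCENTRATION_MEASURES else (
                ">" if m in PERCENT_MEASURES else "=")
        else:
            c9[i] = ">" if m in CONCENTRATION_MEASURES else (
                "<" if m in PERCENT_MEASURES else "=")

    v = np.exp(rng.normal(np.log(10.0), 1.0, (cfg.n_rows, 2)))
    v[rng.random((cfg.n_rows, 2)) < cfg.variable_missing_rate] = np.nan

    df = pd.DataFrame({
        "compound_id": np.array(comp_ids, dtype=object)[row_comp],
        "activity_value": activity,
    })
    ctx_rows = ctx.iloc[row_ctx].reset_index(drop=True)
    for f in ("c0", "c1", "c2", "c3", "c4", "c5", "c6", "c7", "c8"):
        df[f] = ctx_rows[f].to_numpy()
    df["c9"] = c9
    df["c10"] = ctx_rows["c10"].to_numpy()
    df = pd.concat(
        [df,
         drug.loc[df["compound_id"]].reset_index(drop=True),
         prot.reindex(df["c1"]).reset_index(drop=True),
         pd.DataFrame(v, columns=["V1", "V2"])],
        axis=1,
    )

    truth = GroundTruth(
        p_true=p_true,
        beta=beta,
        gamma=cfg.gamma * cfg.beta_scale,
        condition_effects={"c0": eff_c0, "c10": eff_c10},
        duplicate_columns=dict(_DUPLICATES),
        near_constant_columns=list(_NEAR_CONSTANT),
        intercept=float(intercept),
    )
    return Dataset(df, schema), truth


def expected_separability(cfg: SynthConfig, n_mc: int = 20000) -> float:
    """Monte-Carlo Bayes-ceiling AUC: score = true probability.

    Draws a fresh dataset of ``n_mc`` rows from the same world (offset
    seed) and computes the AUC of p_true against the realised labels.
    """
    from sklearn.metrics import roc_auc_score

    probe = replace(cfg, n_rows=int(n_mc), seed=(cfg.seed + 101) % (2**31))
    ds, truth = generate(probe)
    y = _latent_labels(ds, truth)
    if len(np.unique(y)) < 2:
        return 0.5
    return float(roc_auc_score(y, truth.p_true))


def _latent_labels(ds: Dataset, truth: GroundTruth) -> np.ndarray:
    """Recover the realised Bernoulli labels via the labelling policy."""
    from .labeling import label_dataset

    labeled, _ = label_dataset(ds)
    return labeled.labels.to_numpy(int)
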