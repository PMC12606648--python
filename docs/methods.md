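# Methods

This note documents the modelling choices, defaults and known limitations
of the package.  It states no empirical result beyond what the test suite
and `scripts/acceptance.py` compute at run time.

## Data model

One row per (compound, assay) observation: a raw activity value `v_ij`
whose units are implied by the activity-measure class `c0`; eleven
categorical boundary conditions `c0–c10` (measure class, target name, cell
type, tissue, target/assay organism, target type, subcellular fraction,
buffer, standard relation, assay type); 108 continuous drug descriptors
(molecular weight, Lipinski rule-of-five count, AlogP, and 105 Markovian
atom-class descriptors produced externally and consumed as-is); 15
protein-domain electronegativity descriptors (3 domains × 5 propagation
levels); and two assay concentrations V1/V2 (μM).

Missing categorical cells become the reserved level `"NA"`, which is a
*real grouping level*: sparse fields (cell type, tissue, fraction, buffer)
would otherwise force dropping most rows.  Missing concentrations are
imputed as 0 μM at featurisation so the feature matrix stays finite — the
absence of a reported concentration is treated as "none added", which is
the usual reading of a blank concentration field in assay records.

The column registry is externalised (YAML) so arbitrary CSV headers map
onto roles; numeric parsing is locale-independent (decimal points only).

## Labelling

Desirability and cut-off per measure class:

| family          | examples                       | d  | cut-off       |
|-----------------|--------------------------------|----|---------------|
| percentage      | inhibition, residual activity  | +1 | 70 (%)        |
| concentration   | IC50, Ki, Kd, Km, potency      | −1 | 100 (nM)      |
| everything else | scores, ratios, indices        | +1 | dataset mean  |

The label is 1 iff the value is strictly on the desirable side of the
cut-off; an exact tie is inactive (the rule is "above"/"below", not
"at").  Censored relations are handled conservatively: a record is active
only when the censoring direction *guarantees* the criterion (">80 %"
with a 70 % cut-off is active; "<80 %" is not; "<50 nM" under a 100 nM
cut-off is active; ">150 nM" is inactive; ambiguous bounds default to 0).
Values are assumed to be expressed in the units named by the measure
label; no unit inference is attempted.  Dataset-mean cut-offs are resolved
on the data the labeller is fitted on (the full table by default).

## Perturbation features

Moving averages are computed per *joint level tuple* of each of the two
groupings — c_assay = (c1…c5) and c_dat = (c6…c10) — giving exactly two
Δ operators per descriptor: Δ = D_k − ⟨D_k(tuple)⟩.  A singleton tuple has
Δ = 0 by construction.  The assay concentrations V1/V2 are treated like
descriptors (their deltas are informative perturbations of assay design)
and their raw values are also kept.

The reference function conditions on the full joint tuple (c0…c10).  At
prediction time unseen tuples resolve through a fallback chain: exact
tuple → (c0, c10) pair mean → global prevalence; for the moving averages
the fallback is the scope-wide descriptor mean.  Every fallback use is
recorded per row.

The assembled matrix is `[f_ref | raw | Δ_assay | Δ_dat]` — `1 + 3p`
columns for `p` raw descriptors (376 for the full descriptor set).

### Fit scope and leakage

`scope="full"` (default) fits the MA and reference tables, the filters and
the scaler on the complete table before splitting — this mirrors the
historical protocol, and it leaks held-out label information into `f_ref`
(each test row contributes 1/n_tuple of its own label to its tuple's
prevalence).  `scope="train_only"` fits everything after labelling on the
training partition only.  Both are first-class; on the default synthetic
world the scope difference is worth roughly 0.02 of test AUC, which is the
measured size of the leakage.  The test suite's recovery check uses the
default scope and verifies that test AUC lands within a narrow band of the
Bayes ceiling — at realistic tuple support (~30 rows) the leakage does not
manufacture skill beyond the planted signal.

## Feature filtering and scaling

Variance filter: drop columns with sample variance (ddof = 1) strictly
below 0.01; `f_ref` gets no special treatment.  Correlation filter: scan
columns in registry order, drop the *later* member of any pair with
|Pearson r| > 0.97 against an already-kept column; survivors take part in
later comparisons.  The elimination order is not prescribed by the
original protocol; the deterministic later-dropped rule makes results
reproducible and order-auditable.  Correlation is computed on raw
(pre-scaling) columns — Pearson r is scale-invariant, so the placement is
immaterial.  Scaling is a z-score with population standard deviation,
fitted once and reapplied verbatim to new rows.

## Models

Splits: random stratified 80/20 (default), or K-Means (k = 5, k-means++
with the global seed) on the standardized features with an 80/20 split
inside each cluster; clusters under 5 rows go wholly to training with a
warning.  One global seed (default 42) flows through splits, clustering,
folds and stochastic learners.

LDA uses the least-squares solver without shrinkage and exposes its
fitted intercept and per-feature weights so the linear score can be
audited term by term (`decision_function` equals the explicit expansion to
1e-10).  The classification threshold is a fixed probability of 0.5 for
every family.

**XGBoost substitution.**  The xgboost library is not available in the
runtime environment, so the "XGB" family is backed by scikit-learn's
`HistGradientBoostingClassifier` — the same histogram gradient-boosting
algorithm family (XGBoost's `tree_method=hist` construction).
Hyperparameter names are translated (`n_estimators → max_iter`);
`subsample` is accepted only at 1.0 (the value the original tuning
selected) because the backend does not subsample rows.

Tuning follows a two-stage regimen: randomized search (45 settings for
XGB, 15 for LDA by default; selection by mean CV accuracy) followed by a
grid refinement over a ±1-step neighbourhood of each optimum (integers
±1, floats ±25 %).  Search ranges bracket the originally reported optima
(depth 3–15, learning rate 0.01–0.5, 50–300 rounds).

## Evaluation

Specificity, sensitivity and accuracy are percentages; precision, recall
and F1 are emitted both for the positive class and label-weighted (the
two conventions both appear in published tables of this kind — the linear
model's figures match the weighted variant, the boosting model's the
positive-class variant).  MCC and unweighted Cohen's kappa come from the
same 2×2 table; undefined denominators yield 0 with an explicit flag.
AUC is the Mann–Whitney rank statistic (equal to the trapezoidal integral
of the ROC staircase, asserted to 1e-12 in tests).  The acceptability gate
is accuracy > 70 % *and* sensitivity > 70 %.

Feature importances: |coefficient × column std| for LDA, impurity gain for
tree ensembles, permutation importance (3 repeats) for the histogram
boosting backend, ties broken by registry order.

## Screening

New compounds inherit the *stored* group means and reference table —
refitting on queries would silently shift the training features.  The
relative-outcome heatmap aggregates the difference in predicted *class*
(not probability) between compound and reference over the filtered tuple
set, so single-condition comparisons land exactly on ±1; cells with no
shared tuple stay empty rather than being imputed.  The default
aggregation filter keeps binding assays (`c10 = "B"`), mirroring the use
case of ranking candidates for a binding-assay programme.

## Synthetic world

Defaults (chosen once, before any benchmark was run):

* 5000 rows, 1000 compounds, 20 targets, 150 assay contexts (a context is
  one full condition tuple; ~33 rows each, enough support for stable
  `f_ref` estimates while leaving room for sparse-tuple fallbacks in
  screening tests);
* all 13 measure classes (5 concentration, 4 percentage, 4 unit-less), a
  50/30/20 concentration/percentage/other split over contexts;
* condition cardinalities at ~1/5 of the curated table's composition;
  30 % missingness on the four sparse fields; 10 % censored relations,
  emitted only in label-preserving directions;
* planted effect: β = beta_scale × [1, −1, 0.75, −0.75, 0.5] on five drug
  descriptors, 0.5 × beta_scale on one protein descriptor, per-level
  condition effects ~N(0, 0.75²) on c0 and c10; intercept solved by root
  finding so mean activity equals the configured prevalence (0.5);
* planted pathologies: two exact duplicate columns and three
  near-constant columns (σ = 0.05, variance 0.0025 < 0.01);
* activity back-mapping: log-normal around 100 nM for concentrations,
  70 ± |N(0, 10)| for percentages, 50 ± (5 + |N(0, 5)|) for unit-less
  measures — the guard gap keeps the dataset-mean cut-off strictly
  between the two classes, so labelling recovers the latent class
  exactly.

`expected_separability` estimates the Bayes-ceiling AUC by scoring a
fresh 20 000-row draw (offset seed) with the true probability; its
Monte-Carlo standard error is ≈ 0.004.

What the generator does **not** emulate: realistic descriptor marginals or
correlations derived from chemical structure, compound-series clustering,
inter-assay systematic error, or the curated table's exact level
frequencies.  A green recovery test therefore establishes that the
pipeline extracts a planted additive-logistic signal at realistic sample
sizes — not that it would match any particular published benchmark
figure.

## Numerical choices

* Boundary ties in labelling → inactive (strict inequalities).
* Variance threshold is strict `<` for removal (a column at exactly the
  threshold survives).
* Group means and prevalences are plain arithmetic means — no shrinkage or
  smoothing; equivalence with nested-loop recomputation is asserted to
  1e-12 on 500-row instances.
* All tables are keyed by sorted group tuples, making fits independent of
  row order.
* Seeds are plumbed end to end; every split, fit and tune is reproducible
  bit for bit under a fixed seed.

## Known limitations

* Dose–response curve fitting, descriptor computation and database
  retrieval are out of scope; descriptors arrive precomputed.
* The deduplication key behind a curated table's "unique data points"
  count is not defined here; the loader reports raw row counts.
* `SVC(probability=True)` is deprecated upstream (scikit-learn ≥ 1.9) and
  will eventually need the calibration wrapper.
* Whether the historical protocol computed one Δ per *individual*
  condition rather than per grouping tuple is ambiguous; this package
  implements the two-grouping form (one Δ_assay and one Δ_dat per
  descriptor), which matches the stated c_assay/c_dat decomposition.
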