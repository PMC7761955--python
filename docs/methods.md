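# Methods

This note documents the statistical procedures implemented in `metabopanel`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that make runs reproducible.

## Data model

A feature table is a nonnegative intensity matrix (features × samples); each
feature carries a retention time (minutes) and m/z, encoded in its label as
`"RT_mz"`. Zeros are the only missing encoding — they represent
below-detection-limit censoring, which is why imputation uses half the
feature's minimum positive value rather than a distributional estimate. NaN
on input is rejected rather than silently coerced. Sample metadata carries
the diagnostic group (normal / benign / borderline / malignant), study
cohort (discovery / validation), acquisition batch, a QC flag, optional
clinical markers (CA125 in U/mL) and optional FIGO stage.

## Preprocessing

Applied strictly in this order: missingness filter → QC CV filter →
half-minimum imputation → median normalization → log2.

- **80% rule.** A feature is removed when its missing fraction among
  *biological* (non-QC) samples is ≥ `missing_fraction_threshold`
  (default 0.20). QC injections are technical replicates, not biological
  observations, so they are excluded from the denominator. A per-group
  variant (keep a feature if it passes in any group) is available as a
  config switch.
- **QC CV filter.** CV = sample sd / mean over non-missing QC intensities on
  the raw scale; features with CV strictly greater than 0.30 are removed
  (the boundary value 30.0% is retained). At least
  `min_qc_observations = 3` non-missing QC values are required to estimate a
  CV; features below that are removed and counted separately — an estimate
  from one or two injections is not a repeatability measurement. Batches
  are pooled for the CV.
- **Half-minimum imputation** is per feature by default (half the feature's
  minimum positive intensity across all samples); a global-minimum variant
  exists as a switch. Both filters operate on pre-imputation zeros, so
  imputation can never change which features pass them.
- **Median normalization** multiplies each sample by
  (reference ÷ sample median), with reference = median of the per-sample
  medians. Any positive constant reference would yield identical downstream
  log2 fold-change *differences*; the median-of-medians keeps intensities on
  the original scale. Post-condition: every sample median equals the
  reference to 1e-9 relative error.
- **log2** completes the chain; all downstream statistics operate on log2
  intensities.

## OPLS-DA

For a two-group contrast the response is the centered 0/1 dummy coding.
After Pareto scaling (center, divide by √sd; sd with ddof = 1), orthogonal
components are removed iteratively: with initial weight `w ∝ Xᵀy`, each
step computes the loading `p` of the current predictive score, the
orthogonalized weight `w_o ∝ p − (wᵀp)w`, and deflates
`X ← X − t_o p_oᵀ`. A single-component PLS on the filtered matrix gives the
predictive component; with zero orthogonal components this reduces exactly
to PLS1-DA (verified against an independent NIPALS implementation at 1e-8).

- **Number of orthogonal components**: default 1, configurable — the common
  default in chemometrics practice; the machinery supports any count and
  stops early when no orthogonal variation remains.
- **Sign convention**: the predictive component is oriented so the class
  coded 1 has positive mean score, removing the sign ambiguity of latent
  variable models.
- **R2Y** is computed on the full training fit; **Q2 = 1 − PRESS/TSS** under
  stratified k-fold cross-validation (default 7), with scaling and all
  components re-estimated inside each training fold to avoid leakage. TSS is
  the total sum of squares of the centered dummy response. Fold assignment
  uses one seeded global shuffle with fold = within-class rank mod k — a rule
  chosen because it is invariant to swapping the class labels, which makes
  Q2 itself label-symmetric.
- **VIP** over the single predictive component is `√p · |w_j|`, so
  Σ VIP² = p by construction and VIP > 1 marks features contributing more
  than average.
- **Permutation test**: the model (including cross-validated Q2) is refit
  under `n` label permutations (default 1000); `pQ2` and `pR2Y` use the
  add-one estimator `(#{permuted ≥ observed} + 1)/(n + 1)`, which cannot
  report zero and is valid (super-uniform) under the null. A model is
  declared overfit when `pQ2 ≥ 0.05`. The permutation-inclusive estimator
  was chosen over a regression-intercept criterion because it has an exact
  finite-sample interpretation.

## Differential selection

Per feature, a two-sided Wilcoxon/Mann-Whitney rank-sum test: exact
enumeration when the smaller group has ≤ 10 members and the pooled data are
tie-free, otherwise the tie-corrected normal approximation with continuity
correction. Benjamini–Hochberg step-up FDR is computed across all features
surviving preprocessing in the comparison (not only annotated ones — the
adjustment family is the full tested set). log2FC is oriented case minus
reference, so metabolites lower in tumours than normals are negative.
Selection rules (strict inequalities): `VIP > 1 ∧ FDR < 0.1` (`fdr_rule`,
normal-vs-tumour contrasts) or `VIP > 1 ∧ p < 0.05` (`p_rule`, tumour
subtype contrasts). Pooled sides (`"benign+borderline+malignant"`) and the
borderline→malignant merge are metadata-level relabelings in the comparison
spec.

## Annotation

Precursor-only matching: a reference compound is a candidate for a feature
when the signed mass deviation `(observed − theoretical)/theoretical × 1e6`
is within ±20 ppm (inclusive); candidates are sorted by absolute deviation.
Adduct handling is delegated to the reference list (the supplied m/z is
assumed to be the positive-mode adduct mass). MS2 fragment scoring is out
of scope; every candidate carries an explicit `"precursor-only"` evidence
tag so downstream users cannot mistake matches for identifications.

## Panel search, cutoff transfer, evaluation

- **Classifier**: radial-kernel SVM, `gamma = 0.1` with `cost = 100`
  (normal-vs-tumour) or `cost = 10` (subtype contrasts), probability outputs
  via seeded Platt calibration on internal folds; retraining with the same
  data and seed reproduces identical probabilities. Pareto scaling of the
  panel columns is fit on the training cohort and frozen.
- **Search objective**: mean per-fold cross-validated AUC over seeded
  stratified 7-fold splits, the same folds for every subset. Subsets of
  sizes 1..10 are enumerated exhaustively while the subset count fits the
  evaluation `budget` (function default 10⁶); beyond it the search falls
  back to seeded greedy forward selection, which stops growing the panel
  once a step no longer improves the CV AUC, and the fallback is recorded in
  the result. True exhaustion over all ≤10-subsets of ~50+ candidates
  (~10¹⁰ subsets) is computationally meaningless, so the budget cap is the
  honest version of "exhaustive within 10 variables"; the pipeline default
  budget is 2000 subsets to keep full runs interactive. Ties in CV AUC
  resolve to the first subset encountered (smaller panels first, candidate
  order within a size), making results deterministic.
- **Cutoff**: the Youden-optimal threshold (max sensitivity + specificity −
  1) over observed discovery scores; ties break toward higher specificity,
  then the larger threshold (a conservative rule: prefer fewer false
  positives). The cutoff, scaler and classifier are frozen on discovery
  data; evaluation on the validation cohort (or any subset, e.g. FIGO I–II
  early-stage cases) never re-estimates anything. AUC is cutoff-free; the
  cutoff determines sensitivity/specificity and the confusion counts.
- **Hybrid models** append the log2-transformed clinical marker as an extra
  pareto-scaled column; samples missing the marker are excluded from
  marker-dependent models only, with counts reported. The raw marker is also
  evaluated alone, at its Youden cutoff and at a user-fixed clinical cutoff
  (35 U/mL for CA125).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- log-normal intensities — per-feature log2 baseline ~ N(17, 2) (typical
  peak-area magnitudes), per-feature biological sd ~ U(0.6, 1.4) log2 units;
- planted differential features (default 65 of 1300, |log2FC| = 2) with an
  independent shift sign per tumour group — in particular the borderline
  group is *not* on a benign→malignant gradient, and a feature can therefore
  cancel in pooled contrasts;
- planted features are drawn from the quantifiable part of the feature
  space (baseline sufficiently above the detection limit that a −effect
  shift stays detectable): an effect planted on an undetectable feature is
  unrecoverable by construction and carries no information about the
  selection machinery under test;
- missing-not-at-random zeros: detection probability is a logistic function
  of the underlying log2 intensity, with the detection limit placed at the
  `missing_baseline` quantile of feature baselines (default 0.02 — peak
  tables whose missing values were largely filled upstream have few
  residual zeros). A completely-at-random switch exists for ablation;
- two acquisition batches with multiplicative per-feature shifts
  (log2 sd 0.3), balanced across groups;
- pooled QCs: the mean of a random 20% sample subset under multiplicative
  log-normal noise (sd 0.05 ≈ 5% RSD), one QC per 20 biological samples;
- an internal-standard feature spiked at constant level with analytical
  noise only;
- a CA125-like marker drawn per group from a moment-matched log-normal
  truncated at zero (group means/sds 8.35/5.81, 83.45/234.82,
  183.88/326.63, 1254.34/1597.27 U/mL — strongly right-skewed, as the
  sd > mean implies), plus FIGO-like stages for tumour samples;
- default cohort design: discovery 40/36/13/74
  (normal/benign/borderline/malignant), validation 40/45/7/76; both cohorts
  drawn from a single feature model (the i.i.d. transfer setting).

Not emulated: feature-feature covariance beyond optional block structure,
retention-time drift, chromatographic artefacts, batch×group confounding,
and population heterogeneity between discovery and validation cohorts.
Passing tests therefore demonstrate the correctness and calibration of the
*machinery* under the stated generative assumptions, not the clinical
performance of any particular panel on real cohorts — in real transfer
settings the validation drop can exceed the i.i.d. bounds tested here.

## Numerical conventions and reproducibility

Sample statistics use ddof = 1 throughout. Every stochastic step (cohort
generation, fold assignment, permutations, SVM calibration) is driven by an
explicit integer seed; identical config + seed yields byte-identical output
files, and the pipeline manifest records seeds, parameters and sha256
checksums of every artifact. Features constant within a comparison's samples
are dropped before scaling (their VIP is reported as 0); a feature with no
positive values is an upstream error, not an imputation case. Degenerate
inputs (single-class labels, all-equal scores, empty groups, missing panel
features) raise typed errors naming the offending item.

## Test-suite problem sizes

The acceptance-grade checks run at reduced but statistically meaningful
sizes chosen as part of the package design: oracle equivalences on 1000
random p-vectors / 200 score vectors / 92-subset enumerations; permutation
calibration on 100 null cohorts (40 vs 40, 200 features, 99 permutations);
recovery on 1000 features with 50 planted effects; cutoff transfer over 10
seeds with a 200-sample validation cohort. The acceptance script runs the
full study at 600 features with 199 permutations; all sizes are constants at
the top of the script.

## Known limitations

- The permutation screen is a 5%-level test: one in twenty truly null
  models will pass it by construction; the pipeline guard is therefore a
  filter, not a proof of validity.
- Greedy forward selection is not guaranteed to find the best subset when
  the budget forces the fallback; the result records which method ran.
- Probability calibration (Platt) inside small discovery cohorts is noisy;
  cutoffs near 0.5 on well-separated data are an artefact of calibration,
  not of the decision boundary.
- Annotation is precursor-mass-only and inherits whatever adduct assumptions
  the reference list embodies.
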