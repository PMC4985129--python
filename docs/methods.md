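# Methods

This note documents the statistical model behind `exacmark`, the choices
that were genuinely open, and what the synthetic-data results do and do not
demonstrate.

## Data model

The unit of quantification is the per-sample ratio of endogenous peptide
signal to a spiked stable-isotope-labelled standard. A cohort pairs each
patient's hospital-admission (exacerbation) sample with a later outpatient
(convalescent) sample; the positive class is exacerbation throughout.
Missing measurements are treated as left-censoring at the limit of
detection (LOD), never as zeros: a value that is absent is presumed low,
which motivates both the missingness QC rule and half-minimum imputation.

## Pre-processing

Four exclusion rules remove peptides that quantify poorly: median ratio
< 0.005, median instrument response < 100, more than two standard
recoveries outside the inclusive 80–120 % window, and more than 25 %
missing values. All four are strict inequalities, so a peptide exactly at
a threshold is retained; medians are computed over non-missing values only
(missingness means below-LOD, not zero). Retention is the conjunction of
the four rules, so their order is irrelevant to the retained set; the
exclusion report attributes each excluded peptide to the first failed rule
in the fixed order ratio → response → standards → missingness, purely for
deterministic reporting. Imputation happens on the ratio scale before the
log2 transform (half the peptide's own minimum, per peptide), so imputed
values are always strictly below every observed value of that peptide.

Proteins measured by several peptides are represented by the peptide that
attains the per-sample maximum in the largest number of samples. Shared
per-sample maxima count for every peptide attaining them; win-count ties
break by higher overall median, then lexicographic peptide id. Because the
rule compares peptides within a sample, adding a constant to all of a
protein's peptides cannot change the winner (shift equivariance).

## Moderated paired test

Per-protein paired log2 differences d_g (exacerbation − convalescence, one
value per patient) are tested against zero with variance moderation: the
per-protein sample variance s²_g (df = n−1) is shrunk toward a prior
scaled-inverse-χ² with hyperparameters (d₀, s₀²) estimated across proteins
by the method of moments on log s²_g, using digamma/trigamma moments and a
Newton inversion of the trigamma function. When the observed spread of
log-variances does not exceed what n−1 degrees of freedom already imply,
d₀ = ∞ and every protein is standardized by s₀ (normal reference);
d₀ = 0 recovers the ordinary paired t test. Both limits are asserted
numerically in the tests, and the whole machinery is cross-checked against
the reference Bioconductor empirical-Bayes implementation on a fixture
(agreement to 1e-6 relative on t and p, 1e-4 on the hyperparameters).

Patients with several convalescent samples (e.g. day-30 and day-90 visits)
contribute the earliest by default; the choice is logged and configurable.
Candidates are gated at FDR < 0.01 and fold change > 1.2, both strict and
evaluated on unrounded values — displayed tables round fold changes to two
decimals, so a displayed 1.20 can be a selected protein whose unrounded
fold change exceeds 1.2.

## Elastic-net panel

The classifier is penalized logistic regression of state on log2 protein
levels with the glmnet-form penalty λ[α‖w‖₁ + (1−α)/2‖w‖₂²]. Nothing in
the source analysis pins α, λ or the selection rule beyond "stringent
feature selection", so the defaults here are α = 0.9 (heavily L1, sparse
panels), a 20-point log-spaced λ grid from the data-derived λ_max down to
λ_max/100, inner stratified 5-fold cross-validated deviance, and the
one-standard-error rule (the most penalized λ within one SE of the
minimum). All are configurable; the default seed is fixed. Features are
standardized internally and coefficients are reported back on the input
scale, so panel weights multiply log2 protein levels directly. Paired
samples enter the logistic fit as independent observations (no pairing
term); pairing is honoured at evaluation time instead. Exact refit of the
published weights is not expected — it depends on solver internals the
source does not state — so the published 5-protein panel ships as a fixed
constant, and the biomarker score is its linear predictor (no logistic
transform).

The solver is scikit-learn's saga with warm starts along the λ path,
convergence tolerance 1e-5 and a seeded sample order, which makes whole
pipeline runs byte-reproducible. At near-zero penalty the fit matches an
independent maximum-likelihood logistic regression to 1e-3, which bounds
the effect of the tolerance.

## Leave-pair-out cross-validation

The CV-AUC enumerates all (positive, negative) sample pairs. For each pair
the panel stage is refitted with both patients' samples removed
(patient-aware removal: a held-out sample's within-patient partner never
appears in training, which would otherwise leak pairing information), and
the pair contributes 1, 0.5 or 0 according to the held-out ranking. With
refitting disabled the estimator is exactly the Mann–Whitney AUC of the
fixed score — an identity the tests assert, alongside null calibration
(mean CV-AUC 0.50 under permuted labels). Training sets are cached by the
removed-patient set (two patients define one training set, halving the
~n² fits to ~n²/2), and each fold's inner CV seed derives deterministically
from the global seed and the removed patients, so honest refitting and
reproducibility coexist. A fold whose fit fails is excluded from the mean
and counted in the report rather than scored with a stale model.

Each sample's held-out score is the mean of the scores it received across
the folds where it was held out; these held-out scores feed threshold
selection, keeping thresholds out-of-sample. Cutoffs are the midpoints
between adjacent distinct scores; the exacerbation threshold maximizes
Youden's J = sens + spec − 1 subject to sensitivity ≥ 0.90, the
convalescence threshold subject to specificity ≥ 0.90, with ties broken
toward the higher complementary metric. If no cutoff meets a constraint
(e.g. all scores identical) the selection raises rather than silently
relaxing it. PPV/NPV are reported over a prevalence grid with 0/0 left
undefined (NaN), not coerced to 0. Replication cohorts are scored with the
fixed panel and evaluated with the Mann–Whitney AUC (equivalently LPOCV
without refitting); discovery thresholds are applied, not reselected.

## Synthetic cohorts

The generator emulates the paired design at the scale of the original
study: 230 peptides over 129 proteins, 72 patients by default, seven
differential proteins carrying the gene symbols and directions of the
published candidate list, with effect magnitudes drawn uniformly from
[log2 1.2, log2 1.64] per cohort (the published fold-change range; the
printed 1.20 values are rounded, so boundary effects are not pinned).
Protein log2 abundances decompose into a patient baseline
(between-patient SD 0.7) plus within-patient noise (SD 0.3) — plausible
plasma-proteomics values on the log2 scale, chosen once since the source
reports no variance components, and configurable. Peptides carry fixed
per-peptide offsets (SD 0.5) plus small measurement noise (SD 0.05), which
makes the rollup's highest-level choice meaningful; missingness is
left-censoring below a per-peptide LOD quantile (default 5 %); QC failures
are injected per rule into peptides of non-differential proteins so ground
truth stays interpretable. All randomness flows from one seed through
independent child streams per stage. External (unpaired) groups draw from
the convalescent distribution — on the scale the pipeline would produce,
i.e. including each protein's representative-peptide offset — plus an
optional mean shift.

Under these defaults the analytic cross-pair AUC of the true linear score,
Φ(√(Σe²)/√(2(σ²_b+σ²_w))), typically falls in the 0.7–0.9 band, so
pipeline CV-AUCs on generated cohorts bracket the originally reported
discovery value qualitatively; a given seed's value depends on the drawn
effect magnitudes. Passing tests on these cohorts demonstrate correctness
of the statistical machinery under the stated generative model — they do
not demonstrate clinical performance on real plasma, where peptide noise
is heteroscedastic, missingness is messier than clean left-censoring, and
proteins are correlated (the generator draws them independently, which is
the main idealization).

## Problem sizes and numerical choices

The test suite exercises LPOCV at 10–16 patients with reduced λ grids, the
null-calibration property at 12 patients × 200 label permutations with a
pinned λ, hyperparameter recovery at 5,000 proteins, and candidate
recovery at the full 72-patient scale × 100 seeds; the acceptance script
runs the full 72-patient discovery (5,184 pairs, 2,628 cached refits) plus
37- and 109-patient replications. Degenerate inputs raise typed validation
errors: all-missing peptides, nonpositive values at log2, unpaired
patients, single-class labels, empty candidate sets, unsatisfiable
threshold constraints.

## Known limitations

- No batch/plate correction and no covariate adjustment (none described
  for the source analysis).
- No transition-level modelling below the peptide table; instrument-side
  processing is out of scope.
- No confidence intervals on AUCs (none reported in the source); the
  LPOCV pair outcomes are available for resampling if needed.
- The elastic-net λ grid is data-derived; two cohorts of different size
  see different grids, which is standard but means λ values are not
  comparable across runs.
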