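# Methods and modeling choices

This note documents the statistical machinery, the conventions chosen where
the field admits several, and what the synthetic data can and cannot
establish.

## Data model and preprocessing

Peak-area tables are samples × features with nonnegative finite values and
complete cases; readers reject missing or non-numeric cells rather than
impute, because every downstream model assumes a complete matrix.  Files
are tab-separated (metabolite names contain commas).  Group labels are a
case-sensitive controlled vocabulary of seven clinical groups that pool to
four diagnosis-level cohorts (SLE, pSS, SSc, HV).

Between-sample intensity variation in GC-MS serum profiling is dominated by
injection efficiency and ion suppression, which act multiplicatively on
every peak of a sample.  Normalization therefore fits a **one-component,
non-centered PCA** on the spiked internal-standard (IS) submatrix and takes
the magnitude of each sample's first score as its intensity factor.  Two
conventions are ours:

* IS columns are scaled to unit mean before the fit so a single
  high-abundance standard cannot dominate the score direction;
* factors are rescaled to median 1, keeping normalized data on the original
  intensity scale.  Division by the rescaled |t1| is our reading of "score
  magnitude as a general intensity measure"; the alternative (regressing
  each feature on t1) was rejected as it changes the estimator only at
  second order while complicating equivariance.

Feature filtering to the 73 uniquely identified analytes happens **after**
normalization (normalization needs the IS columns, which are then dropped).
The full 243-feature putative set remains selectable.

## NIPALS PCA, DModX and DCrit

Components are extracted one at a time by power iteration with deflation;
convergence is a relative score change below 1e-9 with a 10 000-iteration
cap (near-degenerate eigenvalue pairs in small class matrices legitimately
need thousands of linear-rate iterations).  Each loading's
largest-magnitude element is made positive so scores are reproducible.
Default scaling is centered unit-variance, with Pareto and center-only
available; zero-variance columns receive weight 0.  The scaling is recorded
in every model artifact because R2X/Q2 values are meaningless without it.

Residual statistics use the degrees-of-freedom convention

* `s0² = SS(E) / ((N − A − 1)(K − A))` for centered models
  (`(N − A)(K − A)` non-centered),
* training DModX carries the leverage correction `sqrt(N / (N − A − 1))`,
* `DCrit(α) = sqrt(F⁻¹(1 − α; K − A, (N − A − 1)(K − A)))`.

The exact correction used by commercial chemometrics software is
unpublished; the convention above is validated by simulation — held-out
in-class draws from a Gaussian factor model are rejected at the nominal
rate (α ± 0.015 for α ∈ {0.01, 0.05, 0.10} with 200 training rows, 30
variables, 3 components).  The calibration holds for center-only scaling,
where residual noise stays homoscedastic across columns.  Unit-variance
scaling of strongly structured data makes residual variances heterogeneous
and inflates the rejection rate by a few points (≈0.10 at nominal 0.05 in
the same simulation); this is a known property of the χ²/F approximation
underlying DModX, not of the implementation.

### Cross-validated Q² for PCA

Rows are assigned to folds by deterministic round-robin (row i → fold
i mod folds, default 7); scaling is refit inside each fold.  The predictive
residual for variable j of a held-out row estimates the scores from the
*other* variables only (closed-form Sherman–Morrison correction, loadings
being orthonormal).  A naive projection that reconstructs a held-out row
from its own full projection explains ≈ A/K of even pure noise; with the
corrected residual, white noise yields Q² ≤ 0 while a strong planted
rank-1 structure yields Q² > 0.9.

## SIMCA

One PCA model per class, fit on that class's rows only, each with its own
scaling statistics; membership is `DModX ≤ DCrit(α)` and is deliberately
soft (zero, one or both classes).  Component counts default to the value
maximizing leave-one-out Q² over 1–5, overridable per class.  Leave-one-out
validation refits the class model without each own-class sample
(sensitivity); other-class samples are judged against the full model
(specificity), since LOO removal is undefined for non-members.  When the
fitted SLE/HV pair predicts the external pSS and SSc cohorts, the per-model
specificity is the fraction rejected, and the reported aggregate is the
mean of the two per-model specificities.

## OPLS-DA

Single-response formulation: classes coded +1/−1 (the disease is the
positive class in disease-versus-control contrasts, so positive p(corr)
means higher in disease), `w ∝ Xᵀy` normalized, A_o orthogonal components
(default 1, common practice for two-class metabolomics contrasts) removed
by sequential deflation, then one predictive component.  Predictions filter
the orthogonal variation out of new data before applying `w`; the class
threshold is zero, ties going to the positive class.

Cross-validation uses class-stratified round-robin folds and refits
everything — scaling included — inside each fold; this is stricter than
merely refitting the decomposition but is required for honest Q² with wide
matrices.  CV-ANOVA compares PRESS of the cross-validated predictions to
total response variance with `df_model = 1 + A_o` and
`df_error = N − 1 − df_model`; PRESS ≥ SS truncates F at 0 (p = 1).  Under
label-independent data the resulting p-values are approximately uniform
(fraction below 0.05 within 0.05 ± 0.04 over 200 simulated datasets).  The
ROC for an OPLS-DA model scores the cross-validated predicted responses.

## Univariate statistics

Welch's unequal-variance two-tailed t-test (Satterthwaite degrees of
freedom) is applied per feature on natural-log intensities — the data model
is multiplicative, so direction is a mean log-ratio.  Two zero-variance
samples with equal means give p = 1, with unequal means p = 0.  No
multiple-testing correction by default (significance is raw p < 0.05);
Benjamini–Hochberg q-values are available behind a flag.  ROC curves use a
threshold sweep with half-credit ties, making the trapezoidal AUC exactly
the Mann–Whitney concordance.

## Identification

Match values are a weighted squared cosine on the 0–999 integer scale
(rounded half-up), symmetric and scale-invariant, with self-match exactly
999.  Weights `mz^m · I^n` default to the Stein–Scott exponents m = 3,
n = 0.6 — the study's source only says higher m/z peaks weigh more, so the
exponents are a documented convention, configurable.  m/z values are
rounded to nominal (integer) mass before alignment, the GC-EI convention.
Retention indices interpolate linearly between alkane retention times
(C10 = 1000 … C40 = 4000) with no extrapolation; the acceptance window
(±10) is in index units, not seconds.  Library search keeps the best match
inside the window, ties broken by smaller |RI deviation| then name, and
accepts it only above the minimum match value (default 700).

## Synthetic cohorts

`x_ij = f_i · b_j · exp(δ_gj) · exp(ε_ij)` with log-normal injection factor
`f_i` (σ = 0.25) shared by all columns of a sample, per-feature baseline
`b_j` (log-uniform over [2, 6]), planted log-scale group effects δ versus
the HV baseline, and iid log-normal noise (σ = 0.15), optionally
block-correlated within chemical class.  Internal standards carry no group
effect.  Group sizes, feature counts (243/73/11) and the qualitative effect
pattern — exactly 5 up- and 15 down-shifted identified metabolites in SLE,
tryptophan the strongest (δ = −1.0, making it the top discriminator by
construction), urea/uric acid/cystine up, a milder amino-acid depression in
SSc with arginine up, organic acids including fumaric acid up in pSS while
fumaric acid is down in SLE — mirror the study design.  Effect magnitudes
|δ| ∈ [0.4, 1.0] were chosen once so planted effects are detectable at
these group sizes without being trivial; per-metabolite fold-changes and
variances of the real cohorts are not public, so the magnitudes are
stand-ins and are labeled as such in the generator's truth output.

What the generator does **not** emulate: chromatographic peak shapes and
co-elution, drug metabolites and treatment confounding, age/sex structure,
batch drift beyond the single global intensity factor, and realistic
between-metabolite correlation beyond the optional class-block term.
Passing recovery tests therefore show the pipeline is correct and
well-calibrated under its own assumptions, not that the real cohorts'
printed accuracies are reproduced; the study's R2X/Q2, sensitivity,
specificity and AUC values are treated as descriptive context, with only
the weakest printed specificity (67%) used as a floor the synthetic system
must clear.

## Problem sizes and numerics

Simulation-backed tests use the default 87-sample cohort across 20 seeds;
calibration simulations use 200 training / 2000 test observations (DModX)
and 200 replicates (CV-ANOVA uniformity), sizes at which the whole suite
completes in well under a minute per module.  Tolerances: NIPALS
orthogonality 1e-8 (relative for score products), SS conservation 1e-8
relative, oracle subspace angles 1e-6, exact identities (AUC complement,
confusion formulas, self-match) asserted to machine precision.  Degenerate
inputs are defined rather than undefined wherever a sensible convention
exists: s0 = 0 models flag any nonzero residual as outside, all-tied ROC
scores give AUC 0.5, and zero-variance Welch cases follow the rules above.

## Known limitations

* DModX calibration degrades mildly under unit-variance scaling of strongly
  structured data (see above); for strict type-I control use center-only
  scaling for class models.
* CV-ANOVA degrees of freedom follow one published construction; its
  adequacy is established here only by the uniformity simulation.
* SIMCA component selection by LOO Q² can be unstable for classes near the
  minimum size (components + 2); fixing counts per class is recommended for
  cohorts of ten.
* The identification module scores centroided stick spectra; it does not
  deconvolve chromatograms or model isotope patterns.
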