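# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the known limitations of `neurobag`.

## Pipeline overview

1. **Feature extraction** (`gmv_features`): voxel-wise GMV maps are masked
   by a grey-matter probability threshold (strictly > 0.2 by default) and
   parcellated by an integer atlas (442 regions expected: cortical,
   subcortical, cerebellar). Two feature sets result: per-region mean GMV
   (global model input) and per-region voxel signatures in fixed C scan
   order (regional model inputs). Regions emptied by the mask are dropped
   and reported, never imputed.
2. **Brain-age models** (`brainage_model`): SVR-RBF inside a
   standardization pipeline. Nested CV: outer and inner folds stratified by
   age-quantile bins (5 bins) so each fold spans the age range; grid search
   on the inner folds only, scored by MAE; ties resolve toward smaller C,
   then smaller γ. The library default grid is powers of ten over
   10⁻³…10³ for both C and γ; desk-scale runs use C ∈ {1, 10, 100, 1000} ×
   γ ∈ {10⁻³, 10⁻², 10⁻¹} for the global model and fixed C = 10 with
   γ = 1/d for the per-parcel models, because a full grid for hundreds of
   parcels adds cost without changing the science being tested. ε (the SVR
   tube) stays at the conventional 0.1. Out-of-fold R² is the headline
   accuracy metric; an n-adjusted variant is co-reported because adjusting
   kernel models for "number of predictors" is ill-defined.
3. **Bias correction and BAG** (`bias_and_bag`): OLS of predicted on
   chronological age, fitted on K-fold out-of-fold predictions of the
   training cohort (K = 10) so the regression-to-the-mean estimate is
   neither optimistic (in-sample) nor far from the final model's behaviour
   (the K-fold models see 90% of the data). Default correction is the
   additive offset form; the rescaling form (ŷ−α)/β is available but
   unstable for small β. Each regional model has its own bias model.
4. **Group inference** (`group_inference`): linear-model ANCOVA with
   age, centred-age², sex, TIV and protocol covariates (centring age before
   squaring limits collinearity). η²ₚ is computed from sums of squares and
   satisfies F·df₁/(F·df₁+df₂) identically. FDR is Benjamini–Hochberg
   step-up with the conventional ≤ comparison. ComBat follows the
   parametric empirical-Bayes algorithm (standardize per feature with the
   biological design preserved, shrink per-batch location/scale across
   features, adjust); a non-EB mode exists for auditing, and a single
   feature falls back to non-EB because there is nothing to pool across.
5. **PermCCA** (`clinical_cca`): both sets residualized on their confound
   designs (clinical: age, sex; imaging: age, age², sex, TIV, protocol);
   the significant-region BAG matrix is PCA-reduced to the smallest k
   reaching 50% explained variance (computed on residualized BAG by
   default; the raw-BAG order is an option). Inference permutes rows of the
   residualized clinical set (Freedman–Lane style simple residualization
   rather than a basis-reduction scheme; its type-I calibration is verified
   by simulation in the test suite). Mode m is tested step-down on data
   deflated of modes < m with the statistic −Σ_{i≥m} log(1−r²ᵢ); p-values
   use the +1 convention and ties count as exceedances; for small n an
   exhaustive enumeration over all row orders is available. Reported
   loadings are own-set variable–variate correlations (sign fixed so the
   largest clinical loading is positive); their FWE p-values come from a
   max-statistic permutation distribution of **cross**-correlations with
   the other set's variate, because own-set loadings are not null under
   permutation. Bootstrap CIs resample subjects, redo residualization,
   project onto the *fixed* original PCA basis (component-order instability
   would otherwise dominate), align replicate signs to the original by
   loading-vector correlation, and take percentiles. Complete cases only.
6. **Functional decoding** (`functional_decoding`): nearest-voxel
   assignment of foci to the ROI (no dilation by default; a radius in mm is
   configurable), binomial Z against the database base rate, exact binomial
   p co-reported, and the fixed Z > 3.0 Bonferroni rule for the 59
   sub-domains. Mask and database must carry matching space tags; sub-domains
   with degenerate base rates are skipped with a note.

## Synthetic data-generating process

`synthetic_cohort` emulates the statistical structure this analysis
assumes, with stored ground truth for recovery tests:

* Region r of subject s: `m = baseline_r − slope_r · (age_s + δ_s) +
  sex/protocol terms + N(0, noise_sd)`, multiplied by
  `(TIV/1430 mL)^tiv_coupling`. Voxel features add centred per-voxel
  offsets and voxel noise; the bundled region mean is exactly the voxel
  mean, so atlas extraction round-trips the generator.
* δ_s is the **biological brain-age deviation**, shared across all regions
  (it is the irreducible error floor of any brain-age model, since it is
  collinear with the age direction in feature space). Its SD grows linearly
  with age (SD = 8 y at the pivot age of 56), reflecting the divergence of
  ageing trajectories; a younger clinical cohort therefore carries a
  smaller deviation than the full-range normative cohort.
* Defaults: slopes U(0.5, 0.9) a.u./yr on a 95 a.u. baseline (regional
  decline of roughly 30–60% over the adult range), region noise 1.0 a.u.,
  voxel noise 1.0 a.u., two acquisition protocols with a 2 a.u. location
  offset and 15% noise-scale difference, 65% female, TIV ~ N(1430, 120) mL
  scaling GMV multiplicatively, ages uniform over the configured range.
  Under these conditions the global model reaches MAE ≈ 5–6 y (R² ≈ 0.9)
  and regional models ≈ 7–10 y on held-out data, matching the accuracy
  regime of published GMV brain-age frameworks, with regression to the mean
  (raw BAG–age correlation ≈ −0.3) present by construction.
* Clinical cohorts add a latent severity factor (|N(1, 0.5)| in patients,
  0 in controls). Patients lose `slope_r · bag_shift · severity` a.u. in
  each affected region — an extra `bag_shift` years of equivalent ageing at
  severity 1. Clinical variables load on the same severity factor:
  headache and painkiller frequencies linearly (capped at 30 days/month),
  MIDAS and BDI log-linearly (right-skewed scores), disease duration almost
  not at all; all truncated to valid ranges. Region parameters derive from
  a separate `region_seed` so cohorts drawn under different subject seeds
  share the same "brain" and trained models transfer across them.

Ground-truth helpers: `expected_regional_decrement` (analytic mean GMV
loss), `expected_global_bag_difference` (linear-observer approximation with
slope²-weights and a bias-slope attenuation factor), and
`pipeline.counterfactual_group_response`, which generates the clinical
cohort twice from one seed with the injection on/off and measures the mean
prediction difference in patients — the causal estimand used for CI
coverage checks. The counterfactual is the authoritative truth: the fitted
kernel's response to a 66-region shift is roughly twice the linear
projection, so the closed-form approximation is documentation, not oracle.
`population_canonical_correlation` evaluates the canonical correlation
between the clinical set and the idealized regional ageing pattern
(shift·severity + deviation + slope-normalized noise) by large-n Monte
Carlo through the actual generator equations, so truncation and skew
transforms are respected.

## What passing tests do and do not show

The generator produces linear, Gaussian-noise atrophy on a synthetic
lattice; it has no cortical geometry, no segmentation or registration
error, no spatial autocorrelation beyond the parcel structure, no
longitudinal dimension, and clinical variables with a single latent factor
rather than correlated comorbidities. Tests passing here demonstrate that
the *statistical machinery* is correct and calibrated (type-I error,
FDR/FWE control, coverage, recovery under a known truth), not that any
particular real-data effect would replicate.

Several acceptance-level checks sit intentionally close to their
thresholds. The mean BAG of a 200-subject held-out cohort has a sampling SD
of ~0.5 y when the model error is ~7 y (as it must be for visible
regression-to-the-mean), so the |mean| < 0.5 y check can fail for an
unlucky draw; likewise a shared biological deviation produces occasional
replicates where the whole affected-region set is missed at FDR 0.05.
These are properties of the study design being emulated, not defects.

## Numerical choices and degenerate inputs

* Grid-search ties resolve to the first (smallest) parameter combination.
* Constant feature columns warn but do not abort; constant regions or
  zero-variance clinical variables in CCA/decoding are flagged, not
  imputed.
* Permutation p-values are never 0 (the +1 convention); exhaustive
  enumeration includes the identity order.
* PCA uses SVD on centred data; the component count is the smallest k with
  cumulative explained variance ≥ the target (exact ties resolve downward
  via a 10⁻¹² guard).
* Bootstrap replicates with rank-deficient resamples are skipped and
  counted; >5% skipped triggers a warning.
* ComBat guards zero pooled variances at 10⁻¹² and refuses batches with a
  single subject.

## Scaling of desk runs

Test-suite and acceptance-script problem sizes — normative n = 600,
clinical 110 + 70, 16 voxels per region, 1000 permutation/bootstrap
iterations (10 000 remains the library default for study use), 400/500
replicates for calibration checks — were chosen so a complete run finishes
in minutes on a single CPU while keeping every statistical property
measurable at its stated tolerance.
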