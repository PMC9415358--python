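# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limitations of `ecotransfer`.

## The analysis

The package evaluates how well site-level biodiversity measures can be
predicted from two remotely sensed covariates, within and across studies of
a hierarchical biodiversity database (studies → sites → species records).

Per study *j*, each measure is regressed on one covariate at a time:
`y_i = α_j + β_j x_i + ε`. Species richness uses a Poisson GLM with log
link (explained variance reported as the deviance pseudo-R²,
`1 − dev/null_dev`); log abundance and evenness use Gaussian fits (squared
Pearson correlation of fitted vs observed). Compositional similarity is a
pairwise distance-decay model, `logit(Sorensen) ~ env_diff + log10(km +
0.05)`, fitted on all within-study site pairs. Fits require at least 3
sites (4 pairs); degenerate designs (zero-variance or perfectly collinear
predictors) are flagged and skipped downstream, never silently fitted.

Prediction error is the symmetric mean absolute percentage error (sMAPE,
0–100%), computed **on each model's response scale**: counts for richness,
`log10(A+1)`, `arcsin√PIE` and `logit(Sorensen)` otherwise. Using the
modelled scale keeps the error comparable across measures with different
units; the alternative (back-transforming abundance before scoring) would
make sMAPE dominated by a handful of high-abundance sites.

### Permutation design

Ten permutation sets split each study's sites into 33% test / 66% train
(`n_test = round(0.33 n)`, minimum 1). Predictability test sites are drawn
without replacement with probability proportional to their great-circle
distance from the study's spatial centroid — peripheral sites are harder
hold-outs; co-located sites fall back to uniform weights. Transferability
partners come from the focal study's methodology group (exact concatenation
of taxon group × sampling method × sampling unit; groups with < 2 studies
are ineligible). Partner choice uses inverse-frequency weights
`(1 + times_partnered)^-1` plus a repair pass that swaps a never-tested
study into a set, guaranteeing that over ten sets every eligible study
serves as both training and test source. Transferability fits use **all**
sites of the focal study (only the partner loses 33% of sites, as the
design removes test sites from a different study, not from the training
one). Composition transfer applies the focal study's coefficients to the
partner's pair predictors; spectral centroid distances are within-study
quantities in each study's own PCA space, so no cross-space projection
arises.

### Meta-regression

The per-study mean transferability sMAPE (over sets, measures and
predictors) is modelled with a random intercept per methodology group.
Covariates — median sampling extent (m), sampling duration (days), number
of sites, mean samples per site, accessibility (m to nearest city),
pre-imputation missing-data fraction, terrain ruggedness — are standardized
(mean 0, SD 1); constant columns are dropped with a warning. All covariate
subsets are fitted (an extent × effort interaction only alongside both main
effects; 160 candidates for 7 covariates), by maximum likelihood for AICc
comparability; the best `ceil(0.05 M)` models are refit by REML and their
coefficients averaged with equal weights, counting absent terms as zero
(full averaging, which shrinks weakly supported effects toward zero).
R² is variance-partition based: marginal = var(fixed predictor) / (fixed +
group + residual); conditional adds the group variance to the numerator,
computed from the REML fit of the full model (falling back to the
best-ranked candidate when the full model has more parameters than
studies). The mixed-model optimizer tries statsmodels' default, then
Powell, then L-BFGS; models that still fail are dropped from the candidate
set rather than poisoning the ranking.

## Environmental predictors

Sub-monthly reflectance is averaged to calendar months per band. Missing
months (a month is missing as a whole across bands) are imputed per site
and band with a local level + trend state-space model fitted by maximum
likelihood and evaluated with the Kalman smoother; if the optimization does
not converge, linear interpolation over time is used instead. Only gap runs
of ≤ 4 consecutive months are filled; a site is excluded (with a recorded
reason) when it has ≥ 6 missing months in total or any longer run. The
12 months immediately preceding a site's sampling start form the predictor
window; a series that does not cover the window is an error, not a silent
truncation.

The per-study PCA for spectral variability pools all site-months (12 rows
per site × 7 bands), centring and scaling each band — bands have different
dynamic ranges, and without scaling the index would be dominated by the
brightest band. A consequence worth knowing: scaling makes the index
invariant to a uniform rescaling of a *whole study's* deviations (it is
still monotone in a site's deviations relative to its study); passing
`standardize=False` restores strict linear scaling. Variance explained by
the two components is reported per study; for degenerate zero-variance
input it is defined as 100%.

## The synthetic generator

The generator is the package's study-condition definition, not a
convenience fixture. Per study: intercept `α_j ~ N(2.0, 0.5)` and slope
`β_j ~ N(2.0, 0.5)` on the log-abundance scale; a disjoint species pool
(default 40) with per-species offsets `γ_s ~ N(0, 1.5)` so many species are
rare and richness responds to the environment instead of saturating. Per
site: a latent mean vegetation signal `v_i ~ U(0.10, 0.55)`; species counts
`Poisson(exp(α_j + β_j v_i + γ_s))` thinned binomially with detection
probability `1 − exp(−0.15 k_i)` for `k_i` samples (study-level mean sample
count log-uniform over 1–25). Sampling effort therefore has a *planted*
effect on measurement noise: poorly sampled studies detect fewer
individuals and carry noisier measures, which is what the meta-regression
is asked to recover. A `deterministic_counts` switch replaces draws by
their expectations for noiseless recovery tests.

Reflectance follows the MODIS land-band convention (band 1 = red, band 2 =
NIR). The monthly latent vegetation index is `v_i` plus a 12-month harmonic
(amplitude 0.08, study-specific phase) plus `N(0, 0.02)` noise; NIR is
constructed by inverting the EVI2 formula at a noisy red baseline (0.08),
so the EVI2 of the generated bands equals the latent signal by
construction, and its 12-month window mean equals `v_i` exactly when noise
is zero (the harmonic sums to zero over any 12 consecutive months). Five
nuisance bands load linearly on the latent signal with independent noise.
Whole months are masked missing completely at random (default rate 0.05);
`inject_gaps` plants additional runs, including forced ≥ 6-month gaps for
exclusion tests.

What the generator does **not** emulate: reflectance physics, phenology or
biome structure; spatial autocorrelation beyond isotropic Gaussian site
scatter (SD 0.05°) around a study centre; non-linear
biodiversity–environment relationships; taxon-specific detection; real
inter-annual variation. Passing tests therefore demonstrate that the
pipeline's statistical machinery is correct and recovers planted structure
— not that real-world biodiversity is predictable at the levels the
synthetic runs show.

## Problem sizes and defaults

The shipped demo (`configs/demo.yaml`) uses 20 studies × 20 sites,
24 months, gap rate 0.03 and slope SD 0.5. The headline
predictability/transferability contrast is computed at 30 studies × 30
sites with ten permutation sets — large enough that every
measure's transferability error exceeds its predictability error by a
stable margin, small enough to run in well under a minute. The
effort-effect analysis uses 60 studies with samples-per-site spanning 1–40
and per-sample detection 0.03: the wide effort gradient is what makes a
seven-covariate model-selection exercise at 60 studies resolve the planted
negative effect reliably. These sizes are scaled-down analogues of a
database with hundreds of studies; coefficients' magnitudes are not
comparable to any real-data analysis, only their directions and orderings.

## Numerical conventions and edge cases

- PIE uses raw (pre-effort-correction) counts; it is a function of
  individual counts that rescaling would distort. `N ≤ 1` gives PIE = 0;
  empty sites have richness 0, `log10(A+1) = 0`, and evenness flagged
  undefined.
- Sørensen is computed on binarized data and clamped to
  `[0.001, 0.999]` before the logit.
- Occurrence-only studies keep richness and composition; abundance and
  evenness are flagged invalid.
- Richness responses are rounded to integers before the Poisson fit (only
  relevant after effort correction).
- Missing sampling extents are filled from the mean of studies sharing, in
  order: method and taxon; method; taxon; the global mean — with the level
  recorded per value.
- Great-circle distances use the haversine formula on a 6371 km sphere.
- A sMAPE term with observed = predicted = 0 contributes zero.
- All randomness flows from a single top-level seed; derived stage seeds
  are offsets of it, and reruns are bit-identical at the CSV level.

## Known limitations

- The Kalman-smoother imputation fits one model per site × band, which is
  the dominant cost on gap-heavy data; `--impute-method linear` is an
  order of magnitude faster when gaps are few and short.
- Transferability requires exact methodology-group matches; fuzzy
  comparability (e.g. similar but not identical sampling units) is out of
  scope.
- The meta-model averages coefficients with equal weights over the top-5%
  models; Akaike-weighted averaging is deliberately not implemented.
- No GAM/non-linear comparison models, no coverage-based rarefaction, no
  abundance-weighted similarity indices, no raster/Earth-Engine ingestion.
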