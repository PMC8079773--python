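# Methods

This note documents the models, conventions and design choices behind
`gliorad`, in the order the pipeline applies them. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Lattices and geometry

All image math runs on axis-aligned voxel lattices (`VoxelGrid`,
`VoiMask`): intensities plus per-axis spacing in mm and a world origin;
voxel centre *(i,j,k)* sits at `origin + (i,j,k)·spacing`. Oblique
orientation matrices are rejected at load time with an instruction to
resample externally — supporting them would complicate every lattice
operation for a case the workflow never produces. Two lattices count as
aligned when shape matches and spacing/origin agree within 1e-3 mm,
which absorbs file-format float noise while rejecting genuine mismatch.
Times are months, volumes ml (1 ml = 1000 mm³).

The peritumoral rim contains every voxel whose **centre** lies within
the rim distance (default 15 mm) of some tumor voxel centre — computed
as an anisotropy-aware Euclidean distance transform of the tumor
complement — minus the tumor and all exclusion masks. Centre-to-centre
distance (rather than distance to a tumor surface mesh) is the
implementable reading when slice thickness ranges from sub-millimetre
to several millimetres; it is what the brute-force geometry tests
verify exhaustively. The rim is built on the native grid, before any
resampling. Tumors strictly smaller than 0.2 ml are flagged for
exclusion; a mask of exactly 0.2 ml is kept (strict comparison).

## Resampling and normalization

Shape analysis uses a 1 mm cubic resample of the mask; intensity and
texture use a 3 mm cubic resample of the image, both trilinear
(`scipy.ndimage.map_coordinates`, order 1), new voxel centres anchored
at the original origin. Masks are resampled with the same transform and
thresholded at 0.5.

Two normalization/discretization schemes:

* **Fixed bin number** (default 32): `level = 1 + floor(G·(I−I_min)/(I_max−I_min))`
  over in-VOI intensities, the maximum mapped to G. A constant VOI
  yields level 1 everywhere with a degeneracy warning. First-order
  intensity statistics under this scheme are computed **on the bin
  levels**, not the raw intensities, so the whole fixed-bin-number
  branch is invariant to affine intensity transforms of the raw image —
  the property that makes the scheme useful across scanners, and the
  property the tests assert.
* **Linear two-point rescaling**: solve `I′ = aI + b` so the mean over
  the white-matter mask equals the white-matter anchor and the mean
  over the vitreous mask equals the vitreous anchor, apply to the whole
  volume, then discretize with `level = 1 + floor((I−I_min)/bin_size)`
  (bin size 50, minimum anchored at the in-VOI minimum, recorded in
  provenance). The anchors are configuration parameters, defaulting to
  vitreous → 0 and white matter → 300; with the phantom's tissue
  contrast this yields roughly 30–35 occupied levels at bin size 50,
  deliberately comparable to the 32 bins of the first scheme so that
  the two branches have similar sensitivity to noise. Equal reference
  means are a degeneracy error. The map is idempotent and invariant to
  affine distortions of its input.

Discretization is per VOI: tumoral and peritumoral regions are
discretized independently, because features are computed and modelled
per VOI throughout.

## The 180-feature set

Per VOI: 24 shape + 19 intensity + 137 texture features. Wavelet
features are excluded by design — the analyzed regions are too small
for a meaningful multi-resolution decomposition.

**Shape (24).** Voxel count/volume; mesh volume and surface area from a
marching-cubes triangulation; surface-to-volume ratio; compactness 1
and 2, spherical disproportion, sphericity, asphericity; equivalent
spherical diameter; maximum 3D diameter (over convex-hull vertices);
major/minor/least axis lengths as 4·√(eigenvalue) of the voxel-centre
covariance, with elongation and flatness as √(λ₂/λ₁), √(λ₃/λ₁);
volume/area densities against the axis-aligned bounding box, the
approximate enclosing ellipsoid (Thomsen surface approximation) and the
convex hull; convex-hull volume. The binary mask is lightly smoothed
(Gaussian, σ = 0.8 voxel) before marching cubes: a binary level set
produces a staircase surface whose area is biased high by ~9% for a
10-mm sphere, while the smoothed level set brings a digital ball's
sphericity above 0.97. If smoothing washes out a tiny mask entirely,
the unsmoothed surface is used. For a uniform ellipsoid with semi-axis
a, the covariance eigenvalue is a²/5, so the axis-length convention
yields 4a/√5 ≈ 1.79a; the tests assert against this analytic value.
Degenerate geometries (single voxel, coplanar voxels) yield flagged
conventional values, never NaN.

**Intensity (19).** Population-convention mean, variance, skewness and
excess kurtosis; median, min, max, range, 10th/90th percentiles;
coefficient of variation (flagged degenerate at zero variance); robust
mean absolute deviation (within the 10–90 percentile core); energy and
root mean square; histogram entropy and histogram energy on the
discretized grey-level histogram (base-2 logs); and the
intensity-volume-histogram features `enhancing_tumor_volume_{30,40,70}`
— the fraction of VOI voxels strictly above X% of the in-VOI intensity
range (flagged degenerate for a constant VOI).

**Texture (137).** Six matrix constructions over five families, all 3D
with 26-connectivity, grey levels from the per-VOI discretization:

| construction | features |
|---|---|
| GLCM, merged over the 13 unique directions, symmetrized | 26 (incl. maximal correlation coefficient) |
| GLCM, features averaged over non-empty directions | 25 |
| GLRLM, merged | 16 |
| GLRLM, direction-averaged | 16 |
| GLSZM (26-connected equal-level zones) | 16 |
| GLDZM (same zones × min city-block distance to the VOI border) | 16 |
| NGTDM (26-neighborhood grey-tone differences) | 5 |
| NGLDM (dependence counts, α = 0, Chebyshev distance 1) | 17 |

The exact 137-name list is reconstructed from these standardized
families; the merged scheme is the primary aggregation (single value
per feature), with the direction-averaged variants of the two
directional families included as the other common aggregation. The
maximal correlation coefficient is computed for the merged GLCM only
(it is the one eigenvalue-based descriptor in the set; per-direction
matrices of small VOIs are often too sparse for it to be stable). All
feature names used in the clinical radiomics literature for the
modelled descriptors resolve through an alias table
(`gliorad.features.names.ALIASES`).

Conventions, applied identically in the package and in the brute-force
test oracles: entropies are base-2 and skip empty cells; neighborhoods
and pairs are restricted to in-mask voxels, missing neighbors ignored;
the NGLDM dependence count includes the centre voxel (a fully dependent
interior voxel has count 27); zone distances are city-block, minimum 1,
with the grid border counting as outside the mask; merged run/pair
percentages normalize by voxels × directions. Degenerate cases get
fixed conventional values plus a flag (correlation 0 for a single grey
level, coarseness capped at 1e6 for a constant volume, busyness 0, an
empty matrix zeroing its family) so that no NaN ever reaches the PCA.

Every texture matrix and every one of the 137 features is verified, on
a randomized suite of volumes up to 5³ with up to 4 grey levels,
against an independent naive reference implementation (explicit loops,
literal formulas) to 1e-9 relative tolerance; merged features are also
checked invariant under 90° lattice rotations and translations.

## Synthetic data

The phantom generator emulates the *inputs* of the imaging workflow:
an ellipsoidal enhancing tumor (default semi-axes 13/11/9 mm ≈ 5.4 ml,
within the clinically reported tumor-volume range) with a concentric
necrotic core (25% of the volume), axis-aligned boxes for contralateral
white matter and vitreous body, an optional cavity-like exclusion box,
Gaussian noise (SD 8 on a ~200-intensity background), and an affine
scanner gain/offset. Tissue means (background 200, white matter 220,
vitreous 30, necrotic 80, rim contrast +150) are chosen to mimic the
ordering and rough contrast of gadolinium-enhanced T1 tissue classes.
Identical spec + seed is bit-identical. The phantom deliberately does
**not** model brain anatomy, bias fields, partial-volume mixtures or
motion: geometry is axis-aligned ellipsoids and boxes precisely so that
volumes, surfaces and distances have analytic ground truth. Passing
tests therefore demonstrate correctness of the computational pipeline,
not segmentation robustness on real anatomy.

The cohort generator draws, per subject, latent group scores
z_g ~ N(0,1); each observed feature in group g is
√ρ·z_g + √(1−ρ)·ε (pairwise within-group correlation exactly ρ,
default 0.8). The binary label is Bernoulli(σ(b₀ + Σβ_g z_g)); event
times are exponential proportional hazards λ₀·exp(Ση_g z_g); censoring
is uniform on (0, T_max) with T_max solved numerically (Brent) so the
expected censored fraction hits the target. Defaults mirror the target
study's conditions: 69 training + 49 validation subjects, 16 validation
subjects without a methylation label, 7 latent groups × 10 features,
prevalence ≈ 41% (intercept −0.37), baseline rates matching median
PFS₂ ≈ 2.7 and OS ≈ 11.3 months, censoring target 0.10, and a single
informative group whose logistic effect is calibrated — by
Gauss–Hermite quadrature on the exact generative model — so that the
theoretical observed-feature AUC is 0.67. Survival effects default to
log-hazards 0.4 (PFS₂) and 0.35 (OS) on the same group, a concordance
≈ 0.6 regime.

## Feature selection

Features are standardized to mean 0 / variance 1 (population SD) on the
training cohort; constant features are dropped with a warning; the
identical transform is applied to validation data. Horn's parallel
analysis retains the leading eigenvalues of the training correlation
matrix that exceed the same-rank 95th percentile over 1000 (default)
standard-normal datasets of the same shape, counting stopping at the
first failing rank. Each feature is assigned to the retained component
with the greatest contribution, defined as the squared loading
(loading = eigenvector × √eigenvalue); exact ties break to the lowest
component index. If no component is retained, the pipeline falls back
to a single group containing all features and records that in the
branch details.

Screening is univariable per feature: a logistic (binary endpoint) or
Cox (survival) fit with a Wald p-value, plus a direction-free
discrimination metric (AUC, or the concordance of the fitted
univariable predictor). Complete separation — detectable for a single
covariate as non-overlapping class ranges — retains the feature with
metric 1.0 and a flag rather than trusting the exploding Wald SE. Per
group, the significant (p < 0.05) feature with the best metric is the
group's candidate; ties break by smaller p, then name. No
multiple-testing correction is applied: the group structure is the
redundancy control, and at most one candidate per group enters the
model. Screening operates on the scaled features (scaling precedes
grouping, and the univariable fits use the same matrix the
multivariable fit will see).

## Outcome models

The multivariable model starts from all candidates and repeatedly drops
the variable whose removal lowers the AIC most, until no removal
lowers it; the empty (intercept-only logistic, or null-partial-
likelihood Cox) model takes part, so a branch can legitimately end with
"no model". An unfittable variable set (separation, collinearity) is
treated as AIC = +∞ so that selection explores its subsets; only a
problem with no fittable subset raises an error naming the variables.
Logistic fits use `statsmodels.Logit`; multivariable Cox fits use
`lifelines.CoxPHFitter`; the fast univariable Cox screening uses
`statsmodels.PHReg`. The null Cox AIC is computed directly from the
Breslow partial likelihood with no covariates.

Evaluation: AUC is the normalized Mann–Whitney statistic with
half-credit ties; its 95% interval uses the DeLong structural-component
variance. Harrell's concordance counts censoring-aware comparable pairs
(strictly shorter observed time with an event; predictor ties get 1/2;
tied times are not comparable) and its interval uses an asymptotic
normal approximation from per-subject influence values — both verified
against exhaustive pair enumeration at small n, and the concordance
against `lifelines` on tie-free data. Risk stratification thresholds at
the **median training prediction**; scores strictly above it are
high-risk; groups are compared by log-rank test, and an empty group is
flagged with the p-value undefined. Internal validation is stratified
5-fold cross-validation (stratified by label or event flag) in which
scaling, grouping, screening and fitting are re-run inside each
training fold; folds that lose a class or all events are skipped with a
warning. Subjects without a methylation label are excluded from the
binary branch only; they keep their survival endpoints.

External-validation discipline is structural: the training function
takes only training data, and a test poisons a copy of the validation
table and asserts the trained model is unchanged.

## Image quality

Per scan: resolution metrics from the grid geometry, repetition/echo
time passed through from metadata, foreground statistics (mean, range,
SNR = foreground mean / background SD) over an Otsu-thresholded
foreground, and the entropy focus criterion — Shannon entropy of the
normalized voxel magnitudes divided by log(voxel count), hence in
[0, 1], 0 for a single-point signal, 1 for a uniform image, invariant
to global scaling. Cohorts are compared per metric with the
Kruskal–Wallis rank test; because that tests location rather than
spread, a second mode applies the same test to absolute deviations from
each cohort's median (a rank-based dispersion comparison), and the
pipeline reports both readings. Constant metrics are flagged with the
p-value undefined.

## Orchestration and reproducibility

`run_end_to_end` attempts, per endpoint (methylation, PFS₂, OS), 2
normalizations × 2 VOIs = 4 branches; each branch ends in `model`,
`no_model` or `error` without affecting siblings. All randomness
derives from one seed via SHA-256 expansion per stage
(`derive_seed(seed, label)`, always below 2³¹), so a rerun of the same
config — or of the config embedded in a run's manifest — reproduces
feature tables and coefficients byte-for-byte. The CLI (`gliorad`) maps
one subcommand to each stage and exits nonzero only when a requested
branch errored; a branch that finds no model is a valid outcome.

## Problem sizes in the checked experiments

The test suite and acceptance script run, as the package's own choice
of problem sizes: the texture oracle suite on 200 random ≤5³ volumes;
exhaustive rim checks on ≤40³ grids; Horn calibration on 200×40
matrices (two planted factors at loading 0.65, and pure noise at
60×40) over 200 seeds with 200 parallel-analysis simulations each;
1000 null simulations of the median-split log-rank test at n = 100;
and 200 seeds of the end-to-end 69/33 recovery experiment with 200
parallel-analysis simulations per fit. Monte-Carlo cohort checks use
n = 2000.

## Known limitations

* Only axis-aligned lattices; no DICOM ingestion, registration or
  bias-field correction.
* The phantom has no anatomical realism (see above); conclusions about
  real-data robustness require real data.
* The 137-texture-name list is a reconstruction from the standardized
  families; counts and all literature-named features are guaranteed,
  individual untested descriptors beyond those carry the usual risk of
  convention mismatch with other extractors.
* The concordance confidence interval is a large-sample approximation;
  at very small n it is reported but approximate.
* `dependence_count_percentage` is identically 1 whenever every in-mask
  voxel is tallied; it is kept for completeness of the family.
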