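# Methods

## The model

Within one brain region (or one phantom sample series), each quantitative
MRI parameter q ∈ {R1, MTsat, MD, R2} is modeled as an affine function of
the macromolecular tissue volume fraction:

    q = a · MTV + b

The slope *a* — the MTV derivative — is the region's relaxivity with
respect to its own non-water fraction. The vector of slopes across
parameters is the region's MDM signature. The model is a first-order
approximation; it is accurate over the physiological MTV range
(~0.05–0.40) and is fitted only there.

An alternative regressor, the inverse water content 1/WC = 1/(1 − MTV),
is supported (`regressor_mode="INV_WC"`). Over the physiological range
1/WC is nearly linear in MTV, so slope *rankings* across regions are
essentially preserved between the two choices; the MTV form is the
default because it extends naturally to all parameters.

## Binned fitting

Voxelwise regression would weight the fit by wherever voxels happen to be
dense along MTV. Instead, a region's voxels are pooled into `n_bins = 36`
equal-width bins on [`lo`, `hi`] = [0.05, 0.40]; bins are half-open
[edge_i, edge_{i+1}) with the final bin closed at `hi`. Voxels with MTV
outside the range are ignored entirely — they populate no bin and do not
count toward the filter denominator. Bins holding fewer than
`min_bin_frac = 4%` of the region's in-range, NaN-free voxels are removed
(on the reading that the denominator is the population actually eligible
for binning; for typical brain ROIs, where nearly all voxels fall in
range, the distinction is immaterial). The fit is unweighted ordinary
least squares of the per-bin median q on the per-bin median regressor;
each bin then counts equally regardless of its voxel load, which makes
the fitted slope invariant to duplicating voxels within bins. Per-bin
dispersion is the unscaled median absolute deviation (no 1.4826
consistency factor) — it is descriptive, not an SD estimate.

Guard rails, all configurable:

- `min_bins_for_fit = 5`: a 2-point line is formally fittable but
  meaningless; fits with fewer surviving bins raise `InsufficientBins`.
  No constraint is placed on bin contiguity or MTV span.
- Per-parameter minimum ROI voxel counts before any fit: 500 (MTsat, R1),
  150 (MD), 50 (R2) — proportional to each map's native resolution.
  Parameters failing a rule are excluded from the signature with a
  machine-readable reason, never silently.
- R² is adjusted for the number of bins: R²_adj = 1 − (1−R²)(n−1)/(n−2).
  A flat response (zero variance in q) reports slope 0 and R² = 0.

Phantom series use the same fit operation on a different profile: the
per-concentration sample medians stand in for bin medians.

## ROI extraction

Maps and labels must share the grid exactly (identical shape; affines
equal within 1e-4) — no resampling is ever performed. Region cores are
extracted by morphological erosion with the 6-connectivity (face
neighbor) structuring element, default depth 1, to strip the
partial-volume shell; depth and connectivity are parameters because only
"remove the outer shell" semantics are fixed, not a specific element. A
voxel that is NaN in *any* requested map is dropped from *all* parameter
vectors, so every fitted dimension sees the same voxel pool and the
signature's dimensions stay comparable. Bilateral structures are pooled
by concatenating hemisphere voxel pools before any statistic.

## Closed forms

- MTsat (percent units, per-voxel):
  `MTsat = M0·B1·α·(R1·TR)/S_MT − (B1·α)²/2 − R1·TR`, with α in radians
  internally (the CLI accepts degrees, since acquisition tables list
  degrees). Values below the physical floor −R1·TR are flagged, not
  clamped.
- R2* correction of MTV: `MTV_C = 1 − (1 − MTV)·exp(TE·R2*)`. Identity at
  R2* = 0, strictly decreasing in TE·R2*; negative outputs (large TE·R2*)
  are returned with a warning, never clamped.
- Desiccation: the printed convention `(W_wet − W_dry)/W_wet` is the
  *water* mass fraction, although MTV elsewhere denotes the non-water
  fraction; both conventions are implemented (`AS_PRINTED`, default, and
  `NON_WATER = W_dry/W_wet`), they sum to one, and callers should pick
  deliberately.

## Mixtures

Forward model: mixture slope (and intercept) per parameter is the
fraction-weighted sum over components — the fast-exchange additivity of
relaxation contributions. Inversion solves A·f = m, columns of A being
component slope vectors, by least squares. By default unmixing uses
slopes only (the signature proper); intercept rows can be stacked in.
Three constraint modes:

- `NONE`: plain QR least squares (the classical solver for this system);
  underdetermined systems return the minimum-norm solution with a loud
  warning.
- `SUM_TO_ONE`: equality-constrained via the KKT system.
- `NONNEG_SUM_TO_ONE` (default — compositions are fractions): exact
  simplex-constrained solution by enumerating supports (KKT solve per
  support, feasible candidates compete on residual). Exact and exactly on
  the simplex for component counts ≤ 12; an SLSQP fallback covers larger
  libraries.

A rank-deficient A (collinear component signatures) raises
`CollinearLibrary` with the condition number: no fractions are invented
for an ill-posed inversion.

## Signature analysis

MDM dimensions carry heterogeneous units, so every cross-region analysis
z-scores each column (sample SD, ddof = 1) across regions first. PCA is
the eigendecomposition of the covariance of the z-scored columns
(correlation-mode PCA); no additional row centering. Signs are fixed
deterministically: each loading vector is oriented so its
largest-magnitude entry is positive, with magnitude ties (within 1e-9
relative) resolved to the lowest index — stable under last-ulp
eigensolver differences. Per-cell dispersions (MAD across subjects) are
projected onto the PC basis by applying the same per-column scale factors
(no re-centering: dispersions are spreads, not locations) and multiplying
through the loadings.

Molecular features are predicted from the dR1/dMTV and dMTsat/dMTV
columns by OLS with intercept, evaluated under leave-one-out
cross-validation; the reported R² compares LOO predictions to observed
values and is adjusted for the two predictors. Plain OLS inside each fold
was chosen over regularized variants: with ~7 regions and 2 predictors
there is little to tune and the unregularized fit keeps the weights
interpretable. Covariate correlations use simple regression with the
F-test p-value; FDR families are always declared explicitly (e.g. 57
comparisons), with unseen family members entering the step-up at p = 1 —
the family is never inferred silently.

## Aging statistics

Group comparison is the equal-variance independent-sample t-test,
two-sided (Welch by flag; with group sizes 23/18 and similar spreads the
choice is immaterial, and the plain test is the stated convention).
Benjamini–Hochberg correction is applied over the family of all (region,
marker) cells tested in one call. Cohen's d uses the pooled SD with
(n−1) weights; its sampling SD uses the standard asymptotic formula
√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))). Effect profiles report d per (region,
marker) with old − young orientation (positive d = increases with age),
the dominant marker per region by |d|, and a flag for regions whose
largest effect is below the small-effect floor d = 0.2. Significance
stars (\*, \*\*, \*\*\*) are rendered on FDR-adjusted values. Where MTV or the
MTsat derivative should be corrected for R2* effects, the correction is
applied upstream by recomputing from R2*-corrected MTV maps
(`correct_mtv_r2star`) rather than adjusting the statistic itself.

Note that BH adjusted values are not idempotent under re-adjustment (a
second pass can only raise them); the implemented guarantees are the
exact step-up values and q ≥ p.

## Synthetic generators

The generators emulate the statistical structure the estimators consume,
not MR physics:

- **Phantoms**: each component has true (slope, intercept) per parameter;
  samples at 8 concentrations spanning 0.05–0.40, 3 replicates, additive
  Gaussian noise per parameter (defaults ~1–3% of typical dynamic range).
  Mixtures are generated through the same forward model the inversion
  assumes.
- **Brains**: regions are disjoint blocks in a 3-D grid; voxel MTV is
  drawn from a per-region normal truncated to [0.05, 0.40] (the
  truncation keeps the 4% bin filter meaningful); qMRI values are the
  region's line plus i.i.d. Gaussian voxel noise. Default magnitudes are
  physiological (e.g. R1 ≈ 0.3–1.5 s⁻¹ across the MTV range). No spatial
  noise correlation, no anatomy, no partial-volume mixing at borders —
  consequently, passing tests demonstrate estimator correctness under
  the model's own assumptions, not robustness to registration error,
  B1 bias, or segmentation leakage.
- **Cohorts**: 23 young and 18 old subjects by default (the reference
  study design; one figure caption in the source literature says 17
  younger subjects, but the cohort description says 23, which is used
  here). Marker values are Gaussian around region baselines; planted
  effects shift the old-group mean by d × between-subject SD. The default
  output is the tidy marker table the statistics consume; an optional
  mode simulates per-subject map volumes and runs the full signature
  pipeline per subject, exercising the entire chain at reduced sizes.

All generators are pure functions of (spec, seed).

## Numerical choices and degenerate inputs

- Bin edge ties go to the upper bin (half-open intervals), final bin
  closed; `x == hi` lands in the last bin.
- Median of an even count is the midpoint average (numpy convention);
  medians commute with the affine voxel model, which is what makes the
  noiseless recovery exact rather than approximate.
- Zero regressor variance across bins → `DegenerateRegressor`; zero
  pooled SD → `DegenerateVariance`; empty eroded ROI → `EmptyRegion`;
  each is an explicit signal for the caller, never a silent skip.
- The acceptance script sizes its simulations (2000-voxel regions,
  2000 t-test replicates, 100 mixture seeds, 20-region cohorts) to give
  Monte-Carlo error comfortably below the properties being checked while
  completing in seconds.

## Known limitations

- The linear MDM model is first-order by design; curvature in q(MTV) is
  out of scope (no quadratic option).
- Registration, resampling, segmentation, and bias-field handling are
  upstream concerns; this package requires exact grid agreement.
- The synthetic cohort plants effects directly on markers (or slopes);
  it does not model age-related changes in MTV *distributions* within
  regions.
- Unmixing assumes the library spans the mixture; components missing
  from the library alias into the returned fractions.
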