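# Methods

## The analytical problem

Traditional morphometric datasets — linear distances and angles measured on
crania, bony labyrinths, brain endocasts — confound size with shape. When
the scientific question is whether small-bodied (e.g. island-dwarfed)
populations differ in shape beyond what their size predicts, three views of
the same matrix are informative: the raw *form*, a size-standardized
*shape*, and an *allometry-free* shape with the size-predictable component
regressed out. This package implements that triplet, the PCA morphospaces
over each, and a single multivariate allometry test, as composable
scikit-learn-style estimators.

## Size proxy

No external body-size measure is assumed, and no single variable should be
privileged as a size proxy, so size is the per-specimen geometric mean

    GM_i = (prod_j x_ij)^(1/n)

over the n *linear* variables, computed in log space
(exp of the mean log) to avoid overflow. Angles are excluded from the GM
for every structure: they are dimensionless and size-free by construction.
For the cranial catalog this means all nine measurements enter the GM; for
the endocast catalog, the nine linear ones. (Which variables feed the GM is
recorded per catalog; a user catalog can change the split.)

## Treatments

- **form** — the raw matrix, untouched. Its PCA is dominated by size
  whenever size variation is large, which is itself a diagnostic (a PC1 on
  which all loadings share a sign is a size axis).
- **log_shape_ratio** — Mosimann shape variables ln(x_ij / GM_i) for linear
  variables; angles pass through raw. Natural logs throughout; the
  downstream R² is invariant to the log base, so the choice is
  consequence-free. Algebraic consequence used as a test oracle: the linear
  components of every row sum to zero exactly
  (Σ_j ln(x_j/GM) = ln Π x_j − n·ln GM = 0), and the ratios are invariant
  to uniform scaling of a specimen.
- **allometry_free** — per-variable OLS residuals (intercept + slope) of
  the *raw* variable on the *raw* GM across specimens. Per-response OLS
  equals the residual matrix of the multivariate linear model of all
  variables on GM, so no multivariate test machinery is needed just to
  extract residuals. Residuals are computed on raw scales (not log-log)
  to match the convention of regressing the measured variables directly on
  the size proxy. Every residual column is zero-mean and has zero sample
  covariance with GM — a second exact oracle. By default angles are
  residualized along with the linear variables; `include_angles=False`
  instead centers them only. With fewer than 3 specimens a line fit leaves
  residuals identically zero, so that case is rejected.

Degenerate inputs: missing cells must be removed (listwise) before any
treatment; non-positive lengths are coerced to missing at table
construction with a warning, so a single impossible cell costs one
specimen, not the run; zero variance in GM makes residualization (and the
allometry test) undefined and raises.

## PCA morphospaces

Covariance-matrix PCA: columns centered, *not* scaled to unit variance,
because within a treatment the variables are commensurate (all mm, or all
dimensionless). Correlation-matrix PCA is available behind `scale=True`
but is never the default. Components come from the SVD of the centered
matrix; eigenvalues use the n−1 divisor; all components are retained
(PC1–PC2 selection is presentation only). The eigendecomposition of the
sample covariance matrix is the independent oracle the SVD route is tested
against.

Eigenvector signs are arbitrary, so axes are oriented deterministically:
on each component the loading of largest absolute value is made positive,
ties broken by lowest variable index, scores flipped consistently. This
pins plotted loading directions and makes outputs bit-reproducible across
runs, platforms and LAPACK builds. Orientation changes no variance
quantity and no R².

## Allometry test

With many variables, allometry is evaluated jointly rather than by a
myriad of bivariate regressions (the Jolicoeur multivariate-allometry
tradition): the PC1 scores of the *log-shape-ratio* PCA — the dominant
axis of shape — are regressed by OLS on ln GM. The single-covariate ANOVA
is identical to the slope F test with (1, n−2) df, so it is implemented as
such; r² equals the squared Pearson correlation and F = r²/(1−r²)·(n−2).
α defaults to 0.05. R² is always computed and carried with the
significance flag, so the convention of quoting R² only when the slope is
significant remains available as a view without information loss. Applying
the test to PC1 of another treatment is allowed but labelled
non-canonical. Sign of PC1 and base of the logarithm provably do not
affect R², F or p; both invariances are tested.

## Synthetic data generator

The generator draws from the standard allometric growth model

    ln x_ij = alpha_j + beta_j ln s_i + offset_gj + eps_ij,
    eps_ij ~ N(0, sigma_j^2),   ln s_i ~ N(mu_g, tau_g) per group g,

with angles drawn size-independently from a normal truncated to (0, 360)
by redraw. Latent size is log-normal so all measurements are positive by
construction. beta_j = 1 for all j is isometry; then the log shape ratios
are constant in s (ln(x_j/GM) = alpha_j − mean(alpha) plus noise), so shape
carries no size signal. With sigma = 0 and spread in beta, the
log-shape-ratio matrix is exactly rank one along (beta_j − mean(beta))·ln s,
so PC1 carries 100% of the variance and the allometry R² is exactly 1 —
both used as frozen expectations in the tests.

Scenario defaults (chosen once, as what a museum-collection craniometric
study of this kind realistically looks like):

- `island_dwarf`: island group n=30 with ln s ~ N(5.1, 0.10) vs
  comparative n=140 with N(5.5, 0.15); rostrum-style exponents, lengths
  beta 1.02–1.15, widths 0.88–0.95 (so small specimens show relatively
  wider, shorter muzzles); sigma = 0.02 per variable.
- `two_archipelago`: two island groups (n=9, n=20) of distinct mean size
  plus the comparative sample (n=138).
- `isometric_null`: beta = 1 everywhere, sigma = 0.05, n = 90 total.
- Intercepts anchor typical adult-horse cranial proportions (basilar
  length ≈ 2.2 × size, premaxillary width ≈ 0.32 × size) at a reference
  ln s = 5.3 regardless of the exponent.

A generator design constraint worth knowing: under the isometric null the
per-variable noise SDs are equal. The specimen-mean log noise enters
ln GM while the shape ratios contain the deviations from that mean; for
i.i.d. equal-variance normals the mean and deviations are independent, so
PC1 scores are exactly independent of ln GM and the slope test holds its
nominal level (verified: rejection rate over 250 seeded replicates within
the 99% binomial band [0.02, 0.09] around 0.05). With *unequal* sigmas
that independence fails and the test would be anti-conservative — a
property of the statistic, not of the generator.

What the generator does **not** emulate: measurement error correlated
across variables, group-specific allometric slopes (only offsets),
ontogenetic trajectories (maturity labels are metadata, not modelled
growth), phylogenetic/breed covariance structure, and missingness
mechanisms other than the ones tests inject by hand. Passing tests
therefore certify the algebra and the statistical calibration of the
pipeline, not the biological fidelity of any particular dataset.

## Sampling rules

Only confirmed-mature specimens enter an analysis; `maturity == "unknown"`
is dropped by default (overridable), since analyses of ontogenetically
heterogeneous samples would conflate growth with static allometry. Missing
data are handled by listwise deletion per structure, no imputation; an
all-incomplete table is a hard error. Merging tables requires identical
catalogs and disjoint specimen ids; source labels travel with rows.

## Reproduction of published values

`study_report()` holds a reproduction run against the published reference
values for the horse insular-dwarfism dataset (172 complete cranial
specimens; form PCA 90.02%/4.13%; log-shape-ratio PC1 39.46%;
allometry-free PC1 33.29%; cranial allometry R² 33.25%; bony-labyrinth R²
72.67%; endocast R² 84.54%). The measurement tables themselves are
distributed with the original publication, not with this package, so the
function flags a structure whose CSV is absent instead of failing; when
the files are present each computed number is compared at ±0.05 percentage
points. One catalog note: the source tabulates four endocast angles (IHA,
HPA, CSA, OFA) and totals 13 endocast measurements, while its running text
mentions three angles; the packaged catalog follows the tabulated 13
(9 linear + 4 angle) and this discrepancy is surfaced here rather than
silently resolved.

## Problem sizes

Default test and acceptance runs use the scenario sample sizes above
(tables of 40–181 specimens, 3–13 variables) and 250 replicates for the
null-calibration estimate; these sizes make every quantity stable to well
within the asserted tolerances while keeping a full run fast.

## Known limitations

- The allometry test conditions on PC1 being the size-related axis; if
  allometry is weak and PC1 reflects some other contrast, the test answers
  a different question. Inspect the morphospace and loadings first.
- Residualization on raw GM assumes approximately linear
  measurement–size relations over the observed range; strongly curved
  allometries leave structure in the "allometry-free" residuals.
- No geometric-morphometric (landmark/Procrustes) mode; inputs are
  interlandmark distances and angles as numbers.
- Angles are treated as plain numbers on (0, 360); no circular statistics.
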