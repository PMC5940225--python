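# Methods

This note documents the models implemented in `reefbudget`, the choices made
where the procedure was genuinely open, and what the synthetic-data tests do
and do not establish about field data.

## Budget model

Budgets are solved per transect and averaged to the site. The components,
all in kg CaCO₃ m⁻² y⁻¹:

- **Gross calcification** `Cal = r·(Σⱼ mⱼ·(xⱼ/100)·dⱼ·gⱼ·10 + ca)`.
  Rugosity `r` is defined as the *ratio* of contour tape length to
  horizontal chord length. Field protocols often record the raw length
  difference, but the budget multiplies cover by `r` as an area-correction
  factor, which requires a dimensionless index ≥ 1; ratios a hair below 1
  (measurement noise) are clamped to 1, anything lower is rejected.
- **Cover conventions.** Coral and coralline-algae covers (`x`, `pca`) are
  percentages (0–100); the formulas divide by 100 or carry the 0.018·10
  factor accordingly. Macroborer cover `plamc` is a *proportion* (0–1),
  because the erosion term is `plamc·mec` with `mec` = 10 kg m⁻² y⁻¹ at
  full cover; passing a percent raises an error that names the likely
  confusion. At realistic borer covers of ~0.5% this yields the
  ~0.04–0.06 kg m⁻² y⁻¹ erosion rates typical of Pacific reefs.
- **Parrotfish erosion** chains three allometries in fork length `L` (cm):
  bite volume `exp(1.32 + 0.06·L)/1000` cm³, scar proportion
  `logistic(−2.46 + 0.089·L)`, and bite rate
  `60·((4.31 + brc − 0.36) − 0.045·reeftime·L)` bites day⁻¹ with
  `reeftime` = 9 h. The bite-rate line goes negative for large fish with
  small species constants `brc`; we clamp at zero — a fish cannot erode
  negatively — because the regression is being used outside its fitted
  range. The units narrative of the bite-rate expression is internally odd
  (a minutes-to-hours factor multiplying a term that already contains
  hours); we implement the formula exactly as published and expose
  `reeftime` in the constants object.
- **Area normalization.** The published component equations carry no
  explicit per-area divisor. To deliver kg m⁻² y⁻¹ we divide summed fish
  erosion by the surveyed video area (transects × 120 m²) and echinoid
  erosion by the belt area (transects × 6 m²).
- **Substrate density `D`** for fish erosion is the cover-weighted mean of
  the trait densities of live coral at the site; a coral-free site falls
  back to a configurable 1.5 g cm⁻³.
- **Sediment** contributes +0.4 kg m⁻² y⁻¹ by default; the sign switch for
  high-sedimentation settings is exposed as `sediment_sign` since the
  switching covariate is not defined quantitatively in the source model.
- **Constants** live in one frozen dataclass (`BudgetConstants`) validated
  at construction (including the 365 × 0.001 = 0.365 unit identity);
  overrides go through `replace()` or the pipeline config and are logged.

**Vertical growth.** `v = Cp + Cp·(Cp·α)` converts production to potential
vertical accretion. α is calibrated in closed form (the model is linear in
α) from published conversion pairs; the single pair (9.7 kg ↔ 7.9 mm) gives
α = −0.01913 (kg m⁻² y⁻¹)⁻¹. For α < 0 the parabola peaks at
Cp = −1/(2α) ≈ 26 kg m⁻² y⁻¹; beyond the apex the curve would decrease,
which is physically meaningless, so values are clamped at the apex with a
warning. The conversion is monotone on the calibrated domain [0, 25].

## Spatial interpolation

Coordinates are projected to a local tangent plane (transverse
equirectangular on the WGS84 ellipsoid, centred on the site cloud) before
any distance is computed; at island scale (< 100 km) the metric distortion
relative to a conformal projection is below 0.1%, far inside kriging noise.

The empirical semivariogram is the method-of-moments estimator on distance
bins (optionally bearing-sectored at 0/45/90/135° ± 22.5°); empty bins are
reported with zero counts rather than interpolated. Model fitting is
weighted least squares over (nugget, partial sill, range) with weights
`pairs/h²`; `range_m` is the effective range for all three families
(factor-3 scaling for exponential/Gaussian). A Gaussian profile-likelihood
fitter (`fit_variogram_ml`) is also provided: binned WLS is statistically
inefficient for the nugget unless the design contains near-coincident
pairs, and at n ≈ 200 the ML fit is markedly more accurate. Simulation
recovery studies in the tests therefore use nested sampling designs
(stations plus 5 m and 500 m satellites) — the standard remedy for nugget
estimation — and aggregate the median estimate over replicate realizations,
because a single realization of a correlated field carries irreducible
ergodic fluctuation in its realized variogram.

Ordinary kriging solves the unit-sum-constrained system per grid node with
one shared factorization; predictions are exact at data locations, weights
sum to 1 to 1e−10, and variances are non-negative. Duplicate coordinates
are averaged on ingest. The anisotropy diagnostic refits only the range per
bearing (nugget and sill held at the omnidirectional fit — free directional
fits on a quarter of the pairs are too noisy) and recommends a geometric
correction only when directional ranges differ by more than 50%; even so,
at survey-sized n the diagnostic triggers on a few percent of genuinely
isotropic fields, so a recommended correction should be read as a prompt
for inspection, not proof of anisotropy.

## Threshold model

Net production per transect is modelled as
`G = β₀ + f(LCC) + Habitatₕ + a_country + ε` with a cubic O'Sullivan spline
`f` (5 interior knots at cover quantiles, boundary knots at 0 and 100% so
curves evaluate on the full grid). The spline is built as in the
Wand–Ormerod mixed-model construction: B-spline basis, exact
integrated-squared-second-derivative penalty (2-point Gauss–Legendre per
inter-knot interval — exact because the second derivatives are piecewise
linear), spectral transform into 2 fixed (linear) directions plus
`n_knots + 2` penalized columns acting as iid random effects.

Priors are deliberately diffuse: Normal(0, 100) on fixed effects,
half-Normal(10) on the residual, spline and country standard deviations.
The sampler is a blocked Gibbs scheme — all coefficients drawn jointly from
their conditional multivariate normal, the three standard deviations
updated by slice sampling on the log scale — with defaults of 4 chains ×
2000 draws after 1000 warmup. Convergence is summarized by max split-R̂
(accepted at ≤ 1.05) and min ESS via ArviZ; `strict=True` raises on
non-convergence.

**Inverse problem.** For each habitat the expected curve is evaluated on a
0–100% grid (step 0.1) per posterior draw and solved for the first crossing
from negative to non-negative, interpolated linearly within the bracketing
step; a curve already non-negative at 0% has threshold 0, a draw that never
crosses has none, and the result is flagged when more than half the draws
have none or when draws show multiple crossings.

**Identifiability and the country effect.** Habitats are nested within
country (every 5-level habitat occurs in exactly one country), so the
country contrast is confounded with the habitat effects: a curve evaluated
at "country = 0" is not identified, and under diffuse priors its level
wanders enough to destroy the threshold CIs. Thresholds are therefore
computed, by default, on the curve evaluated at the habitat's own country
intercept — the identified quantity — with `typical` (recentered zero-mean
deviation) and explicit-country options available. Because the full
expected curve is used, the habitat contrast coding cannot move the
thresholds (asserted by test). Transects are treated as replicates within
site within country; no site-level random effect is included, matching the
printed model structure.

## Synthetic data

The generator reproduces the study design: Palau with 4+4 outer (west/east),
10 patch and 6 inner sites, Yap with 6+4 outer and 14 inner (no patch
stratum), six transects per site, parrotfish and urchin observations per
transect. Within that fixed structure the quantitative settings are this
package's own choices, tuned once to be ecologically plausible and then
frozen:

- per-habitat Beta-distributed coral/CCA/macroborer covers (outer-west
  richest ≈ 32–35% coral, inner poorest ≈ 20–25%, borers ≈ 0.5%);
- a log-normal Gaussian-random-field multiplier (sd 0.4, range 12 km) on
  coral-cover means plus habitat-structured site placement (inner nearshore,
  patch mid-lagoon, outer on the rim, west/east by azimuth), which is what
  gives net production its mappable spatial gradient;
- truncated log-normal fish lengths (5–60 cm) with an optional rare
  60–120 cm bumphead class on Yap's western outer reefs, reproducing
  localized heavy fish erosion; urchin densities an order of magnitude
  higher on Yap;
- trait table (m, d, g, brc) of literature-typical values for the named
  growth forms — explicitly non-canonical stand-ins for unpublished
  laboratory tables.

Every realization carries a `GroundTruth` computed from the raw records by
an independent closed-form code path (plain arithmetic, no budget-engine
calls), so engine-vs-truth comparisons at 1e−9 are a genuine dual-route
check. With these settings almost no synthetic site is in net erosion, so
the survey-world threshold estimates sit near 0% cover; the dedicated
threshold-data generator is the testbed for the inverse problem. It draws
cover uniform on (0, 60)%, builds `G = f(LCC) − f(LCC*ₕ) + N(0, σ)` with a
*common* monotone smooth `f` (slope 0.25 kg per cover point plus a
one-unit sinusoidal perturbation of 60-point period), so the true crossing
of every habitat curve is exactly `LCC*ₕ` and the truth is additive in
habitat — matching the model structure by construction. Recovery tests at
the design size (48 sites × 6 transects = 288 rows, σ = 1) recover the
five habitat thresholds with |bias| ≤ ~0.5 cover points and near-nominal
CI coverage.

What passing these tests does **not** show: that the allometric constants,
trait values or cover distributions describe any particular reef; that the
threshold model is robust to non-additive habitat × cover interactions
(the generator is additive by design); or that kriged maps extrapolate
beyond the surveyed envelope. Field conclusions require the field data.

## Problem sizes and numerics

Test and demo runs use 2 chains × 800–1000 draws (the blocked Gibbs sampler
converges within a few hundred iterations on these designs; R̂ ≤ 1.03
throughout), 100×100 kriging grids, and n = 200–500 spatial samples; the
library defaults remain 4 × 2000. Degenerate inputs are handled explicitly:
zero-length horizontal tapes, empty selections (cover 0), coral-free sites
(density fallback), all-zero production (α unidentifiable → error), singular
kriging systems (de-duplication hint), tiny residual variance in the Gibbs
conditional (relative-ridge Cholesky retry confined to the unidentified
intercept/country direction).
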