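# Methods

## Scope and model overview

`xylosafe` implements the quantitative chain of a branch xylem-safety
field campaign on European beech: per-branch vulnerability curves from
flow-centrifuge conductivity series, site water-availability metrics,
stand/branch covariates, and mixed-effects trait models with variance
decomposition, plus a synthetic-data generator that emulates the
30-site × 10-tree study design so the whole chain is testable without
field data.

## Vulnerability curves

The curve model is the sigmoidal conductivity-loss model fitted
directly on the conductivity scale (not on percent loss):

    K(Ψ) = Kmax · (1 − 1/(1 + exp(s(Ψ − P50))))

with Ψ the imposed xylem pressure (MPa, negative), Kmax the conductivity
of the fully functional segment, P50 the pressure at 50 % loss and s the
logit-scale slope (MPa⁻¹). Loss quantiles invert in closed form,
Ψ_q = P50 + ln((1−q)/q)/s, giving P12 and P88; logistic symmetry implies
P12 + P88 = 2·P50 for every fit, which the tests enforce.

Fitting is nonlinear least squares (scipy trust-region reflective,
analytic Jacobian, bounds Kmax > 0, P50 < 0, s > 0). Starting values
are deterministic: Kmax₀ = max observed K; P50₀ from linear
interpolation of the first crossing of Kmax₀/2; s₀ from a logit-linear
regression through interior points (clamped to [0.2, 20]). On
non-convergence the start is jittered up to five times with a seeded
generator before a fit error carrying per-attempt diagnostics is
raised. A series with no observation below half the observed maximum
cannot pin down P50 and is flagged `identifiable=False` rather than
rejected. Parameter SEs come from the asymptotic covariance
RSS/(n−3)·(JᵀJ)⁻¹.

Uncertainty bands use a case-resampling (pairs) bootstrap with
percentile 95 % intervals (default B = 1000; replicates warm-started at
the point estimate; non-converging replicates dropped and counted;
B < 100 triggers a warning). Pairs resampling was chosen over residual
resampling because the pressure grid is fixed by the instrument
protocol while the error structure (heteroscedasticity, zero
truncation) is unknown. A known cost of the percentile method at the
typical series length (≈15–18 points) is mild undercoverage of the
nominal 95 % level; the acceptance suite measures this directly.

Flushed versus non-flushed samples are compared with a tie-corrected
Kruskal–Wallis H test (χ², 1 df for two groups).

## Site water availability

Climatic water balance is monthly precipitation minus potential
evapotranspiration; the site summary reports MAP (mean annual
precipitation sum), MAT (mean of annual means), MSP (April–June
precipitation), MGSP (growing-season precipitation, default April to
September — the growing season is configurable since no single
definition is canonical) and mean monthly CWB. Missing months are a
hard error listing the gaps.

Soil water retention uses the van Genuchten closed form
θ(h) = θr + (θs−θr)[1+(αh)ⁿ]^(−m), m = 1−1/n, with suction h in cm of
water. pF is computed in hPa (pF = log₁₀ suction/hPa), with the
conversion 1 cm H₂O = 0.980665 hPa applied explicitly; the conventional
anchors are field capacity at −60 hPa (pF 1.8) and permanent wilting
point at −1.5 MPa (pF 4.2).

Retention parameters come from a texture-class lookup: the USDA texture
triangle classifies each layer and the Carsel & Parrish (1988) class
means supply (θr, θs, α, n). A full neural-network pedotransfer
(Rosetta) is deliberately not reproduced — parameters computed
externally can be passed through the `override` argument, and the
package's contract is the retention → AWC arithmetic. Bulk density is
accepted for schema completeness but does not modulate the class means.

Profile AWC sums [θ(pF 1.8) − θ(pF 4.2)] × thickness over layers
(0–10, 10–30, 30–60 cm natively) and extends the deepest layer's
parameters to the 100 cm standard depth (homogeneous-subsoil
assumption). No stone correction is applied by default; an optional
flag multiplies each layer by (1 − stone fraction).

## Stand and branch covariates

The Hegyi competition index is CI_i = Σ_j (d_j/d_i)/Dist_ij over the
three nearest neighbours by Euclidean stand-map distance, ties broken
by tree id. The index uses neighbour *diameters*: where a verbal
protocol mentions neighbour height, the defining equation uses d_j, and
the equation is authoritative here. Branch xylem area uses the linear
allometry A_xylem = −3.715 + 0.770·A_cross (mm²; inputs below the line's
root ≈ 4.825 mm² are rejected), specific conductivity is
Ks = Kh,max/A_xylem with one central mm²→m² conversion, and branch age
is the mean of basipetal and acropetal ring counts (acropetal counts
exceeding basipetal ones are rejected — age cannot increase toward the
tip).

## Trait models

One REML random-intercept model per response (P12, P50, P88, log slope,
Ks): y = β₀ + Σβk·z(xk) + b_site + ε. Branch age enters as its natural
log; the slope response is log transformed; all predictors are centred
and SD-scaled *within the modelled dataset*, so coefficients are per-SD
effects and the intercept equals the response mean. Rows with missing
modelled values are dropped listwise and counted. No multiple-testing
correction is applied across the five models; this is stated in the
pipeline manifest.

Estimation: a statsmodels `MixedLM` REML fit seeds the variance ratio
λ = σ_b²/σ_e²; the package then maximizes its own closed-form profiled
REML criterion (grouped Woodbury identities, bounded scalar search in
log λ to xatol 1e−12) so the optimum is located to machine precision
and the σ_b² = 0 boundary is handled explicitly (returned as a flagged
singular fit, not an exception). Tests verify the optimum against an
independent dense-covariance REML implementation.

Inference is Wald t with Satterthwaite df:
df_k = 2·Var(β̂_k)²/Var̂(Var(β̂_k)), where the denominator combines the
finite-difference gradient of Var(β̂_k) with respect to (σ_b², σ_e²)
with the inverse observed REML information (numerical Hessian). When
the information matrix is ill-conditioned (e.g. singular fits) the df
fall back to the residual df n − p and the result is flagged. In the
balanced one-way case this machinery reproduces the closed-form
between-group df (g − 1) exactly, which the tests check.

Variance decomposition follows Nakagawa & Schielzeth: with
σ_f² = var(Xβ̂) (sample variance of the fixed-effect predictor),
marginal R² = σ_f²/(σ_f²+σ_b²+σ_e²), conditional R² adds σ_b², and the
three shares (fixed, site, residual) sum to one. The collinearity
screen reports pairwise Pearson correlations among predictors and flags
|r| ≥ 0.7.

## Synthetic data generator

The generator's defaults are the study conditions, not free dials:

* design 30 sites × 10 trees, one branch per tree;
* P50 generating model: intercept −3.381 MPa, per-SD effects
  CWB 0.004, AWC 0.086, height 0.000, log branch age 0.088, CI −0.011,
  site SD 0.199, residual SD 0.279 MPa;
* log slope: mean 1.049, site SD 0.118, residual SD 0.258;
  Ks: mean 1.536, site SD 0.175, residual SD 0.535 kg m⁻¹ MPa⁻¹ s⁻¹
  (truncated above 0.05 by redrawing the residual);
* site covariate ranges: CWB −10.82…25.56 mm month⁻¹, AWC
  43.4…301.0 mm, MAP 522…886 mm yr⁻¹, MAT 9.0…10.0 °C, tree height
  21.1…34.4 m, DBH 35.7…58.2 cm;
* branch age: shifted lognormal (1 + LogN, σ = 0.55) calibrated to
  mean 6.0 years and rejected outside [1.5, 20.5]; ring counts at the
  two segment ends reproduce the half-integer mean;
* cavitron protocol: start −0.37 MPa, fixed step −0.25 MPa (the
  protocol prescribes only a stepwise descent; the step size is a
  configurable design choice), termination at the first pressure past
  90 % modelled loss, minimum five points; additive Gaussian noise with
  SD = noise_cv·Kmax (default 5 %), truncated at zero. The additive
  truncated model keeps Kmax interpretable and is the simplest noise
  structure consistent with non-negative conductivities.

Monthly climate is built backwards from the site targets: seasonal
shapes with lognormal/Gaussian noise are rescaled so that MAP, MAT and
mean monthly CWB aggregate back to the drawn site values exactly
(a round-trip the tests verify). Soil profiles are three sandy layers
whose textures are rejection-sampled until the profile AWC lands inside
the configured range — so the AWC covariate is genuinely computed from
the soil tables, not asserted. Stands are 7×7 jittered grids at 6 m
spacing (chosen so site-mean Hegyi CI lands in the observed 0.39–0.73
range); the ten targets are interior trees so every target has honest
neighbours. Covariates are drawn independently across sites, which
satisfies the |r| < 0.7 collinearity screen by construction.

All randomness derives from one root seed through named
`SeedSequence` children (climate, soil, stand, branches, traits,
cavitron, extras), so identical configurations produce byte-identical
tables and each stage is individually reproducible.

What the generator does not emulate — and hence what passing tests do
not establish about real data: spatial autocorrelation of climate,
provenance/genetic structure, within-tree curve replication, open-vessel
artefacts, leaf-area allometry, and any real pedotransfer beyond the
class-mean lookup. Parameter-recovery results certify the estimators
under the assumed generating model, not the field inference itself.

## Pipeline

`run_pipeline` chains simulate/load → validate (schema, unit ranges,
referential integrity) → per-branch curve fits → climate/soil summary →
covariates → five trait models, writing CSV outputs and a JSON manifest
with config hash, versions, per-stage row counts, all warnings
(non-identifiable fits, singular fits, dropped bootstrap replicates,
dropped rows) and a SHA-256 checksum per output. A single master seed
fans out to per-stage child seeds. Pressures are stored as negative
MPa throughout; suctions as positive cm; conversions happen only at the
documented module boundaries.

## Problem sizes used in validation

The shipped validation suite uses problem sizes chosen to make
Monte-Carlo error small relative to the effects being checked while
keeping the suite convenient to run: 200 synthetic branches (with
B = 500 bootstrap replicates each) for fit error and interval coverage,
200 replicates of the 30×10 design for mixed-model recovery, and
400–500-site runs for law-of-large-numbers checks. The acceptance
script uses 150 branches with B = 400 and one full 30×10 pipeline run.

## Known limitations

* Percentile pairs-bootstrap intervals mildly undercover at the
  protocol's series lengths; coverage is reported, not hidden.
* The texture-class lookup is a coarse stand-in for sample-specific
  pedotransfer; absolute AWC values are class-quantized.
* Satterthwaite df rely on numerical curvature; near-singular fits fall
  back to residual df (flagged).
* No hierarchical pooling across branches in curve fitting; each branch
  is fitted independently, matching the per-sample subscript of the
  model. Pooled fitting would be a natural extension.
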