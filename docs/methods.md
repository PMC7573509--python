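# Methods

## The model

The package analyses repeated measures of posttraumatic distress with the
cusp catastrophe, the simplest model in which a continuously driven system
shows discontinuous change. The canonical state *y* evolves on the
potential V(y) = ¼y⁴ − ½βy² − αy. Its equilibria are the real roots of
y³ − βy − α = 0; with discriminant D = 4β³ − 27α² the system is bistable
(two stable states separated by an unstable one) iff D > 0. β is the
bifurcation parameter — it decides *whether* two states coexist — and α
the asymmetry parameter — it decides which state dominates. Substantively,
trauma coping self-efficacy (CSE, 1–7) maps inversely onto β (low
self-efficacy creates the split) and perceived loss (0–4) or peritraumatic
dissociation (0–5) maps onto α (pulling survivors toward the high-distress
state).

State jumps follow the **delay convention**: a subject stays in the
current basin until its attractor vanishes, which produces hysteresis
(different up- and down-sweep paths through the bistable band). The
geometry layer solves the cubic in closed form (trigonometric form for
three real roots, Cardano otherwise) with a Newton polish, because
iterative solvers lose accuracy near the bifurcation set. Double roots on
the set are labeled unstable so simulated trajectories never park on a
measure-zero configuration; a basin-boundary start resolves to the upper
basin (measure-zero tie, documented rather than randomized).

## The statistical test

For a wave pair (earlier x₁, later x₂) on complete cases:

- dv = residuals of OLS(x₂ ~ 1 + x₁) — a baseline-adjusted change score
  with mean 0, orthogonal to x₁;
- z = (x₁ − min x₁)/SD(x₁) (sample SD), so min z = 0 and SD z = 1;
- the cusp model is dv ~ 1 + z³ + z² + (z·CSE) + asymmetry covariates,
  all columns z-standardized before fitting so coefficients are
  standardized betas (the reporting convention of the source tables, which
  never state how standardization was done — we standardize dv and every
  predictor, and report no intercept, which is 0 by construction);
- pruning at α-level 0.05: drop z³ if non-significant, then drop
  non-significant asymmetry covariates one at a time (largest p first);
  z² and the bifurcation product are never pruned so the cusp hypothesis
  stays evaluable. Every removal is logged.

Inference is classical OLS (statsmodels): SEs from σ̂²(XᵀX)⁻¹ with
σ̂² = RSS/(n−k), two-sided t tests. AIC/BIC use the full-constant Gaussian
log-likelihood at the MLE variance, with k counting all coefficients plus
the error variance; only differences between models on the same dv matter,
and the printed criteria of the source cannot pin the constant anyway.
ΔAIC/ΔBIC categories use strict thresholds (2/4/10 and 2/6/10).

The linear baseline regresses the same dv on the raw bifurcation variable
and asymmetry covariates. In the pipeline the baseline is restricted to
the covariates that survived pruning in the cusp model, mirroring the
published comparison, whose linear model used exactly the final cusp
model's predictors; an unrestricted baseline is available
(`fit_linear_model(..., match_fit=None)`). Without this restriction the
comparison is biased toward whichever model was allowed to discard noise
covariates.

The support verdict: *no_cusp* if neither z² nor a retained z³ is
significant; *cusp_supported* only if a state term, the bifurcation
product and ≥ 1 asymmetry covariate are all significant; otherwise
*cusp_unsupported*. The sign of the product is reported but not enforced.

## Synthetic data

The generator realizes the process the analysis presumes, so parameter
recovery, test size and power are measurable.

**Covariates.** A latent vulnerability L ~ N(0,1) per subject; each scale
covariate is clip(μ* + σ*(λL + √(1−λ²)ε), lo, hi). The pre-clip (μ*, σ*)
are solved from censored-normal moment equations so the *post*-clip mean
and SD hit the published descriptive targets exactly; loadings λ set the
correlation pattern. Gender is Bernoulli (female share 0.69 / 0.73 by
profile); an exposure count is rounded to integers.

**Dynamics.** Controls are affine in standardized covariates:
βᵢ = b0 + b1·std(cseᵢ), αᵢ = a0 + a1·std(lossᵢ or pdᵢ). The canonical
state follows dy = −(y³ − βᵢy − αᵢ)dt + σ dW by Euler–Maruyama with
dt = 0.01 and time in units of 10 days, so the 30–180-day wave gaps are
many relaxation times long. The wave-1 state is drawn from the diffusion's
stationary density ∝ exp(−2V(y)/σ²) by inverse-CDF on a dense grid (the
canonical member, density ∝ exp(αy + ½βy² − ¼y⁴), is exposed as
`sample_cobb` and checked against quadrature; σ = 0 degenerates to the
deepest well). Observed distress is clip(s·y + o, 0, 4).

**Calibration.** Profile constants were calibrated once against the
published descriptive tables and frozen in `src/cuspshift/profiles/`:

- *study1* (n = 189, waves at 0/30/60 days, loss as asymmetry source):
  b1 = −0.8, a1 = +0.8, σ = 0.4 define the strong-effect condition;
  a0 = 0.8, b0 = 1.2 place roughly a third of subjects in the bistable
  wedge; the observation map (s, o) = (1.9955, −1.6184) reproduces T1
  distress 0.91 (SD 0.75) and r(distress, CSE) = −0.73 at n = 10,000.
- *study2* (n = 148, waves at 0/42/183 days, dissociation as asymmetry
  source): σ = 0.9, a0 = b0 = 1.2, λ_pd = 0.3,
  (s, o) = (2.0869, −0.69), reproducing T1 distress 1.93 (SD 1.08),
  PD 2.43 (SD 1.01), r(distress, PD) ≈ 0.59 and r(distress, CSE) ≈ −0.56.
  The larger diffusion noise reflects the far more heterogeneous sample
  (five fires, time-since SD of 131 vs 10 days); with small σ the
  bistable mean response is a near-step in α and the distress–PD
  correlation saturates near 0.8, which no observation map can undo. The
  price of decoupling is a CSE–PD correlation of about −0.20, weaker than
  the sample's −0.50.

**Missingness.** MCAR cell deletion at the sub-percent per-wave rates of
the two samples, and monotone per-wave attrition at rates (0.18, 0.21) and
(0.446, 0.195) matching the published completer counts (189→155→123,
148→82→66). Wave 1 is never deleted. MAR/MNAR are out of scope: the
observed missingness is below 1% and its mechanism unreported.

**Linear null.** The no-cusp condition keeps the covariate cross-section
(baseline distress loads 0.9 on L) but makes change purely autoregressive:
x_{t+1} = c0 + c1·x_t + noise, parked mid-scale (mean 2.0, SD 0.55) so the
clip never binds. Two deliberate choices follow from measured failure
modes of naive nulls, and are properties of the *method*, not bugs in it:
(1) a floor-clipped null is convex in the baseline and the quadratic term
detects that real nonlinearity; (2) the cusp polynomial spans z² and z³
but not z itself, and since the shifted z is positive, z² is nearly
collinear with z — so any change effect of a baseline-correlated covariate
(even a purely linear one) loads onto z² and inflates its rejection rate
far above the nominal level (we measured 14–57% depending on effect size).
Users testing for a cusp in real data should treat a significant z² with
caution whenever covariates correlate with baseline severity. Under the
clean null the measured size of the z² test is ≈ 5–6% at n = 150.

## What the synthetic conditions do and do not show

Passing tests show the pipeline recovers the qualitative structure it
assumes: near-nominal size under a genuinely linear process, ≥ 80% power
for the bifurcation product at n = 150 under the strong-effect condition,
and AIC preferring the right model family in each condition. They do not
show that real post-wildfire distress follows a cusp diffusion, that the
single-latent-factor covariate structure is right (the generator matches
targeted moments and two key correlations, not full correlation
matrices), or that distress declines over waves (the stationary process
has no secular trend, while the samples show one). Observed distress is an
item-mean scale treated as continuous; item-level measurement is out of
scope.

## Imputation

Cell-level holes are imputed by linear iterative PCA: start from column
means, alternate a rank-r truncated-SVD reconstruction of the
column-centered matrix with refill of the originally missing cells, stop
when the largest refill change is below tol (defaults r = 2, tol = 1e-6,
cap 500 iterations; non-convergence warns and returns the best iterate).
Observed cells are never altered; imputed cells are clipped to declared
scale ranges. The reference analyses used a *non-linear* PCA imputation;
at sub-percent missingness the linear and non-linear variants are
practically indistinguishable for downstream fits, and every run report
records that the linear method was used. The component count and
convergence settings of the original were not reported; the defaults here
are package choices.

## Numerical choices and degenerate inputs

Cubic roots: closed form + ≤ 4 Newton steps; residual tolerance 1e-9;
boundary classification at |D| ≤ 1e-9. Stationary sampling: grid of 1601
points spanning all wells ± 2σ, row-wise trapezoid CDF, linear
interpolation within cells. Quadrature oracles use adaptive `scipy` quad
on [−5−|α|−√β⁺, 5+|α|+√β⁺]. Constant state vectors, rank-deficient
designs (named collinear columns), all-missing columns, > 20% missingness
and out-of-range cells raise typed errors rather than proceeding.
Determinism: every stochastic operation is a pure function of its inputs
and an integer seed; the pipeline report is byte-identical across runs at
a fixed seed.

## Known limitations

- Maximum-likelihood stochastic-cusp estimation (Cobb-style) is not
  implemented; the polynomial-regression approximation is the method under
  study, and its z²-collinearity pathology (above) is inherited by design.
- The generator measures covariates at wave 1 only; contrasts that would
  use later-wave moderators in the sources reuse the wave-1 measures.
- Study2's subgroup sensitivity analysis is expressible via the pipeline's
  subset filter, but no quantitative targets exist for it without raw data.
- The AIC/BIC likelihood constant is a convention; absolute criterion
  values are not comparable across software, only differences are.
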