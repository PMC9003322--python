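# Methods

This note documents the statistical machinery behind `mmdnet`: what the
synthetic cohort generator emulates and how it is calibrated, how the two
model layers (mixed-effects screening and the hybrid Bayesian network) are
fit, the numerical choices involved, and what the package's tests do and do
not establish about real data.

## 1. The estimand and the variables

The outcome is multiple micronutrient deficiency (MMD) at 24 months:
co-existence of **at least two** of

| indicator | rule (strict inequalities) | units |
|---|---|---|
| anemia | hemoglobin < 11.0 | g/dL (altitude-adjusted upstream) |
| iron deficiency | ferritin < 12.0 **and** TfR > 8.3 | µg/L, mg/L |
| zinc deficiency | plasma zinc < 9.9 | µmol/L |
| vitamin-A deficiency | retinol < 0.70 | µmol/L |

A panel exactly at every cut-off is classified replete. Iron deficiency
requires the ferritin **and** transferrin-receptor criteria jointly; AGP
(α-1-acid glycoprotein) is carried as a systemic-inflammation covariate but
performs no inflammation correction of ferritin — published cut-offs are
applied to concentrations as given, and no imputation is done anywhere
(complete-case analysis throughout).

Exposures are derived per child over a months 9–24 window (a configuration
switch widens it): stool biomarkers (MPO, NEO, AAT) enter as the mean of
natural logs of the monthly concentrations (= ln geometric mean — natural
logs throughout, consistent with the magnitude of the log-scale summary
statistics being matched); intakes as arithmetic means of monthly 24-h
recalls; enteropathogen burden as total detections divided by stool samples
tested, per class (bacteria/virus/parasite) and pooled; breastfeeding as
the percentage of observed days (observed days, not calendar days, in the
denominator); diarrheal incidence as episodes per 100 child-months of
observation. The crowding index is persons-per-room dichotomized at the
pooled cohort median.

Retinol unit note: the published site medians for retinol (17–31 in a
column labelled µmol/L) sit 25–45× above the 0.70 µmol/L cut-off, which is
consistent with µg/dL, not µmol/L. The calibration therefore treats those
values as µg/dL and converts by ÷28.645 (molar mass 286.45 g/mol). The
generator emits µmol/L.

## 2. The synthetic cohort generator

### What it emulates

Seven sites (BGD, BRF, INV, NPB, PEL, PKN, TZH) with the published
per-site enrolment, blood-draw, missing-value, and analytic counts; monthly
diet and stool tables over months 9–24; one 24-month blood panel per child.
By default `generate_cohort` produces the analytic totals (1093 children at
scale 1); with `attrition=True` it produces the blood-draw totals (1294)
so that `apply_missingness` + the complete-case filter reproduce the
analytic accounting exactly. Missingness is completely at random within
site, with the per-site, per-biomarker counts drawn as **disjoint** child
sets (9 + 166 + 20 + 6 = 201 children lose exactly one marker each), since
the published counts sum exactly to the attrition.

### Marginals

Positive right-skewed quantities (intakes, blood concentrations, income)
are log-normal with parameters solved from the published median and IQR
(`µ = ln median`, `σ = ln(q3/q1) / (2 · 0.6745)`). Stool biomarkers are
specified directly as mean ± SD on the natural-log scale. Pathogen scores
are Gamma-mixed Poisson counts: a child-level rate with coefficient of
variation chosen so that the per-sample score (mean of 16 monthly Poisson
draws) reproduces the published mean ± SD. Monthly observation noise is
log-normal: SD 0.30 (natural log) for intakes, 0.25 for stool biomarkers —
small enough that derived window means carry < 2% extra variance, so
planted coefficients survive derivation essentially unattenuated.

Untabulated quantities get declared defaults, all configurable on the
truth object: TfR log-spread from a 5–10 mg/L IQR with the per-site level
tied to the site's ferritin-depletion probability (elevated TfR tracks
depleted iron stores); AGP median 1.0 g/L (IQR 0.7–1.4); site-level
income/schooling/diarrhea-rate/breastfeeding defaults chosen as plausible
for the seven settings. These are defaults of this package, not inferences
about the source cohort.

### Planted structure

Structural effects act on **within-site z-scores of the realized derived
variables**: for example, the MPO node is
`z(log-mean MPO) = −0.47·z(ln protein̄) + 0.08·z(bacteria score)
− 0.17·z(diarrheal incidence) + residual`, with the residual scaled so the
node keeps unit variance; the outcome is
`logit P(MMD) = α_site + ln(0.72)·female + ln(0.70)·z(ln vitC̄) +
ln(1.31)·z(log-mean MPO)`, with `α_site` solved by root-finding on the
realized cohort so the site's mean risk equals its prevalence target.
Because generation uses exactly the quantities the derivation pipeline
recomputes, a correctly specified fit recovers the planted coefficients
with no attenuation by construction. SES→intake and SES→pathogen arcs are
planted at ±0.10 to ±0.15 per SD with the qualitatively reported signs
(the source reports these numerically only in an appendix not available to
this package; where a sign is not stated — parasite score vs maternal
schooling — a protective −0.10 is used).

### Coupling the outcome to the blood panel

MMD must be *derivable* from the blood panel by thresholding, yet follow
the logistic model above. The generator resolves this with a latent
one-factor Gaussian copula over five deficiency propensities (hemoglobin,
zinc, retinol, ferritin, TfR; pairwise latent correlation ρ = 0.3,
configurable): it first draws the Bernoulli outcome `M_i`, then
rejection-samples the latent vector conditioned on "≥ 2 indicators" when
`M_i = 1` and "≤ 1" otherwise, and maps latents to concentrations through
the site's log-normal marginals. Because the copula's unconditional
probability of ≥ 2 crossings is calibrated to the same site target as the
Bernoulli draw, the mixture leaves every biomarker's marginal at its
calibration; and classification of the generated panel reproduces `M_i`
exactly.

Calibration of the crossing probability uses a single per-site knob: a
multiplicative concentration shift applied to all five markers (deficient
direction), solved by Brent's method on a one-dimensional Gauss–Hermite
integral over the shared factor. Shifting all markers by the same relative
amount (rather than by the same latent z) keeps every site's generated
medians within ~7% of the published values (the largest shift, for the
highest-prevalence site, is e^0.075 ≈ 7.2%).

### Site prevalence targets

Two site prevalences and the pooled figure are published (90.1% PKN, 6.3%
BRF, 47.6% overall). The remaining five sites are anchored at the
prevalence implied by their own biomarker marginals under a shared
concentration shift solved so the size-weighted pooled prevalence equals
47.6%. The shared shift comes out at e^0.024 ≈ 2.4% — i.e. the published
marginals almost imply the published pooled prevalence on their own.

### What passing tests do not show

The generator demonstrates internal consistency (calibration, recovery,
bookkeeping), not realism: real cohorts have informative missingness,
assay error, seasonal and within-child dynamics, correlated SES structure,
site-by-exposure interactions, and measurement units that drift across
laboratories. Parameter recovery here certifies the *estimators*, not the
substantive conclusions of any real-data analysis.

## 3. Mixed-effects screening

The bivariate screen fits one covariate at a time in a logistic model with
a random country intercept; covariates with Wald p strictly below 0.20
enter the multivariable stage. The marginal likelihood integrates the
random intercept by **adaptive Gauss–Hermite quadrature** (15 nodes;
integrand re-centred at its per-cluster mode and scaled by the mode
curvature), maximized by BFGS over (β, log θ) from a ridge-stabilized
Newton logistic start. With a single cluster the model degrades to
ordinary logistic regression; non-convergence and separation (|β| > 15)
are flagged, never silent. Wald intervals are used throughout (profile
likelihood would be more accurate near boundaries but is slower and the
screening decisions here are far from boundaries); agreement with lme4's
`glmer` (nAGQ = 15) is at the 5th decimal on a test fixture.

Collinearity gatekeeping reports all pairs with |Spearman ρ| > 0.4 and
breaks them by an explicit priority list (vitamin C, MPO, sex first) —
the "biological justification" step made declarative and logged. VIFs are
1/(1−R²) per covariate; no VIF cut-off is published, so the default is the
conventional 10 with a warning threshold at 5, both configurable.

## 4. The hybrid network and its sampler

Nodes are laid out in layers (SES/demographics → crowding → intakes,
pathogen scores, morbidity → gut/systemic biomarkers → MMD); candidate
arcs respect the layer order and include every reported association plus
the remaining biologically sensible candidates (NEO, AAT, AGP, birth
weight, breastfeeding, diarrhea as candidate MMD parents). Acyclicity is
enforced at construction and re-checked before fitting. Structure learning
is out of scope: the DAG is fixed a priori, and retained arcs are
statistical associations, not causal claims.

Sampling: linear-Gaussian nodes use conjugate sweeps
(β | σ² multivariate normal via Cholesky of the posterior precision;
σ² | β inverse-gamma). The logistic node uses Polya-Gamma augmentation —
ω_i ~ PG(1, x_iᵝ) renders β conditionally Gaussian — with the exact
Devroye/alternating-series rejection sampler for PG(1, z) implemented in
a JIT-compiled kernel (validated against the closed-form mean
tanh(z/2)/(2z) and variance at z = 0). A random-walk Metropolis sampler
targeting the same posterior is included purely for cross-verification.
Default settings are 4 chains × 5000 iterations with 2500 warm-up;
convergence is gated at split R-hat < 1.05 (via ArviZ), and retention
decisions with fewer than 100 effective draws are flagged unstable.

The logistic node carries fixed per-site intercepts. This matters:
site-level MMD risk spans 6% to 90%, and a single-intercept logistic fit
would attenuate within-site slopes by non-collapsibility; with site
intercepts (and site-centred covariates) the planted per-SD log odds are
recovered to ±0.04 at n ≈ 10,930. Linear nodes need only a global
intercept because their variables are site-standardized already.

Arc selection: central 95% posterior interval (2.5th–97.5th quantiles)
excludes zero. Under a null truth this retains each structural-zero arc at
the nominal ~5% rate (measured 6.0% over 384 pooled arc decisions in the
suite's replicate study). Sensitivity refits drop one node (never MMD) and
report per-arc median shifts and retention flips.

## 5. Numerical choices and degenerate inputs

- Within-site z-scores use the site SD with a zero-variance guard
  (constant columns standardize to 0 and are excluded from screening with
  a logged reason).
- Duplicated months in a biomarker series are averaged on the log scale
  before the window mean; an empty window yields a missing value, never 0.
- A pathogen score with zero stool samples is missing, not zero.
- Monthly intake draws include a −τ²/2 correction so the arithmetic
  monthly mean is centred on the child's level; stool biomarkers omit it
  because their derived statistic is the mean of logs.
- Copula rejection sampling is vectorized with a 10,000-round cap;
  acceptance probability per child is min(target, 1−target) ≥ ~6%, so the
  cap is unreachable under valid calibration.
- Seeds: every stochastic entry point takes an explicit seed;
  `SeedSequence(seed, spawn_key)` fans a single global seed out to stages
  and chains, all derived seeds < 2³¹. The PG kernel's RNG is reseeded per
  chain.

## 6. Problem sizes used by the test suite and acceptance script

Calibration checks run on a scale-20 cohort (≈ 21,860 children); recovery
checks in the test suite use two scale-10 cohorts with shortened chains
(2 × 2000, warm-up 1000) — posterior medians at that sample size are
stable to ~0.01, so chain length is not the binding error term — while
`scripts/acceptance.py` uses the full 4 × 5000 settings over three seeds.
The null-retention study pools 32 candidate arcs over 12 replicate fits at
study scale. These sizes are the package's own trade-off between
Monte-Carlo error and turnaround; all are parameters, not constants.

## 7. Known limitations

- The GLMM supports a single random intercept (country); no random slopes
  or nested levels.
- Wald inference in the screen; no profile or bootstrap intervals.
- The network fixes its structure; no structure learning, latent
  environmental-enteric-dysfunction construct, or causal identification.
- The generator does not simulate 7/15-month blood draws, diarrheal-stool
  sampling, assay noise, or recruitment/loss dynamics; hemoglobin arrives
  pre-adjusted for altitude.
- Missingness is MCAR within site by design; the complete-case pipeline is
  exact under it and untested under informative mechanisms.
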