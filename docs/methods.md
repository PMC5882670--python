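# Methods

This note documents the statistical models the package implements, the
assumptions behind them, the synthetic observation process used to validate
them, and the numerical and design choices a maintainer would want spelled
out.

## Study design the package targets

A short stream reach (total wetted surface 746.27 m², default) sampled
biannually in mid-June and mid-September with two consecutive
electrofishing passes per occasion. Every fish handled for the first time
has its adipose fin clipped; fish longer than 115 mm additionally receive a
persistent individual tag. Sub-yearlings (0+) emerge shortly before the
June sampling and are catchable only from their first September onward.
Because the reach sits below an impassable waterfall, older fish immigrate
from an unsampled source population: a fish with an intact adipose fin at an
age/season where any local fish would already have been clipped (1+
September or older) must be such a "late incomer". The seasonal intervals
are unequal: June→September ≈ 0.25 yr, September→June ≈ 0.75 yr.

## Removal density

Two-pass removal with constant per-pass capture probability `p`:
`E[c1] = Np`, `E[c2] = (N−c1)p`. The closed-form (conditional) maximum
likelihood estimates are `N̂ = c1²/(c1−c2)` and `p̂ = 1 − c2/c1`, with
`Var(N̂) = c1²c2²(c1+c2)/(c1−c2)⁴`. The likelihood factorizes into the
pass split given the total catch (which estimates only `p`) and a binomial
for the total catch out of `N` with probability `1−(1−p)²`; the test suite
uses this factorization as a brute-force grid oracle. Non-depleting counts
(`c2 ≥ c1`) return the minimum possible abundance `c1+c2` flagged
`fallback` with no SE. Densities are `N̂/area·10⁴` (fish ha⁻¹); rounding
happens only at reporting time.

The analytic SE is asymptotic. Against a parametric bootstrap it agrees
within 15% in the design's own capture regime (per-pass `p ≳ 0.88`,
first-pass catches ≥ 50); at low capture probabilities the estimator's
sampling distribution becomes strongly right-skewed and its spread
genuinely exceeds the asymptotic SE, which users should keep in mind before
applying two-pass removal to poorly catchable populations.

## Random-effects von Bertalanffy growth

`L(t) = L∞(1 − e^(−k(t−t0)))` with, per individual `i` in group `j` and
static covariate `x`:

    log k_i  = α₀ + α₁(j) + α₂ x + σᵤ u_i,   u_i ~ N(0,1)
    log L∞_i = β₀ + β₁(j) + β₂ x + σᵥ v_i,   v_i ~ N(0,1)
    t0 = γ₀ (one shared scalar)

with independent `u` and `v` (no correlation parameter) and Gaussian
measurement error `σ_ε` on observed length. Ages for September samples are
measured from a nominal mid-June emergence of the birth cohort, so a 0+
fish in September is 0.25 yr old. Lifetime-growth fitting uses September
records of tagged fish only (one record per fish per occasion); growth
increments `G_d = ΔL/Δdays` use all occasions.

Estimation is marginal maximum likelihood. For each individual the joint
log-density of its observations and `(u, v)` is maximized by damped 2-D
Newton iterations (Gauss–Newton curvature for the steps, which is always
negative definite; gradient tolerance 1e-8, warm-started across outer
iterations with a reset to the origin whenever the cached mode is worse),
and the Laplace approximation uses the exact Hessian at the mode (falling
back to the Gauss–Newton curvature in the rare non-negative-definite
corner). The outer problem runs L-BFGS-B on
`(α, β, γ₀, log σᵤ, log σᵥ, log σ_ε)` with wide bounds; variance
components are bounded below at 1e-4 so σ→0 degenerates smoothly into
nonlinear least squares (verified against `scipy.optimize.curve_fit`).
Standard errors come from a central finite-difference Hessian of the
marginal negative log-likelihood (relative step 1e-4), with log-scale
σ-SEs mapped by the delta method. Continuous covariates are centred and
scaled internally; slopes are reported on both scales. Categorical
reference levels are the smallest labels (earliest cohort, most-downstream
sector).

An adaptive Gauss–Hermite quadrature (product grid centred and scaled at
each individual's mode) evaluates the same marginal likelihood
independently; at the study's measurement-error scale (σ_ε ≈ 3 mm, 3–4
measurements per fish) Laplace and 9–15-node quadrature agree to well
under 0.5 log-units on 20-fish subsets.

Predicted trajectories at `u = v = 0` are labelled *mode* trajectories:
`L∞` is lognormal across individuals, so the zero-effects curve lies below
the population mean (Jensen), and the delta-method band propagates only
fixed-effect uncertainty.

## CJS apparent survival

Capture histories condition on first release (only tagged fish, hence all
aged ≥ 1+). Apparent survival confounds death with permanent emigration.
Because intervals alternate between 3 and 9 months, `φ` is parametrized on
the annual scale through a logit link and powered by the interval length in
years: `φ_int = expit(Xθ)^τ`, making "annual survival" the native
parameter. Capture probability `p` has its own logit design. Trailing
non-detections enter through the standard `χ` recursion
(`χ_t = 1−φ_t + φ_t(1−p_{t+1})χ_{t+1}`), verified against exhaustive
enumeration over all continuation histories for K ≤ 5.

The formula vocabulary is a closed set — `1, cohort, time, season, age,
bs(age), tbar, bs(tbar), density` for `φ`; `1, time, season` for `p` — with
treatment coding, `:` products, and cubic B-splines (df 3, interior knots at
covariate quantiles). Models using an unavailable covariate (e.g. interval
temperature never supplied) refuse to fit rather than silently drop terms.
Identical (history, cohort, origin) rows are collapsed with multiplicities,
and the likelihood and its analytic gradient are fully vectorized, so a
57-parameter fit on ~2,300 histories × 23 occasions takes a couple of
seconds. SEs invert a finite-difference Jacobian of the analytic gradient.

Under fully time-dependent `p` the final interval identifies only the
product `φ·p` (the classic terminal confound): the information matrix is
singular, SEs are reported missing rather than split, and the mean-annual-
survival summary excludes the terminal interval by default. Two-stage
selection (recapture structure first under the global survival model, then
survival candidates, plain AIC with the ΔAIC < 2 equivalence rule) is
provided as a driver; arbitrary (φ, p) pairs can also be ranked directly.
No overdispersion adjustment is applied.

## First-overwinter survival

0+ fish are never tagged, so September 0+ → June 1+ survival is a binomial
count ratio restricted to fin-clipped fish: `σ̂ = s1/n0` with
`SE = √(σ̂(1−σ̂)/n0)`, where `s1` counts June 1+ fish whose fin was already
clipped at capture. Intact-fin immigrants cannot enter the numerator, which
is the identification trick that makes the estimator invariant to the
immigration rate (tested by simulation at immigration 0 vs 60 per
occasion). Annualization uses the actual interval length,
`σ̂_a = σ̂^(365.25/days)`, with a delta-method SE; an optional division by
the June capture probability (from the removal estimates) corrects for
clipped survivors alive but missed — off by default since per-occasion
detection in this design is ≈ 0.99. Density dependence is an OLS of
`log σ̂_a` on `log D̄` (mean September/June density of older fish); years
with zero estimates are excluded with a warning.

## Recruitment, incomers, movement, anomalies

*Recruitment* (0+ September density) is modelled against lagged spawner
density (fish > 150 mm) and spring (1 Jan–31 May) degree-days with an
AIC-ranked candidate set: intercept-only, linear terms, and fixed-df (3)
cubic regression splines in place of penalized smoothers — with ~10 annual
data points penalization has nothing to shrink against, and fixed-df OLS
keeps every candidate checkable against normal equations. At this sample
size plain AIC computed from maximum-likelihood variances is known to
favour larger models, so "no predictor needed" is asserted through the
ΔAIC < 2 equivalence rule (null first or equivalent) rather than strict
rank; exact AIC ties break toward fewer parameters.

*Late-incomer proportion*: per September occasion, among fish aged ≥ 1+
whose 0+ September falls inside the study period (earlier cohorts are
unclassifiable under the fin-clip protocol and are excluded), the fraction
never sampled at 0+ September or 1+ June — intact fin now, or a tag history
whose first capture was past those stages. Carrying the classification
across recaptures requires identity, i.e. tags; the tag-free intact-fin
component alone is a threshold-invariant lower bound.

*Movement*: per-fish sector counts, the proportion ever sampled in more
than one sector (binomial SE), adjacency on integer sector labels, and a
logistic GLM (statsmodels, IRLS) of the multi-sector indicator on the
number of years sampled — per-fish coding.

*Cohort anomaly flags* are hypothesis-generating: predicted mode length at
a reference age per cohort, flagged when the interval excludes the
cross-cohort median. Since every cohort is tested against the median
simultaneously, the default per-cohort interval is 99.5% — a
Bonferroni-style choice keeping the family-wise false-flag rate near 5%
for ~10 cohorts; a conventional 95% band would false-flag a normal cohort
in roughly a quarter of datasets. A fast-growing flagged cohort is a
pointer toward unusual early-life conditions (e.g. a density crash before
the observation window), not a demonstration.

## Environmental covariates

Growing degree-days: `Σ max(T_d − base, 0)` over a calendar window, base
0 °C by default and configurable — the defining base for this system is not
settled, and the reported annual values (~1200 at mean 8.4 °C) imply the
choice matters; missing days are counted and reported, never interpolated.
Interval mean temperature is the arithmetic mean over `[start, end)` with a
missing-fraction report. Rainfall-maxima percentiles use the nearest-rank
convention (`100·#{x ≤ v}/n`).

## Synthetic data generator

The generator is the package's ground-truth instrument and mirrors the
design above: biannual occasions (default 23, September 2004 start), local
recruits entering at 0+ September (`Poisson(300)` per cohort), immigrants
entering at ages 1–3 (`Poisson(40)` per occasion; arrivals at 1+ June count
as early incomers, matching the fin-clip accounting), growth from the
random-effects model (defaults `k = 0.3 yr⁻¹`, `L∞ = 330 mm`, `t0 = −0.2`,
`σᵤ = σᵥ = 0.1`, `σ_ε = 3 mm`, lengths to the nearest mm, ≥ 1 mm), survival
applied between occasions as `φ_annual^τ` from an additive logit design
(intercept 0.2 ≈ 0.55 annual), first-order Markov movement to adjacent
sectors (probability 0.1 per interval), and two removal passes at per-pass
capture probability 0.9. Pre-study cohorts (3 by default) are thinned by
powered survival so the first occasion starts with a standing age
structure. The rate defaults were fixed once against the design facts the
generator must emulate — ≈ 2,600 tagged fish over the study and older-fish
abundance in the low hundreds — and give ≈ 2,630 tags, 380–590 older fish
and a standing late-incomer share of ≈ 0.23 among classifiable cohorts
(the generator's stationary demography cannot simultaneously match a
higher incomer share without overshooting the tag count; the incomer
estimator is validated by tracking the generator's own truth, not an
absolute value).

What it deliberately does not emulate: tag loss, sex, fecundity or an egg
stage, density- or temperature-dependent vital rates (survival and growth
truths are set by the caller), observation heterogeneity beyond the
constant per-pass capture probability, and any demographic difference
between immigrants and locals (immigrant growth draws fresh random effects
from the same distribution). Passing recovery tests on these data therefore
demonstrates estimator correctness under the stated model, not robustness
to the many ways real data violate it.

Determinism: one `numpy` generator seeded from the config drives every
draw, so identical configs give byte-identical CSVs. The pipeline spawns
per-stage seeds from one root seed via `SeedSequence`.

## Problem sizes used in validation

Unit tests run on 6–9-occasion populations of a few hundred fish and
growth panels of 60–120 individuals. The validation suite
(`tests/test_acceptance.py`) and `scripts/acceptance.py` use: the full
removal-oracle sweep (all `c1 ≤ 200`, `c2 < c1`); 200 fish × 4 lengths for
growth recovery; ~2,300 tagged fish × 23 occasions for CJS recovery with 25
replicates for selection consistency; 11-year default simulations for the
early-survival invariance plus 5 replicate 10-year datasets for slope
recovery (a single 3-SE check on one 10-year draw carries ~2% tail risk
even for an exact estimator); and 10 replicates of 8-cohort growth panels
for the anomaly detector.

## Known limitations

- Growth random effects are independent; a `u`–`v` correlation (fast
  growers maturing smaller) is not estimable here by design.
- One shared `σ_ε`; occasion-specific measurement variances are not
  modelled.
- The CJS layer has no multistate/spatial structure, no random effects and
  no Bayesian fitting; emigration to the source reach is indistinguishable
  from death.
- Fixed-df spline candidates are not penalized smoothers; with long annual
  series a GAM package would be preferable.
- The anomaly flag inherits every assumption of the growth model; flags on
  real data deserve model criticism before ecological interpretation.
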