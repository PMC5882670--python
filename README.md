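# vitalrates

Estimation of spatial and temporal variation in the vital rates of a stream
salmonid population from tag–recapture data: density, individual growth,
apparent survival, recruitment and movement, in a **source–sink** setting
where the study reach receives immigrants from an unsampled source
population upstream of a waterfall.

The package is aimed at fish ecologists and quantitative biologists working
with biannual electrofishing designs: two removal passes per sampling
occasion, fin-clipping of every first-captured fish, individual tags above a
length threshold (115 mm), and unequal seasonal intervals (June→September ≈
3 months, September→June ≈ 9 months).

## What it computes

- **Density** — two-pass removal estimates per occasion and stratum:
  `N̂ = c1²/(c1−c2)`, `p̂ = 1 − c2/c1`,
  `Var(N̂) = c1²c2²(c1+c2)/(c1−c2)⁴`, scaled to fish ha⁻¹.
- **Growth** — the von Bertalanffy function `L(t) = L∞(1 − e^(−k(t−t0)))`
  with individual random effects on the log scale:
  `log k_i = α₀ + α₁(j) + α₂x + σᵤu_i`, `log L∞_i = β₀ + β₁(j) + β₂x + σᵥv_i`,
  `u, v ~ N(0,1)`, fitted by marginal maximum likelihood with a Laplace
  approximation over the per-individual effects (empirical Bayes modes
  returned; adaptive Gauss–Hermite quadrature available as a cross-check).
- **Survival of tagged fish** — Cormack–Jolly–Seber models with
  design-matrix covariates on `φ` (apparent survival, annual scale,
  powered by the interval length: `φ_int = φ_annual^τ`) and `p` (capture),
  B-spline terms for age and temperature, and AIC ranking with the
  two-stage (p first, then φ) protocol.
- **First-overwinter survival** — the immigration-robust binomial estimator
  `σ̂₀₊ = s1/n0` (fin-clipped June 1+ over September 0+), annualized as
  `σ̂^(365.25/days)`, with a log–log density-dependence regression.
- **Recruitment, incomers, movement** — AIC-ranked recruitment models,
  the intact-adipose-fin estimate of the late-incomer proportion, lagged
  density correlations, movement summaries and a years-sampled logistic GLM,
  plus a hypothesis-generating cohort growth-anomaly flag.
- **Synthetic data** — a full generator of the above observation process
  with known ground truth, so every estimator is validated by parameter
  recovery.

## Worked example

```python
import vitalrates as vr

est = vr.two_pass_estimate(100, 10)
print(f"N = {est.n_hat:.2f} +- {est.se_n:.2f}, p = {est.p_hat:.2f}")
# N = 111.11 +- 1.29, p = 0.90

print(round(vr.density_from_abundance(548)))   # 548 fish on 746.27 m^2
# 7343   (fish per hectare)

cfg = vr.SimConfig(seed=42)                     # study-scale synthetic reach
enc, truth = vr.simulate_population(cfg)
ch = vr.build_capture_histories(enc)
fit = vr.fit_cjs(vr.CJSModelSpec(phi="season", p="time"), ch)
print(f"mean annual apparent survival: {fit.mean_annual_phi():.3f}")
# mean annual apparent survival: 0.549   (generator truth: 0.550)
```

The first block is the closed-form removal estimate for catches of 100 and
10 fish; the density line converts an abundance of 548 fish on the 746.27 m²
stream surface to fish per hectare. The last block simulates a ~2,500-tag
dataset, builds capture histories and recovers the generating annual
survival (0.55) from a CJS fit.

Longer narrative walk-throughs, one per capability, live in `examples/`
(`python examples/growth_trajectories.py` etc.). A thin CLI mirrors the
library: `vitalrates simulate|density|growth-fit|cjs-fit|early-survival|
recruitment|movement|anomalies|run`.

## Conventions worth knowing

- Percentile ranks of rainfall maxima use the nearest-rank convention
  (`100 · #{x ≤ value} / n`), so the sample maximum is the 100th percentile.
- Growing degree-days default to base 0 °C (configurable); missing days are
  counted and reported, never imputed.
- Mode-vs-mean: predicted growth trajectories at zero random effects are
  the *modal* fish; with lognormal L∞ they sit below the population mean.
- Under fully time-dependent capture probability the terminal CJS interval
  identifies only the product `φ·p`; summaries exclude it and its SEs are
  reported missing rather than split arbitrarily.
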