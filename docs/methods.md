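# Methods note

This note records the model, the generative assumptions behind the synthetic
cohorts, the numerical choices, and what the test suite does and does not
establish.

## 1. Decision-theoretic core

The gain function is a linear ramp on a half-open support:
G(e) = 100·(e − 7)/23 for e ∈ (7, 30], else 0 (distances in cm). Expected
gain of an aim point E under Gaussian endpoint noise σ is

EG(E, σ) = ∫ G(e)·N(e; E, σ²) de,

evaluated by 200-node Gauss–Legendre quadrature on
[max(7, E − 8σ), min(30, E + 8σ)]. The integrand is smooth inside that
interval (the only kinks are at its ends), so the quadrature agrees with a
dense-trapezoid oracle to < 1e-4 and with the closed-form
truncated-Gaussian integral to < 1e-8. The optimal aim E\*(σ) is found by a
257-point pre-search plus bounded scalar minimisation (xatol 1e-6), cached
per (σ, gain function). E\* decreases monotonically in σ (28.79 cm at
σ = 0.5 down to 25.39 cm at σ = 3.0); a flat gain function has no unique
maximiser and raises.

A subject's **risk sensitivity** is mean endpoint − E\*(σ̂), with σ̂ the
sample SD of the same endpoint window. Positive values are risk-seeking.

## 2. Virtual opponent

Before each competitive block the opponent's SD is set to the subject's own
reaching SD — over the last 40 reaches (`rolling_40`) or frozen at the late
baseline value (`frozen_baseline`, exp4) — and its endpoints are drawn from
N(α·E\*(σ̂), σ̂²). The risk coefficient α is 1 (risk-neutral) or a schedule
declining to 0.925 (risk-averse): for the exp1b schedule, α = 1 on blocks
1–4, linear steps of 0.015 down to 0.925 across blocks 5–8, and 0.925 on
blocks 9–12. (The source text's "steps of 0.15" is arithmetically
inconsistent with its own endpoints; 0.015 is the only reading consistent
with both.)

## 3. Synthetic subject (generative model)

The synthetic subject is *not* a theory of the participants; it is the
minimal generator that reproduces the statistical structure the analysis
pipeline measures, so that the pipeline can be validated by parameter
recovery. Per block, aim = E\*(σ_block) + b + response + jitter with:

- **Baseline bias b** (default +1.0 cm): the risk-seeking offset. Cohorts
  draw b ~ N(b, 0.65²) per subject; 0.65 cm is the reference between-subject
  SD of baseline risk sensitivity. This heterogeneity is load-bearing: it is
  the only source of opponents-above-baseline in risk-averse protocols.
- **Two-slope response**: the block aim moves by slope·x where
  x = α·E\*(σ̂) − (baseline aim) is the opponent's relative aim, with
  slope 0.63 for x ≥ 0 and 0.21 for x < 0 (the reference asymmetry).
- **First-block inhibition**: a 1.0-cm aim decrease at competition onset,
  decaying linearly to zero over 5 trials.
- **Variance reduction with practice**: σ_block = max(1.0, σ₀·0.985^(block−1))
  with σ₀ = 2.2 cm (log-normal CV 0.15 across subjects). The per-block ratio
  0.985 is anchored to the reported 0.73× SD reduction over ~21 blocks
  (0.985²¹ ≈ 0.728).
- **Block-to-block aim jitter** SD 0.3 cm.

Reproducibility: one root `SeedSequence` spawns an independent child stream
per subject, so enlarging a cohort never perturbs earlier subjects, and equal
seeds give byte-identical CSVs.

## 4. Inference layer

- **Split-slope test**: the relative-aim scatter (x = A_o − A_i,
  y = A_c − A_i; one point per subject × block, block 1 excluded for the
  inhibition transient) is split at x = 0 and an OLS slope fitted per side
  (≥ 3 points required). 50,000 (default) paired bootstrap resamples give
  percentile CIs per slope; resamples with < 3 points on a side are redrawn.
  The permutation-style p is the bootstrap fraction with
  slope_left ≥ slope_right (ties counted; a strict variant exists).
- **Model comparison**: statsmodels OLS for the linear and quadratic fits;
  AIC = −2·llf + 2k with k counting coefficients plus the variance
  parameter; AICc and BIC likewise from the full Gaussian likelihood.
- **Effect size / power**: paired d = (m₁ − m₂)/√(s₁² + s₂² − 2·r·s₁·s₂);
  required n by exact noncentral-t power iteration
  (power(n) = P(|T′(df = n−1, nc = d√n)| > t_crit)). scipy's noncentral-t
  tails lose accuracy for nc ≳ 8.5; a Johnson–Kotz Gaussian approximation
  takes over there (power ≈ 1 in that regime, so the n-search is unaffected).
  Degenerate t-tests: zero-variance differences return the defined limit
  (t = 0, p = 1) when the mean difference is also zero, and raise otherwise.
- **Win chance**: Monte-Carlo — two samples of 10 scored endpoints, 10,000
  repetitions, ties worth half (preserves chance(a,b) + chance(b,a) = 1);
  the map averages chances in 0.25-cm half-open bins of the relative-aim
  plane.

## 5. Known limitation: one-sided identifiability under risk-averse opponents

With the prescribed recovery generator (b = +1.0 cm, exp1b schedule), the
opponent's expected relative aim is −(1 − α)·E\* − b, i.e. between −0.8 and
−2.6 cm — always negative. Positive-x points arise only when a subject's
sampled bias falls below the opponent's aim, which yields 0–3 weak points
per 88-point cohort. Consequences, measured over 100 replicate cohorts:
baseline-bias recovery and slope-CI coverage pass, but the permutation test
detects the slope asymmetry in only ~7% of cohorts (13% have no defined test
at all). This is a property of the design geometry, not of the estimator:
the corresponding acceptance test reports the measured rate and fails
honestly. The calibration (null) check instead uses a balanced schedule
(α from 1.06 to 0.95) so the equal-slope generator has support on both sides
of the split; its measured false-positive rate is 0.04–0.05.

## 6. What passing the suite shows — and does not

Passing shows the pipeline is internally coherent: the optimizer matches
grid-search oracles, the generator's parameters are recoverable where the
design identifies them, the null test is calibrated, and the headline
desk-scale statistics (d = 1.54, n = 6) follow exactly from the reference
summary statistics. It does **not** show that the generative subject model is a
correct account of human behaviour, nor reproduce data-dependent quantities
(bootstrap slope CIs, AIC values, group t-statistics), which require the
human dataset.
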