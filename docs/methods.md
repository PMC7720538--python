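# Methods

## Generative model

Each simulated study contains `n` subjects, split exactly in half between a
control and an experimental group (odd totals are rejected rather than
rounded). True scores are Gaussian and mutually independent unless a pathway
is stated:

| quantity | distribution | default |
|---|---|---|
| pre-test T1 | Normal(μ_pre, σ_pre²) | (50, 10²), T-scale norms |
| predictors P-I, P-II | Normal(μ_p, σ_p²) | (50, 10²) |
| control gain Δ | deterministic shift μ_Δ,ctl | calibrated |
| experimental gain Δ | μ_Δ,exp + β·(P-I − μ_p) + ε | calibrated |

with ε ~ Normal(0, σ_Δ²·(1 − ρ²)) independent of everything else, so the
total true gain variance is σ_Δ² and corr(P-I, Δ) = ρ. P-II has no pathway
anywhere; it exists to measure the alpha error. The post-test true score is
T2 = T1 + Δ by construction.

Two structural choices deserve justification because the observed-scale
targets alone do not determine them:

* **cov(T1, Δ) = 0 in both groups.** With the experimental pre/post SDs
  fixed at 10 and 13, this zero covariance is what makes the population
  pre-test coefficient of the post-test regression equal the reliability
  (0.80 at the reference level): cov(T1, T2) = var(T1). Any nonzero
  covariance would contradict that anchor. It also fixes
  σ_Δ² = 13² − 10² = 69.
* **The control gain is deterministic.** SD 10 at both occasions with zero
  pre/gain covariance forces var(Δ_ctl) = 0. The control dz target (0.05)
  is therefore defined on the observed change, whose SD is pure measurement
  noise.

## Calibration of constant true effects

Users state effect sizes where applied researchers state them: on observed
scores at a reference reliability (default .80). `calibrate_true_effects`
converts them once into true-score constants that are then held fixed while
reliability varies, so observed effects attenuate naturally:

* observed change variance (experimental):
  v = σ_Δ² + e_pre² + e_postE², with e = error SD at the reference
  reliability; the observed change score is Δ + E_post − E_pre, so its
  reliability is r_gain = σ_Δ²/v;
* ρ = r_target / √(r_tt · r_gain) — attenuation inverted with the *change
  composite's* reliability on one side, because the target correlation is
  with the change score, not the post-test (ρ ≥ r_target always; |ρ| ≥ 1
  raises a calibration error);
* μ_Δ,exp = dz_exp · √v and μ_Δ,ctl = dz_ctl · √(e_pre² + e_postC²);
* β = ρ·σ_Δ/σ_p.

At the defaults this gives μ_Δ,exp = 5.836, ρ = 0.471, β = 0.392. A
200,000-subject cohort measured at reliability .80 recovers dz = 0.50 and
r = .30 to within ±0.01 (the calibration fixed-point test).

## Measurement layer

Observed = true + independent Normal(0, e²) noise per measure and subject,
with e = SD_true·√((1−r_tt)/r_tt). Each measure uses its own true SD — in
particular the experimental post-test error scales with 13, not 10, because
reliability is a variance ratio per measure. At reliability 1.0 observed
equals true exactly. Noise is redrawn independently for every dataset; cells
of the study grid never share data.

## Criterion variables

* absolute change: post − pre;
* relative change: **100·(post − pre)/pre** — percent units. The ×100 scale
  is a deliberate choice (isolated in one function): it matches how
  norm-referenced gains are reported, and the intercepts it produces (≈7.8
  at the reference cell) sit on the percent scale. A zero pre-test value
  raises an explicit division error naming the subject.
* residualized change: residuals of one pooled OLS line of post on pre,
  fitted per dataset across *both* groups. Pooling is what gives the
  criterion its characteristic signature — a negative control-group mean
  residual (the treated group pulls the common line up). Residualizing per
  group would instead absorb the treatment effect entirely.

## Regression engine

Design matrices center every continuous predictor at its full-sample mean
per dataset, code group 0/1 (control/experimental), and form interactions as
centered-predictor × dummy. Inference is textbook homoskedastic OLS (QR
factorization; coefficient covariance σ̂²(X'X)⁻¹ with σ̂² = RSS/(n−k);
two-sided t tests). Classical rather than heteroskedasticity-robust standard
errors are intentional even though the design is heteroskedastic by
construction (the treated group's criterion variance is larger): the point
of the study is to characterize the analyses practitioners actually run.
Columns whose diagonal R entry falls below 1e−10 of the largest trigger a
singular-design error. No multiple-testing correction is applied anywhere;
significance is per coefficient at α = .05, strict inequality.

## Study runner

The grid defaults to n ∈ {50, 100, 150, 200, 250, 300, 400, 500},
r_tt ∈ {.60, .70, .80, .90}, 1000 replications, all five models and all four
criteria — 1,280,000 regressions counting the parallel fits on noise-free
scores. Per replicate the seed is
`SeedSequence((master_seed, n, round(1000·r_tt), replicate))`, spawned into
one child for the true-score draw and one for the noise, so any replicate is
reproducible in isolation and cells are mutually independent. Replicates
where any fit fails are dropped whole (keeping the observed/true pairing)
and counted; a cell aborts if more than 1% fail. In practice failures do not
occur at these sample sizes.

Studentized bias uses the literal formula
mean(b_obs − b_true) / (SD(b_obs)·√n): the per-replicate difference between
the observed-score and noise-free estimates of the same dataset, scaled by
the spread of the observed estimates times the root sample size so values
are comparable across criteria scales and n. Its magnitude is reported as
is; no further normalization is attempted.

## What the tests do and do not show

The suite exercises the generator's own study conditions: Gaussian true
scores, homogeneous CTT noise, equal allocation, exactly two external
predictors independent of each other and of baseline. Passing tests
demonstrate the statistical properties of the *analyses* under this model —
power orderings, alpha calibration, the c₁ = b₁ − 1 artifact — not that real
cognitive-training data satisfy the model. Real data bring non-Gaussian
scores, correlated predictors (age and baseline, for instance), practice
effects that correlate with baseline, and heteroskedastic or correlated
measurement error; none of these is simulated. One consequence worth
flagging: because the predictors are independent of the pre-test here,
excluding the pre-test covariate (Model 5 vs Model 4) changes only the
precision of the interaction estimate, never its expectation. With
predictor/baseline correlation, omission would also shift the estimate.

Problem sizes in the test suite were chosen to keep the statistical checks
sharp at desk scale: the reference cell runs its full 1000 replications;
large-sample moment checks use 10⁶ subjects (tolerances ±0.005 on
correlations); qualitative power-monotonicity checks use 400 replications
per cell with a ±0.03 Monte-Carlo jitter allowance; algebraic identity
checks (which are exact, not statistical) use 50 random small datasets at
tolerance 1e−8.

## Known limitations

* The exact reference-cell means for the intercept and group terms depend on
  how the mean gain is anchored; the closed-form anchoring used here
  (μ_Δ,exp = dz·√v) is one defensible choice, and alternatives (anchoring on
  the noise-free change SD, or on the post-test SD) shift those two
  coefficients by a few tenths of a raw point.
* The interaction coefficient implied by the r = .30 / dz = 0.50 targets is
  r·SD(gain_obs)/SD(p_obs) = 0.313 at the reference cell, and the Model-4/5
  interaction powers follow from it (≈0.76/0.73 at n = 200). Power figures
  quoted elsewhere for nominally similar setups can differ by several points
  depending on how that correlation target is anchored.
* Relative change inherits ratio-of-noisy-variables inflation: its
  population mean exceeds 100·E[Δ]/E[pre]. This is a property of the
  estimand, not a bug, and is one reason the percent criterion behaves worse
  than absolute change.
* The five models and four criteria are fixed vocabulary; the package does
  not do model selection, SEM/latent-change modeling, multi-level models, or
  unequal group allocation.
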