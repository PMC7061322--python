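# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the design decisions taken where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Learning-curve model

Trial latencies y(x), x = 1..20 (seconds, in (0, 60]; timed-out trials
enter at the 60-s ceiling with no censoring adjustment, because the goal is
revealed at the timeout) are modelled as y = a·x^b. The exponent b indexes
learning rate; a is the expected first-trial latency.

**Cut-off.** A quadratic c0 + c1·x + c2·x² is fitted to all trials by OLS.
If c2 > 0 and the vertex −c1/(2c2) lies in [4, n], the cut-off is the
vertex rounded half-up to the nearest trial; otherwise all trials are used
(no interior trough means there is nothing to trim). The lower clamp of 4
guarantees a two-parameter fit with residual degrees of freedom. The
cut-off exists to separate initial learning from post-plateau behaviour
(fatigue, disengagement), which otherwise penalises exactly the fastest
learners with the worst fits.

**Power fit.** Default `loglog_ols`: OLS of ln y on ln x over trials
1..cut-off; b is the slope, a = exp(intercept), and R² is reported on the
log–log scale. This is deterministic and closed-form, which makes the
permutation screen exactly reproducible. A `nonlinear_ls` option refits
(a, b) on the raw scale (initialised from the log–log solution, R² on the
raw scale) for users who prefer raw-scale residuals; which scale the
"right" R² lives on is a genuine modelling choice, so both are exposed and
the method is recorded in every result.

**Mean latency to cut-off** is the arithmetic mean of trials 1..cut-off —
a slope-free performance measure that remains meaningful for participants
excluded by the behavioural screen (whether those participants re-enter
that analysis is a config flag, `include_excluded_in_mean_latency`,
default off).

## Permutation screen

For each participant the trial order is shuffled `n_perm = 500` times and
the fit statistic recomputed per shuffle. Two readings of the statistic
are implemented: `"full"` (default) re-derives the cut-off for every
shuffle and so compares like with like — the observed statistic is one
more draw from the same functional; `"all_trials"` fits the power model to
every trial of the shuffle. The threshold is the empirical 84th percentile
of the null — the upper edge of its central 68% interval, the
distribution-free reading of "1 SD"; a `mean_plus_sd` variant is provided.
Exclusion: true R² ≤ threshold. Under exchangeable (trend-free) latencies
the percentile rule excludes ≈ 84% of participants by construction; the
acceptance suite verifies this calibration at 2,000 participants.

## MAD outlier screen

Per metric: scaled MAD = 1.4826 · median(|x − median|) (the constant makes
it a consistent SD estimator under normality); values beyond 2.5 scaled
MADs from the median are removed, two-sided. Screens are applied
per-metric, not listwise, so each correlation reports its own n. If the
MAD is zero, only values equal to the median are kept.

## Correlation suite

- One-sided Pearson/Spearman p-values use the t transform
  t = r·√((n−2)/(1−r²)) on n−2 df (Spearman on mid-ranks; the t
  approximation is adequate at the n ≈ 25–30 this analysis targets; an
  exact permutation p would be the alternative at smaller n).
- **Default Bayes factor.** Prior on ρ: stretched beta of width κ
  (default κ = 1, i.e. uniform on (−1, 1), the cited software's default).
  The reduced likelihood of ρ given (r, n) is the exact sampling density
  of the correlation coefficient (hypergeometric form); BF10 integrates it
  against the prior by adaptive quadrature (absolute tolerance 1e−10) and
  divides by the likelihood at ρ = 0; BF₊₀/BF₋₀ truncate and renormalise
  the prior to one sign. Likelihood values are accumulated in log space
  relative to their maximum, so large-n integrands cannot underflow.
  Credible intervals are central 95% intervals of the *two-sided*
  posterior (whether a one-sided analysis should truncate the posterior is
  ambiguous; two-sided is the transparent default), located by Brent
  root-finding on the quadrature CDF.
- **Steiger Z** for two dependent overlapping correlations uses the
  pooled-correlation (rbar) covariance term — the classical 1980 variant —
  on Fisher-z transformed coefficients.
- **Partial correlations** use the residual method (OLS residuals on
  covariates with intercept), t on n−2−k df. The JZS Bayes factor compares
  y ~ covariates + x against y ~ covariates under a Zellner–Siow
  mixture-of-g prior (g ~ InvGamma(1/2, n/2)), computed by quadrature on
  g/(1+g); direction is imposed by the order-restriction identity
  BF± = BF10 · 2 · P(sign | data), with the posterior sign probability
  approximated by the t CDF at the OLS t statistic. This is a
  BayesMed-style construction; second-decimal deviations from that R
  package are expected.
- **Bootstrap comparison** of dependent Spearman correlations resamples
  complete participant triples with replacement (1,000 resamples by
  default — a count the analysis convention leaves open) and reports the
  95% percentile interval of Δρ.
- Bonferroni: α/m with m = 2 comparisons per metric class by default.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not the task's psychology:

- **Latencies:** y(x) = min(60, a·min(x, plateau)^b · exp(ε)), with
  ε ~ N(0, noise_sd²) up to the plateau and N(0, late_noise_sd²) after it.
  Per participant: b ~ N(−0.32, 0.08) truncated negative, a ~ U(35, 60) s,
  plateau ~ U{7..20}. The plateau-plus-variable-tail shape mirrors the
  observed phenomenology (fast early learning, erratic late trials).
- **Noise defaults** noise_sd = 0.05, late_noise_sd = 0.45 (log-latency
  SDs) were fixed once at design time: the late scale makes post-plateau
  trials visibly erratic (±1 SD spans a factor ~1.6), while the learning-
  phase scale keeps the fitted slope's estimation error small relative to
  the population SD of b, so that recovery of the generating distribution
  (mean within ±0.01, SD within ±0.02 at n = 1,000) is a meaningful check
  of the estimator rather than of noise cancellation.
- **Metrics:** fornix MD is built as mu + sd·(r·z + √(1−r²)·e) with z the
  standardised true b — a correlated-Gaussian construction whose
  population correlation equals the target (default .44) exactly; fornix
  FA uses target −.24; ILF metrics, volumes and gender are independent of
  learning. Scales (fornix MD 0.85 ± 0.04 ×10⁻³ mm²/s, FA 0.40 ± 0.04,
  etc.) are plausible free-water-corrected adult values; only the
  correlation structure, not the scale, matters downstream.
- **Non-learners** (optional fraction) emit i.i.d. lognormal latencies
  with no trend — the behavioural profile the permutation screen is
  designed to catch.
- **Arena agent:** a step-walker in the 8×8 m room (step 0.25 m / 0.1 s,
  reflecting walls, four mid-wall starts cycling per 4-trial block) whose
  heading blends a random direction with the bearing to the sensor at
  weight `goal_bias`; the sensor is an axis-aligned 0.8 m square (the
  task description's "0.25% of floor area" is inconsistent with that side
  length, so the side is a parameter). The agent produces plausible
  trajectories and latency orderings, not human behaviour.

What passing tests on this generator do **not** show: robustness to the
serial dependence, censoring-at-ceiling patterns, strategy switches and
non-lognormal noise of real participants; nor anything about real
brain-behaviour effect sizes, which enter only through the targeted
correlation.

**Seeding.** `simulate_cohort` and `flag_nonlearners` spawn one
`SeedSequence` child per participant from the master seed (spawn-by-
position), so extending a cohort never perturbs earlier participants'
data; the pipeline spawns separate stage streams (screening, bootstrap)
from its master seed. Identical config + seed reproduces the report
byte-for-byte.

## Problem sizes in the test suite

Calibration and recovery checks run at the sizes that make their
tolerances meaningful: parameter recovery at n = 1,000 participants,
correlation targeting at n = 10,000, permutation-screen calibration at
2,000 participants × 500 permutations (vectorised closed-form refits make
this cheap), type-I calibration at 10,000 replicates. End-to-end pipeline
tests use cohorts of 60–200 with reduced permutation/bootstrap counts,
which is ample for their sign- and bookkeeping-level assertions.

## Known limitations

- The default BF quadrature uses the exact reduced likelihood of the
  sample correlation; published values computed by other software from
  unrounded data can differ in the second decimal when recomputed from
  rounded (r, n) inputs.
- The directional JZS partial-correlation BF's sign probability is a
  t-approximation, not an exact posterior integral.
- Spearman results attach a Bayes factor by applying the Pearson machinery
  to ρ — a pragmatic companion number, not a rank-based Bayes factor.
- No trajectory-derived performance measures (path length,
  distance-to-goal); latency is the only behavioural input.
- Missing trials are rejected at I/O rather than imputed.
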