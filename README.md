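# navlearn

Individual-differences analysis of navigational learning in a virtual
water-maze task, with a focus on relating learning rate to white-matter
tract microstructure (diffusion MRI metrics).

## Who this is for

Researchers analysing hidden-goal navigation experiments (virtual Morris
Water Maze variants) who want a principled per-participant learning index
and a hypothesis-driven correlation analysis against brain measures —
without hand-tuned exclusion rules. Everything runs on plain CSV tables,
and a built-in synthetic cohort generator makes the whole pipeline testable
end to end with no data download.

## The model

Per participant, trial latencies (time in seconds to reach a hidden floor
sensor, capped at the 60-s trial timeout) are modelled with a power law

    time = a · x^b,   x = 1, 2, …  (trial index)

where the exponent **b** is the learning-rate index: more negative b means
a steeper, faster-converging learning curve. Because many participants
learn quickly, plateau, and then behave erratically, the fit is restricted
to the initial learning phase: a second-order polynomial is fitted to all
trials, and its trough (the trial where the fitted parabola's first
derivative crosses zero) defines a per-participant **cut-off**; the power
model is fitted (log–log OLS by default) only to trials up to the cut-off.
A non-slope alternative, the **mean latency to the cut-off**, is derived
alongside.

Screening and inference:

- **Permutation screen** — each participant's trial order is shuffled 500
  times and the fit R² recomputed; participants whose true R² does not
  exceed the 84th percentile of their own null (the upper edge of its
  central 68% interval) show no behavioural evidence of learning and are
  excluded.
- **MAD outlier screen** — per metric, values beyond 2.5 scaled median
  absolute deviations from the median are removed (two-sided, consistency
  constant 1.4826).
- **Directional correlations** — one-sided Pearson and Spearman tests of
  the predicted sign structure (learning rate positively associated with
  mean diffusivity, negatively with fractional anisotropy), with
  Bonferroni-corrected α (.05 / 2 = .025), default Bayes factors (BF₊₀ /
  BF₋₀, stretched-beta prior of width 1 on ρ) and 95% credible intervals,
  Steiger Z tests and a robust bootstrap for comparing the tract of
  interest (fornix) against a comparison tract (inferior longitudinal
  fasciculus), and partial correlations controlling proportional
  hippocampal volume (volume / eTIV) or gender, with JZS-style Bayes
  factors.

## Worked example

```python
from navlearn import AnalysisConfig, CohortParams, run_full_analysis

cfg = AnalysisConfig(
    simulate=CohortParams(n_participants=100, seed=7),  # synthetic cohort
    seed=7,
)
results = run_full_analysis(cfg)
print(results.summary())
```

```
Navigational learning analysis
==============================================
participants: 100  behaviourally excluded: 4
corrected alpha: 0.025 (alpha 0.05 / 2)

measure                 metric         n       r       p       BF  95% BCI
b                       fornix_md     95   0.326   0.001    43.35  [0.13, 0.49]
b                       fornix_fa     90  -0.328   0.001    34.86  [-0.49, -0.12]
b                       ilf_md        96   0.009   0.467     0.14  [-0.19, 0.21]
b                       ilf_fa        96   0.160   0.940     0.05  [-0.04, 0.34]
...
comparison                           n       z       p  bootstrap 95% CI
b: fornix_md vs ilf_md              95    2.02   0.022  [0.01, 0.61]
b: fornix_fa vs ilf_fa              90   -2.96   0.002  [-0.76, -0.23]
...
```

Reading the output: the synthetic cohort was generated with a population
correlation of .44 between fornix MD and the true learning rate and
independent ILF metrics. The pipeline excludes 4 participants whose
learning curves are indistinguishable from shuffled data, recovers a
positive fornix-MD association (r = .33, one-sided p = .001, BF₊₀ ≈ 43 —
strong evidence) while both ILF metrics stay at chance (BF < 1/3, evidence
for the null), and the Steiger Z and bootstrap comparisons confirm the
fornix correlations exceed the ILF ones. Per-pair n varies because the MAD
screen runs per metric.

The same analysis runs from the shell on real or simulated tables:

```bash
navlearn simulate --n 28 --seed 11 --out-dir cohort/
navlearn run --latencies cohort/latencies.csv --metrics cohort/metrics.csv \
             --seed 11 --out-dir analysis/
```

Input formats: a wide latency CSV (`participant_id, trial_01..trial_20`,
seconds) and a metrics CSV (`fornix_fa, fornix_md, ilf_fa, ilf_md` — or
hemispheric `ilf_*_left/right` pairs, which are averaged —
`hippocampal_volume, etiv, gender`; MD in 10⁻³ mm²/s).

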