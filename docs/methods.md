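# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot demonstrate.

## Measurement model

A subject record carries anthropometry (weight kg, stature cm),
single-frequency 50 kHz bioimpedance (resistance R and reactance Xc, ohm),
and the DXA components fat mass (FM), bone mineral content (BMC), and lean
soft tissue (LST), all kg.  Derived quantities:

- impedance magnitude `Z = sqrt(R² + Xc²)`.  The resistive and capacitive
  components of bioimpedance add vectorially, and only this form is
  consistent with observed cohort summaries (for R ≈ 479.5 and
  Xc ≈ 62.4, Z ≈ 483.5, not 541.9).  The arithmetic sum `R + Xc`, which
  occasionally appears in print, is available behind
  `impedance_magnitude(..., method="arithmetic_sum")` and is never used by
  the catalogue.
- impedance index `S²/R` (cm²/Ω) and its base-10 logarithm.
- reference fat-free mass `FFM = BMC + LST`, exactly.
- BMI = weight / (stature/100)².

Cohort CSV validation tolerates a configurable discrepancy (default 5 kg)
between `FM + BMC + LST` and scale weight, since DXA-derived total mass
and scale weight disagree in real data.

## Equation catalogue

Each of the nine equations is an `EquationSpec` whose named coefficients
are evaluated by a dedicated dispatcher.  Unit conventions that matter:

- the impedance indices `S²/R` and `S²/Z` always take stature in cm;
- the two Deurenberg equations additionally contain a standalone stature
  term in metres.  This mixed convention is the only one that produces
  estimates on the scale of adult FFM (≈55 and ≈58 kg rather than
  hundreds) and is therefore implemented as stated;
- sex is coded 1 = male, 0 = female;
- Kotler's power-law term `0.50·(S^1.48/Z^0.55)·(1.0/1.21)` keeps the
  published 1/1.21 calibration factor as an explicit coefficient rather
  than folding it into the slope, so the stored spec mirrors the source
  term-for-term.  Its published SEE is a percentage and is stored as
  printed, not converted to kg.

All computation is at full floating precision; rounding (kg and % to one
decimal, ρ and C_b to four, CCC and R² to two) happens only in the report
formatter.

## Agreement statistics

Differences are predicted minus reference throughout.

- **Paired comparison.** Both series are screened with Shapiro–Wilk at
  α = 0.05; if either fails, both are log10-transformed before the
  two-sided paired t-test and the report flags the transform.  Descriptive
  and agreement statistics stay on the kg scale regardless — only the
  test changes scale.  A constant series is treated as carrying no
  evidence against normality; identical series return (t = 0, p = 1).
- **Lin's CCC.** `CCC = 2·s_xy / (s_x² + s_y² + (mean_x − mean_y)²)` with
  sample (n−1) moments; precision ρ is the Pearson correlation and
  accuracy `C_b = CCC/ρ`, so the decomposition holds exactly by
  construction.  The statistic is symmetric in its arguments and
  `|CCC| ≤ |ρ|` always.
- **Pure error** uses the n divisor (root mean squared difference), hence
  the identity `PE² = mean_diff² + sd_diff²·(n−1)/n`.
- **Calibration fit** regresses the reference on the prediction by OLS
  (statsmodels); SEE is the residual SD with n−2 degrees of freedom.
- **Bland–Altman** limits are bias ± 1.96·SD of the differences (95%
  limits); the trend test is the Pearson correlation of differences
  against pairwise means, whose significance indicates proportional bias
  (bias depending on the amount of FFM).
- **Reliability.** `TEM = sqrt(Σd²/(2n))` over test–retest pairs.  The
  companion CV% is the within-subject SD (numerically the TEM) divided by
  the grand mean of all measurements, times 100 — the standard companion
  definition.

## Development and cross-validation

`split_cohort` assigns subjects by a seeded uniform permutation; the
development-group size is round-half-up of `n·dev_fraction`, so 396
subjects at 2/3 give the conventional 264/132 partition.

`stepwise_fit` is classic bidirectional stepwise OLS: repeatedly enter
the candidate with the smallest partial-F p-value while it is below
α_enter = 0.05, then drop any included predictor whose p-value exceeds
α_remove = 0.10, until stable (the conventional defaults of the SPSS
family; both are configurable).  The candidate pool is fixed to the eight
predictors used in this line of research: age, stature, BMI, R, Xc, Z,
weight, and log10(S²/R); interactions and polynomial terms are excluded.
A candidate whose entry would make the design rank-deficient is skipped
with a warning.  Residual sums of squares below `1e-12 × TSS` count as a
perfect fit, which keeps the selection sane for noiseless responses.
The procedure is pure OLS: with too few observations for the candidate
pool it refuses rather than regularises.

Post-selection caveat: the reported standard errors are the usual OLS
ones and do not account for selection.  In simulation, the joint
"both slopes within 2 SE" rate for a truly two-predictor response is
about 87% rather than the nominal ≈91–95%, because a spurious entrant is
admitted precisely when its t-statistic is extreme, which conditions the
distribution of the other coefficients.  Per-slope coverage is ≈93%.
Similarly, with ~6 null candidates at α_enter = 0.05 the probability that
the final model contains only the true predictors is about 0.8, not
higher — stepwise selection admits a false entrant at roughly the rate
`1 − (1−α)^k` for k effective null candidates.

## Synthetic cohort generator

The generator's defaults are the study conditions of a 396-subject
army-cadet-like sample of young adult males: stature 175.8 ± 6.4 cm
(range 159.6–192.7), age 19.2 ± 1.8 y (17–24), FM% 17.2 ± 3.9 (9.0–27.8),
reactance 62.4 ± 7.0 Ω (27–86), FFM 58.2 ± 6.5 kg (40.6–79.5),
stature–FFM correlation 0.6, BMC fraction 3.0/58.2 of FFM, and true-model
coefficients (0.508, 39.234, −48.263) with 2.2 kg of model noise.

Generative scheme: stature and FFM are jointly normal (joint rejection
against both ranges); FM% is an independent truncated normal; weight is
FFM/(1 − FM%/100); resistance is obtained by inverting the true model,
`R = S² · 10^{−(FFM − 0.508·Wt + 48.263 − ε)/39.234}` with
ε ~ N(0, 2.2); reactance is an independent truncated normal; and the DXA
components close exactly (BMC = fraction·FFM, LST = FFM − BMC,
FM = weight − FFM).  Subjects whose resistance falls outside a
physiologic guard band of 250–900 Ω are redrawn in full.  All truncation
is rejection sampling, preserving normality in the interior.  Age is
continuous (the equations use it linearly, so integer rounding would
change nothing).  One named random stream per channel hangs off the
single integer seed, so adding a channel never perturbs existing draws.

Making FFM latent and deriving resistance guarantees the two-predictor
equation is the true model — the alternative (drawing R independently)
would leave no ground truth to recover.  The construction also reproduces
the key predictor couplings: corr(weight, FFM) ≈ 0.92 emerges from
FM%'s variability (sd(weight) ≈ 8.5 kg follows too).

What the generator does *not* reproduce, and why it matters:

- **Errors-in-variables structure.**  Because the model noise ε sits
  inside the resistance inversion, the *observed* log-index contains
  −ε/39.234.  Regressing the generator's FFM on (weight, log-index) is
  therefore an errors-in-variables problem: the log-index slope
  attenuates to ≈22 (not 39.234) and the apparent residual SD shrinks to
  ≈1.7 kg.  Parameter-recovery experiments therefore use
  `synthesize_response`, which adds fresh noise to the *response* over
  the generated predictor columns — the textbook regression setting in
  which OLS is unbiased.  Pipeline-level results (cross-validated CCC,
  absence of mean bias) are unaffected by the distinction.
- **Derived-channel moments are emergent.**  Weight and resistance are
  not drawn, so their means come out ≈70.8 kg and ≈495 Ω (about 1% and 3%
  above the real-sample summaries); resistance is also more dispersed
  (SD ≈ 100 Ω vs 48.8), which makes the off-the-shelf catalogue equations
  look somewhat worse on synthetic cohorts than on the real population.
  Asymmetric truncation shifts some drawn means slightly (age by
  +0.36 y); tests compare against analytic truncated-normal expectations.
- No ethnicity or body-proportion heterogeneity, no dependence between
  reactance and resistance, and no DXA/scale mass discrepancy (closure is
  exact by construction).

Consequently, green pipeline tests demonstrate internal statistical
correctness — calibration of the tests, recovery of planted structure,
reproducibility — not field validity of any equation on real subjects.

The retest generator perturbs each channel with independent N(0, TEM)
noise per replicate, so the within-pair difference SD is TEM·√2 and the
standard estimator targets the configured TEM (defaults: 3.54 Ω and
0.49 Ω for R and Xc; 0.25, 0.02, 0.25 kg for FM, BMC, LST; 23 pairs).

## Problem sizes and determinism

Simulation-based tests use the study-scale sizes directly (n = 396
cohorts, 264-subject development groups); replicate counts are 100–200
for selection/recovery studies, 2,000 for type-I-error calibration, and
10,000 for limits-of-agreement coverage — sizes at which the binomial
noise of the checked rates is small relative to the asserted bands.  All
randomness flows from explicit integer seeds; hypothesis runs
derandomised.  CLI runs are deterministic given (input file, config,
seed), and repeated runs produce byte-identical outputs.

## Known limitations

- Stepwise inference is reported without post-selection correction (see
  above); the development pipeline mirrors the classical procedure rather
  than modern selective-inference practice, by design.
- The conditional log-transform rule applies one normality gate to both
  series jointly; per-series treatment on real, mixed-scale data is a
  judgement call the package does not attempt.
- Limits of agreement are parametric (1.96·SD); no nonparametric or
  repeated-measures variants.
- The catalogue is restricted to single-frequency, whole-body, adult-male
  applicable equations; no body-fat-percent equations, no multi-frequency
  or segmental models, no pediatric/elderly hydration corrections.
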