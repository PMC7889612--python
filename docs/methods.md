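# Methods

This note records the models behind each module, the parameters that
matter, the calibration and numerical choices, and what the synthetic
cohorts do and do not establish about real data.

## Trajectory model

A case's biomarker path is `x(t) = start + (end − start)·g(t)` on
normalized time `t ∈ [0, 1]`, with `g(0) = 0`, `g(1) = 1`:

| shape        | g(t)                                                        | parameter (default) |
|--------------|-------------------------------------------------------------|---------------------|
| linear       | `t`                                                         | —                   |
| logarithmic  | `ln(1 + kt) / ln(1 + k)`                                    | curvature `k` (99)  |
| logistic     | `(σ(k(t−½)) − σ(−k/2)) / (σ(k/2) − σ(−k/2))`                | steepness `k` (10)  |
| heaviside    | `0` if `t < p`, else `1` (right-continuous at `p`)          | impulse `p`         |

The two-point fit through (start, end) does not pin down the logistic and
logarithmic families; the normalized forms above were chosen because they
anchor both endpoints exactly for every parameter value and make the
curvature/steepness an explicit knob rather than a hidden constant. The
defaults put the logarithmic path well above the linear path (it spends
most of its time near the end value) and the logistic path below it for
`t < ½`, which is what drives the ordering of attenuation ratios across
shapes: trajectories that linger near the end value attenuate least.

Right-continuity of the step ("impulse in the first `p` of the
trajectory" reads as the jump completing within that fraction) means a
uniform-time sample equals the start value with probability exactly `p`.

## Biomarker laws and start-value imputation

Case and control arms are log-normal with shared log-scale SD
`sigma_log` and medians in ratio `median_ratio = 0.85` (the only
distributional facts carried over from the source setting: log-normality
and a 15% control-vs-case median gap). Centile tables are generated from
the laws and the laws re-fit from centiles by regressing `log(value)` on
`Φ⁻¹(percentile)` — exact on noiseless tables, least-squares otherwise.

`sigma_log` defaults to 0.25, which yields a modest baseline association
(per-SD odds ratio ≈ 1.9). This regime matters more than it looks: with a
fixed 15% median gap, a large `sigma_log` makes the raw-scale laws so
heavy-tailed that a uniform-time linear trajectory pushes the simulated
prospective case arm *below* the control mean and the weighted-sampling
ratios turn negative; the attenuation-ratio framework is meaningful in
the near-linear regime where coefficients scale with group separation.

Start-value imputation:

* **weighted sampling** — inverse-CDF draw from the control law
  restricted to `(0, case value)`; distributionally identical to
  rejection sampling (tested by KS against a rejection-sampling oracle)
  but with bounded runtime.
* **percentile matching** — `F_control⁻¹(F_case(case value))`. Pushing
  case draws through this map reproduces the control law exactly, which
  is what makes the Heaviside ratios distribution-free: the case arm
  becomes a `p:(1−p)` control/case mixture and the coefficient scales by
  `1 − p`.
* **percent shift** — multiply by `1 − shift_fraction` (default 0.15).
  With shared `sigma_log`, percentile matching and a 15% shift coincide
  by construction; they differ whenever the arms' shapes differ.

`relative_effect_summary` refits the baseline on every repetition's fresh
draws (the ratio is within-repetition) and shares each repetition's
case-end/control draws across grid cells — statistically equivalent for
the mean ratio and far cheaper. The 95% interval is the empirical
2.5–97.5 percentile across repetitions. Logistic fits standardize the
exposure internally (the MLE is affine-invariant) and flag
(quasi-)separation, non-convergence, or single-class outcomes as
estimation failures; failed repetitions are excluded and counted, and a
cell aborts if more than 10% fail.

## Claims cohort and window designs

One calendar year of synthetic claims for an all-female cohort (sex is
therefore not a feature). Cases deliver in a month uniform over Feb–Dec;
gestation covers the `gestation_months = 9` months up to and including
delivery, so a November delivery is pregnant Feb–Nov and events before
January are simply outside the extract. Two code channels:

* **background codes** (`B00..B19`): Poisson, homogeneous over the year
  and identical for cases and controls (rate 0.6/month) — pure noise;
* **gestational stage codes** (`G00..G09`): code `Gk` can occur only in
  the k-th month after conception, with per-month Poisson rate ramping
  from 0.05 at conception to 1.5 at delivery along a normalized logistic
  curve in gestation progress (center 0.35, steepness 6).

Stage-specific codes are essential, not decorative: if pregnancy codes
were exchangeable, an event-indexed-trained linear model and a
calendar-trained one would rank January patients identically (both count
pregnancy codes) and the two prospective evaluations would coincide.
With stage codes, a model trained on month-of-gestation 6 features has
never seen early-stage codes and misses mid-year deliveries that are in
early pregnancy in January — the mechanism behind the CC-Cohort
collapse. The saturating ramp (rather than a linear-to-delivery ramp)
keeps the event-indexed window informative while its steepness controls
how informative *early* gestation is; steepening it therefore widens the
CC-CC vs CC-Cohort gap instead of degrading both.

Matching is greedy 1:1 exact on (age, region) without replacement;
controls inherit their case's delivery month as baseline. The default
control pool is twice the case count — exact matching from an equal-size
pool loses ~15–20% of cases to stratum imbalance alone, which mirrors
selecting matched controls from a large claims database. Feature
matrices are binary code-occurrence indicators over the patient's single
window month, plus age. Studies split patients 80/20 before windowing
(leakage is asserted), train `n_models = 10` logistic regressions on
bootstrap resamples, and always window the evaluation set under the
evaluation design. Event-indexed windows that would precede the data
year (Feb/Mar deliveries at offset 3) exclude the patient from
event-indexed studies, with a log line. The confusion matrix thresholds
the across-model mean score at 0.5 (configurable).

## Longitudinal cohort and lookback sweep

Yearly exposure `x_it = max(0, m_i + e_it)` with subject means
`m_i ~ N(10, 1.5)` and AR(1) deviations (`ρ = 0.3`, innovation SD 3.8,
stationary SD ≈ 4.0), surveyed 1994–2010. The per-year event hazard is
`expit(−4.9 − 0.05·x_it)` — logit-linear in the *current* year's
exposure only, protective. Events start in the third survey year so
every case has ≥ 2 pre-event surveys; post-event surveys are dropped.
Defaults produce ≈ 2,000 cases per 30,000 subjects.

The variance split is deliberate: the quintile contrast at lookback `L`
captures `corr(Σx, x_baseline)`-type structure, so the within-subject
component decays like `1/√L` (plus autocorrelation) while the persistent
`m_i` component does not decay at all. If subject means dominated the
exposure variance, the top-quintile split would select the same subjects
at every lookback and no decay would be visible; the defaults keep the
persistent spread (SD 1.5) well below the year-to-year spread (SD ≈ 4.0).

Each trial matches every eligible case 1:1 to an event-free control on
(age at baseline, sex); the control's baseline year is implied by the age
match (birth year + case age), which also aligns control baselines with
the case event-year distribution. The effect is the risk difference in
event proportion between the top cumulative-exposure quintile (ties at
the 80th-percentile cut all labeled in) and the remainder, with a
two-sided Welch t-test; a risk difference is the effect measure a t-test
on a binary outcome actually addresses, and an odds-ratio view can be
derived from the same split. Sweeps normalize effects by the mean
absolute 1-year effect of the same sweep (the 1-year mean |normalized
effect| is therefore exactly 1) and apply Benjamini–Hochberg FDR across
the full lookback × trial grid, matching a display in which all plotted
points share one correction.

**Single-cohort caveat.** Repeated matchings of one cohort share that
cohort's chance case-set association. At ~2,000 cases this cohort-level
noise (±0.1–0.2 on the normalized scale) is comparable to the structural
decay between adjacent lookbacks, so a single cohort's per-L curve can be
locally non-monotone even though the expected curve decays. The
acceptance test therefore spreads its 200 trials over eight independent
cohorts, and the null (type-I) calibration draws a fresh cohort per
replicate — with a single cohort the 400-replicate rejection rate is
inflated (~7.5%) for the same reason.

## Repeated-measures cohort and selection schemes

True levels are log-normal (log-SD 0.5) with 2–6 tests per subject; test
values add zero-mean Gaussian noise truncated at zero (the biomarker
cannot be negative), and MI status is Bernoulli, logit-linear in the true
level. Two printed statistics calibrate the generator: mean test result
49.4 mg/dl and mean within-subject sample SD 12.2 mg/dl. Hitting them
takes two corrections that a naive generator misses: the `n−1` sample SD
is biased low by the factor `c4(n)` (≈ 0.92 at n = 4), and truncation at
zero lifts the observed mean while compressing the observed spread for
low-level subjects. The generator solves for the log-normal location and
the per-subject noise scale by a short fixed-point iteration on the
truncated-normal moments, so the *observed* statistics match the targets
(within ~±1% / ±3% across seeds) rather than the latent ones.

Selection schemes model preferential selection **among case exposure
values**: the scheme (largest / smallest / mean / random test) picks the
case's representative value while controls always contribute a random
timepoint. This asymmetry is what produces the reported phenomenon —
applying max/min to both arms merely shrinks the selected-noise variance
(the max of n draws varies less than a single draw) and nudges *both*
ratios slightly above 1, with no preferential direction. Ratios are
reported against the random-timepoint reference.

## Determinism and problem sizes

Every generator and pipeline takes a seed and is bit-reproducible under
it; named sub-streams keep the four generators independent. Analyses at
the reduced problem sizes used throughout (20,000 draws per arm and 100
repetitions for the effect-size grid; 3,000 matched pairs and 10 model
repeats for the window studies; 30,000 subjects, 200 trials for the
lookback sweep) reproduce the qualitative structure stably; the
coefficient *ratios* are insensitive to the per-arm draw count well
below the 150,000-draw full setting.

## What the synthetic cohorts do not show

The generators encode exactly the temporal structure the analyses are
designed to detect; passing tests demonstrate that the estimators recover
known structure, not that any particular real dataset behaves this way.
Real claims data have correlated, non-stationary code streams, coding
practice drift, and enrollment churn; real biomarker trajectories need
not belong to any of the four shape families; real dietary exposures have
measurement error and secular trends that the AR(1) model omits.
Quantities that depend on restricted real datasets (absolute AUROC
levels, the exact selection-scheme ratio range, the exact fraction of
significant lookback trials) are reproduced only as orderings and decay
patterns, never as numbers.
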