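# temporalbias

A simulation toolkit for **temporal bias** in case-control study designs:
the distortion that arises when case observations are anchored to a future
event (a diagnosis, a delivery, a myocardial infarction) so that the
underlying control-to-case trajectory is sampled unevenly in time.

The package is aimed at epidemiologists, biostatisticians and ML
researchers who build risk predictors from observational data and want to
quantify — on synthetic cohorts with *known* ground-truth trajectories —
how much of an observed association or a validation AUROC is an artifact
of event-indexed sampling rather than prospective signal.

## The model

Each case progresses along a trajectory `x(t)` on normalized time
`t ∈ [0, 1]`, from a healthy-era start value `x(0)` to the value `x(1)`
observed at its event. A conventional case-control study measures every
case at `t = 1`; a prospective observer sees `x(T)` with `T ~ U(0, 1)`.
The package provides three linked demonstrations:

1. **Effect-size inflation.** Case and control biomarker levels follow
   log-normal laws (control median 15% below the case median). For each
   simulated case the healthy start value is imputed (truncated draw from
   the control law, percentile matching, or a 15% shift), a trajectory of
   configurable shape (linear / logistic / logarithmic / Heaviside step)
   is laid between start and end, and the case observation is replaced by
   a uniform-time sample. The **relative effect size**

   `ratio = β̂_prospective / β̂_baseline`

   (logistic-regression coefficients of case status on biomarker value)
   measures the attenuation; `ratio = 1` means no temporal bias. For a
   Heaviside trajectory with the impulse in the first fraction `p`, the
   prospective case arm is a `p : (1-p)` mixture of the control and case
   laws, so `ratio ≈ 1 - p` regardless of the biomarker laws.

2. **Prospective prediction collapse.** A one-year synthetic claims
   cohort in which pregnancy-stage codes appear only during gestation.
   Classifiers are trained and evaluated under event-indexed windows (the
   month three months before delivery — unknowable in real time) or a
   calendar-fixed window (January). Training event-indexed and evaluating
   calendar-fixed (CC-Cohort) collapses the AUROC, with false negatives
   concentrated in Oct–Dec deliveries whose January features are
   uninformative.

3. **Lookback-window fragility.** A longitudinal cohort whose yearly
   exposure is protective only through the *current* year's value.
   Matched case-control trials aggregating exposure over lookbacks of
   1–4 years show the association's magnitude and FDR-corrected
   significance decaying as the lookback grows — replication failure by
   study design.

A fourth module shows **measurement-selection bias**: with repeated
biomarker tests per subject (calibrated to a mean test of 49.4 mg/dl and
within-subject SD of 12.2 mg/dl), representing each case by its largest /
smallest / random test moves the fitted association up or down.

## Worked example

```bash
temporalbias trajectory-table --seed 42 --out out/table --preset small
```

fits the full 3-imputation × 6-shape grid (100 repetitions, 20,000 draws
per arm per repetition) and writes `trajectory_table.csv`:

```
             method       shape  shape_param  ratio  ci_lo  ci_hi
  weighted_sampling      linear          NaN  0.133  0.103  0.164
  weighted_sampling logarithmic          NaN  0.696  0.684  0.708
  weighted_sampling   heaviside        0.100  0.798  0.790  0.810
percentile_matching      linear          NaN  0.524  0.507  0.541
percentile_matching logarithmic          NaN  0.808  0.801  0.814
percentile_matching   heaviside        0.100  0.895  0.889  0.900
percentile_matching   heaviside        0.010  0.989  0.987  0.991
percentile_matching   heaviside        0.001  0.999  0.998  0.999
      percent_shift   heaviside        0.001  0.999  0.998  0.999
```

(excerpt). Reading: had the baseline case-control experiment been run
prospectively, a linear trajectory with percentile-matched starts would
have shown only ~52% of the reported effect; reproducing the reported
effect requires a step-function trajectory with the jump in the first
fraction of a percent of the trajectory (`ratio → 1 - p`), i.e. the
assumption that cases' biomarker levels were essentially static until
just before their event.

The same seed drives the other pipelines:

```bash
temporalbias design-study  --seed 42 --out out/design --preset small
# CC-CC:         mean AUROC 0.896
# Cohort-Cohort: mean AUROC 0.708
# CC-Cohort:     mean AUROC 0.509   (272 of 298 eval cases are false negatives)

temporalbias lookback-sweep --seed 42 --out out/lb --preset small
# lookback 1y -> mean |normalized effect| 1.00, 2y -> 0.70, 3y -> 0.64, 4y -> 0.66
```

The event-indexed model is near-perfect under its own evaluation regime
and near-chance when deployed on calendar-anchored data; the lookback
association is strongest at one year and decays (up to single-cohort
noise) as the window widens.

`temporalbias generate` writes all four synthetic input datasets as CSV;
`temporalbias selection-analysis` reports the per-scheme coefficients and
their ratios to random timepoint selection. Every subcommand accepts
`--config` (YAML overrides), `--seed`, `--preset {small,paper}` and
writes a `summary.json` with the config echo, seed, library versions and
wall-clock time.

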