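"""Lookback-window sensitivity of an exposure-outcome association.

Retrospective case-control studies aggregate exposure over a lookback
window ending at the case's event date (controls get an arbitrary matched
baseline).  When the true association is concentrated in the most recent
year, lengthening the lookback dilutes it.  This module computes cumulative
exposures, splits subjects at the top quintile of cumulative consumption,
estimates the top-quintile risk difference with a two-sided t-test, and
sweeps lookback lengths over repeated matchings with Benjamini-Hochberg
FDR correction, normalizing effects to the mean 1-year association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError, MatchingError
from .synthetic_data import LongitudinalCohort

__all__ = [
    "LookbackResult",
    "cumulative_exposure",
    "top_quintile_split",
    "lookback_trial",
    "lookback_sweep",
]


@dataclass(frozen=True)
class LookbackResult:
    """One simulated case-control trial at a fixed lookback length."""

    lookback_years: int
    effect: float  # risk difference: MI proportion, top quintile minus rest
    p_value: float
    trial_index: int = 0
    n_pairs: int = 0
    normalized_effect: float | None = None  # filled in by lookback_sweep
    significant_fdr: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidInputError("p_value must lie in [0, 1]")
        if self.lookback_years < 1:
            raise InvalidInputError("lookback_years must be >= 1")


def cumulative_exposure(subject_exposures, baseline_year: int, lookback_years: int) -> float:
    """Sum of yearly exposures over the window ending at ``baseline_year``.

    ``subject_exposures`` maps survey year -> consumption; the window covers
    ``baseline_year - lookback_years + 1 .. baseline_year`` and every year
    must be present (a missing survey excludes the subject from a trial).
    """
    if lookback_years < 1:
        raise InvalidInputError("lookback_years must be >= 1")
    exp = dict(subject_exposures) if not isinstance(subject_exposures, dict) else subject_exposures
    years = range(baseline_year - lookback_years + 1, baseline_year + 1)
    try:
        return float(sum(exp[y] for y in years))
    except KeyError as missing:
        raise InvalidInputError(f"missing survey year {missing} in lookback span") from None


def top_quintile_split(values) -> np.ndarray:
    """Label 1 for values at or above the 80th-percentile cut, else 0.

    Ties at the cut are all labeled 1, so heavy ties can push the labeled
    fraction above 20%.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise InvalidInputError("need at least 5 values for a quintile split")
    if np.ptp(v) == 0:
        raise InvalidInputError("all values identical; quintile split is degenerate")
    cut = np.quantile(v, 0.8)
    return (v >= cut).astype(int)


class _PreparedCohort:
    """Wide exposure matrix + subject arrays, built once per cohort."""

    def __init__(self, cohort: LongitudinalCohort):
        subj = cohort.subjects.reset_index(drop=True)
        self.year0 = int(cohort.exposures["year"].min())
        self.year1 = int(cohort.exposures["year"].max())
        wide = cohort.exposures.pivot_table(
            index="subject_id", columns="year", values="exposure", aggfunc="first"
        ).reindex(
            index=subj["subject_id"], columns=range(self.year0, self.year1 + 1)
        )
        mat = wide.to_numpy(dtype=float)
        present = ~np.isnan(mat)
        filled = np.where(present, mat, 0.0)
        # cumulative sums with a leading zero column: window sums in O(1)
        self.csum = np.concatenate(
            [np.zeros((len(mat), 1)), np.cumsum(filled, axis=1)], axis=1
        )
        self.cnt = np.concatenate(
            [np.zeros((len(mat), 1), dtype=int), np.cumsum(present, axis=1)], axis=1
        )
        self.birth_year = subj["birth_year"].to_numpy(dtype=int)
        self.sex = subj["sex"].to_numpy()
        ev = subj["event_year"]
        self.event_year = np.where(ev.isna(), -1, ev.fillna(-1).astype(int)).astype(int)
        self.is_case = self.event_year > 0

    def window_sum(self, rows: np.ndarray, baseline: np.ndarray, L: int):
        """(sums, complete) for windows baseline-L+1..baseline per row."""
        j1 = baseline - self.year0 + 1
        j0 = j1 - L
        sums = self.csum[rows, j1] - self.csum[rows, j0]
        n = self.cnt[rows, j1] - self.cnt[rows, j0]
        return sums, n == L


def _match_pairs(
    prep: _PreparedCohort, L: int, rng: np.random.Generator, max_drop_fraction: float = 0.20
):
    """1:1 match each case to an event-free control on (age at baseline, sex).

    The control's baseline year is chosen so its age at baseline equals the
    case's age at event, which also makes control baseline years follow the
    case age/event-year distribution within strata.
    """
    case_rows = np.flatnonzero(prep.is_case & (prep.event_year >= prep.year0 + L - 1))
    ctrl_rows = np.flatnonzero(~prep.is_case)
    if case_rows.size == 0 or ctrl_rows.size == 0:
        raise MatchingError("no eligible cases or controls")

    case_age = prep.event_year[case_rows] - prep.birth_year[case_rows]

    matched_case, matched_ctrl, ctrl_baseline = [], [], []
    for sex in np.unique(prep.sex[case_rows]):
        c_rows = case_rows[prep.sex[case_rows] == sex]
        c_age = case_age[prep.sex[case_rows] == sex]
        pool_rows = ctrl_rows[prep.sex[ctrl_rows] == sex]
        pool_by = prep.birth_year[pool_rows]
        by_lo, by_hi = int(pool_by.min()), int(pool_by.max())
        n_bins = by_hi - by_lo + 1
        pools: list[list[int]] = [[] for _ in range(n_bins)]
        order = rng.permutation(len(pool_rows))
        for k in order:
            pools[pool_by[k] - by_lo].append(int(pool_rows[k]))
        counts = np.array([len(p) for p in pools], dtype=float)

        case_order = rng.permutation(len(c_rows))
        for k in case_order:
            age = int(c_age[k])
            # control baseline b = birth + age must fit a full window
            lo = max(by_lo, prep.year0 + L - 1 - age)
            hi = min(by_hi, prep.year1 - age)
            if hi < lo:
                continue
            seg = counts[lo - by_lo : hi - by_lo + 1]
            total = seg.sum()
            if total <= 0:
                continue
            pick = rng.choice(hi - lo + 1, p=seg / total)
            bin_idx = lo - by_lo + pick
            ctrl = pools[bin_idx].pop()
            counts[bin_idx] -= 1
            matched_case.append(int(c_rows[k]))
            matched_ctrl.append(ctrl)
            ctrl_baseline.append((by_lo + bin_idx) + age)

    n_cases = case_rows.size
    n_dropped = n_cases - len(matched_case)
    if n_dropped > max_drop_fraction * n_cases:
        raise MatchingError(
            f"{n_dropped}/{n_cases} cases unmatched at lookback {L}"
        )
    return (
        np.asarray(matched_case, dtype=int),
        np.asarray(matched_ctrl, dtype=int),
        np.asarray(ctrl_baseline, dtype=int),
    )


def _run_trial(
    prep: _PreparedCohort, L: int, rng: np.random.Generator, trial_index: int
) -> LookbackResult:
    c_rows, k_rows, k_base = _match_pairs(prep, L, rng)
    c_base = prep.event_year[c_rows]
    c_sum, c_ok = prep.window_sum(c_rows, c_base, L)
    k_sum, k_ok = prep.window_sum(k_rows, k_base, L)
    keep = c_ok & k_ok  # drop pairs with incomplete survey coverage
    exposure = np.concatenate([c_sum[keep], k_sum[keep]])
    y = np.concatenate([np.ones(keep.sum()), np.zeros(keep.sum())])
    top = top_quintile_split(exposure).astype(bool)
    effect = float(y[top].mean() - y[~top].mean())
    p = float(stats.ttest_ind(y[top], y[~top], equal_var=False).pvalue)
    return LookbackResult(
        lookback_years=L,
        effect=effect,
        p_value=p,
        trial_index=trial_index,
        n_pairs=int(keep.sum()),
    )


def lookback_trial(
    cohort: LongitudinalCohort, lookback_years: int, seed: int | None = None, trial_index: int = 0
) -> LookbackResult:
    """One matched case-control trial at a single lookback length.

    Cases are first-event subjects (the generator guarantees two pre-event
    surveys); controls are event-free, matched 1:1 on age at baseline and
    sex, with the control baseline year implied by the age match.  The
    effect is the MI-proportion difference between the top cumulative-
    exposure quintile and the rest, with a two-sided Welch t-test p-value.
    """
    if not (1 <= lookback_years <= 4):
        raise InvalidInputError("lookback_years must be in 1..4")
    prep = _PreparedCohort(cohort)
    rng = np.random.default_rng(seed)
    return _run_trial(prep, lookback_years, rng, trial_index)


def lookback_sweep(
    cohort: LongitudinalCohort,
    lookbacks: tuple[int, ...] = (1, 2, 3, 4),
    n_trials: int = 200,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat matched trials across lookback lengths and summarize.

    Returns ``(results, summary)``: one row per trial with the effect, the
    effect normalized by the mean absolute 1-year effect of this same
    sweep, the t-test p-value and the Benjamini-Hochberg significance flag
    (FDR applied across the full lookback x trial grid); and a per-length
    summary with the mean |normalized effect| and significant fraction.
    """
    if n_trials < 2:
        raise InvalidInputError("n_trials must be >= 2")
    if 1 not in lookbacks:
        raise InvalidInputError("lookbacks must include 1 (the normalization anchor)")
    prep = _PreparedCohort(cohort)
    root = np.random.SeedSequence(seed)
    rows = []
    for L in lookbacks:
        for trial, ss in enumerate(root.spawn(n_trials)):
            res = _run_trial(prep, L, np.random.default_rng(ss), trial)
            rows.append(res)

    df = pd.DataFrame(
        {
            "lookback_years": [r.lookback_years for r in rows],
            "trial": [r.trial_index for r in rows],
            "effect": [r.effect for r in rows],
            "p_value": [r.p_value for r in rows],
            "n_pairs": [r.n_pairs for r in rows],
        }
    )
    anchor = df.loc[df["lookback_years"] == 1, "effect"].abs().mean()
    if anchor == 0:
        raise InvalidInputError("mean 1-year effect is zero; cannot normalize")
    df["normalized_effect"] = df["effect"] / anchor
    df["significant_fdr"] = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")[0]

    summary = (
        df.groupby("lookback_years")
        .agg(
            mean_abs_normalized_effect=("normalized_effect", lambda s: s.abs().mean()),
            mean_normalized_effect=("normalized_effect", "mean"),
            frac_significant=("significant_fdr", "mean"),
            frac_p_below_alpha=("p_value", lambda s: (s < alpha).mean()),
        )
        .reset_index()
    )
    return df, summary
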