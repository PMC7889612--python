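"""Synthetic cohorts with known ground-truth temporal structure.

Every downstream analysis in this package runs on data produced here, so
each generator encodes — explicitly and reproducibly — the temporal
structure whose distortion the analyses measure:

* biomarker centile tables for a case and a control arm (log-normal laws
  whose control median sits 15% below the case median);
* an insurance-claims cohort in which pregnancy-stage codes are emitted
  only during the gestation months preceding a delivery, at a rate that
  ramps upward toward the delivery month;
* a longitudinal yearly-exposure cohort in which the event hazard depends
  only on the *current* year's exposure;
* a repeated-biomarker-test cohort with intra-individual measurement noise
  calibrated to an observed mean test result of 49.4 mg/dl and mean
  within-subject SD of 12.2 mg/dl.

All generators are deterministic given ``GeneratorParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

from .errors import InvalidInputError, InvalidParameterError
from .trajectory import LognormalParams

__all__ = [
    "DATA_YEAR",
    "GeneratorParams",
    "CentileTable",
    "ClaimsCohort",
    "LongitudinalCohort",
    "RepeatedMeasuresCohort",
    "make_standin_centiles",
    "gen_claims_cohort",
    "gen_longitudinal_cohort",
    "gen_repeated_measures",
]

#: calendar year covered by the claims extract; months are 1..12 within it
DATA_YEAR = 2015

#: percentile grid used for stand-in centile tables
DEFAULT_PERCENTILES = (0.025, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.975)


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the four generators, with study-condition defaults.

    Biomarker law (mg/dl): ``median_case`` with log-scale SD ``sigma_log``
    shared between arms; the control median is ``median_ratio`` times the
    case median (default 0.85, i.e. a 15% gap).

    Claims cohort: deliveries are uniform over Feb-Dec of the data year;
    pregnancy-stage codes are emitted only in the ``gestation_months``
    preceding (and including) the delivery month.  The per-month Poisson
    rate ramps from ``gestational_rate_base`` at conception to
    ``gestational_rate_peak`` at delivery along a normalized logistic curve
    in gestation progress u: rates stay low before
    ``gestational_ramp_center`` and saturate after it, with
    ``gestational_ramp_steepness`` controlling how sharply early gestation
    becomes informative.  Background codes are emitted homogeneously all
    year for everyone.

    Longitudinal cohort: yearly exposure is a subject mean plus AR(1) noise,
    truncated at 0; the per-year event hazard is logit-linear in the
    *current* year's exposure with slope ``recent_effect`` (negative for a
    protective exposure).

    Repeated measures: ``repeat_noise_sd`` is specified on the observed
    within-subject *sample*-SD scale; the generator divides by the Gaussian
    small-sample bias factor c4(n) so the expected sample SD matches it.
    """

    seed: int | None = None

    # --- biomarker laws ---
    median_case: float = 60.0
    median_ratio: float = 0.85
    sigma_log: float = 0.25
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES

    # --- claims cohort ---
    n_cases: int = 3000
    n_controls: int = 6000  # control pool; 1:1 matching selects from it
    gestation_months: int = 9
    gestational_rate_base: float = 0.05
    gestational_rate_peak: float = 1.5
    gestational_ramp_steepness: float = 6.0
    gestational_ramp_center: float = 0.35
    background_rate: float = 0.6
    n_background_codes: int = 20
    age_min: int = 18
    age_max: int = 44
    n_regions: int = 5

    # --- longitudinal cohort ---
    n_subjects: int = 30_000
    survey_start: int = 1994
    survey_end: int = 2010
    exposure_mean: float = 10.0
    exposure_subject_sd: float = 1.5
    exposure_innovation_sd: float = 3.8
    exposure_autocorr: float = 0.3
    recent_effect: float = -0.05
    event_base_logodds: float = -4.9
    birth_year_min: int = 1930
    birth_year_max: int = 1955

    # --- repeated measures ---
    n_repeat_subjects: int = 5000
    tests_min: int = 2
    tests_max: int = 6
    repeat_noise_sd: float = 12.2
    repeat_mean: float = 49.4
    repeat_sigma_log: float = 0.5
    mi_slope: float = 0.02
    mi_intercept: float = -1.85

    def __post_init__(self) -> None:
        if not (self.median_case > 0):
            raise InvalidParameterError("median_case must be positive")
        if not (0.0 < self.median_ratio < 1.0):
            raise InvalidParameterError("median_ratio must lie in (0, 1)")
        if not (self.sigma_log > 0):
            raise InvalidParameterError("sigma_log must be positive")
        if self.gestation_months > 11:
            raise InvalidParameterError("gestation_months must be <= 11")
        if self.gestation_months < 1:
            raise InvalidParameterError("gestation_months must be >= 1")
        for name in (
            "gestational_rate_base",
            "gestational_rate_peak",
            "background_rate",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.gestational_ramp_steepness <= 0:
            raise InvalidParameterError("gestational_ramp_steepness must be positive")
        if not (0.0 < self.gestational_ramp_center < 1.0):
            raise InvalidParameterError("gestational_ramp_center must lie in (0, 1)")
        if not (0.0 <= self.exposure_autocorr < 1.0):
            raise InvalidParameterError("exposure_autocorr must lie in [0, 1)")
        if not np.isfinite(self.recent_effect):
            raise InvalidParameterError("recent_effect must be finite")
        if self.repeat_noise_sd < 0:
            raise InvalidParameterError("repeat_noise_sd must be >= 0")
        if self.tests_min < 2:
            raise InvalidParameterError("tests_min must be >= 2")
        if self.tests_max < self.tests_min:
            raise InvalidParameterError("tests_max must be >= tests_min")
        if self.survey_end - self.survey_start < 3:
            raise InvalidParameterError("survey span must cover at least 4 years")

    def with_seed(self, seed: int) -> "GeneratorParams":
        return replace(self, seed=seed)


def _rng(params: GeneratorParams, stream: str) -> np.random.Generator:
    """Named sub-stream so each generator is independent of the others."""
    if params.seed is None:
        return np.random.default_rng()
    tag = int.from_bytes(stream.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([params.seed, tag]))


# ---------------------------------------------------------------------------
# centile tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CentileTable:
    """Percentile -> biomarker value mapping for one study arm."""

    percentiles: tuple[float, ...]
    values: tuple[float, ...]
    arm: str  # "case" | "control"

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if p.size != v.size or p.size < 3:
            raise InvalidInputError("centile table needs >= 3 matched points")
        if not (np.all(p > 0) and np.all(p < 1) and np.all(np.diff(p) > 0)):
            raise InvalidInputError("percentiles must be strictly increasing in (0,1)")
        if not (np.all(v > 0) and np.all(np.diff(v) > 0)):
            raise InvalidInputError("values must be positive and strictly increasing")
        if self.arm not in ("case", "control"):
            raise InvalidInputError("arm must be 'case' or 'control'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"percentile": self.percentiles, "value": self.values, "arm": self.arm}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, arm: str) -> "CentileTable":
        sub = df[df["arm"] == arm].sort_values("percentile")
        return cls(
            percentiles=tuple(sub["percentile"].to_numpy(dtype=float)),
            values=tuple(sub["value"].to_numpy(dtype=float)),
            arm=arm,
        )


def make_standin_centiles(
    params: GeneratorParams,
) -> tuple[CentileTable, CentileTable]:
    """Centile tables of two log-normal laws differing only in median.

    The case arm has median ``median_case``; the control arm's median is
    ``median_ratio`` times that; both share ``sigma_log``.  These stand in
    for published case/control biomarker centiles: the median gap and
    log-normality are the only distributional facts carried over, so the
    arms are identical up to a multiplicative shift.
    """
    if params.median_case <= 0 or params.sigma_log <= 0:
        raise InvalidParameterError("median and sigma must be positive")
    p = np.asarray(params.percentiles, dtype=float)
    z = stats.norm.ppf(p)
    case_vals = params.median_case * np.exp(params.sigma_log * z)
    ctrl_vals = params.median_ratio * case_vals
    return (
        CentileTable(tuple(p), tuple(case_vals), "case"),
        CentileTable(tuple(p), tuple(ctrl_vals), "control"),
    )


def standin_laws(params: GeneratorParams) -> tuple[LognormalParams, LognormalParams]:
    """The (case, control) log-normal laws behind :func:`make_standin_centiles`."""
    mu_case = float(np.log(params.median_case))
    return (
        LognormalParams(mu_case, params.sigma_log),
        LognormalParams(mu_case + float(np.log(params.median_ratio)), params.sigma_log),
    )


# ---------------------------------------------------------------------------
# claims cohort
# ---------------------------------------------------------------------------

@dataclass
class ClaimsCohort:
    """Synthetic one-year claims extract (all-female delivery cohort).

    ``patients``: patient_id, age, region, delivery_month (Int64, NA for
    controls; months are 1..12 within :data:`DATA_YEAR`, deliveries Feb-Dec).
    ``events``: patient_id, month, code, code_class (background|gestational).
    """

    patients: pd.DataFrame
    events: pd.DataFrame

    @property
    def vocabulary(self) -> list[str]:
        return sorted(self.events["code"].unique())

    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pats = self.patients.copy()
        pats["delivery_month"] = _month_to_iso(pats["delivery_month"])
        pats.to_csv(directory / "patients.csv", index=False)
        evs = self.events.copy()
        evs["month"] = _month_to_iso(evs["month"])
        evs.to_csv(directory / "events.csv", index=False)

    @classmethod
    def from_csv(cls, directory) -> "ClaimsCohort":
        directory = Path(directory)
        pats = pd.read_csv(directory / "patients.csv")
        pats["delivery_month"] = _iso_to_month(pats["delivery_month"])
        evs = pd.read_csv(directory / "events.csv")
        evs["month"] = _iso_to_month(evs["month"]).astype(int)
        return cls(patients=pats, events=evs)


def _month_to_iso(months: pd.Series) -> pd.Series:
    m = pd.array(months, dtype="Int64")
    out = pd.Series(
        [f"{DATA_YEAR}-{int(v):02d}" if pd.notna(v) else "" for v in m],
        index=months.index if isinstance(months, pd.Series) else None,
    )
    return out


def _iso_to_month(col: pd.Series) -> pd.Series:
    def parse(v):
        if pd.isna(v) or v == "":
            return pd.NA
        return int(str(v).split("-")[1])

    return pd.Series([parse(v) for v in col], index=col.index, dtype="Int64")


def _codes(prefix: str, indices: np.ndarray) -> np.ndarray:
    """Zero-padded code strings like ``B07``; handles empty index arrays."""
    if indices.size == 0:
        return np.empty(0, dtype="<U4")
    return np.char.add(prefix, np.char.zfill(indices.astype(str), 2))


def gen_claims_cohort(params: GeneratorParams) -> ClaimsCohort:
    """Generate the delivery-prediction claims cohort.

    Cases deliver in a month drawn uniformly from Feb-Dec; pregnancy-stage
    codes ``G00..Gk`` (k = gestation_months) are emitted only while
    pregnant, each code tied to one month-of-gestation, at a Poisson rate
    ramping (saturating logistic in gestation progress) from
    ``gestational_rate_base`` at conception to ``gestational_rate_peak`` at
    delivery.  Stage months falling before January of the data year are
    simply unobserved (the extract covers one calendar year).  Background
    codes ``B00..`` occur homogeneously for cases and controls alike.
    """
    rng = _rng(params, "claims")
    n_case, n_ctrl = params.n_cases, params.n_controls
    if n_case < 1 or n_ctrl < 1:
        raise InvalidParameterError("cohort sizes must be >= 1")
    n = n_case + n_ctrl

    ages = rng.integers(params.age_min, params.age_max + 1, size=n)
    regions = rng.integers(0, params.n_regions, size=n)
    delivery = np.full(n, -1, dtype=int)
    delivery[:n_case] = rng.integers(2, 13, size=n_case)  # Feb..Dec uniform

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": ages,
            "region": [f"R{r}" for r in regions],
            "delivery_month": pd.array(
                [m if m > 0 else pd.NA for m in delivery], dtype="Int64"
            ),
        }
    )

    # background events: homogeneous over the 12 observed months
    bg_counts = rng.poisson(params.background_rate * 12, size=n)
    bg_pid = np.repeat(np.arange(n), bg_counts)
    total_bg = int(bg_counts.sum())
    bg_month = rng.integers(1, 13, size=total_bg)
    bg_code = rng.integers(0, params.n_background_codes, size=total_bg)

    # gestational events: stage s = months since conception (0..gestation)
    g = params.gestation_months
    stages = np.arange(g + 1)
    case_idx = np.arange(n_case)
    months_mat = delivery[:n_case, None] - g + stages[None, :]  # (n_case, g+1)
    progress = stages / g
    s, c = params.gestational_ramp_steepness, params.gestational_ramp_center
    lo, hi = expit(-s * c), expit(s * (1.0 - c))
    ramp = (expit(s * (progress - c)) - lo) / (hi - lo)
    rates = params.gestational_rate_base + (
        params.gestational_rate_peak - params.gestational_rate_base
    ) * ramp
    observed = months_mat >= 1  # extract starts in January
    counts = rng.poisson(np.where(observed, rates[None, :], 0.0))
    flat = counts.ravel()
    keep = flat > 0
    ge_pid = np.repeat(np.repeat(case_idx, g + 1)[keep], flat[keep])
    ge_month = np.repeat(months_mat.ravel()[keep], flat[keep])
    ge_stage = np.repeat(np.tile(stages, n_case)[keep], flat[keep])

    events = pd.DataFrame(
        {
            "patient_id": np.concatenate([bg_pid, ge_pid]),
            "month": np.concatenate([bg_month, ge_month]).astype(int),
            "code": np.concatenate(
                [
                    _codes("B", bg_code),
                    _codes("G", ge_stage),
                ]
            ),
            "code_class": np.concatenate(
                [
                    np.full(len(bg_pid), "background"),
                    np.full(len(ge_pid), "gestational"),
                ]
            ),
        }
    ).sort_values(["patient_id", "month"], kind="stable", ignore_index=True)

    return ClaimsCohort(patients=patients, events=events)


# ---------------------------------------------------------------------------
# longitudinal cohort
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalCohort:
    """Yearly-exposure cohort with first-event years.

    ``subjects``: subject_id, sex, birth_year, event_year (Int64, NA if no
    event).  ``exposures``: subject_id, year, exposure (one row per
    subject-year; cases stop being surveyed after their event year).
    """

    subjects: pd.DataFrame
    exposures: pd.DataFrame

    def to_csv(self, path) -> None:
        merged = self.exposures.merge(self.subjects, on="subject_id")
        merged.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LongitudinalCohort":
        df = pd.read_csv(path)
        df["event_year"] = pd.array(df["event_year"], dtype="Int64")
        subjects = (
            df[["subject_id", "sex", "birth_year", "event_year"]]
            .drop_duplicates("subject_id")
            .reset_index(drop=True)
        )
        exposures = df[["subject_id", "year", "exposure"]].reset_index(drop=True)
        return cls(subjects=subjects, exposures=exposures)


def gen_longitudinal_cohort(params: GeneratorParams) -> LongitudinalCohort:
    """Generate the yearly-exposure cohort with a recent-year event effect.

    Exposure in year t is ``max(0, m_i + e_t)`` with subject mean m_i ~
    Normal(exposure_mean, exposure_subject_sd) and e_t a stationary AR(1)
    process.  The event hazard in year t is
    ``expit(event_base_logodds + recent_effect * x_t)`` — the association
    is wholly concentrated in the current year's exposure.  Events start in
    the third survey year, so every case has at least two pre-event
    surveys; post-event surveys are dropped.
    """
    rng = _rng(params, "longitudinal")
    n = params.n_subjects
    years = np.arange(params.survey_start, params.survey_end + 1)
    T = len(years)

    means = np.maximum(
        rng.normal(params.exposure_mean, params.exposure_subject_sd, size=n), 0.0
    )
    rho = params.exposure_autocorr
    innov_sd = params.exposure_innovation_sd
    e = np.empty((n, T))
    stat_sd = innov_sd / np.sqrt(1.0 - rho**2) if innov_sd > 0 else 0.0
    e[:, 0] = rng.normal(0.0, stat_sd, size=n) if stat_sd > 0 else 0.0
    shocks = rng.normal(0.0, innov_sd, size=(n, T - 1)) if innov_sd > 0 else np.zeros((n, T - 1))
    for t in range(1, T):
        e[:, t] = rho * e[:, t - 1] + shocks[:, t - 1]
    x = np.maximum(means[:, None] + e, 0.0)

    hazard = expit(params.event_base_logodds + params.recent_effect * x)
    hazard[:, :2] = 0.0  # events begin in the third survey year
    event_draws = rng.uniform(size=(n, T)) < hazard
    has_event = event_draws.any(axis=1)
    first_idx = np.where(has_event, event_draws.argmax(axis=1), -1)
    event_year = np.where(has_event, years[0] + first_idx, -1)

    subjects = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "sex": "F",
            "birth_year": rng.integers(
                params.birth_year_min, params.birth_year_max + 1, size=n
            ),
            "event_year": pd.array(
                [y if y > 0 else pd.NA for y in event_year], dtype="Int64"
            ),
        }
    )

    # long format; drop surveys after the event year
    sid = np.repeat(np.arange(n), T)
    yr = np.tile(years, n)
    exp_flat = x.ravel()
    last = np.where(has_event, event_year, years[-1])
    keep = yr <= np.repeat(last, T)
    exposures = pd.DataFrame(
        {"subject_id": sid[keep], "year": yr[keep], "exposure": exp_flat[keep]}
    )
    return LongitudinalCohort(subjects=subjects, exposures=exposures)


# ---------------------------------------------------------------------------
# repeated measures
# ---------------------------------------------------------------------------

def _c4(n: np.ndarray) -> np.ndarray:
    """Expected value of the sample SD of n iid N(0,1) draws (n-1 denom)."""
    n = np.asarray(n, dtype=float)
    return np.sqrt(2.0 / (n - 1.0)) * np.exp(gammaln(n / 2.0) - gammaln((n - 1.0) / 2.0))


@dataclass
class RepeatedMeasuresCohort:
    """Repeated biomarker tests per subject with a latent true level.

    ``measurements``: subject_id, test_value (mg/dl), one row per test.
    ``subjects``: subject_id, true_level, mi_status.
    """

    subjects: pd.DataFrame
    measurements: pd.DataFrame

    def measurements_by_subject(self) -> pd.core.groupby.SeriesGroupBy:
        return self.measurements.groupby("subject_id")["test_value"]

    def to_csv(self, path) -> None:
        merged = self.measurements.merge(self.subjects, on="subject_id")
        merged.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RepeatedMeasuresCohort":
        df = pd.read_csv(path)
        subjects = (
            df[["subject_id", "true_level", "mi_status"]]
            .drop_duplicates("subject_id")
            .reset_index(drop=True)
        )
        measurements = df[["subject_id", "test_value"]].reset_index(drop=True)
        return cls(subjects=subjects, measurements=measurements)


def _truncnorm_at_zero(
    loc: np.ndarray, scale: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Normal(loc, scale) conditioned on being positive, via inverse CDF."""
    if np.all(scale == 0):
        return loc.copy()
    lo = stats.norm.cdf(-loc / np.where(scale > 0, scale, 1.0))
    u = rng.uniform(lo, 1.0)
    draws = loc + scale * stats.norm.ppf(u)
    return np.where(scale > 0, draws, loc)


def _truncnorm_moments(loc: np.ndarray, scale: np.ndarray):
    """Mean and SD of Normal(loc, scale) conditioned on being positive."""
    safe = np.where(scale > 0, scale, 1.0)
    alpha = -loc / safe
    lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)  # inverse Mills ratio
    mean = loc + safe * lam
    var = safe**2 * (1.0 + alpha * lam - lam**2)
    mean = np.where(scale > 0, mean, loc)
    sd = np.where(scale > 0, np.sqrt(np.maximum(var, 0.0)), 0.0)
    return mean, sd


def gen_repeated_measures(params: GeneratorParams) -> RepeatedMeasuresCohort:
    """Generate the repeated-test cohort.

    True levels are log-normal; each subject gets a uniform number of tests
    in [tests_min, tests_max]; test values are the true level plus Gaussian
    noise truncated at 0.  Because truncation lifts the observed mean and
    compresses the observed spread — and the n-1 sample SD is biased low by
    the factor c4(n) at few tests — the generator calibrates itself: it
    solves (by fixed-point iteration on the truncated-normal moments) for
    the log-normal location and the per-subject noise scale such that the
    observed grand mean of tests equals ``repeat_mean`` and the expected
    within-subject sample SD equals ``repeat_noise_sd``.  MI status is
    Bernoulli with logit-linear dependence on the true level.
    """
    rng = _rng(params, "repeated")
    n = params.n_repeat_subjects
    s = params.repeat_sigma_log
    z = rng.standard_normal(n)
    n_tests = rng.integers(params.tests_min, params.tests_max + 1, size=n)
    c4 = _c4(n_tests)

    mu = np.log(params.repeat_mean) - s**2 / 2.0
    if params.repeat_noise_sd > 0:
        noise_scale = np.full(n, params.repeat_noise_sd) / c4
        for _ in range(4):
            true_level = np.exp(mu + s * z)
            _, sd_obs = _truncnorm_moments(true_level, noise_scale)
            noise_scale *= params.repeat_noise_sd / np.maximum(c4 * sd_obs, 1e-12)
            mean_obs, _ = _truncnorm_moments(true_level, noise_scale)
            grand = np.average(mean_obs, weights=n_tests)
            mu += np.log(params.repeat_mean / grand)
        true_level = np.exp(mu + s * z)
    else:
        true_level = np.exp(mu + s * z)
        noise_scale = np.zeros(n)

    sid = np.repeat(np.arange(n), n_tests)
    locs = np.repeat(true_level, n_tests)
    scales = np.repeat(noise_scale, n_tests)
    values = _truncnorm_at_zero(locs, scales, rng)

    mi_p = expit(params.mi_intercept + params.mi_slope * true_level)
    mi_status = (rng.uniform(size=n) < mi_p).astype(int)

    subjects = pd.DataFrame(
        {"subject_id": np.arange(n), "true_level": true_level, "mi_status": mi_status}
    )
    measurements = pd.DataFrame({"subject_id": sid, "test_value": values})
    return RepeatedMeasuresCohort(subjects=subjects, measurements=measurements)
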