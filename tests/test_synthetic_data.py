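"""Generator contracts: distributional structure, invariants, determinism."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from temporalbias import (
    GeneratorParams,
    InvalidParameterError,
    gen_claims_cohort,
    gen_longitudinal_cohort,
    gen_repeated_measures,
    intra_individual_variation,
    make_standin_centiles,
)


class TestGeneratorParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(median_case=-1.0),
            dict(median_ratio=1.2),
            dict(sigma_log=0.0),
            dict(gestation_months=12),
            dict(background_rate=-0.1),
            dict(exposure_autocorr=1.0),
            dict(tests_min=1),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            GeneratorParams(**kwargs)


class TestStandinCentiles:
    def test_median_gap_and_quantiles(self):
        params = GeneratorParams(
            median_case=60.0, sigma_log=1.0, percentiles=(0.025, 0.5, 0.975)
        )
        case_t, ctrl_t = make_standin_centiles(params)
        i_med = case_t.percentiles.index(0.5)
        assert case_t.values[i_med] == pytest.approx(60.0)
        assert ctrl_t.values[i_med] == pytest.approx(51.0)
        # closed-form log-normal quantile, cross-checked vs scipy's inverse CDF
        i_hi = case_t.percentiles.index(0.975)
        z975 = stats.norm.ppf(0.975)
        assert case_t.values[i_hi] == pytest.approx(60.0 * np.exp(z975), rel=1e-12)
        assert case_t.values[i_hi] == pytest.approx(
            stats.lognorm.ppf(0.975, s=1.0, scale=60.0), rel=1e-9
        )


class TestClaimsGenerator:
    def test_controls_emit_no_gestational_codes(self, claims_cohort):
        ctrl_ids = claims_cohort.patients.loc[
            claims_cohort.patients["delivery_month"].isna(), "patient_id"
        ]
        gest = claims_cohort.events[claims_cohort.events["code_class"] == "gestational"]
        assert not gest["patient_id"].isin(set(ctrl_ids)).any()

    def test_gestational_events_confined_to_gestation_span(self, claims_cohort):
        """November delivery with 9-month gestation: events only in Feb-Nov."""
        merged = claims_cohort.events.merge(
            claims_cohort.patients[["patient_id", "delivery_month"]], on="patient_id"
        )
        gest = merged[merged["code_class"] == "gestational"]
        delivery = gest["delivery_month"].astype(int)
        assert (gest["month"] <= delivery).all()
        assert (gest["month"] >= delivery - 9).all()
        nov = gest[delivery == 11]
        assert nov["month"].between(2, 11).all()

    def test_delivery_months_uniform_feb_to_dec(self):
        params = GeneratorParams(seed=7, n_cases=10_000, n_controls=10)
        cohort = gen_claims_cohort(params)
        months = cohort.patients["delivery_month"].dropna().astype(int)
        counts = months.value_counts().reindex(range(2, 13), fill_value=0)
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01

    def test_gestation_longer_than_eleven_months_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_claims_cohort(GeneratorParams(gestation_months=12))

    def test_csv_roundtrip(self, claims_cohort, tmp_path):
        claims_cohort.to_csv(tmp_path / "claims")
        back = type(claims_cohort).from_csv(tmp_path / "claims")
        pd.testing.assert_frame_equal(back.patients, claims_cohort.patients)
        pd.testing.assert_frame_equal(back.events, claims_cohort.events)


class TestLongitudinalGenerator:
    def test_null_effect_has_no_exposure_event_association(self):
        """With recent_effect = 0 the fitted log-OR is within 3 SE of zero."""
        params = GeneratorParams(seed=13, n_subjects=8000, recent_effect=0.0)
        cohort = gen_longitudinal_cohort(params)
        merged = cohort.exposures.merge(cohort.subjects, on="subject_id")
        eligible = merged[merged["year"] >= params.survey_start + 2]
        y = (
            eligible["event_year"].notna()
            & (eligible["event_year"] == eligible["year"])
        ).to_numpy(dtype=float)
        x = eligible["exposure"].to_numpy()
        res = sm.Logit(y, sm.add_constant((x - x.mean()) / x.std())).fit(disp=0)
        assert abs(res.params[1] / res.bse[1]) < 3.0

    def test_high_autocorrelation_shows_in_sample_acf(self):
        params = GeneratorParams(
            seed=19, n_subjects=700, exposure_autocorr=0.99,
            exposure_subject_sd=0.0, recent_effect=0.0,
        )
        cohort = gen_longitudinal_cohort(params)
        wide = cohort.exposures.pivot(index="subject_id", columns="year", values="exposure")
        full = wide.dropna().to_numpy()
        a = full[:, :-1].ravel()
        b = full[:, 1:].ravel()
        acf1 = np.corrcoef(a - a.mean(), b - b.mean())[0, 1]
        assert acf1 > 0.9

    def test_protective_effect_lowers_case_event_year_exposure(self):
        params = GeneratorParams(seed=23, n_subjects=10_000)
        assert params.recent_effect < 0
        cohort = gen_longitudinal_cohort(params)
        merged = cohort.exposures.merge(cohort.subjects, on="subject_id")
        case_event_rows = merged["event_year"].notna() & (
            merged["event_year"] == merged["year"]
        )
        ctrl_rows = merged["event_year"].isna()
        assert (
            merged.loc[case_event_rows, "exposure"].mean()
            < merged.loc[ctrl_rows, "exposure"].mean()
        )

    def test_cases_have_two_pre_event_surveys(self):
        params = GeneratorParams(seed=29, n_subjects=5000)
        cohort = gen_longitudinal_cohort(params)
        cases = cohort.subjects[cohort.subjects["event_year"].notna()]
        merged = cohort.exposures.merge(cases, on="subject_id")
        pre = merged[merged["year"] < merged["event_year"]]
        assert (pre.groupby("subject_id")["year"].count() >= 2).all()
        assert (cases["event_year"] >= params.survey_start + 2).all()


class TestRepeatedMeasuresGenerator:
    def test_calibration_targets_met(self, repeated_cohort, default_params):
        """Observed grand mean ~49.4 mg/dl and within-subject SD ~12.2 mg/dl."""
        within_sd, grand_mean = intra_individual_variation(repeated_cohort)
        assert grand_mean == pytest.approx(default_params.repeat_mean, rel=0.02)
        assert within_sd == pytest.approx(default_params.repeat_noise_sd, rel=0.05)

    def test_zero_noise_gives_identical_tests(self):
        params = GeneratorParams(seed=3, n_repeat_subjects=200, repeat_noise_sd=0.0)
        cohort = gen_repeated_measures(params)
        spread = cohort.measurements.groupby("subject_id")["test_value"].agg(np.ptp)
        assert (spread == 0.0).all()

    def test_measurement_count(self):
        params = GeneratorParams(seed=5, n_repeat_subjects=5000, tests_min=4, tests_max=4)
        cohort = gen_repeated_measures(params)
        assert len(cohort.measurements) == 20_000

    def test_measurements_strictly_positive(self, repeated_cohort):
        assert (cohort_values := repeated_cohort.measurements["test_value"]).min() > 0
        assert np.isfinite(cohort_values).all()


class TestDeterminism:
    @pytest.mark.parametrize(
        "gen",
        [gen_claims_cohort, gen_longitudinal_cohort, gen_repeated_measures],
        ids=["claims", "longitudinal", "repeated"],
    )
    def test_same_seed_bitwise_identical_different_seed_not(self, gen):
        params = GeneratorParams(
            seed=11, n_cases=200, n_controls=200, n_subjects=500, n_repeat_subjects=200
        )
        a = gen(params)
        b = gen(replace(params))
        c = gen(replace(params, seed=12))
        frames = lambda coh: [  # noqa: E731
            getattr(coh, name)
            for name in ("patients", "events", "subjects", "exposures", "measurements")
            if hasattr(coh, name)
        ]
        for fa, fb in zip(frames(a), frames(b)):
            pd.testing.assert_frame_equal(fa, fb)
        assert any(
            not fa.equals(fc) for fa, fc in zip(frames(a), frames(c))
        )
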