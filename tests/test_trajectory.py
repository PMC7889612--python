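"""Trajectory shapes, log-normal centile fits, and start-value imputation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from temporalbias import (
    CentileTable,
    GeneratorParams,
    ImputationMethod,
    InvalidInputError,
    LognormalParams,
    TrajectorySpec,
    fit_lognormal_from_centiles,
    impute_start_value,
    make_standin_centiles,
    sample_case_observation,
    trajectory_value,
)

GRID = (0.025, 0.25, 0.5, 0.75, 0.975)


def _table_from_law(mu, sigma, grid=GRID, arm="case", noise=None, rng=None):
    vals = np.exp(mu + sigma * stats.norm.ppf(grid))
    if noise is not None:
        vals = vals * np.exp(rng.normal(0.0, noise, size=len(vals)))
        vals = np.sort(vals)
    return CentileTable(tuple(grid), tuple(vals), arm)


class TestFitLognormal:
    @pytest.mark.parametrize("mu,sigma", [(4.0, 1.0), (3.8, 0.9), (0.5, 0.2)])
    def test_exact_quantiles_recovered(self, mu, sigma):
        fit = fit_lognormal_from_centiles(_table_from_law(mu, sigma))
        assert fit.mu == pytest.approx(mu, abs=1e-9)
        assert fit.sigma == pytest.approx(sigma, abs=1e-9)

    def test_perturbed_quantiles_recovered_approximately(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            fit = fit_lognormal_from_centiles(
                _table_from_law(3.8, 0.9, noise=0.01, rng=rng)
            )
            assert fit.mu == pytest.approx(3.8, abs=0.05)
            assert fit.sigma == pytest.approx(0.9, abs=0.05)

    def test_roundtrip_through_standin_tables(self, default_params):
        case_t, ctrl_t = make_standin_centiles(default_params)
        case = fit_lognormal_from_centiles(case_t)
        ctrl = fit_lognormal_from_centiles(ctrl_t)
        assert case.median == pytest.approx(default_params.median_case, rel=1e-9)
        assert ctrl.median / case.median == pytest.approx(
            default_params.median_ratio, rel=1e-9
        )
        assert case.sigma == pytest.approx(default_params.sigma_log, abs=1e-9)

    def test_degenerate_tables_rejected(self):
        class TwoPoint:
            percentiles = (0.25, 0.75)
            values = (10.0, 20.0)

        with pytest.raises(InvalidInputError):
            CentileTable((0.25, 0.5, 0.75), (50.0, 50.0, 50.0), "case")
        with pytest.raises(InvalidInputError):
            fit_lognormal_from_centiles(TwoPoint())


class TestTrajectoryValue:
    @pytest.mark.parametrize(
        "spec,t,expected",
        [
            (TrajectorySpec(10, 20, "linear"), 0.5, 15.0),
            (TrajectorySpec(10, 20, "heaviside", 0.1), 0.05, 10.0),
            (TrajectorySpec(10, 20, "heaviside", 0.1), 0.10, 20.0),  # right-continuous
            (
                TrajectorySpec(10, 20, "logarithmic", 99.0),
                0.5,
                10.0 + 10.0 * np.log(50.5) / np.log(100.0),
            ),
        ],
    )
    def test_closed_form_values(self, spec, t, expected):
        assert trajectory_value(spec, t) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_time_rejected(self):
        spec = TrajectorySpec(10, 20, "linear")
        for t in (-0.01, 1.01):
            with pytest.raises(InvalidInputError):
                trajectory_value(spec, t)

    @settings(derandomize=True, max_examples=200)
    @given(
        start=st.floats(0.1, 100.0),
        end=st.floats(0.1, 100.0),
        shape=st.sampled_from(["linear", "logistic", "logarithmic", "heaviside"]),
        param=st.floats(0.01, 0.99),
    )
    def test_endpoints_anchored_and_monotone(self, start, end, shape, param):
        """Every shape hits start at t=0 and end at t=1; non-decreasing if start<=end."""
        shape_param = param if shape == "heaviside" else 1.0 + 30.0 * param
        spec = TrajectorySpec(start, end, shape, shape_param)
        t = np.linspace(0.0, 1.0, 101)
        v = trajectory_value(spec, t)
        assert v[0] == pytest.approx(start, rel=1e-9)
        assert v[-1] == pytest.approx(end, rel=1e-9)
        if start <= end:
            assert np.all(np.diff(v) >= -1e-9 * max(1.0, end))

    def test_logarithmic_dominates_linear_dominates_early_logistic(self):
        """Shape ordering that drives the relative-effect ordering downstream."""
        t = np.linspace(0.0, 1.0, 51)
        lin = trajectory_value(TrajectorySpec(10, 20, "linear"), t)
        log_ = trajectory_value(TrajectorySpec(10, 20, "logarithmic", 99.0), t)
        logi = trajectory_value(TrajectorySpec(10, 20, "logistic", 10.0), t)
        assert np.all(log_ >= lin - 1e-9)
        early = t < 0.5
        assert np.all(lin[early] >= logi[early] - 1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidInputError):
            TrajectorySpec(10, 20, "heaviside")  # missing impulse fraction
        with pytest.raises(InvalidInputError):
            TrajectorySpec(10, 20, "heaviside", 1.5)
        with pytest.raises(InvalidInputError):
            TrajectorySpec(-1, 20, "linear")
        with pytest.raises(InvalidInputError):
            TrajectorySpec(10, 20, "parabola")


class TestImputeStartValue:
    def test_percent_shift_is_fifteen_percent_by_default(self, laws):
        case, ctrl = laws
        got = impute_start_value(100.0, ctrl, case, ImputationMethod("percent_shift"))
        assert got == pytest.approx(85.0)

    def test_percentile_matching_maps_median_to_median(self):
        # distinct sigmas so the mapping is not a constant rescaling
        case = LognormalParams(mu=np.log(60.0), sigma=1.0)
        ctrl = LognormalParams(mu=np.log(51.0), sigma=0.7)
        got = impute_start_value(60.0, ctrl, case, ImputationMethod("percentile_matching"))
        assert got == pytest.approx(51.0, rel=1e-9)

    def test_percentile_matching_pushforward_equals_control_law(self, laws):
        """Mapping case draws through percentile matching recovers the control law."""
        case, ctrl = laws
        rng = np.random.default_rng(17)
        ends = case.rvs(10_000, rng)
        starts = np.array(
            [
                impute_start_value(x, ctrl, case, ImputationMethod("percentile_matching"))
                for x in ends[:200]
            ]
        )
        # vectorized path for the full sample
        from temporalbias.trajectory import _impute_start_array

        starts_full = _impute_start_array(
            ends, ctrl, case, ImputationMethod("percentile_matching"), rng
        )
        np.testing.assert_allclose(starts_full[:200], starts, rtol=1e-9)
        ks = stats.kstest(
            np.log(starts_full), "norm", args=(ctrl.mu, ctrl.sigma)
        )
        assert ks.pvalue > 0.01

    def test_weighted_sampling_matches_rejection_oracle(self, laws):
        """Truncated inverse-CDF draws equal rejection sampling in law."""
        case, ctrl = laws
        case_value = 60.0
        rng = np.random.default_rng(23)
        from temporalbias.trajectory import _impute_start_array

        draws = _impute_start_array(
            np.full(10_000, case_value), ctrl, case,
            ImputationMethod("weighted_sampling"), rng,
        )
        assert np.all(draws < case_value)

        # independent oracle: naive rejection sampling from the control law
        oracle = []
        while len(oracle) < 10_000:
            batch = ctrl.rvs(20_000, rng)
            oracle.extend(batch[batch < case_value].tolist())
        oracle = np.asarray(oracle[:10_000])
        ks = stats.ks_2samp(draws, oracle)
        assert ks.pvalue > 0.01

    def test_non_positive_case_value_rejected(self, laws):
        case, ctrl = laws
        with pytest.raises(InvalidInputError):
            impute_start_value(0.0, ctrl, case, ImputationMethod("percent_shift"))

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidInputError):
            ImputationMethod("quantile_hopping")


class TestSampleCaseObservation:
    def test_heaviside_start_fraction_matches_impulse(self):
        spec = TrajectorySpec(10, 20, "heaviside", 0.2)
        rng = np.random.default_rng(31)
        draws = np.array([sample_case_observation(spec, rng) for _ in range(20_000)])
        frac_start = np.mean(draws == 10.0)
        se = np.sqrt(0.2 * 0.8 / 20_000)
        assert abs(frac_start - 0.2) < 3 * se

    def test_degenerate_trajectory_is_constant(self):
        spec = TrajectorySpec(42.0, 42.0, "linear")
        rng = np.random.default_rng(3)
        assert all(sample_case_observation(spec, rng) == 42.0 for _ in range(50))

    def test_linear_sample_mean_is_midpoint(self):
        spec = TrajectorySpec(1.0, 2.0, "linear")
        rng = np.random.default_rng(7)
        draws = np.array([sample_case_observation(spec, rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(1.5, abs=0.01)
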