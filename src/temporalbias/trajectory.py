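"""Control-to-case biomarker trajectories.

A case observed at its event sits at the end of a hidden trajectory that
began in the control population.  This module represents that trajectory on
normalized time t in [0, 1]: it fits log-normal laws to published centile
tables, imputes a healthy-era ("start") value for each case, interpolates
start-to-end paths of several functional forms, and draws uniformly-timed
observations along the path — the building blocks for re-estimating an
association as if the study had been run prospectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "LognormalParams",
    "TrajectorySpec",
    "ImputationMethod",
    "fit_lognormal_from_centiles",
    "impute_start_value",
    "trajectory_value",
    "sample_case_observation",
]

ShapeName = Literal["linear", "logistic", "logarithmic", "heaviside"]
MethodName = Literal["weighted_sampling", "percentile_matching", "percent_shift"]

#: default steepness / curvature of the two-point interpolants
DEFAULT_LOGISTIC_K = 10.0
DEFAULT_LOGARITHMIC_K = 99.0


@dataclass(frozen=True)
class LognormalParams:
    """Log-normal law with log-scale location ``mu`` and SD ``sigma``.

    The median is ``exp(mu)``; quantile q is ``exp(mu + sigma * z_q)``.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise InvalidInputError(f"mu must be finite, got {self.mu}")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise InvalidInputError(f"sigma must be positive, got {self.sigma}")

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    def quantile(self, q):
        """Inverse CDF, vectorized over ``q``."""
        return np.exp(self.mu + self.sigma * stats.norm.ppf(q))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        pos = x > 0
        out = np.where(pos, stats.norm.cdf((np.log(np.where(pos, x, 1.0)) - self.mu) / self.sigma), 0.0)
        return out if out.ndim else float(out)

    def rvs(self, size, rng: np.random.Generator):
        return np.exp(self.mu + self.sigma * rng.standard_normal(size))


@dataclass(frozen=True)
class TrajectorySpec:
    """One case's start-to-end biomarker path on normalized time [0, 1].

    ``shape_param`` is the logistic steepness k, the logarithmic curvature
    k, or the Heaviside impulse fraction p in (0, 1).  Every shape passes
    exactly through ``start`` at t=0 and ``end`` at t=1 (the Heaviside step
    is right-continuous: the value at t = p is already ``end``).
    """

    start: float
    end: float
    shape: ShapeName = "linear"
    shape_param: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "logistic", "logarithmic", "heaviside"):
            raise InvalidInputError(f"unknown shape {self.shape!r}")
        if self.start <= 0 or self.end <= 0:
            raise InvalidInputError("start and end values must be positive")
        p = self.shape_param
        if self.shape == "heaviside":
            if p is None or not (0.0 < p < 1.0):
                raise InvalidInputError(
                    "heaviside requires impulse fraction shape_param in (0, 1)"
                )
        elif self.shape in ("logistic", "logarithmic") and p is not None and p <= 0:
            raise InvalidInputError(f"{self.shape} steepness must be positive")


@dataclass(frozen=True)
class ImputationMethod:
    """How a case's healthy-era start value is generated.

    * ``weighted_sampling`` — draw from the control law conditioned on being
      below the case's observed value.
    * ``percentile_matching`` — map the case value through its own law's CDF
      onto the control law's quantile function.
    * ``percent_shift`` — multiply by ``1 - shift_fraction`` (default 0.15,
      the observed control-vs-case median gap).
    """

    name: MethodName
    shift_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.name not in ("weighted_sampling", "percentile_matching", "percent_shift"):
            raise InvalidInputError(f"unknown imputation method {self.name!r}")
        if not (0.0 < self.shift_fraction < 1.0):
            raise InvalidInputError("shift_fraction must lie in (0, 1)")


def fit_lognormal_from_centiles(table) -> LognormalParams:
    """Fit a log-normal law to a centile table by least squares.

    Regresses log(value) on the standard-normal quantile of each percentile:
    under a log-normal law the relation is exactly linear with intercept mu
    and slope sigma, so noiseless centiles are recovered exactly.

    Parameters
    ----------
    table
        A :class:`~temporalbias.synthetic_data.CentileTable` (or any object
        with strictly increasing ``percentiles`` in (0,1) and strictly
        increasing positive ``values``).
    """
    p = np.asarray(table.percentiles, dtype=float)
    v = np.asarray(table.values, dtype=float)
    if p.size != v.size or p.size < 3:
        raise InvalidInputError("need at least 3 centile points")
    if not (np.all(np.diff(p) > 0) and np.all(p > 0) and np.all(p < 1)):
        raise InvalidInputError("percentiles must be strictly increasing in (0, 1)")
    if not (np.all(v > 0) and np.all(np.diff(v) > 0)):
        raise InvalidInputError("values must be positive and strictly increasing")
    z = stats.norm.ppf(p)
    sigma, mu = np.polyfit(z, np.log(v), 1)
    if sigma <= 0:
        raise InvalidInputError("fitted sigma is non-positive; table is not log-normal-like")
    return LognormalParams(mu=float(mu), sigma=float(sigma))


def _impute_start_array(
    case_values: np.ndarray,
    control: LognormalParams,
    case: LognormalParams,
    method: ImputationMethod,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized start-value imputation (internal fast path)."""
    x = np.asarray(case_values, dtype=float)
    if np.any(x <= 0):
        raise InvalidInputError("case values must be positive")
    if method.name == "percent_shift":
        return (1.0 - method.shift_fraction) * x
    if method.name == "percentile_matching":
        q = stats.norm.cdf((np.log(x) - case.mu) / case.sigma)
        return control.quantile(q)
    # weighted sampling: inverse-CDF draw from the control law truncated
    # to (0, case value) — same law as rejection sampling, bounded runtime
    f_upper = stats.norm.cdf((np.log(x) - control.mu) / control.sigma)
    u = rng.uniform(0.0, f_upper)
    return control.quantile(u)


def impute_start_value(
    case_value: float,
    control: LognormalParams,
    case: LognormalParams,
    method: ImputationMethod,
    rng: np.random.Generator | None = None,
) -> float:
    """Impute the healthy-era start value for one case observation.

    See :class:`ImputationMethod` for the three schemes.  The result is
    below ``case_value`` whenever the control law places mass below it.
    """
    if rng is None:
        rng = np.random.default_rng()
    out = _impute_start_array(np.asarray([case_value]), control, case, method, rng)
    return float(out[0])


def _shape_fraction(shape: ShapeName, shape_param: float | None, t: np.ndarray) -> np.ndarray:
    """Normalized progress g(t) in [0, 1] with g(0)=0 and g(1)=1."""
    if shape == "linear":
        return t
    if shape == "logarithmic":
        k = DEFAULT_LOGARITHMIC_K if shape_param is None else shape_param
        return np.log1p(k * t) / np.log1p(k)
    if shape == "logistic":
        k = DEFAULT_LOGISTIC_K if shape_param is None else shape_param
        sig = lambda u: 1.0 / (1.0 + np.exp(-u))  # noqa: E731
        lo = sig(-k / 2.0)
        hi = sig(k / 2.0)
        return (sig(k * (t - 0.5)) - lo) / (hi - lo)
    # heaviside, right-continuous at the impulse fraction
    return np.where(t >= shape_param, 1.0, 0.0)


def trajectory_value(spec: TrajectorySpec, t):
    """Evaluate the trajectory at normalized time ``t`` in [0, 1].

    Vectorized over ``t``.  All shapes return exactly ``start`` at t=0 and
    ``end`` at t=1, and are non-decreasing in t when start <= end.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0) or np.any(t_arr > 1.0):
        raise InvalidInputError("t must lie in [0, 1]")
    g = _shape_fraction(spec.shape, spec.shape_param, t_arr)
    out = spec.start + (spec.end - spec.start) * g
    return out if out.ndim else float(out)


def _trajectory_values_array(
    starts: np.ndarray,
    ends: np.ndarray,
    shape: ShapeName,
    shape_param: float | None,
    t: np.ndarray,
) -> np.ndarray:
    """Vectorized trajectory evaluation across cases (internal fast path)."""
    g = _shape_fraction(shape, shape_param, np.asarray(t, dtype=float))
    return starts + (ends - starts) * g


def sample_case_observation(
    spec: TrajectorySpec, rng: np.random.Generator | None = None
) -> float:
    """Draw one observation at a uniformly random time along the trajectory."""
    if rng is None:
        rng = np.random.default_rng()
    return float(trajectory_value(spec, rng.uniform()))
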