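"""Internal logistic-fit helper shared by the effect-estimation modules."""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import EstimationError

#: |standardized coefficient| beyond which we declare quasi-separation
_COEF_SANITY = 50.0


def fit_binary_exposure_coef(x: np.ndarray, y: np.ndarray) -> float:
    """MLE slope of a logistic regression of binary ``y`` on scalar ``x``.

    The exposure is standardized internally for conditioning and the slope
    mapped back to per-unit scale (the MLE is invariant to affine rescaling
    of x).  Raises :class:`EstimationError` on single-class outcomes,
    (quasi-)separation, or non-convergence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    classes = np.unique(y)
    if classes.size < 2:
        raise EstimationError("outcome has a single class")
    sd = x.std()
    if sd == 0:
        raise EstimationError("exposure is constant")
    xs = (x - x.mean()) / sd
    design = sm.add_constant(xs)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise EstimationError(f"perfect separation: {exc}") from exc
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular design: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise EstimationError("logistic fit did not converge")
    beta_std = float(res.params[1])
    if abs(beta_std) > _COEF_SANITY:
        raise EstimationError("coefficient diverged; data are (quasi-)separated")
    return beta_std / sd


def fit_case_control_coef(case_values: np.ndarray, control_values: np.ndarray) -> float:
    """Exposure coefficient of case status regressed on biomarker value."""
    x = np.concatenate([case_values, control_values])
    y = np.concatenate(
        [np.ones(len(case_values)), np.zeros(len(control_values))]
    )
    return fit_binary_exposure_coef(x, y)
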