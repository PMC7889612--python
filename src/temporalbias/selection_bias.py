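"""Measurement-selection bias with repeated biomarker tests.

When a subject has several tests on record, the analyst must pick one value
to represent them.  Because the biomarker fluctuates around its true level,
preferentially selecting the largest (or smallest) available test inflates
(or deflates) the fitted association with the outcome relative to picking a
random timepoint.  This module implements the selection schemes, the
per-scheme logistic fits, and the intra-individual variation summary used
to calibrate the generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._glm import fit_binary_exposure_coef
from .errors import InvalidInputError
from .prospective_effect import EffectEstimate
from .synthetic_data import RepeatedMeasuresCohort

__all__ = [
    "SelectionScheme",
    "SelectionAnalysisResult",
    "select_exposure",
    "selection_effect_analysis",
    "intra_individual_variation",
]

_SCHEMES = ("max", "min", "mean", "random_single")


@dataclass(frozen=True)
class SelectionScheme:
    """Which of a subject's repeated tests represents them."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in _SCHEMES:
            raise InvalidInputError(f"scheme must be one of {_SCHEMES}")


@dataclass(frozen=True)
class SelectionAnalysisResult:
    """Per-scheme effect estimates and their ratios to random selection."""

    estimates: dict[str, EffectEstimate]
    ratios: dict[str, float]  # scheme coefficient / random_single coefficient
    seed: int | None = None


def select_exposure(
    measurements,
    scheme: SelectionScheme,
    rng: np.random.Generator | None = None,
) -> float:
    """Reduce one subject's measurements to a single exposure value."""
    m = np.asarray(measurements, dtype=float)
    if m.size == 0:
        raise InvalidInputError("measurements must be non-empty")
    if scheme.name == "max":
        return float(m.max())
    if scheme.name == "min":
        return float(m.min())
    if scheme.name == "mean":
        return float(m.mean())
    if rng is None:
        rng = np.random.default_rng()
    return float(m[rng.integers(m.size)])


def _selected_exposures(
    cohort: RepeatedMeasuresCohort, scheme: SelectionScheme, rng: np.random.Generator
) -> pd.Series:
    grp = cohort.measurements.groupby("subject_id")["test_value"]
    if scheme.name in ("max", "min", "mean"):
        return grp.agg(scheme.name)
    # random_single: shuffle rows once, then take the first per subject
    perm = rng.permutation(len(cohort.measurements))
    shuffled = cohort.measurements.iloc[perm]
    return shuffled.groupby("subject_id")["test_value"].first()


def selection_effect_analysis(
    cohort: RepeatedMeasuresCohort,
    schemes: Sequence[SelectionScheme] | None = None,
    seed: int | None = None,
) -> SelectionAnalysisResult:
    """Fit the biomarker-outcome association under each selection scheme.

    Each scheme governs which of a *case's* repeated tests enters the
    regression; controls are always represented by a random timepoint, so
    the schemes model preferential selection among case exposure values.
    Preferring a case's largest test widens the apparent case-control gap,
    preferring the smallest narrows it.  The reported ratio is each
    scheme's logistic coefficient over the ``random_single`` reference
    (random timepoint selection in both arms).
    """
    if schemes is None:
        schemes = [SelectionScheme(n) for n in _SCHEMES]
    names = {s.name for s in schemes}
    names.add("random_single")  # always needed as the reference
    rng = np.random.default_rng(seed)

    subj = cohort.subjects.set_index("subject_id")
    y_all = subj["mi_status"]
    # one shared random-timepoint draw keeps the control arm identical
    # across schemes, isolating the case-selection effect
    random_pick = _selected_exposures(cohort, SelectionScheme("random_single"), rng)
    is_case = y_all.loc[random_pick.index].to_numpy(dtype=float) == 1

    estimates: dict[str, EffectEstimate] = {}
    for name in sorted(names):
        if name == "random_single":
            exposures = random_pick.to_numpy()
        else:
            scheme_pick = _selected_exposures(cohort, SelectionScheme(name), rng)
            exposures = np.where(is_case, scheme_pick.to_numpy(), random_pick.to_numpy())
        coef = fit_binary_exposure_coef(exposures, is_case.astype(float))
        n_case = int(is_case.sum())
        estimates[name] = EffectEstimate(
            coef, n_case=n_case, n_control=len(is_case) - n_case, seed=seed
        )
    ref = estimates["random_single"].coefficient
    ratios = {n: e.coefficient / ref for n, e in estimates.items()}
    return SelectionAnalysisResult(estimates=estimates, ratios=ratios, seed=seed)


def intra_individual_variation(
    cohort: RepeatedMeasuresCohort,
) -> tuple[float, float]:
    """(mean within-subject sample SD, grand mean over all tests).

    The per-subject SD uses the n-1 denominator; every subject must have at
    least two measurements.
    """
    grp = cohort.measurements.groupby("subject_id")["test_value"]
    counts = grp.count()
    if (counts < 2).any():
        raise InvalidInputError("every subject needs >= 2 measurements")
    mean_within_sd = float(grp.std(ddof=1).mean())
    grand_mean = float(cohort.measurements["test_value"].mean())
    return mean_within_sd, grand_mean
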