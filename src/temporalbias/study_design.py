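"""Event-indexed versus calendar-fixed observation windows.

A case-control ("event-indexed") window is anchored a fixed number of
months before each subject's event — information unavailable in real time.
A cohort ("calendar-fixed") window is anchored at a calendar month and is
prospectively deployable.  This module matches cases to controls, assigns
windows under either design, extracts binary code-occurrence features, and
runs train/evaluate studies in which the training and evaluation designs
may differ, exposing the performance collapse and false-negative structure
that event-indexed training produces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .errors import EstimationError, InvalidInputError, MatchingError
from .synthetic_data import ClaimsCohort

__all__ = [
    "StudyDesign",
    "FeatureMatrix",
    "MatchResult",
    "StudyResult",
    "match_controls",
    "assign_window",
    "extract_features",
    "run_design_study",
    "logistic_reference",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyDesign:
    """How each subject's one-month observation window is anchored.

    ``event_indexed``: the window is the single month ``offset_months``
    before the subject's delivery / matched baseline month.
    ``calendar_fixed``: the window is ``fixed_month`` (January by default)
    for everyone, regardless of event timing.
    """

    anchor: str  # "event_indexed" | "calendar_fixed"
    offset_months: int = 3
    fixed_month: int = 1
    window_length_months: int = 1

    def __post_init__(self) -> None:
        if self.anchor not in ("event_indexed", "calendar_fixed"):
            raise InvalidInputError(f"unknown anchor {self.anchor!r}")
        if self.offset_months < 1:
            raise InvalidInputError("offset_months must be >= 1")
        if not (1 <= self.fixed_month <= 12):
            raise InvalidInputError("fixed_month must be a month 1..12")
        if self.window_length_months != 1:
            raise InvalidInputError("only one-month windows are supported")


CASE_CONTROL = StudyDesign(anchor="event_indexed")
COHORT = StudyDesign(anchor="calendar_fixed")


@dataclass
class MatchResult:
    """1:1 exactly matched cohort; controls inherit their case's baseline."""

    matched: pd.DataFrame  # patient_id, age, region, label, anchor_month
    n_dropped: int
    dropped_case_ids: list[int] = field(default_factory=list)


def match_controls(
    cohort: ClaimsCohort,
    keys: Sequence[str] = ("age", "region"),
    seed: int | None = None,
    max_drop_fraction: float = 0.20,
) -> MatchResult:
    """Greedy 1:1 exact matching of cases to controls without replacement.

    Within every stratum of ``keys``, randomly ordered cases are paired
    with randomly ordered unused controls; each matched control inherits
    its case's delivery month as baseline month.  Cases in exhausted strata
    are dropped with a warning; more than ``max_drop_fraction`` dropped
    raises :class:`MatchingError`.
    """
    rng = np.random.default_rng(seed)
    pats = cohort.patients
    cases = pats[pats["delivery_month"].notna()]
    controls = pats[pats["delivery_month"].isna()]

    rows = []
    dropped: list[int] = []
    as_tuple = lambda k: k if isinstance(k, tuple) else (k,)  # noqa: E731
    ctrl_by_stratum = {
        as_tuple(k): v.index.to_numpy() for k, v in controls.groupby(list(keys))
    }
    for stratum, case_grp in cases.groupby(list(keys)):
        stratum = as_tuple(stratum)
        pool = ctrl_by_stratum.get(stratum, np.array([], dtype=int))
        pool = rng.permutation(pool)
        case_order = rng.permutation(case_grp.index.to_numpy())
        n_pairs = min(len(case_order), len(pool))
        for ci, ki in zip(case_order[:n_pairs], pool[:n_pairs]):
            month = int(cases.at[ci, "delivery_month"])
            rows.append((cases.at[ci, "patient_id"], *stratum, 1, month))
            rows.append((controls.at[ki, "patient_id"], *stratum, 0, month))
        dropped.extend(int(cases.at[ci, "patient_id"]) for ci in case_order[n_pairs:])

    if dropped:
        logger.warning("dropped %d/%d cases in exhausted strata", len(dropped), len(cases))
    if len(dropped) > max_drop_fraction * max(len(cases), 1):
        raise MatchingError(
            f"{len(dropped)}/{len(cases)} cases unmatched (> {max_drop_fraction:.0%})"
        )
    matched = pd.DataFrame(
        rows, columns=["patient_id", *keys, "label", "anchor_month"]
    )
    return MatchResult(matched=matched, n_dropped=len(dropped), dropped_case_ids=dropped)


def assign_window(anchor_month: int | None, design: StudyDesign) -> int | None:
    """Window month for one subject, or ``None`` if it precedes the data year.

    ``event_indexed``: ``anchor_month - offset_months`` (a May delivery with
    offset 3 is observed in February); windows before January fall outside
    the one-year extract and the subject is excluded.  ``calendar_fixed``:
    ``fixed_month`` for everyone.
    """
    if design.anchor == "calendar_fixed":
        return design.fixed_month
    if anchor_month is None or pd.isna(anchor_month):
        raise InvalidInputError("event_indexed design requires an anchor month")
    m = int(anchor_month) - design.offset_months
    return m if m >= 1 else None


@dataclass
class FeatureMatrix:
    """Binary code-occurrence matrix plus age, with labels and event months."""

    X: pd.DataFrame  # index patient_id; columns: vocabulary codes + "age"
    y: np.ndarray
    event_month: pd.Series  # Int64; NA for controls

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise InvalidInputError("X and y row counts differ")


def extract_features(
    cohort: ClaimsCohort,
    windows: pd.Series,
    matched: pd.DataFrame,
    vocabulary: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Indicator of >= 1 occurrence of each code inside each patient's window.

    ``windows`` maps patient_id -> window month for the patients to
    featurize (already excluding out-of-year windows); ``matched`` supplies
    labels, ages and anchor months.  Codes never seen in a window give an
    all-zero row; occurrences are binarized, not counted.
    """
    if vocabulary is None:
        vocabulary = cohort.vocabulary
    sub = matched.set_index("patient_id").loc[windows.index]
    ev = cohort.events
    win = windows.rename("window_month")
    joined = ev.merge(win, left_on="patient_id", right_index=True)
    in_window = joined[joined["month"] == joined["window_month"]]
    onehot = (
        in_window.groupby(["patient_id", "code"]).size().unstack(fill_value=0) > 0
    ).astype(float)
    X = onehot.reindex(index=windows.index, columns=list(vocabulary), fill_value=0.0)
    X = X.fillna(0.0)
    X["age"] = sub["age"].astype(float)
    y = sub["label"].to_numpy(dtype=int)
    event_month = pd.array(
        [m if lbl == 1 else pd.NA for m, lbl in zip(sub["anchor_month"], sub["label"])],
        dtype="Int64",
    )
    return FeatureMatrix(X=X, y=y, event_month=pd.Series(event_month, index=X.index))


def logistic_reference() -> LogisticRegression:
    """The reference classifier: plain L2 logistic regression."""
    return LogisticRegression(max_iter=2000)


@dataclass
class StudyResult:
    """Outcome of one train-design / eval-design study."""

    train_design: StudyDesign
    eval_design: StudyDesign
    aurocs: list[float]
    confusion: np.ndarray  # [[tn, fp], [fn, tp]] at the score threshold
    scores_by_month: pd.DataFrame  # per eval patient: label, event_month, mean_score
    n_train: int
    n_eval: int
    n_excluded_train: int
    n_excluded_eval: int

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.aurocs))

    def mean_case_score_for_months(self, months: Sequence[int]) -> float:
        s = self.scores_by_month
        mask = (s["label"] == 1) & s["event_month"].isin(list(months))
        return float(s.loc[mask, "mean_score"].mean())


def _windows_for(
    matched: pd.DataFrame, design: StudyDesign
) -> tuple[pd.Series, int]:
    months = [assign_window(m, design) for m in matched["anchor_month"]]
    win = pd.Series(months, index=matched["patient_id"].to_numpy(), dtype="object")
    excluded = win.isna()
    if excluded.any():
        logger.info(
            "excluded %d patients whose window precedes the data year", int(excluded.sum())
        )
    return win[~excluded].astype(int), int(excluded.sum())


def run_design_study(
    cohort: ClaimsCohort,
    train_design: StudyDesign,
    eval_design: StudyDesign,
    model_factory: Callable[[], object] = logistic_reference,
    n_models: int = 10,
    seed: int | None = None,
    test_size: float = 0.2,
    threshold: float = 0.5,
) -> StudyResult:
    """Train under one window design, evaluate under another.

    Patients are split 80/20 at the patient level *before* windowing so no
    subject contributes to both sides (asserted).  ``n_models`` classifiers
    are trained on bootstrap resamples of the training rows; evaluation
    features are always extracted under ``eval_design``.  Returns per-model
    AUROCs, the pooled confusion matrix of the mean score at ``threshold``,
    and per-patient mean scores broken down by event month.
    """
    rng = np.random.default_rng(seed)
    match = match_controls(cohort, seed=int(rng.integers(2**31)))
    matched = match.matched
    vocab = cohort.vocabulary

    # stratified patient-level split
    idx = np.arange(len(matched))
    test_mask = np.zeros(len(matched), dtype=bool)
    for lbl in (0, 1):
        lbl_idx = rng.permutation(idx[matched["label"].to_numpy() == lbl])
        n_test = int(round(test_size * len(lbl_idx)))
        test_mask[lbl_idx[:n_test]] = True
    train_tbl = matched[~test_mask]
    eval_tbl = matched[test_mask]

    train_ids = set(train_tbl["patient_id"])
    eval_ids = set(eval_tbl["patient_id"])
    assert not (train_ids & eval_ids), "patient leakage between train and eval"

    train_win, n_excl_train = _windows_for(train_tbl, train_design)
    eval_win, n_excl_eval = _windows_for(eval_tbl, eval_design)
    fm_train = extract_features(cohort, train_win, train_tbl, vocab)
    fm_eval = extract_features(cohort, eval_win, eval_tbl, vocab)
    if len(np.unique(fm_train.y)) < 2 or len(np.unique(fm_eval.y)) < 2:
        raise EstimationError("degenerate single-class split")

    Xtr = fm_train.X.to_numpy()
    Xev = fm_eval.X.to_numpy()
    aurocs: list[float] = []
    scores = np.zeros((n_models, len(Xev)))
    for m in range(n_models):
        boot = rng.integers(len(Xtr), size=len(Xtr))
        if len(np.unique(fm_train.y[boot])) < 2:  # pathological resample
            boot = np.arange(len(Xtr))
        model = model_factory()
        model.fit(Xtr[boot], fm_train.y[boot])
        s = model.predict_proba(Xev)[:, 1]
        scores[m] = s
        aurocs.append(float(roc_auc_score(fm_eval.y, s)))

    mean_score = scores.mean(axis=0)
    pred = (mean_score >= threshold).astype(int)
    confusion = np.array(
        [
            [int(((fm_eval.y == 0) & (pred == 0)).sum()), int(((fm_eval.y == 0) & (pred == 1)).sum())],
            [int(((fm_eval.y == 1) & (pred == 0)).sum()), int(((fm_eval.y == 1) & (pred == 1)).sum())],
        ]
    )
    scores_by_month = pd.DataFrame(
        {
            "patient_id": fm_eval.X.index,
            "label": fm_eval.y,
            "event_month": fm_eval.event_month.to_numpy(),
            "mean_score": mean_score,
        }
    )
    return StudyResult(
        train_design=train_design,
        eval_design=eval_design,
        aurocs=aurocs,
        confusion=confusion,
        scores_by_month=scores_by_month,
        n_train=len(Xtr),
        n_eval=len(Xev),
        n_excluded_train=n_excl_train,
        n_excluded_eval=n_excl_eval,
    )
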