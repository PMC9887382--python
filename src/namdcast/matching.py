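"""Eligibility screening and propensity-score calliper matching.

Hypothetical patients are screened against the trial's visual-acuity
eligibility window, then matched 1:1 to sham-arm participants on the logit
of a propensity score fitted by unpenalised logistic regression of group
membership on age (band midpoint, years), sex (female = 1) and baseline VA
(letters).  Matching is greedy best-first without replacement within a
calliper of 0.1 standard deviations of the pooled logit propensity — pairs
are admitted in ascending order of |delta logit|, with lexicographic id
tie-breaks so the result is deterministic and order-invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from namdcast.ehr_preprocess import age_band_midpoints

logger = logging.getLogger(__name__)

#: Default trial eligibility window in ETDRS letters, inclusive.  The lower
#: bound is the treatment floor (6/96) and the upper the good-vision
#: threshold (6/12); both are configurable.
DEFAULT_VA_WINDOW = (25, 70)


class MatchingError(RuntimeError):
    """Raised when the propensity model cannot be fitted."""


def screen_eligibility(
    profiles: pd.DataFrame,
    va_min: int = DEFAULT_VA_WINDOW[0],
    va_max: int = DEFAULT_VA_WINDOW[1],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split profiles into trial-eligible and ineligible by baseline VA.

    Bounds are inclusive.  Returns (eligible, ineligible); the ineligible
    table carries a ``reason`` column naming the violated bound.
    """
    if va_min >= va_max:
        raise ValueError(f"need va_min < va_max, got [{va_min}, {va_max}]")
    va = profiles["baseline_va"]
    eligible = profiles[(va >= va_min) & (va <= va_max)].reset_index(drop=True)
    ineligible = profiles[(va < va_min) | (va > va_max)].copy()
    ineligible["reason"] = np.where(
        ineligible["baseline_va"] < va_min,
        f"va_below_{va_min}",
        f"va_above_{va_max}",
    )
    return eligible, ineligible.reset_index(drop=True)


def _design(profiles: pd.DataFrame) -> np.ndarray:
    age = age_band_midpoints(profiles)
    female = (profiles["sex"] == "female").to_numpy(dtype=float)
    va = profiles["baseline_va"].to_numpy(dtype=float)
    return np.column_stack([age, female, va])


@dataclass(frozen=True)
class PropensityModel:
    """Fitted propensity model with per-subject scores.

    ``subjects`` has one row per fitted subject: subject_id, group
    ('cohort' or 'sham'), propensity e(x) in (0,1) and logit(e).
    ``params`` are the logistic coefficients (const, age, female,
    baseline_va) for group membership (cohort = 1).
    """

    params: pd.Series
    bse: pd.Series
    subjects: pd.DataFrame

    @property
    def logit_sd(self) -> float:
        """Sample sd of the logit propensity over all fitted subjects."""
        return float(self.subjects["logit"].std(ddof=1))


def fit_propensity(cohort: pd.DataFrame, sham: pd.DataFrame) -> PropensityModel:
    """Fit the propensity of being a hypothetical-cohort member (vs sham).

    Maximum-likelihood logistic regression on age-band midpoint, sex and
    baseline VA.  Perfect separation or a singular design raises
    :class:`MatchingError` (review covariate overlap before matching).
    """
    if len(cohort) == 0 or len(sham) == 0:
        raise ValueError("both the cohort and the sham group must be non-empty")
    X = np.vstack([_design(cohort), _design(sham)])
    y = np.concatenate([np.ones(len(cohort)), np.zeros(len(sham))])
    X = sm.add_constant(X, has_constant="add")
    names = ["const", "age", "female", "baseline_va"]
    try:
        fit = sm.Logit(y, X).fit(disp=False)
    except Exception as exc:  # separation / singular design
        raise MatchingError(
            f"propensity model could not be fitted ({exc}); check covariate "
            "overlap between the cohort and the sham arm"
        ) from exc
    logit = X @ fit.params
    prop = 1.0 / (1.0 + np.exp(-logit))
    if not ((prop > 0.0) & (prop < 1.0)).all():
        raise MatchingError(
            "fitted propensities reached 0 or 1 (perfect separation); "
            "review the calliper and covariate overlap"
        )
    subjects = pd.DataFrame(
        {
            "subject_id": np.concatenate(
                [cohort["patient_id"].to_numpy(), sham["participant_id"].to_numpy()]
            ),
            "group": ["cohort"] * len(cohort) + ["sham"] * len(sham),
            "propensity": prop,
            "logit": logit,
        }
    )
    return PropensityModel(
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        subjects=subjects,
    )


@dataclass(frozen=True)
class MatchSet:
    """Result of calliper matching.

    ``pairs`` holds (profile_id, participant_id, delta_logit) with
    delta_logit = |logit difference| <= calliper; ``unmatched_profiles``
    lists cohort members left without a partner and why.
    """

    calliper: float
    pairs: pd.DataFrame
    unmatched_profiles: pd.DataFrame


def match_within_calliper(
    model: PropensityModel,
    calliper_mult: float = 0.1,
) -> MatchSet:
    """Greedy best-first 1:1 matching without replacement.

    All cross-group pairs within ``calliper_mult * sd(logit)`` are ranked by
    ascending |delta logit| (ties broken by profile then participant id) and
    admitted whenever both members are still free.  Zero matches is a valid
    outcome and is logged, not raised.
    """
    if calliper_mult < 0:
        raise ValueError("calliper multiplier must be non-negative")
    subj = model.subjects
    cohort = subj[subj["group"] == "cohort"]
    sham = subj[subj["group"] == "sham"]
    calliper = calliper_mult * model.logit_sd

    delta = np.abs(
        cohort["logit"].to_numpy()[:, None] - sham["logit"].to_numpy()[None, :]
    )
    ci, si = np.nonzero(delta <= calliper)
    candidates = pd.DataFrame(
        {
            "profile_id": cohort["subject_id"].to_numpy()[ci],
            "participant_id": sham["subject_id"].to_numpy()[si],
            "delta_logit": delta[ci, si],
        }
    ).sort_values(
        ["delta_logit", "profile_id", "participant_id"], kind="mergesort"
    )

    used_profiles: set = set()
    used_participants: set = set()
    rows = []
    for row in candidates.itertuples(index=False):
        if row.profile_id in used_profiles or row.participant_id in used_participants:
            continue
        used_profiles.add(row.profile_id)
        used_participants.add(row.participant_id)
        rows.append(row)
    pairs = pd.DataFrame(rows, columns=["profile_id", "participant_id", "delta_logit"])
    unmatched_ids = [
        pid for pid in cohort["subject_id"] if pid not in used_profiles
    ]
    unmatched = pd.DataFrame(
        {"profile_id": unmatched_ids,
         "reason": ["no_neighbour_in_calliper"] * len(unmatched_ids)}
    )
    if len(pairs) == 0:
        logger.warning("no pairs within calliper %.4g", calliper)
    logger.info(
        "matched %d of %d cohort profiles within calliper %.4g",
        len(pairs), len(cohort), calliper,
    )
    return MatchSet(calliper=calliper, pairs=pairs, unmatched_profiles=unmatched)


def match_exact(cohort: pd.DataFrame, sham: pd.DataFrame) -> MatchSet:
    """Exact 1:1 matching on (age_band, sex, baseline_va).

    Alternative reading of "matched exactly ... based on age, sex and VA";
    not the default pipeline behaviour (see the ``--exact`` CLI flag).
    Pairs within each exact cell are assigned in lexicographic id order.
    """
    rows = []
    used: set = set()
    sham_cells: dict = {}
    for rec in sham.sort_values("participant_id").itertuples(index=False):
        sham_cells.setdefault((rec.age_band, rec.sex, rec.baseline_va), []).append(
            rec.participant_id
        )
    for rec in cohort.sort_values("patient_id").itertuples(index=False):
        cell = (rec.age_band, rec.sex, rec.baseline_va)
        free = [p for p in sham_cells.get(cell, []) if p not in used]
        if free:
            used.add(free[0])
            rows.append((rec.patient_id, free[0], 0.0))
    pairs = pd.DataFrame(rows, columns=["profile_id", "participant_id", "delta_logit"])
    matched = set(pairs["profile_id"])
    unmatched_ids = [p for p in cohort["patient_id"] if p not in matched]
    unmatched = pd.DataFrame(
        {"profile_id": unmatched_ids, "reason": ["no_exact_match"] * len(unmatched_ids)}
    )
    return MatchSet(calliper=0.0, pairs=pairs, unmatched_profiles=unmatched)


def standardized_mean_difference(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute standardised mean difference with the pooled-sd denominator;
    0 when both groups are constant and equal."""
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    denom = np.sqrt((sx**2 + sy**2) / 2.0)
    if denom == 0:
        return 0.0 if np.mean(x) == np.mean(y) else np.inf
    return abs(np.mean(x) - np.mean(y)) / denom
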