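"""Normalise raw patient records into analysis-ready baseline profiles.

Visual acuity is handled in approximate ETDRS letters (0–100, higher is
better); Snellen fractions recorded in clinic are converted with the standard
logMAR-based approximation ``letters = 85 + 50*log10(numerator/denominator)``.
Ages arrive deidentified as six bands; where a numeric age is needed
downstream the band midpoint is used.

A patient profile is one row of a pandas DataFrame with the columns in
:data:`PROFILE_COLUMNS`; collections of profiles are plain DataFrames so the
rest of the pipeline composes with ordinary pandas operations.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

CENTRES = ("MEH", "UHB")
SEXES = ("female", "male")
AGE_BANDS = ("<65", "65-69", "70-74", "75-79", "80-84", "85+")
ETHNICITIES = ("white", "not_white", "not_reported")
SMOKING = ("yes", "no_or_unknown")

#: Numeric age assigned to each deidentified band when a covariate is needed.
AGE_BAND_MIDPOINT = {
    "<65": 60.0,
    "65-69": 67.0,
    "70-74": 72.0,
    "75-79": 77.0,
    "80-84": 82.0,
    "85+": 88.0,
}

PROFILE_COLUMNS = [
    "patient_id",
    "centre",
    "sex",
    "age_band",
    "ethnicity",
    "smoker",
    "index_year",
    "index_week",
    "study_eye",
    "baseline_va",
]


def snellen_to_etdrs(numerator: float, denominator: float) -> int:
    """Convert a Snellen fraction to approximate ETDRS letters.

    Uses ``round(85 + 50*log10(numerator/denominator))`` with round-half-up,
    clamped to [0, 100].  This reproduces the standard clinical equivalences
    6/6 -> 85, 6/12 -> 70, 6/96 -> 25 and 3/60 -> 20.
    """
    if numerator <= 0 or denominator <= 0:
        raise ValueError(
            f"Snellen fraction must be positive, got {numerator}/{denominator}"
        )
    letters = 85.0 + 50.0 * math.log10(numerator / denominator)
    return int(min(100, max(0, math.floor(letters + 0.5))))


def designate_study_eye(
    diagnosis_date_right: _dt.date | None,
    diagnosis_date_left: _dt.date | None,
) -> str:
    """Designate the study eye as the first eye diagnosed.

    When both eyes present on the same date the right eye is designated; a
    single dated eye is the study eye by default.
    """
    if diagnosis_date_right is None and diagnosis_date_left is None:
        raise ValueError("at least one eye must have a diagnosis date")
    if diagnosis_date_left is None:
        return "right"
    if diagnosis_date_right is None:
        return "left"
    return "left" if diagnosis_date_left < diagnosis_date_right else "right"


def validate_profiles(profiles: pd.DataFrame) -> None:
    """Raise ValueError on any profile violating the type invariants."""
    missing = [c for c in PROFILE_COLUMNS if c not in profiles.columns]
    if missing:
        raise ValueError(f"profiles missing columns: {missing}")
    va = profiles["baseline_va"]
    if ((va < 0) | (va > 100)).any():
        raise ValueError("baseline_va outside [0, 100]")
    bad_band = set(profiles["age_band"]) - set(AGE_BANDS)
    if bad_band:
        raise ValueError(f"unknown age bands: {sorted(bad_band)}")
    wk = profiles["index_week"]
    if ((wk < 1) | (wk > 53)).any():
        raise ValueError("index_week outside ISO range 1-53")


@dataclass(frozen=True)
class BaselineSummary:
    """Per-centre and pooled baseline cohort summary.

    ``counts`` is long-format (cohort, variable, level, count, percent) with
    percentages to one decimal; ``va`` has one row per cohort with n, mean,
    sd, median, min, max and the three threshold counts/percentages.
    ``welch_t``/``welch_p`` compare the two centre VA means with the
    unequal-variance two-sample t-test.
    """

    counts: pd.DataFrame
    va: pd.DataFrame
    welch_t: float
    welch_p: float


_CATEGORICALS = {
    "sex": SEXES,
    "age_band": AGE_BANDS,
    "ethnicity": ETHNICITIES,
    "smoker": SMOKING,
}


def _va_row(cohort: str, va: pd.Series) -> dict:
    n = len(va)
    sd = float(va.std(ddof=1)) if n > 1 else 0.0
    row = {
        "cohort": cohort,
        "n": n,
        "mean": float(va.mean()),
        "sd": sd,
        "median": float(va.median()),
        "min": float(va.min()),
        "max": float(va.max()),
    }
    for name, mask in (
        ("ge70", va >= 70),
        ("le20", va <= 20),
        ("lt25", va < 25),
    ):
        count = int(mask.sum())
        row[f"n_{name}"] = count
        row[f"pct_{name}"] = round(100.0 * count / n, 1)
    return row


def summarize_baseline(profiles: pd.DataFrame) -> BaselineSummary:
    """Summarise a baseline cohort per centre and pooled.

    Category percentages are 100*count/n to one decimal; VA uses sample
    (n-1) standard deviation, reported as 0 for a single patient so the
    summary stays numeric.  The Welch t-statistic compares centre VA means
    and is NaN when fewer than two centres are present.
    """
    if len(profiles) == 0:
        raise ValueError("cannot summarise an empty cohort")
    validate_profiles(profiles)

    cohorts = [("overall", profiles)] + [
        (c, g) for c, g in profiles.groupby("centre", sort=True)
    ]
    count_rows = []
    va_rows = []
    for name, group in cohorts:
        n = len(group)
        for variable, levels in _CATEGORICALS.items():
            observed = group[variable].value_counts()
            for level in levels:
                count = int(observed.get(level, 0))
                count_rows.append(
                    {
                        "cohort": name,
                        "variable": variable,
                        "level": level,
                        "count": count,
                        "percent": round(100.0 * count / n, 1),
                    }
                )
        va_rows.append(_va_row(name, group["baseline_va"]))

    va = pd.DataFrame(va_rows)
    centre_rows = va[va["cohort"] != "overall"]
    if len(centre_rows) == 2:
        a, b = (centre_rows.iloc[0], centre_rows.iloc[1])
        welch = _stats.ttest_ind_from_stats(
            a["mean"], a["sd"], a["n"], b["mean"], b["sd"], b["n"], equal_var=False
        )
        welch_t, welch_p = float(welch.statistic), float(welch.pvalue)
    else:
        welch_t = welch_p = float("nan")
    return BaselineSummary(
        counts=pd.DataFrame(count_rows), va=va, welch_t=welch_t, welch_p=welch_p
    )


def age_band_midpoints(profiles: pd.DataFrame) -> np.ndarray:
    """Numeric age covariate (band midpoints, years) for a profile table."""
    return profiles["age_band"].map(AGE_BAND_MIDPOINT).to_numpy(dtype=float)
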