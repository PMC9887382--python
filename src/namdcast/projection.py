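"""Project untreated 12-month visual-acuity trajectories.

Matched patients inherit their sham partner's change from baseline: the
partner's VA change at each horizon month is added to the patient's own
baseline, so the projected cohort keeps the sampled cohort's baseline
distribution while following the trial arm's natural-history decline.
Unmatched patients are projected with per-month ordinary-least-squares
models of observed sham VA on age, sex and baseline VA.

All projected values are clamped to the ETDRS range [0, 100].  The horizon
grid is months 0, 3, 6 and 12.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from namdcast.ehr_preprocess import AGE_BAND_MIDPOINT

logger = logging.getLogger(__name__)

HORIZON_MONTHS = (0, 3, 6, 12)


@dataclass(frozen=True)
class Trajectory:
    """Projected per-patient VA at months 0, 3, 6 and 12."""

    profile_id: str
    source: str  # 'matched' | 'modelled'
    va_by_month: dict[int, float]
    partner_id: str | None = None

    def __post_init__(self):
        for month, va in self.va_by_month.items():
            if not 0.0 <= va <= 100.0:
                raise ValueError(f"VA {va} at month {month} outside [0, 100]")


def _partner_va_at(visits: pd.DataFrame, months: tuple[int, ...]) -> np.ndarray:
    """Partner VA at the horizon months: observed values where visits exist,
    linear interpolation between adjacent visits, and last observation
    carried forward past the final visit."""
    visits = visits.sort_values("month")
    obs_months = visits["month"].to_numpy(dtype=float)
    obs_va = visits["va"].to_numpy(dtype=float)
    if len(obs_months) < 2:
        raise ValueError(
            "partner has only a baseline visit; no trajectory information"
        )
    # np.interp holds the boundary value beyond the last visit (LOCF).
    return np.interp(np.asarray(months, dtype=float), obs_months, obs_va)


def carry_matched_trajectory(
    profile: pd.Series,
    partner_visits: pd.DataFrame,
    partner_id: str | None = None,
    months: tuple[int, ...] = HORIZON_MONTHS,
) -> Trajectory:
    """Carry a sham partner's change-from-baseline onto a matched patient.

    ``va(t) = clamp(baseline + (partner_va(t) - partner_baseline), 0, 100)``.
    """
    baseline = float(profile["baseline_va"])
    partner_va = _partner_va_at(partner_visits, months)
    partner_baseline = partner_va[list(months).index(0)] if 0 in months else float(
        partner_visits.sort_values("month")["va"].iloc[0]
    )
    values = {
        int(t): float(np.clip(baseline + (v - partner_baseline), 0.0, 100.0))
        for t, v in zip(months, partner_va)
    }
    values[0] = baseline
    return Trajectory(
        profile_id=str(profile["patient_id"]),
        source="matched",
        va_by_month=values,
        partner_id=partner_id,
    )


@dataclass(frozen=True)
class VaPredictionModel:
    """Per-horizon-month OLS models of sham VA on (age, female, baseline VA).

    ``models[t]`` holds the coefficient Series (const, age, female,
    baseline_va), the residual sd and the number of participants used.
    ``va_range`` is the baseline-VA range seen in training, used to flag
    extrapolation.
    """

    models: dict[int, dict] = field(default_factory=dict)
    va_range: tuple[float, float] = (0.0, 100.0)


def _sham_design(sham: pd.DataFrame) -> np.ndarray:
    age = sham["age_band"].map(AGE_BAND_MIDPOINT).to_numpy(dtype=float)
    female = (sham["sex"] == "female").to_numpy(dtype=float)
    va = sham["baseline_va"].to_numpy(dtype=float)
    return np.column_stack([age, female, va])


def fit_va_model(
    sham: pd.DataFrame,
    visits: pd.DataFrame,
    months: tuple[int, ...] = (3, 6, 12),
    min_participants: int = 10,
) -> VaPredictionModel:
    """Fit one OLS model per horizon month on the sham arm.

    Each model regresses VA observed at that month on age-band midpoint,
    sex and baseline VA.  Requires at least ``min_participants`` sham
    participants with a visit at every horizon month.
    """
    models: dict[int, dict] = {}
    names = ["const", "age", "female", "baseline_va"]
    for month in months:
        obs = visits[visits["month"] == month][["participant_id", "va"]]
        merged = sham.merge(obs, on="participant_id", suffixes=("", "_obs"))
        if len(merged) < min_participants:
            raise ValueError(
                f"only {len(merged)} sham participants have a month-{month} "
                f"visit; need at least {min_participants}"
            )
        X = sm.add_constant(_sham_design(merged), has_constant="add")
        y = merged["va_obs"] if "va_obs" in merged else merged["va"]
        fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
        resid_sd = float(np.sqrt(fit.scale))
        models[int(month)] = {
            "params": pd.Series(fit.params, index=names),
            "bse": pd.Series(fit.bse, index=names),
            "resid_sd": resid_sd,
            "n": int(len(merged)),
        }
    lo = float(sham["baseline_va"].min())
    hi = float(sham["baseline_va"].max())
    return VaPredictionModel(models=models, va_range=(lo, hi))


def predict_unmatched(
    profile: pd.Series,
    model: VaPredictionModel,
    months: tuple[int, ...] = HORIZON_MONTHS,
) -> Trajectory:
    """Project an unmatched patient with the sham-fitted linear models.

    Month 0 is the patient's own baseline; later months are model
    predictions clamped to [0, 100].  A baseline outside the model's
    training VA range is flagged as extrapolation in the log.
    """
    if not model.models:
        raise ValueError("VA prediction model has no fitted horizon months")
    baseline = float(profile["baseline_va"])
    lo, hi = model.va_range
    if baseline < lo or baseline > hi:
        logger.info(
            "extrapolation: profile %s baseline VA %.0f outside the sham "
            "training range [%.0f, %.0f]",
            profile["patient_id"], baseline, lo, hi,
        )
    age = AGE_BAND_MIDPOINT[profile["age_band"]]
    female = 1.0 if profile["sex"] == "female" else 0.0
    x = np.array([1.0, age, female, baseline])
    values = {0: baseline}
    for month in months:
        if month == 0:
            continue
        params = model.models[month]["params"].to_numpy()
        values[int(month)] = float(np.clip(x @ params, 0.0, 100.0))
    return Trajectory(
        profile_id=str(profile["patient_id"]),
        source="modelled",
        va_by_month=values,
    )


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format table: profile_id, source, month, va, partner_id."""
    rows = [
        {
            "profile_id": t.profile_id,
            "source": t.source,
            "month": month,
            "va": va,
            "partner_id": t.partner_id or "",
        }
        for t in trajectories
        for month, va in sorted(t.va_by_month.items())
    ]
    return pd.DataFrame(rows, columns=["profile_id", "source", "month", "va", "partner_id"])
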