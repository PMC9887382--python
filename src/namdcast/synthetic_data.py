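"""Synthetic stand-ins for the hospital EHR and trial inputs.

The real inputs — two centres' EHR initiation records and a trial
sham-control arm — are not publicly available, so this module generates
cohorts with the statistical structure the analysis assumes:

* weekly initiation counts as a Poisson series around a level + linear
  drift + sinusoidal annual cycle;
* patient baseline profiles drawn independently per covariate from the
  published per-centre margins, with truncated-normal baseline VA;
* a sham arm whose per-participant VA follows a linear decline with a
  random slope (mean 12-month change -9.3 letters by default) plus
  visit-level measurement noise.

Every default in :func:`default_scenario` encodes the study conditions:
Moorfields (MEH) margins and VA 55.9 +/- 16.3, Birmingham (UHB) margins and
51.7 +/- 20.0, weekly levels sized so roughly 325 and 51 initiations fall
in the 20-week interruption window, and a 238-participant sham arm with
baseline 53.61 +/- 14.06.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _stats

from namdcast import _weeks
from namdcast.ehr_preprocess import AGE_BANDS, ETHNICITIES
from namdcast.forecasting import WeeklySeries

Week = _weeks.Week


@dataclass
class WeeklyParams:
    """Weekly initiation-count process for one centre.

    ``level`` is the mean count per week, ``trend`` its drift per week^2,
    ``amplitude``/``phase_weeks`` the sinusoidal annual cycle (period 52
    weeks).  ``deterministic`` replaces the Poisson draw by the rounded
    mean, for exact oracles.
    """

    level: float
    trend: float = 0.0
    amplitude: float = 0.0
    phase_weeks: float = 0.0
    deterministic: bool = False

    def mean_at(self, t: np.ndarray) -> np.ndarray:
        cycle = self.amplitude * np.sin(2.0 * np.pi * (t + self.phase_weeks) / 52.0)
        return np.maximum(0.0, self.level + self.trend * t + cycle)


@dataclass
class ProfileParams:
    """Baseline covariate margins for one centre's initiators."""

    p_female: float
    age_band_probs: dict[str, float]
    ethnicity_probs: dict[str, float]
    p_smoker: float
    va_mean: float
    va_sd: float
    va_min: float = 0.0
    va_max: float = 95.0

    def __post_init__(self):
        for name, probs in (
            ("age_band_probs", self.age_band_probs),
            ("ethnicity_probs", self.ethnicity_probs),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} sums to {total}, expected 1")
        for p in (self.p_female, self.p_smoker):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class ShamParams:
    """Sham-arm generator: baseline VA moments, mean and between-subject sd
    of the 12-month VA change (letters), visit months and the visit-level
    measurement noise sd (letters)."""

    n: int = 238
    baseline_mean: float = 53.61
    baseline_sd: float = 14.06
    mean_change_12m: float = -9.3
    slope_sd_12m: float = 12.0
    visit_months: tuple[int, ...] = (0, 3, 6, 12, 24)
    noise_sd: float = 2.0

    def __post_init__(self):
        if 0 not in self.visit_months or 12 not in self.visit_months:
            raise ValueError("sham visit months must include 0 and 12")


@dataclass
class ScenarioConfig:
    """Full synthetic-study configuration (weekly + profile parameters per
    centre, sham-arm parameters and the top-level seed)."""

    weekly: dict[str, WeeklyParams]
    profiles: dict[str, ProfileParams]
    sham: ShamParams
    n_profiles: dict[str, int]
    seed: int = 17

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            weekly={c: WeeklyParams(**v) for c, v in raw["weekly"].items()},
            profiles={c: ProfileParams(**v) for c, v in raw["profiles"].items()},
            sham=ShamParams(**{
                k: tuple(v) if k == "visit_months" else v
                for k, v in raw["sham"].items()
            }),
            n_profiles={c: int(v) for c, v in raw["n_profiles"].items()},
            seed=int(raw.get("seed", 17)),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "weekly": {c: asdict(v) for c, v in self.weekly.items()},
            "profiles": {c: asdict(v) for c, v in self.profiles.items()},
            "sham": {**asdict(self.sham), "visit_months": list(self.sham.visit_months)},
            "n_profiles": dict(self.n_profiles),
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def default_scenario(seed: int = 17) -> ScenarioConfig:
    """The default study conditions (see module docstring)."""
    return ScenarioConfig(
        weekly={
            "MEH": WeeklyParams(level=16.3, trend=0.0, amplitude=2.0, phase_weeks=0.0),
            "UHB": WeeklyParams(level=2.55, trend=0.0, amplitude=0.6, phase_weeks=0.0),
        },
        profiles={
            "MEH": ProfileParams(
                p_female=0.605,
                age_band_probs={
                    "<65": 0.065, "65-69": 0.072, "70-74": 0.140,
                    "75-79": 0.191, "80-84": 0.232, "85+": 0.300,
                },
                ethnicity_probs={"white": 0.469, "not_white": 0.490,
                                 "not_reported": 0.041},
                p_smoker=0.073,
                va_mean=55.9,
                va_sd=16.3,
            ),
            "UHB": ProfileParams(
                p_female=0.685,
                age_band_probs={
                    "<65": 0.030, "65-69": 0.056, "70-74": 0.154,
                    "75-79": 0.142, "80-84": 0.255, "85+": 0.363,
                },
                ethnicity_probs={"white": 0.745, "not_white": 0.052,
                                 "not_reported": 0.203},
                p_smoker=0.034,
                va_mean=51.7,
                va_sd=20.0,
            ),
        },
        sham=ShamParams(),
        n_profiles={"MEH": 1929, "UHB": 267},
        seed=seed,
    )


def _truncnorm_int(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draws = _stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.floor(draws + 0.5), lo, hi).astype(int)


def gen_weekly_counts(
    config: ScenarioConfig,
    centre: str,
    start: Week = (2018, 1),
    end: Week = (2020, 11),
    seed: int | None = None,
) -> WeeklySeries:
    """Generate the historical weekly initiation series for one centre."""
    params = config.weekly[centre]
    weeks = _weeks.week_range(start, end)
    t = np.arange(len(weeks), dtype=float)
    mean = params.mean_at(t)
    if mean.max() <= 0:
        raise ValueError(
            f"weekly parameters for {centre!r} imply an all-zero series"
        )
    if params.deterministic:
        counts = np.floor(mean + 0.5)
    else:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        counts = rng.poisson(mean).astype(float)
    return WeeklySeries(centre=centre, weeks=tuple(weeks), counts=counts)


def gen_patient_profiles(
    config: ScenarioConfig,
    centre: str,
    n: int | None = None,
    seed: int | None = None,
    weeks: list[Week] | None = None,
) -> pd.DataFrame:
    """Generate baseline patient profiles for one centre.

    Covariates are drawn independently from the configured margins; baseline
    VA from a truncated normal rounded to integer letters; index weeks
    uniformly over ``weeks`` (default: the full 2018-W01..2020-W11 history).
    """
    params = config.profiles[centre]
    n = config.n_profiles[centre] if n is None else n
    if n < 1:
        raise ValueError(f"need n >= 1 profiles, got {n}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if weeks is None:
        weeks = _weeks.week_range((2018, 1), (2020, 11))
    week_idx = rng.integers(0, len(weeks), size=n)
    bands = list(params.age_band_probs)
    assert set(bands) <= set(AGE_BANDS) and set(params.ethnicity_probs) <= set(ETHNICITIES)
    frame = pd.DataFrame(
        {
            "patient_id": [f"{centre}-P{i:05d}" for i in range(n)],
            "centre": centre,
            "sex": np.where(rng.random(n) < params.p_female, "female", "male"),
            "age_band": rng.choice(bands, size=n, p=list(params.age_band_probs.values())),
            "ethnicity": rng.choice(
                list(params.ethnicity_probs),
                size=n,
                p=list(params.ethnicity_probs.values()),
            ),
            "smoker": np.where(rng.random(n) < params.p_smoker, "yes", "no_or_unknown"),
            "index_year": [weeks[i][0] for i in week_idx],
            "index_week": [weeks[i][1] for i in week_idx],
            "study_eye": rng.choice(["left", "right"], size=n),
            "baseline_va": _truncnorm_int(
                rng, params.va_mean, params.va_sd, params.va_min, params.va_max, n
            ),
        }
    )
    return frame


def gen_sham_cohort(
    config: ScenarioConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the sham-arm cohort and its longitudinal visits.

    Each participant gets a latent monthly slope drawn from
    Normal(mean_change_12m/12, slope_sd_12m/12); VA at month m is
    ``clamp(round(baseline + slope*m + noise), 0, 100)`` with the month-0
    visit pinned to the baseline exactly.  Returns (participants, visits)
    with visits long-format (participant_id, month, va).
    """
    params = config.sham
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = params.n
    baseline = _truncnorm_int(rng, params.baseline_mean, params.baseline_sd, 0, 95, n)
    slopes = rng.normal(params.mean_change_12m / 12.0, params.slope_sd_12m / 12.0, size=n)
    # Sham-arm covariate margins follow the trial's published column.
    sham = pd.DataFrame(
        {
            "participant_id": [f"S{i:04d}" for i in range(n)],
            "sex": np.where(rng.random(n) < 0.668, "female", "male"),
            "age_band": rng.choice(
                AGE_BANDS, size=n,
                p=np.array([11, 17, 50, 68, 64, 26]) / 236.0,
            ),
            "ethnicity": np.where(rng.random(n) < 0.971, "white", "not_white"),
            "smoker": np.where(rng.random(n) < 0.546, "yes", "no_or_unknown"),
            "baseline_va": baseline,
        }
    )
    visit_rows = []
    for i in range(n):
        for month in params.visit_months:
            if month == 0:
                va = float(baseline[i])
            else:
                noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
                va = float(
                    np.clip(np.floor(baseline[i] + slopes[i] * month + noise + 0.5),
                            0.0, 100.0)
                )
            visit_rows.append(
                {"participant_id": sham["participant_id"].iloc[i],
                 "month": int(month), "va": va}
            )
    visits = pd.DataFrame(visit_rows)
    return sham, visits
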