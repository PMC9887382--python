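import numpy as np
import pandas as pd
import pytest

from namdcast.ehr_preprocess import AGE_BANDS


def make_profiles(
    n: int,
    centre: str = "MEH",
    va=None,
    seed: int = 0,
    index_year: int = 2018,
    index_week: int = 15,
) -> pd.DataFrame:
    """Small valid profile table with controllable VA values."""
    rng = np.random.default_rng(seed)
    if va is None:
        va = rng.integers(10, 90, size=n)
    va = np.asarray(va)
    assert len(va) == n
    return pd.DataFrame(
        {
            "patient_id": [f"{centre}-P{i:04d}" for i in range(n)],
            "centre": centre,
            "sex": rng.choice(["female", "male"], size=n, p=[0.6, 0.4]),
            "age_band": rng.choice(AGE_BANDS, size=n),
            "ethnicity": rng.choice(["white", "not_white", "not_reported"], size=n),
            "smoker": rng.choice(["yes", "no_or_unknown"], size=n, p=[0.1, 0.9]),
            "index_year": index_year,
            "index_week": index_week,
            "study_eye": rng.choice(["left", "right"], size=n),
            "baseline_va": va,
        }
    )


def make_sham(n: int, seed: int = 0, change_12m: float = -9.3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sham cohort with exactly linear-in-time VA (no noise, no rounding)."""
    rng = np.random.default_rng(seed)
    baseline = rng.integers(20, 80, size=n)
    sham = pd.DataFrame(
        {
            "participant_id": [f"S{i:04d}" for i in range(n)],
            "sex": rng.choice(["female", "male"], size=n),
            "age_band": rng.choice(AGE_BANDS, size=n),
            "ethnicity": rng.choice(["white", "not_white"], size=n, p=[0.97, 0.03]),
            "smoker": rng.choice(["yes", "no_or_unknown"], size=n),
            "baseline_va": baseline,
        }
    )
    rows = []
    for i in range(n):
        for month in (0, 3, 6, 12):
            rows.append(
                {
                    "participant_id": sham["participant_id"].iloc[i],
                    "month": month,
                    "va": float(np.clip(baseline[i] + change_12m * month / 12.0, 0, 100)),
                }
            )
    return sham, pd.DataFrame(rows)


@pytest.fixture
def profiles_small():
    return make_profiles(20, seed=1)
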