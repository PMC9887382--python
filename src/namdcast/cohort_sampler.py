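"""Sample the hypothetical lockdown cohort from the historical pool.

Hypothetical patients are drawn uniformly from patients of the same centre
who initiated treatment during the same calendar window (ISO weeks 12-31)
in the two preceding years, so the sampled cohort inherits the joint
covariate distribution of that season's real presentations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Calendar window of the service interruption, as ISO week numbers.
WINDOW_WEEKS = (12, 31)
#: Years pooled to form the sampling frame.
POOL_YEARS = (2018, 2019)


@dataclass(frozen=True)
class SamplingPool:
    """Historical same-season profiles for one centre."""

    centre: str
    profiles: pd.DataFrame

    def __len__(self) -> int:
        return len(self.profiles)


def build_pool(
    profiles: pd.DataFrame,
    centre: str,
    window_weeks: tuple[int, int] = WINDOW_WEEKS,
    years: tuple[int, ...] = POOL_YEARS,
) -> SamplingPool:
    """Restrict profiles to the centre and the seasonal window/years."""
    lo, hi = window_weeks
    mask = (
        (profiles["centre"] == centre)
        & profiles["index_year"].isin(years)
        & (profiles["index_week"] >= lo)
        & (profiles["index_week"] <= hi)
    )
    pool = profiles[mask].reset_index(drop=True)
    if len(pool) == 0:
        raise ValueError(
            f"empty sampling pool for centre {centre!r} "
            f"(weeks {lo}-{hi} of {years})"
        )
    logger.info("sampling pool for %s: %d profiles (weeks %d-%d of %s)",
                centre, len(pool), lo, hi, years)
    return SamplingPool(centre=centre, profiles=pool)


def sample_profiles(pool: SamplingPool, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` profiles uniformly at random from the pool.

    Sampling is without replacement when the pool is large enough, otherwise
    with replacement (logged).  Sampled rows keep every covariate of their
    source record; they get a fresh ``patient_id`` carrying the draw index,
    plus ``source_patient_id`` and ``draw_index`` columns, so repeated draws
    stay distinguishable downstream.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    replace = n > len(pool)
    if replace:
        logger.warning(
            "requested %d profiles from a pool of %d for %s; "
            "sampling with replacement", n, len(pool), pool.centre,
        )
    idx = rng.choice(len(pool), size=n, replace=replace)
    sample = pool.profiles.iloc[idx].reset_index(drop=True)
    sample.insert(0, "draw_index", np.arange(n))
    sample.insert(0, "source_patient_id", sample.pop("patient_id"))
    sample.insert(
        0,
        "patient_id",
        [f"{pool.centre}-H{i:05d}" for i in range(n)],
    )
    return sample
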