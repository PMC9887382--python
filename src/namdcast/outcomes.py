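"""Cohort-level outcome surfaces: mean VA over time and threshold shares.

Matched and modelled trajectories are pooled per centre; missing later
months are imputed with last observation carried forward so denominators
stay constant, and three clinically anchored thresholds are counted at
each month:

* VA >= 70 letters (6/12) — good independent vision (inclusive);
* VA <  25 letters (6/96) — below the anti-VEGF treatment floor (strict);
* VA <= 20 letters (3/60) — severe-sight-impairment registration (inclusive).

Percentages are reported to one decimal place and standard deviations use
the sample (n-1) convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MONTH_GRID = (0, 3, 6, 12)

_COLUMNS = [
    "centre", "month", "n", "mean_va", "sd_va",
    "n_ge70", "pct_ge70", "n_lt25", "pct_lt25", "n_le20", "pct_le20",
]


@dataclass(frozen=True)
class OutcomeTable:
    """Per-month cohort summary for one centre.

    ``table`` has one row per month with n, mean/sd VA (full precision) and
    count/percent for each threshold; percentages are pre-rounded to one
    decimal.  ``n`` is identical at every month (guaranteed by LOCF).
    """

    centre: str
    table: pd.DataFrame

    def __post_init__(self):
        if self.table["n"].nunique() != 1:
            raise ValueError("denominator differs across months (LOCF missing?)")

    @property
    def n(self) -> int:
        return int(self.table["n"].iloc[0])

    @classmethod
    def from_counts(cls, centre: str, counts: pd.DataFrame) -> "OutcomeTable":
        """Build a threshold-only table from per-month counts.

        ``counts`` needs columns month, n and any of n_ge70/n_lt25/n_le20;
        percentages are computed as 100*count/n to one decimal.  Mean/sd are
        NaN (count fixtures carry no patient-level VA).
        """
        rows = []
        for rec in counts.to_dict("records"):
            n = int(rec["n"])
            row = {"centre": centre, "month": int(rec["month"]), "n": n,
                   "mean_va": np.nan, "sd_va": np.nan}
            for key in ("n_ge70", "n_lt25", "n_le20"):
                value = rec.get(key)
                if value is None or (isinstance(value, float) and np.isnan(value)):
                    row[key] = np.nan
                    row["pct_" + key[2:]] = np.nan
                else:
                    row[key] = int(value)
                    row["pct_" + key[2:]] = round(100.0 * int(value) / n, 1)
            rows.append(row)
        return cls(centre=centre, table=pd.DataFrame(rows, columns=_COLUMNS))


def apply_locf(
    trajectories: pd.DataFrame,
    months: tuple[int, ...] = MONTH_GRID,
) -> pd.DataFrame:
    """Complete every trajectory on the month grid by carrying the last
    observation forward.

    Input/output are long-format (profile_id, source, month, va, ...).
    Every trajectory must include month 0; any grid month without an
    observation receives the most recent earlier value.
    """
    completed = []
    grid = sorted(months)
    for pid, group in trajectories.groupby("profile_id", sort=False):
        group = group.sort_values("month")
        observed = dict(zip(group["month"], group["va"]))
        if 0 not in observed:
            raise ValueError(f"trajectory {pid!r} is missing month 0")
        source = group["source"].iloc[0]
        partner = group["partner_id"].iloc[0] if "partner_id" in group else ""
        last = observed[0]
        for month in grid:
            if month in observed:
                last = observed[month]
            completed.append(
                {"profile_id": pid, "source": source, "month": month,
                 "va": last, "partner_id": partner}
            )
    return pd.DataFrame(completed)


def summarize_outcomes(trajectories: pd.DataFrame, centre: str) -> OutcomeTable:
    """Summarise LOCF-completed trajectories for one centre.

    Per month: n, mean and sample sd of VA, and counts/percentages crossing
    the >=70, <25 and <=20 letter thresholds.
    """
    if len(trajectories) == 0:
        raise ValueError("cannot summarise an empty trajectory set")
    rows = []
    for month, group in trajectories.groupby("month", sort=True):
        va = group["va"].to_numpy(dtype=float)
        n = len(va)
        rows.append(
            {
                "centre": centre,
                "month": int(month),
                "n": n,
                "mean_va": float(va.mean()),
                "sd_va": float(np.std(va, ddof=1)) if n > 1 else 0.0,
                "n_ge70": int((va >= 70).sum()),
                "pct_ge70": round(100.0 * (va >= 70).sum() / n, 1),
                "n_lt25": int((va < 25).sum()),
                "pct_lt25": round(100.0 * (va < 25).sum() / n, 1),
                "n_le20": int((va <= 20).sum()),
                "pct_le20": round(100.0 * (va <= 20).sum() / n, 1),
            }
        )
    return OutcomeTable(centre=centre, table=pd.DataFrame(rows, columns=_COLUMNS))


def _pool_sd(n1: int, m1: float, s1: float, n2: int, m2: float, s2: float) -> float:
    """Sample sd of the union of two groups from their summary statistics,
    including the between-group mean shift."""
    n = n1 + n2
    if n <= 1:
        return 0.0
    mean = (n1 * m1 + n2 * m2) / n
    ss = (
        (n1 - 1) * s1**2 + (n2 - 1) * s2**2
        + n1 * (m1 - mean) ** 2 + n2 * (m2 - mean) ** 2
    )
    return float(np.sqrt(ss / (n - 1)))


def pool_cohorts(a: OutcomeTable, b: OutcomeTable) -> OutcomeTable:
    """Pool two outcome tables for the same centre and month grid.

    Counts add; means recombine size-weighted; sds recombine with the
    pooled-variance formula including the between-group term, so pooling
    two subgroup summaries reproduces the summary of the union exactly.
    Degenerate empty complements (n = 0) act as the identity.
    """
    if a.centre != b.centre:
        raise ValueError(f"centre mismatch: {a.centre!r} vs {b.centre!r}")
    ta = a.table.set_index("month")
    tb = b.table.set_index("month")
    if list(ta.index) != list(tb.index):
        raise ValueError("month grids differ between the pooled tables")
    rows = []
    for month in ta.index:
        ra, rb = ta.loc[month], tb.loc[month]
        n1, n2 = int(ra["n"]), int(rb["n"])
        if n2 == 0:
            rows.append({"centre": a.centre, "month": int(month), **ra.drop("centre")})
            continue
        if n1 == 0:
            rows.append({"centre": a.centre, "month": int(month), **rb.drop("centre")})
            continue
        n = n1 + n2
        mean = (n1 * ra["mean_va"] + n2 * rb["mean_va"]) / n
        sd = _pool_sd(n1, ra["mean_va"], ra["sd_va"], n2, rb["mean_va"], rb["sd_va"])
        row = {"centre": a.centre, "month": int(month), "n": n,
               "mean_va": float(mean), "sd_va": sd}
        for key in ("ge70", "lt25", "le20"):
            count = int(ra[f"n_{key}"] + rb[f"n_{key}"])
            row[f"n_{key}"] = count
            row[f"pct_{key}"] = round(100.0 * count / n, 1)
        rows.append(row)
    return OutcomeTable(centre=a.centre, table=pd.DataFrame(rows, columns=_COLUMNS))
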