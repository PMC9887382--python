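"""CSV interchange schemas, validated readers/writers and the run manifest.

All interchange is plain UTF-8 CSV with fixed headers, '.' decimals and the
empty string for missing values.  Every reader validates the header against
the declared schema and raises :class:`SchemaError` naming the file and the
missing columns, so a malformed input aborts the pipeline at the door
rather than mid-stage.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SCHEMAS: dict[str, list[str]] = {
    "weekly_counts": ["centre", "iso_year", "iso_week", "count"],
    "profiles": [
        "patient_id", "centre", "sex", "age_band", "ethnicity", "smoker",
        "index_year", "index_week", "study_eye", "baseline_va",
    ],
    "hypothetical_cohort": [
        "patient_id", "source_patient_id", "draw_index", "centre", "sex",
        "age_band", "ethnicity", "smoker", "index_year", "index_week",
        "study_eye", "baseline_va",
    ],
    "sham_cohort": [
        "participant_id", "sex", "age_band", "ethnicity", "smoker", "baseline_va",
    ],
    "sham_visits": ["participant_id", "month", "va"],
    "forecast": ["centre", "iso_year", "iso_week", "point", "lo95", "hi95"],
    "forecast_totals": ["centre", "total"],
    "matches": ["centre", "profile_id", "participant_id", "delta_logit"],
    "unmatched": ["centre", "profile_id", "reason"],
    "trajectories": ["centre", "profile_id", "source", "month", "va", "partner_id"],
    "outcomes": [
        "centre", "month", "n", "mean_va", "sd_va",
        "n_ge70", "pct_ge70", "n_lt25", "pct_lt25", "n_le20", "pct_le20",
    ],
    "baseline_summary": ["cohort", "variable", "level", "count", "percent"],
}


class SchemaError(ValueError):
    """A CSV file whose header does not match the declared schema."""


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate its header against ``SCHEMAS[schema]``."""
    path = Path(path)
    expected = SCHEMAS[schema]
    frame = pd.read_csv(path, keep_default_na=True)
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {missing} for schema {schema!r} "
            f"(found {list(frame.columns)})"
        )
    return frame[expected + [c for c in frame.columns if c not in expected]]


def write_table(frame: pd.DataFrame, path: str | Path, schema: str) -> int:
    """Write a CSV in the declared column order; returns the row count."""
    path = Path(path)
    expected = SCHEMAS[schema]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"cannot write {path.name}: missing column(s) {missing}")
    path.parent.mkdir(parents=True, exist_ok=True)
    frame[expected].to_csv(path, index=False)
    return len(frame)


@dataclass
class RunManifest:
    """Record of one pipeline run: seed, config echo, per-stage outputs with
    row counts, and timestamps."""

    version: str
    seed: int
    config: dict
    started: str = ""
    finished: str = ""
    stages: dict[str, dict[str, int]] = field(default_factory=dict)

    def record(self, stage: str, path: str | Path, rows: int) -> None:
        self.stages.setdefault(stage, {})[str(path)] = int(rows)

    def validate(self) -> None:
        """Check that every declared output exists with the declared rows."""
        for stage, outputs in self.stages.items():
            for path, rows in outputs.items():
                p = Path(path)
                if not p.exists():
                    raise FileNotFoundError(f"stage {stage!r} output missing: {path}")
                with open(p, "r", encoding="utf-8") as fh:
                    n = sum(1 for _ in fh) - 1  # header
                if n != rows:
                    raise ValueError(
                        f"stage {stage!r} output {path} has {n} rows, "
                        f"manifest says {rows}"
                    )

    def write(self, path: str | Path) -> None:
        self.finished = _dt.datetime.now().isoformat(timespec="seconds")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived deterministically from the master seed, kept
    below 2**31 so it round-trips through any RNG API."""
    import zlib

    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)
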