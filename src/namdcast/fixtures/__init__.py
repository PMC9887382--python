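"""Packaged encodings of the published baseline tables and pooled counts.

These are transcriptions of printed summary tables, not patient-level data:
the per-cohort categorical counts and VA summaries for the two centres and
the trial sham arm, the matched/unmatched cohort sizes, and the pooled
per-month threshold counts behind the outcome bar charts.  The published
baseline VA >= 70 share for the larger centre is printed inconsistently at
source (a count of 83/325, an abstract percentage of 25.5%, and subgroup
counts summing to 77); ``baseline_ge70_variants`` records all three rather
than adjudicating.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FILES = {
    "table1_counts": "table1_counts.csv",
    "table1_va": "table1_va.csv",
    "table2_counts": "table2_counts.csv",
    "table2_va": "table2_va.csv",
    "figure2_counts": "figure2_counts.csv",
    "figure3_counts": "figure3_counts.csv",
    "baseline_ge70_variants": "baseline_ge70_variants.csv",
}


def load_paper_fixtures() -> dict[str, pd.DataFrame]:
    """Load every packaged fixture table as a DataFrame, keyed by name."""
    out = {}
    root = resources.files("namdcast.fixtures")
    for name, filename in _FILES.items():
        with (root / filename).open("r", encoding="utf-8") as fh:
            out[name] = pd.read_csv(fh)
    return out
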