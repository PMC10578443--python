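"""Reference cohort marginals for the study population the generator emulates.

Eight adolescents wore the wristband in everyday life; per participant we
record usable tag counts, wear hours, wear days and the derived per-day /
per-hour rates.  Nine were enrolled; one never wore the device outside the
clinic and one stopped after four days, so seven completed the full
observation period.  These marginals drive the default synthetic cohort and
the acceptability arithmetic.
"""

from __future__ import annotations

from typing import Dict

import pandas as pd

from .ingest import summarize_cohort_table

N_ENROLLED = 9
N_COMPLETED = 7

_ROWS = [
    # id, sex, age_group, n_tags, n_hours, n_days, mean_hours_per_day, mean_tags_per_hour
    ("0", "M", "10-12", 26, 233.32, 36, 6.48, 0.11),
    ("1", "M", "10-12", 313, 372.09, 35, 10.63, 0.84),
    ("3", "F", "10-12", 9, 29.03, 4, 7.26, 0.31),
    ("4", "M", "10-12", 6, 336.71, 35, 9.62, 0.02),
    ("5", "M", "13-16", 38, 118.65, 29, 4.09, 0.32),
    ("6", "F", "13-16", 73, 419.34, 47, 8.92, 0.17),
    ("7", "F", "13-16", 238, 521.33, 48, 10.86, 0.46),
    ("8", "F", "13-16", 936, 374.93, 36, 10.41, 2.50),
]


def reference_cohort() -> pd.DataFrame:
    """Per-participant wear/tag marginals of the reference cohort."""
    df = pd.DataFrame(_ROWS, columns=[
        "participant", "sex", "age_group", "n_tags", "n_hours", "n_days",
        "mean_hours_per_day", "mean_tags_per_hour",
    ])
    return df.set_index("participant")


def reference_summary() -> Dict[str, float]:
    """Cohort totals/means plus the everyday-wear retention percentage."""
    return summarize_cohort_table(reference_cohort(), n_enrolled=N_ENROLLED,
                                  n_completed=N_COMPLETED)
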