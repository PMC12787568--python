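"""Published per-athlete reference values for an eight-athlete elite cohort.

These are the reported subject-specific calibration outcomes of a validation
study on elite Paralympic track-and-field and triathlon athletes with
running-specific prostheses (athletes 007 and 008 are triathletes, whose
sessions contain no Sprint): mean decision thresholds, mean cadences, and
the held-out stride-counting totals and relative errors.  They serve as the
reference for aggregate (cohort mean +/- SD) reproduction checks; the raw
recordings themselves are not public.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ATHLETES",
    "threshold_table",
    "cadence_table",
    "stride_validation_table",
    "cohort_mean_std",
]

ATHLETES = ["001", "002", "003", "004", "005", "006", "007", "008"]

# mean thresholds in g (t3 absent for triathletes)
_THRESHOLDS = {
    "t1": [1.39, 1.24, 1.16, 1.09, 1.51, 1.62, 1.32, 0.44],
    "t2": [0.80, 0.51, 0.69, 0.78, 0.91, 0.57, 0.67, 0.66],
    "t3": [2.07, 2.49, 1.79, 2.40, 2.20, 1.95, np.nan, np.nan],
}

# mean cadences in strides/min
_CADENCES = {
    "walk": [54, 47, 52, 57, 52, 55, 52, 53],
    "jog": [71, 73, 83, 85, 77, 80, 82, 86],
    "sprint": [117, 125, 114, 131, 121, 112, np.nan, np.nan],
}

# held-out stride-counting validation on gold-standard spans:
# total labelled strides and relative error (%) per activity
_STRIDE_VALIDATION = {
    "walk_strides": [3414, 2801, 2433, 6811, 2879, 4599, 2876, 3007],
    "walk_error_pct": [0.43, -0.59, 1.51, 0.04, -0.47, 0.38, 1.57, -0.13],
    "jog_strides": [2895, 4297, 3875, 5379, 2750, 3199, 3088, 2868],
    "jog_error_pct": [0.01, -0.33, -0.07, -1.00, -0.08, -0.03, 0.45, -0.03],
    "sprint_strides": [1257, 2135, 1929, 1668, 2529, 2674, np.nan, np.nan],
    "sprint_error_pct": [0.42, -2.57, 0.22, 0.32, 1.13, 0.16, np.nan, np.nan],
}


def _table(data: dict) -> pd.DataFrame:
    return pd.DataFrame(data, index=pd.Index(ATHLETES, name="athlete"))


def threshold_table() -> pd.DataFrame:
    """Per-athlete mean thresholds T1-T3 in g."""
    return _table(_THRESHOLDS)


def cadence_table() -> pd.DataFrame:
    """Per-athlete mean Walk/Jog/Sprint cadences in strides/min."""
    return _table(_CADENCES)


def stride_validation_table() -> pd.DataFrame:
    """Per-athlete held-out stride totals and relative errors (%)."""
    return _table(_STRIDE_VALIDATION)


def cohort_mean_std(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean and sample SD per column, ignoring absent (NaN) cells."""
    return pd.DataFrame({"mean": table.mean(), "std": table.std(ddof=1)})
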