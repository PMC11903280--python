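"""Published reference values used as generator defaults and test inputs.

These are transcriptions of the printed cohort-level results of the study
the package reproduces: per-patient Dizziness Handicap Inventory (DHI)
totals, group summaries of the clinical gait tests, and group mean ± SD of
the seven dimensionless spatiotemporal parameters at each self-selected
speed.  They parameterize the synthetic cohort generator and serve as inputs
to the reproduction checks; nothing here is a computed output.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

GROUPS = ("HS", "UV", "BV")
SPEEDS = ("slow", "comfortable", "fast")

#: Per-patient DHI totals (0-100). ``None`` = not available (one BV patient).
DHI_BY_PATIENT: dict[str, list[float | None]] = {
    "BV": [2, 48, 48, 20, 34, 74, 40, None, 46, 12],
    "UV": [68, 8, 20, 11, 6, 64, 52, 2, 14, 22],
}

#: Clinical gait test summaries: group -> (median, min, max).
CLINICAL_SUMMARIES: dict[str, dict[str, tuple[float, float, float]]] = {
    "fga_total":    {"HS": (29, 27, 30), "UV": (27.5, 8, 30), "BV": (19, 15, 29)},
    "tug_s":        {"HS": (9, 7.5, 10.5), "UV": (10, 8.5, 15.5), "BV": (10, 8.5, 14.5)},
    "tandem_steps": {"HS": (10, 4, 11), "UV": (10, 2.5, 10.5), "BV": (0.75, 0, 3)},
}

#: Dimensionless spatiotemporal parameters, mean and SD per group and speed.
#: Comfortable-speed single support comes from the results prose (the printed
#: table omits that row).
_DIMENSIONLESS_ROWS = [
    # speed, parameter, HS mean, HS sd, UV mean, UV sd, BV mean, BV sd
    ("slow", "walking_speed", 0.30, 0.04, 0.25, 0.04, 0.26, 0.04),
    ("slow", "cadence", 28.03, 3.41, 26.83, 4.05, 28.57, 2.78),
    ("slow", "step_length", 0.64, 0.05, 0.56, 0.08, 0.56, 0.10),
    ("slow", "step_width", 0.07, 0.04, 0.11, 0.05, 0.12, 0.05),
    ("slow", "stance_pct_gc", 63.50, 2.60, 66.89, 2.78, 65.10, 2.87),
    ("slow", "double_support_pct_gc", 27.58, 4.15, 33.25, 4.57, 30.53, 4.64),
    ("slow", "single_support_pct_gc", 35.65, 2.18, 33.65, 2.83, 34.57, 3.05),
    ("comfortable", "walking_speed", 0.43, 0.04, 0.35, 0.06, 0.36, 0.08),
    ("comfortable", "cadence", 34.89, 1.62, 32.41, 2.37, 34.12, 2.94),
    ("comfortable", "step_length", 0.75, 0.06, 0.64, 0.13, 0.63, 0.12),
    ("comfortable", "step_width", 0.09, 0.04, 0.11, 0.06, 0.11, 0.06),
    ("comfortable", "stance_pct_gc", 61.43, 1.79, 63.65, 2.66, 62.91, 2.35),
    ("comfortable", "double_support_pct_gc", 23.66, 3.25, 27.50, 4.58, 25.46, 4.47),
    ("comfortable", "single_support_pct_gc", 37.79, 1.94, 36.14, 2.85, 37.45, 3.24),
    ("fast", "walking_speed", 0.60, 0.05, 0.54, 0.05, 0.51, 0.09),
    ("fast", "cadence", 41.53, 2.31, 40.73, 4.64, 41.48, 3.55),
    ("fast", "step_length", 0.86, 0.08, 0.80, 0.12, 0.74, 0.10),
    ("fast", "step_width", 0.10, 0.05, 0.11, 0.05, 0.12, 0.05),
    ("fast", "stance_pct_gc", 59.99, 1.50, 60.31, 2.06, 60.74, 2.83),
    ("fast", "double_support_pct_gc", 20.34, 2.63, 21.66, 3.48, 21.49, 5.23),
    ("fast", "single_support_pct_gc", 39.53, 1.68, 38.64, 1.97, 39.25, 3.10),
]


def dimensionless_reference() -> pd.DataFrame:
    """Tidy frame of the published dimensionless group means and SDs."""
    rows = []
    for speed, param, *vals in _DIMENSIONLESS_ROWS:
        for g, (m, s) in zip(GROUPS, zip(vals[0::2], vals[1::2])):
            rows.append({"speed": speed, "parameter": param, "group": g,
                         "mean": m, "sd": s})
    return pd.DataFrame(rows)


def reference_mean(speed: str, parameter: str, group: str) -> float:
    df = dimensionless_reference()
    sel = df[(df.speed == speed) & (df.parameter == parameter)
             & (df.group == group)]
    return float(sel["mean"].iloc[0])


def reference_sd(speed: str, parameter: str, group: str) -> float:
    df = dimensionless_reference()
    sel = df[(df.speed == speed) & (df.parameter == parameter)
             & (df.group == group)]
    return float(sel["sd"].iloc[0])


def study_clinical_table() -> pd.DataFrame:
    """Per-patient clinical records with the published DHI values.

    FGA/TUG/tandem per-patient values were not published; those columns are
    filled with ``NaN`` here — only DHI supports exact per-patient checks.
    """
    rows = []
    for g in GROUPS:
        dhis = DHI_BY_PATIENT.get(g, [0.0] * 10)  # HS defined as DHI 0
        for i, dhi in enumerate(dhis, start=1):
            rows.append({"subject": f"{g}{i:02d}", "group": g,
                         "dhi_total": math.nan if dhi is None else float(dhi)})
    return pd.DataFrame(rows)


def _range_to_sd(lo: float, hi: float) -> float:
    # range/4 is the usual rough SD for n = 10 samples
    return max((hi - lo) / 4.0, 1e-6)


def clinical_distributions() -> dict[str, dict[str, tuple[float, float, float, float]]]:
    """Truncated-normal parameters (mean, sd, lo, hi) per score and group.

    Means are set to the published medians and SDs to range/4, a standard
    coarse recovery of spread from a printed median (min-max) summary.
    """
    out: dict[str, dict[str, tuple[float, float, float, float]]] = {}
    for score, per_group in CLINICAL_SUMMARIES.items():
        out[score] = {}
        for g, (med, lo, hi) in per_group.items():
            out[score][g] = (float(med), _range_to_sd(lo, hi), float(lo), float(hi))
    # DHI: HS fixed at 0; patients get mean/SD from the per-patient values
    dhi: dict[str, tuple[float, float, float, float]] = {"HS": (0.0, 0.0, 0.0, 0.0)}
    for g, vals in DHI_BY_PATIENT.items():
        arr = np.array([v for v in vals if v is not None], dtype=float)
        dhi[g] = (float(arr.mean()), float(arr.std(ddof=1)), 0.0, 100.0)
    out["dhi_total"] = dhi
    return out
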