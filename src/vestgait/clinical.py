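"""Clinical balance and symptom scores: FGA, TUG, tandem walk, DHI.

* Functional Gait Assessment (FGA): ten walking tasks scored 0-3 each,
  summed to a 0-30 total (higher = better).
* Timed Up and Go (TUG): seconds to rise, walk 3 m, turn, return, sit.
  Mobility bands: < 10 s normal, 10-20 s good, > 29 s impaired; >= 12 s
  flags elevated fall risk.  Times in (20, 29] fall outside the published
  bands and are reported as such rather than silently assigned.
* Tandem walk: heel-to-toe steps achieved out of ~10; half-step credit
  occurs in practice and is stored as given.
* Dizziness Handicap Inventory (DHI): 0-100 symptom questionnaire.
  Published severity bands: 16-34 mild, 36-52 moderate, 54-100 severe,
  0 none.  The bands are non-exhaustive; values in the gaps (1-15, 35, 53)
  are labelled ``unbanded``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

GROUPS = ("HS", "UV", "BV")


class ScoreValidationError(ValueError):
    pass


def fga_total(items) -> int:
    """Sum of the ten FGA item scores; items must be integers in {0,1,2,3}."""
    items = list(items)
    if len(items) != 10:
        raise ScoreValidationError(f"FGA needs exactly 10 items, got {len(items)}")
    total = 0
    for i, it in enumerate(items, start=1):
        if isinstance(it, bool) or it != int(it) or not 0 <= int(it) <= 3:
            raise ScoreValidationError(
                f"FGA item {i} must be an integer in 0..3, got {it!r}")
        total += int(it)
    return total


def tug_category(tug_s: float) -> tuple[str, bool]:
    """Mobility band and fall-risk flag for a TUG time in seconds."""
    if not tug_s > 0:
        raise ScoreValidationError("TUG time must be positive")
    if tug_s < 10:
        band = "normal"
    elif tug_s <= 20:
        band = "good"
    elif tug_s > 29:
        band = "impaired"
    else:
        band = "uncategorized"  # (20, 29]: outside the published bands
    return band, tug_s >= 12


def dhi_band(dhi_total: float) -> str:
    """Severity band of a DHI total; gap values are reported verbatim."""
    if not 0 <= dhi_total <= 100:
        raise ScoreValidationError("DHI must lie in [0, 100]")
    if dhi_total == 0:
        return "none"
    if 16 <= dhi_total <= 34:
        return "mild"
    if 36 <= dhi_total <= 52:
        return "moderate"
    if 54 <= dhi_total <= 100:
        return "severe"
    return "unbanded"


@dataclass
class ClinicalScoreRecord:
    """Validated clinical scores of one participant."""

    subject: str
    group: str
    fga_items: tuple[int, ...] | None = None
    tug_s: float | None = None
    tandem_steps: float | None = None
    dhi_total: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ScoreValidationError(f"group must be one of {GROUPS}")
        if self.fga_items is not None:
            self.fga_items = tuple(self.fga_items)
            fga_total(self.fga_items)
        if self.tug_s is not None:
            tug_category(self.tug_s)
        if self.tandem_steps is not None and self.tandem_steps < 0:
            raise ScoreValidationError("tandem steps must be >= 0")
        if self.dhi_total is not None and not math.isnan(self.dhi_total):
            dhi_band(self.dhi_total)

    @property
    def fga_total(self) -> int | None:
        return None if self.fga_items is None else fga_total(self.fga_items)


def group_summary(records: pd.DataFrame, column: str,
                  statistic: str = "median_minmax") -> pd.DataFrame:
    """Per-group summary of one clinical score column.

    ``records`` needs ``group`` and the score column.  Missing values are
    excluded (their count is reported).  ``statistic`` selects the headline
    column (``median_minmax`` or ``mean``); median, min, max and mean are
    always all reported so discrepant published summaries can be checked
    against both.
    """
    if statistic not in ("median_minmax", "mean"):
        raise ValueError("statistic must be 'median_minmax' or 'mean'")
    rows = []
    for g in GROUPS:
        vals = records.loc[records["group"] == g, column]
        n_missing = int(vals.isna().sum())
        vals = vals.dropna().astype(float)
        if vals.empty:
            continue
        row = {"group": g, "n": int(len(vals)), "n_missing": n_missing,
               "median": float(vals.median()), "min": float(vals.min()),
               "max": float(vals.max()), "mean": float(vals.mean())}
        if statistic == "mean":
            row["printed"] = round(row["mean"])
        else:
            row["printed"] = f"{row['median']:g} ({row['min']:g}-{row['max']:g})"
        rows.append(row)
    if not rows:
        raise ValueError(f"no non-missing values of {column!r} in any group")
    return pd.DataFrame(rows)
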