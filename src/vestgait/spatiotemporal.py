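"""Gait-cycle segmentation and per-cycle spatiotemporal parameters.

A gait cycle runs from one foot strike to the next ipsilateral foot strike
and must contain, strictly in order, the contralateral foot off, the
contralateral foot strike and the ipsilateral foot off.  Thirteen
parameters are computed per cycle; the seven canonical ones (step length,
step width, cadence, walking speed, stance / single-support /
double-support fraction) follow the footprint-based definitions of clinical
gait analysis, with the heel-marker position at the strike frame standing
in for the footprint.  The extended set (stride length/time, step time,
swing fraction, stride speed, step-length asymmetry ratio) completes the
thirteen.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .events import FOOT_OFF, FOOT_STRIKE, GaitEvent
from .trajectories import MarkerTrajectorySet

#: The 13 per-cycle parameters, in report order.
PARAMETERS = (
    "step_length_m", "step_width_m", "cadence_spm", "walking_speed_mps",
    "stance_pct_gc", "single_support_pct_gc", "double_support_pct_gc",
    "stride_length_m", "stride_time_s", "step_time_s", "swing_pct_gc",
    "stride_speed_mps", "step_length_asymmetry",
)


@dataclass
class GaitCycle:
    """One strike-to-strike window with its three interior events."""

    side: str
    initial_strike: int
    contralateral_off: int | None
    contralateral_strike: int | None
    ipsilateral_off: int | None
    terminal_strike: int
    valid: bool = True
    reason: str = ""

    def event_frames(self):
        return (self.initial_strike, self.contralateral_off,
                self.contralateral_strike, self.ipsilateral_off,
                self.terminal_strike)


@dataclass
class SpatioTemporalRecord:
    """Per-cycle values of the 13 parameters, SI units."""

    side: str
    start_frame: int
    step_length_m: float
    step_width_m: float
    cadence_spm: float
    walking_speed_mps: float
    stance_pct_gc: float
    single_support_pct_gc: float
    double_support_pct_gc: float
    stride_length_m: float
    stride_time_s: float
    step_time_s: float
    swing_pct_gc: float
    stride_speed_mps: float
    step_length_asymmetry: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def build_cycles(events: list[GaitEvent],
                 exclusion_windows: list[tuple[int, int]] | None = None,
                 ) -> list[GaitCycle]:
    """Pair consecutive ipsilateral strikes and locate the interior events.

    Cycles missing an interior event, with mis-ordered events, or touching
    an exclusion window (e.g. a walkway turn) are kept but marked invalid
    with a machine-readable reason.  An empty event list yields an empty
    cycle list.
    """
    exclusion_windows = exclusion_windows or []
    events = sorted(events, key=GaitEvent._order)
    cycles: list[GaitCycle] = []
    for side in ("left", "right"):
        contra = "right" if side == "left" else "left"
        own_strikes = [e for e in events
                       if e.side == side and e.kind == FOOT_STRIKE]
        for a, b in zip(own_strikes, own_strikes[1:]):
            win = lambda kind, who: [e.frame for e in events
                                     if e.side == who and e.kind == kind
                                     and a.frame < e.frame < b.frame]
            c_off = win(FOOT_OFF, contra)
            c_strike = win(FOOT_STRIKE, contra)
            i_off = win(FOOT_OFF, side)
            cyc = GaitCycle(side, a.frame,
                            c_off[0] if len(c_off) == 1 else None,
                            c_strike[0] if len(c_strike) == 1 else None,
                            i_off[0] if len(i_off) == 1 else None,
                            b.frame)
            missing = [name for name, v in
                       [("contralateral_off", cyc.contralateral_off),
                        ("contralateral_strike", cyc.contralateral_strike),
                        ("ipsilateral_off", cyc.ipsilateral_off)] if v is None]
            if missing:
                cyc.valid, cyc.reason = False, "missing " + ", ".join(missing)
            elif not all(x < y for x, y in
                         zip(cyc.event_frames(), cyc.event_frames()[1:])):
                cyc.valid, cyc.reason = False, "events out of order"
            else:
                for lo, hi in exclusion_windows:
                    if a.frame < hi and b.frame > lo:
                        cyc.valid, cyc.reason = False, "overlaps exclusion window"
                        break
            cycles.append(cyc)
    cycles.sort(key=lambda c: (c.initial_strike, c.side))
    return cycles


class DegenerateCycleError(ValueError):
    """Raised when geometry (e.g. the line of progression) is undefined."""


def _heel_xy(t: MarkerTrajectorySet, side: str, frame: int) -> np.ndarray:
    label = "LHEE" if side == "left" else "RHEE"
    p = t.get(label)[frame, :2]
    if not np.isfinite(p).all():
        raise DegenerateCycleError(f"{label} missing at frame {frame}")
    return p


def compute_parameters(cycle: GaitCycle, t: MarkerTrajectorySet,
                       ) -> SpatioTemporalRecord:
    """Parameters of one valid cycle from heel prints and event timing.

    Spatial quantities are measured in the horizontal plane: step length
    along the travel axis (the ipsilateral line of progression), step width
    as the perpendicular distance from the contralateral heel print to that
    line.  All values are therefore invariant to rotating or translating
    the laboratory frame.
    """
    if not cycle.valid:
        raise ValueError(f"cycle invalid: {cycle.reason}")
    fs = t.sample_rate
    contra = "right" if cycle.side == "left" else "left"
    p0 = _heel_xy(t, cycle.side, cycle.initial_strike)
    pc = _heel_xy(t, contra, cycle.contralateral_strike)
    p1 = _heel_xy(t, cycle.side, cycle.terminal_strike)

    progression = p1 - p0  # ipsilateral two-footprint line
    stride_length = float(np.hypot(*progression))
    if stride_length < 1e-6:
        raise DegenerateCycleError("identical ipsilateral heel prints: "
                                   "line of progression undefined")
    axis = progression / stride_length
    rel = pc - p0
    step_length = abs(float(rel @ axis))
    step_width = abs(float(axis[0] * rel[1] - axis[1] * rel[0]))

    stride_time = (cycle.terminal_strike - cycle.initial_strike) / fs
    step_time = (cycle.contralateral_strike - cycle.initial_strike) / fs
    stance = 100.0 * (cycle.ipsilateral_off - cycle.initial_strike) \
        / (cycle.terminal_strike - cycle.initial_strike)
    single = 100.0 * (cycle.contralateral_strike - cycle.contralateral_off) \
        / (cycle.terminal_strike - cycle.initial_strike)
    double = 100.0 * ((cycle.contralateral_off - cycle.initial_strike)
                      + (cycle.ipsilateral_off - cycle.contralateral_strike)) \
        / (cycle.terminal_strike - cycle.initial_strike)

    second_step = stride_length - step_length  # contralateral-to-terminal step
    asym = float("nan") if step_length < 1e-9 else second_step / step_length

    return SpatioTemporalRecord(
        side=cycle.side,
        start_frame=cycle.initial_strike,
        step_length_m=step_length,
        step_width_m=step_width,
        cadence_spm=120.0 / stride_time,
        walking_speed_mps=stride_length / stride_time,
        stance_pct_gc=stance,
        single_support_pct_gc=single,
        double_support_pct_gc=double,
        stride_length_m=stride_length,
        stride_time_s=stride_time,
        step_time_s=step_time,
        swing_pct_gc=100.0 - stance,
        stride_speed_mps=stride_length / stride_time,
        step_length_asymmetry=asym,
    )


def records_table(records: list[SpatioTemporalRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def aggregate_trial(records: list[SpatioTemporalRecord]) -> pd.DataFrame:
    """Trial-level arithmetic mean and sample SD (n−1) per parameter.

    With a single cycle the SD is reported missing, not zero.  Raises when
    no valid record is available (the trial should then be excluded and
    logged by the caller).
    """
    if not records:
        raise ValueError("no valid cycles: trial must be excluded")
    df = records_table(records)
    rows = []
    for p in PARAMETERS:
        vals = df[p].dropna()
        rows.append({"parameter": p,
                     "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                     "n_cycles": int(len(vals))})
    return pd.DataFrame(rows)
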