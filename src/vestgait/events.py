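"""Foot-strike / foot-off detection with an ensemble of methods.

Two detectors are provided and a selector picks, per trial, the one whose
event train looks most like clean gait (strict left/right alternation, low
stride-time variability, physiological stance fraction).  This replaces an
operator's visual check with reproducible QC flags.

* ``coordinate``: foot strikes at local maxima of (heel − sacrum) progression
  distance, foot offs at local minima of (toe − sacrum); the classic
  marker-coordinate method for overground walking.
* ``velocity``: stance bounded by the smoothed horizontal foot speed
  crossing below/above a fraction of the mean pelvis speed.

Signals are low-pass filtered (zero-phase Butterworth) before detection.
The speed signal of the velocity detector uses the standard 6 Hz gait
cutoff; the coordinate detector defaults to a gentler 10 Hz because extremum
location is sensitive to phase distortion of the sharp heel-contact kink at
high cadence, while a peak position needs far less noise suppression than a
derivative does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sg

from .trajectories import MarkerTrajectorySet, travel_axis

FOOT_STRIKE, FOOT_OFF = "foot_strike", "foot_off"
SIDES = ("left", "right")
#: Fixed preference order used to break plausibility ties.
METHOD_ORDER = ("coordinate", "velocity")

#: Minimum spacing between same-kind events; 0.35 s caps cadence at ~171
#: steps/min, above any self-selected overground walk.
MIN_EVENT_SPACING_S = 0.35


class TrialUnusableError(RuntimeError):
    """Raised when no plausible gait events can be extracted for a side."""


@dataclass(frozen=True)
class GaitEvent:
    side: str
    kind: str
    frame: int
    time_s: float
    method: str = ""
    qc_flag: bool = False

    def _order(self):
        return (self.frame, self.kind, self.side)


@dataclass
class DetectorReport:
    """Per-method event lists, plausibility scores and the selected method."""

    events_by_method: dict[str, list[GaitEvent]]
    scores: dict[str, float]
    selected: str
    flags: list[str] = field(default_factory=list)

    @property
    def selected_events(self) -> list[GaitEvent]:
        return self.events_by_method[self.selected]


def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2:
        return x
    b, a = sg.butter(2, cutoff_hz / (fs / 2))
    return sg.filtfilt(b, a, x, axis=0)


def _side_markers(side: str) -> tuple[str, str]:
    return ("LHEE", "LTOE") if side == "left" else ("RHEE", "RTOE")


def _check_inputs(t: MarkerTrajectorySet, side: str) -> None:
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    heel, toe = _side_markers(side)
    for label in (heel, toe, "SACR"):
        t.index(label)
    if t.missing_mask()[:, [t.index(heel), t.index(toe), t.index("SACR")]].any():
        raise ValueError("detection requires gap-filled heel/toe/sacrum markers")


def detect_coordinate(t: MarkerTrajectorySet, side: str, *,
                      smooth_hz: float = 10.0,
                      min_spacing_s: float = MIN_EVENT_SPACING_S,
                      ) -> list[GaitEvent]:
    """Strikes/offs from extrema of the travel-aligned heel/toe-to-pelvis distance."""
    _check_inputs(t, side)
    axis = travel_axis(t)  # raises for a stationary subject
    heel_l, toe_l = _side_markers(side)
    heel = _lowpass(t.get(heel_l)[:, :2] @ axis, t.sample_rate, smooth_hz)
    toe = _lowpass(t.get(toe_l)[:, :2] @ axis, t.sample_rate, smooth_hz)
    sacr = _lowpass(t.get("SACR")[:, :2] @ axis, t.sample_rate, smooth_hz)
    dist = int(round(min_spacing_s * t.sample_rate))

    strikes, _ = sg.find_peaks(heel - sacr, distance=dist)
    offs, _ = sg.find_peaks(sacr - toe, distance=dist)
    # refine on the unsmoothed signal: the filtered extremum locates the
    # neighbourhood, the raw argmax removes the filter's residual bias
    raw_heel = t.get(heel_l)[:, :2] @ axis - t.get("SACR")[:, :2] @ axis
    raw_toe = t.get("SACR")[:, :2] @ axis - t.get(toe_l)[:, :2] @ axis
    strikes = _refine_extrema(raw_heel, strikes, 5)
    offs = _refine_extrema(raw_toe, offs, 5)
    events = _assemble(t, side, strikes, offs, "coordinate")
    if sum(e.kind == FOOT_STRIKE for e in events) < 2:
        raise TrialUnusableError(f"fewer than 2 {side} foot strikes detected")
    return events


def detect_velocity(t: MarkerTrajectorySet, side: str, *,
                    threshold_fraction: float = 0.1,
                    smooth_hz: float = 6.0,
                    min_spacing_s: float = MIN_EVENT_SPACING_S,
                    ) -> list[GaitEvent]:
    """Stance bounded by smoothed horizontal foot speed threshold crossings.

    The threshold defaults to 10% of the mean pelvis progression speed;
    crossings below it mark foot strikes, crossings above mark foot offs.
    """
    _check_inputs(t, side)
    if threshold_fraction <= 0:
        raise TrialUnusableError("non-positive speed threshold detects no stance")
    axis = travel_axis(t)
    heel_l, toe_l = _side_markers(side)
    fs = t.sample_rate
    foot = 0.5 * (t.get(heel_l)[:, :2] + t.get(toe_l)[:, :2])
    foot = _lowpass(foot, fs, smooth_hz)
    speed = np.hypot(*np.gradient(foot, 1.0 / fs, axis=0).T)

    sacr = t.get("SACR")[:, :2] @ axis
    duration = (t.n_frames - 1) / fs
    pelvis_speed = abs(sacr[-1] - sacr[0]) / duration
    thr = threshold_fraction * pelvis_speed

    below = speed < thr
    if not below.any():
        raise TrialUnusableError(f"no stance below speed threshold for {side}")
    # morphological cleaning: drop implausibly short stance/swing intervals
    below = _close_short_runs(below, int(round(0.15 * fs)))   # swing gaps
    below = _drop_short_runs(below, int(round(0.20 * fs)))    # stance blips
    if not below.any():
        raise TrialUnusableError(f"no stance below speed threshold for {side}")
    edges = np.diff(below.astype(np.int8))
    strikes = np.flatnonzero(edges == 1) + 1
    offs = np.flatnonzero(edges == -1) + 1
    # refine each boundary to the centre of the smeared speed edge (the
    # extreme of the speed derivative), which is unbiased under the
    # zero-phase smoothing
    accel = np.gradient(speed, 1.0 / fs)
    half = int(round(0.08 * fs))
    strikes = np.array([_edge_centre(accel, f, half, falling=True)
                        for f in strikes], dtype=int)
    offs = np.array([_edge_centre(accel, f, half, falling=False)
                     for f in offs], dtype=int)
    dist = int(round(min_spacing_s * fs))
    strikes = _enforce_spacing(np.sort(strikes), dist)
    offs = _enforce_spacing(np.sort(offs), dist)
    events = _assemble(t, side, strikes, offs, "velocity")
    if sum(e.kind == FOOT_STRIKE for e in events) < 2:
        raise TrialUnusableError(f"fewer than 2 {side} foot strikes detected")
    return events


def _close_short_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    out = mask.copy()
    idx = np.flatnonzero(np.diff(np.r_[1, mask.view(np.int8), 1]))
    for a, b in zip(idx[0::2], idx[1::2]):  # False runs
        if b - a < min_len:
            out[a:b] = True
    return out


def _drop_short_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    out = mask.copy()
    idx = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
    for a, b in zip(idx[0::2], idx[1::2]):  # True runs
        if b - a < min_len:
            out[a:b] = False
    return out


def _edge_centre(accel: np.ndarray, frame: int, half: int, falling: bool) -> int:
    lo, hi = max(frame - half, 0), min(frame + half + 1, len(accel))
    window = accel[lo:hi]
    j = int(np.argmin(window)) if falling else int(np.argmax(window))
    return lo + j


def _refine_extrema(raw: np.ndarray, frames: np.ndarray, half: int) -> np.ndarray:
    out = []
    for f in frames:
        lo, hi = max(f - half, 0), min(f + half + 1, len(raw))
        out.append(lo + int(np.argmax(raw[lo:hi])))
    return np.asarray(out, dtype=int)


def _enforce_spacing(frames: np.ndarray, dist: int) -> np.ndarray:
    kept: list[int] = []
    for f in frames:
        if not kept or f - kept[-1] >= dist:
            kept.append(int(f))
    return np.asarray(kept, dtype=int)


def _assemble(t, side, strikes, offs, method) -> list[GaitEvent]:
    fs = t.sample_rate
    ev = [GaitEvent(side, FOOT_STRIKE, int(f), f / fs, method) for f in strikes]
    ev += [GaitEvent(side, FOOT_OFF, int(f), f / fs, method) for f in offs]
    ev.sort(key=GaitEvent._order)
    return ev


# ---------------------------------------------------------------------------
# Method self-selection
# ---------------------------------------------------------------------------

def _plausibility(events: list[GaitEvent], weights=(1.0, 1.0, 1.0)) -> float:
    """Weighted sum of alternation, stride-time regularity and stance range."""
    strikes = sorted((e for e in events if e.kind == FOOT_STRIKE),
                     key=GaitEvent._order)
    # (i) strict L/R alternation of strikes
    if len(strikes) >= 2:
        alt = np.mean([a.side != b.side for a, b in zip(strikes, strikes[1:])])
    else:
        alt = 0.0
    # (ii) low coefficient of variation of stride times (per side)
    cvs = []
    for side in SIDES:
        tt = [e.time_s for e in strikes if e.side == side]
        if len(tt) >= 3:
            d = np.diff(tt)
            if np.mean(d) > 0:
                cvs.append(np.std(d) / np.mean(d))
    cv_term = 1.0 - min(float(np.mean(cvs)) if cvs else 1.0, 1.0)
    # (iii) stance fraction within the physiological band [55, 75] %GC
    fracs = []
    for side in SIDES:
        own = sorted((e for e in events if e.side == side), key=GaitEvent._order)
        sts = [e for e in own if e.kind == FOOT_STRIKE]
        for a, b in zip(sts, sts[1:]):
            off = [e for e in own if e.kind == FOOT_OFF
                   and a.frame < e.frame < b.frame]
            if off:
                st = 100.0 * (off[0].frame - a.frame) / (b.frame - a.frame)
                fracs.append(55.0 <= st <= 75.0)
    stance_term = float(np.mean(fracs)) if fracs else 0.0
    return float(np.dot(weights, (alt, cv_term, stance_term)))


def _qc_alternation(events: list[GaitEvent]) -> tuple[list[GaitEvent], list[str]]:
    out, flags = [], []
    prev_strike = None
    for e in sorted(events, key=GaitEvent._order):
        if e.kind == FOOT_STRIKE:
            if prev_strike is not None and prev_strike.side == e.side:
                e = GaitEvent(e.side, e.kind, e.frame, e.time_s, e.method, True)
                flags.append(f"non-alternating strike {e.side}@{e.frame}")
            prev_strike = e
        out.append(e)
    return out, flags


def select_events(t: MarkerTrajectorySet, *,
                  methods: dict | None = None,
                  weights=(1.0, 1.0, 1.0)) -> DetectorReport:
    """Run every detector on both sides and keep the most plausible event train.

    Ties are broken by the fixed method order.  Events violating strike
    alternation in the winning train are QC-flagged, not dropped.
    """
    detectors = methods or {"coordinate": detect_coordinate,
                            "velocity": detect_velocity}
    by_method: dict[str, list[GaitEvent]] = {}
    failures: list[str] = []
    for name in METHOD_ORDER:
        if name not in detectors:
            continue
        try:
            ev: list[GaitEvent] = []
            for side in SIDES:
                ev.extend(detectors[name](t, side))
            ev.sort(key=GaitEvent._order)
            by_method[name] = ev
        except (TrialUnusableError, ValueError) as exc:
            failures.append(f"{name}: {exc}")
    for name, fn in detectors.items():  # any extra, user-supplied methods
        if name in by_method or name in METHOD_ORDER:
            continue
        try:
            ev = []
            for side in SIDES:
                ev.extend(fn(t, side))
            ev.sort(key=GaitEvent._order)
            by_method[name] = ev
        except (TrialUnusableError, ValueError) as exc:
            failures.append(f"{name}: {exc}")
    if not by_method:
        raise TrialUnusableError("no usable detection method: " + "; ".join(failures))

    scores = {name: _plausibility(ev, weights) for name, ev in by_method.items()}
    order = list(METHOD_ORDER) + [n for n in by_method if n not in METHOD_ORDER]
    # scores within 0.01 of the best count as tied, resolved by method order
    best = max(scores.values())
    selected = min((n for n in by_method if scores[n] >= best - 0.01),
                   key=order.index)
    flagged, flags = _qc_alternation(by_method[selected])
    by_method[selected] = flagged
    return DetectorReport(events_by_method=by_method, scores=scores,
                          selected=selected, flags=flags + failures)


def events_table(events: list[GaitEvent], meta=None):
    """Events as a tidy DataFrame for CSV export."""
    import pandas as pd

    rows = [{"side": e.side, "kind": e.kind, "frame": e.frame,
             "time_s": e.time_s, "method": e.method, "qc_flag": e.qc_flag}
            for e in events]
    df = pd.DataFrame(rows)
    if meta is not None:
        for k in ("subject_id", "group", "speed", "trial"):
            df.insert(0, k, getattr(meta, k))
    return df
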