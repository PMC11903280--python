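"""Dimensionless (leg-length / gravity) scaling of spatiotemporal parameters.

Stature strongly affects raw gait parameters (taller people take longer
steps), so group comparisons use dimensionless quantities: lengths divided
by leg length L0, times by sqrt(L0/g), speeds by sqrt(g*L0).  Cadence in
steps/min is multiplied by sqrt(L0/g) directly — keeping the per-minute
convention — which is the convention under which dimensionless speed,
step length and cadence satisfy v = s*c/60 exactly, matching the published
group tables (cadence magnitudes ~26-42).  Gait-cycle percentages and
ratios are already dimensionless and pass through unchanged.  Body mass is
carried in the anthropometry for completeness but no parameter here
depends on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .spatiotemporal import PARAMETERS, SpatioTemporalRecord
from .trajectories import Anthropometry

STANDARD_GRAVITY = 9.81  # m/s^2

_LENGTHS = ("step_length_m", "step_width_m", "stride_length_m")
_TIMES = ("stride_time_s", "step_time_s")
_SPEEDS = ("walking_speed_mps", "stride_speed_mps")
_CADENCE = ("cadence_spm",)
# percentages and the asymmetry ratio are untouched

#: dimensionless field name for each SI field (unit suffix dropped)
DIMENSIONLESS_NAMES = {
    "step_length_m": "step_length", "step_width_m": "step_width",
    "stride_length_m": "stride_length", "stride_time_s": "stride_time",
    "step_time_s": "step_time", "walking_speed_mps": "walking_speed",
    "stride_speed_mps": "stride_speed", "cadence_spm": "cadence",
    "stance_pct_gc": "stance_pct_gc",
    "single_support_pct_gc": "single_support_pct_gc",
    "double_support_pct_gc": "double_support_pct_gc",
    "swing_pct_gc": "swing_pct_gc",
    "step_length_asymmetry": "step_length_asymmetry",
}


@dataclass
class DimensionlessRecord:
    """Unitless counterpart of :class:`SpatioTemporalRecord`.

    Carries the leg length and gravity used, so the scaling is exactly
    invertible.
    """

    side: str
    start_frame: int
    step_length: float
    step_width: float
    cadence: float
    walking_speed: float
    stance_pct_gc: float
    single_support_pct_gc: float
    double_support_pct_gc: float
    stride_length: float
    stride_time: float
    step_time: float
    swing_pct_gc: float
    stride_speed: float
    step_length_asymmetry: float
    leg_length_m: float = float("nan")
    g: float = STANDARD_GRAVITY

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def to_dimensionless(r: SpatioTemporalRecord, a: Anthropometry,
                     g: float = STANDARD_GRAVITY) -> DimensionlessRecord:
    if a.leg_length_m <= 0:
        raise ValueError("leg length must be > 0")
    if g <= 0:
        raise ValueError("g must be > 0")
    L0 = a.leg_length_m
    time_scale = math.sqrt(L0 / g)
    vals = {}
    for si in PARAMETERS:
        x = getattr(r, si)
        if si in _LENGTHS:
            x = x / L0
        elif si in _TIMES:
            x = x / time_scale
        elif si in _SPEEDS:
            x = x / math.sqrt(g * L0)
        elif si in _CADENCE:
            x = x * time_scale
        vals[DIMENSIONLESS_NAMES[si]] = x
    return DimensionlessRecord(side=r.side, start_frame=r.start_frame,
                               leg_length_m=L0, g=g, **vals)


def from_dimensionless(d: DimensionlessRecord) -> SpatioTemporalRecord:
    """Exact inverse of :func:`to_dimensionless`."""
    if not (d.leg_length_m > 0):
        raise ValueError("record does not carry a valid leg length")
    L0, g = d.leg_length_m, d.g
    time_scale = math.sqrt(L0 / g)
    vals = {}
    for si in PARAMETERS:
        x = getattr(d, DIMENSIONLESS_NAMES[si])
        if si in _LENGTHS:
            x = x * L0
        elif si in _TIMES:
            x = x * time_scale
        elif si in _SPEEDS:
            x = x * math.sqrt(g * L0)
        elif si in _CADENCE:
            x = x / time_scale
        vals[si] = x
    return SpatioTemporalRecord(side=d.side, start_frame=d.start_frame, **vals)
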