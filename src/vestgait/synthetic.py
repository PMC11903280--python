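"""Parametric gait simulator with exact ground truth, plus cohort sampling.

The walker is the simplest kinematic template whose gait events and
spatiotemporal parameters are known in closed form:

* the pelvis (SACR) advances at constant mean speed with sinusoidal lateral
  sway;
* each foot alternates between a stance phase, during which heel and toe are
  stationary on the ground, and a swing phase whose horizontal motion
  follows a monotone cubic Hermite profile;
* the swing foot leaves the ground and strikes it again with a nonzero
  forward speed (default twice the pelvis speed).  Real heels contact the
  ground with forward velocity; numerically this makes the heel-to-pelvis
  distance extremum coincide with the true contact instant, so
  coordinate-based event detection is exact on noiseless data and unbiased
  under symmetric smoothing.

Every stance therefore begins and ends at an exactly known time, and the
per-cycle parameter table is computed from the template itself, not from
the sampled trajectories.

:func:`generate_cohort` is the statistical counterpart: it draws per-cycle
dimensionless parameters (with a subject-level random intercept, so a mixed
model's random effect is identifiable) and bounded clinical scores for a
three-group cohort, defaulting to the published group means and spreads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import datasets
from .trajectories import MarkerTrajectorySet, TrialMeta

LEFT, RIGHT = "left", "right"
FOOT_STRIKE, FOOT_OFF = "foot_strike", "foot_off"


class WalkerParameterError(ValueError):
    """Raised when a walker specification is kinematically impossible."""


@dataclass
class WalkerSpec:
    """Parameters of the kinematic walking template.

    ``double_support_fraction`` is the total double-support fraction of the
    cycle.  For this symmetric-timing template it is structurally
    ``2*stance_fraction - 1``; passing any other value is rejected rather
    than silently ignored.
    """

    step_length_m: float = 0.65
    step_width_m: float = 0.10
    cadence_spm: float = 105.0
    stance_fraction: float = 0.62
    double_support_fraction: float | None = None
    leg_length_m: float = 0.90
    walkway_length_m: float = 10.0
    sample_rate_hz: float = 100.0
    noise_sd_m: float = 0.0
    dropout_rate: float = 0.0
    asymmetry: float = 1.0  # left/right step-length ratio
    direction: int = 1  # +1 or -1 along the walkway
    seed: int = 0
    # template shape constants
    foot_length_m: float = 0.20
    heel_lift_m: float = 0.05
    sway_amplitude_m: float = 0.02
    contact_speed_ratio: float = 2.0  # swing-foot speed at lift-off/contact, × pelvis speed

    def __post_init__(self) -> None:
        if self.step_length_m <= 0 or self.cadence_spm <= 0:
            raise WalkerParameterError("implied walking speed must be > 0")
        if not (0.5 <= self.stance_fraction < 0.8):
            raise WalkerParameterError("stance_fraction must lie in [0.5, 0.8)")
        implied = 2 * self.stance_fraction - 1
        if self.double_support_fraction is None:
            self.double_support_fraction = implied
        elif abs(self.double_support_fraction - implied) > 1e-9:
            raise WalkerParameterError(
                "symmetric timing fixes total double support at "
                f"2*stance-1 = {implied:.4f}")
        if self.leg_length_m <= 0:
            raise WalkerParameterError("leg_length_m must be > 0")
        if self.noise_sd_m < 0:
            raise WalkerParameterError("noise_sd_m must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise WalkerParameterError("dropout_rate must be in [0, 1)")
        if self.asymmetry <= 0:
            raise WalkerParameterError("asymmetry must be > 0")
        if self.direction not in (1, -1):
            raise WalkerParameterError("direction must be +1 or -1")

    @property
    def step_time_s(self) -> float:
        return 60.0 / self.cadence_spm

    @property
    def stride_time_s(self) -> float:
        return 2 * self.step_time_s

    @property
    def walking_speed_mps(self) -> float:
        """Mean progression speed; = step length × cadence / 60."""
        return self.step_length_m * self.cadence_spm / 60.0


@dataclass
class GroundTruth:
    """Exact events and per-cycle parameters of one generated pass."""

    events: pd.DataFrame  # side, kind, frame, time_s
    cycles: pd.DataFrame  # side, start/end frames + 13 parameter columns
    spec: WalkerSpec


def _hermite(u: np.ndarray, m0: float, m1: float) -> np.ndarray:
    """Cubic Hermite from 0 to 1 with endpoint slopes m0, m1 (monotone for m<3)."""
    return (3 * u**2 - 2 * u**3
            + m0 * (u**3 - 2 * u**2 + u)
            + m1 * (u**3 - u**2))


def generate_walk(spec: WalkerSpec) -> tuple[MarkerTrajectorySet, GroundTruth]:
    """Simulate one straight pass along the walkway.

    Returns the sampled marker set (LHEE, RHEE, LTOE, RTOE, SACR) and the
    exact ground truth of the noiseless template.  Noise and dropout are
    applied after the truth is recorded, in that order.
    """
    tau = spec.step_time_s
    T = spec.stride_time_s
    s = spec.stance_fraction
    fs = spec.sample_rate_hz
    v = spec.walking_speed_mps
    a = spec.asymmetry
    L_left = 2 * a / (1 + a) * spec.step_length_m   # step ending at a left strike
    L_right = 2 / (1 + a) * spec.step_length_m

    n_steps = max(int(math.ceil(spec.walkway_length_m / spec.step_length_m)), 4)
    # footprint k strikes at t_k = k*tau; even k = left. Pad both ends so
    # every sampled frame lies inside a defined stride of each foot.
    ks = np.arange(-3, n_steps + 4)
    t_k = ks * tau
    incr = np.where(ks % 2 == 0, L_left, L_right)  # step ending at print k
    x_k = np.concatenate([[0.0], np.cumsum(incr[1:])])
    x_k -= x_k[ks.tolist().index(0)]

    t_end = n_steps * tau
    n_frames = int(math.floor(t_end * fs)) + 1
    t = np.arange(n_frames) / fs

    half_w = spec.step_width_m / 2.0
    pos = {}
    for side in (LEFT, RIGHT):
        parity = 0 if side == LEFT else 1
        own = np.flatnonzero(ks % 2 == parity)
        own_t, own_x = t_k[own], x_k[own]
        j = np.searchsorted(own_t, t, side="right") - 1
        rel = t - own_t[j]
        in_stance = rel <= s * T + 1e-12
        D = own_x[j + 1] - own_x[j]
        u = np.clip((rel - s * T) / ((1 - s) * T), 0.0, 1.0)
        # endpoint slope per unit u giving foot speed ratio×v at lift-off/contact
        m = spec.contact_speed_ratio * v * (1 - s) * T / D
        f = _hermite(u, m, m)
        x = np.where(in_stance, own_x[j], own_x[j] + D * f)
        z = np.where(in_stance, 0.0, spec.heel_lift_m * np.sin(np.pi * u))
        y = np.full_like(t, half_w if side == LEFT else -half_w)
        heel = np.column_stack([x, y, z])
        toe = heel + np.array([spec.foot_length_m, 0.0, 0.0])
        pos["LHEE" if side == LEFT else "RHEE"] = heel
        pos["LTOE" if side == LEFT else "RTOE"] = toe

    sacr = np.column_stack([
        v * t - spec.step_length_m / 2.0,
        spec.sway_amplitude_m * np.sin(2 * np.pi * t / T),
        np.full_like(t, spec.leg_length_m),
    ])
    pos["SACR"] = sacr

    markers = ["LHEE", "RHEE", "LTOE", "RTOE", "SACR"]
    P = np.stack([pos[mk] for mk in markers], axis=1)

    truth = _ground_truth(spec, ks, t_k, x_k, n_steps, t_end)

    if spec.direction == -1:
        # rotate 180 deg about the vertical axis, keep x within the walkway
        P[:, :, 0] = spec.walkway_length_m - P[:, :, 0]
        P[:, :, 1] = -P[:, :, 1]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_m > 0:
        P = P + rng.normal(0.0, spec.noise_sd_m, size=P.shape)
    if spec.dropout_rate > 0:
        drop = rng.random((n_frames, len(markers))) < spec.dropout_rate
        P[drop] = np.nan

    traj = MarkerTrajectorySet(sample_rate=fs, markers=markers, positions=P,
                               meta=TrialMeta())
    return traj, truth


def _ground_truth(spec, ks, t_k, x_k, n_steps, t_end) -> GroundTruth:
    tau, T, s = spec.step_time_s, spec.stride_time_s, spec.stance_fraction
    fs = spec.sample_rate_hz
    side_of = lambda k: LEFT if k % 2 == 0 else RIGHT
    idx = {int(k): i for i, k in enumerate(ks)}

    ev = []
    for k in range(-2, n_steps + 1):
        t_strike = k * tau
        if 0 <= t_strike <= t_end:
            ev.append((side_of(k), FOOT_STRIKE, t_strike))
        t_off = k * tau + s * T
        if 0 <= t_off <= t_end:
            ev.append((side_of(k), FOOT_OFF, t_off))
    ev.sort(key=lambda e: (e[2], e[1]))
    events = pd.DataFrame(
        [{"side": sd, "kind": kd, "frame": int(round(tt * fs)), "time_s": tt}
         for sd, kd, tt in ev])

    rows = []
    for k in range(0, n_steps - 1):
        x0, x1, x2 = (x_k[idx[k]], x_k[idx[k + 1]], x_k[idx[k + 2]])
        step = x1 - x0
        stride = x2 - x0
        rows.append({
            "side": side_of(k),
            "start_frame": int(round(k * tau * fs)),
            "end_frame": int(round((k + 2) * tau * fs)),
            "step_length_m": step,
            "step_width_m": spec.step_width_m,
            "cadence_spm": 120.0 / T,
            "walking_speed_mps": stride / T,
            "stance_pct_gc": 100.0 * s,
            "single_support_pct_gc": 100.0 * (1 - s),
            "double_support_pct_gc": 100.0 * (2 * s - 1),
            "stride_length_m": stride,
            "stride_time_s": T,
            "step_time_s": tau,
            "swing_pct_gc": 100.0 * (1 - s),
            "stride_speed_mps": stride / T,
            "step_length_asymmetry": (x2 - x1) / step,
        })
    return GroundTruth(events=events, cycles=pd.DataFrame(rows), spec=spec)


def generate_back_and_forth(spec: WalkerSpec, n_passes: int = 3,
                            ) -> list[tuple[MarkerTrajectorySet, GroundTruth]]:
    """Successive walkway passes in alternating directions.

    Passes are generated separately (the turn at the walkway end is not
    simulated and is thereby excluded from analysis); each pass gets a
    derived seed so noise realisations differ.
    """
    out = []
    for i in range(n_passes):
        p = WalkerSpec(**{**spec.__dict__,
                          "direction": spec.direction * (-1) ** i,
                          "seed": spec.seed + 1000 * i})
        out.append(generate_walk(p))
    return out


def walker_spec_from_dimensionless(step_length, cadence, stance_pct,
                                   step_width, leg_length_m,
                                   g: float = 9.81, **kwargs) -> WalkerSpec:
    """Build an SI walker from dimensionless targets for a given leg length."""
    root = math.sqrt(leg_length_m / g)
    return WalkerSpec(step_length_m=step_length * leg_length_m,
                      step_width_m=step_width * leg_length_m,
                      cadence_spm=cadence / root,
                      stance_fraction=stance_pct / 100.0,
                      leg_length_m=leg_length_m, **kwargs)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Three-group cohort with planted parameter and clinical-score structure.

    ``parameter_reference`` is a tidy frame (speed, parameter, group, mean,
    sd); defaults to the published group table.  ``icc`` splits each SD into
    a between-subject intercept (variance ``icc*sd^2``) and within-subject
    cycle noise, so repeated cycles per subject are properly correlated.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {g: 10 for g in datasets.GROUPS})
    parameter_reference: pd.DataFrame = field(
        default_factory=datasets.dimensionless_reference)
    clinical: dict = field(default_factory=datasets.clinical_distributions)
    icc: float = 0.5
    cycles_per_subject: int = 20
    speeds: tuple[str, ...] = datasets.SPEEDS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if (self.parameter_reference["sd"] < 0).any():
            raise ValueError("parameter SDs must be >= 0")
        if not 0 <= self.icc <= 1:
            raise ValueError("icc must be in [0, 1]")
        for score, per_group in self.clinical.items():
            for g, (mean, sd, lo, hi) in per_group.items():
                if sd < 0 or not lo <= mean <= hi:
                    raise ValueError(f"invalid clinical distribution {score}/{g}")


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-cycle dimensionless parameters and clinical scores.

    Returns ``(cycles, clinical)``.  ``cycles`` has one row per subject ×
    speed × cycle with a column per parameter; subject values share a random
    intercept.  ``clinical`` has one row per subject with FGA items/total,
    TUG, tandem steps and DHI (bounded by truncation; integer or half-step
    granularity where the instruments demand it).
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.parameter_reference
    params = list(dict.fromkeys(ref["parameter"]))

    cyc_rows = []
    clin_rows = []
    for group, n_sub in spec.group_sizes.items():
        for i in range(1, n_sub + 1):
            subject = f"{group}{i:02d}"
            for speed in spec.speeds:
                sub = ref[(ref.speed == speed) & (ref.group == group)]
                lut = {r.parameter: (r.mean, r.sd) for r in sub.itertuples()}
                draws = {}
                for p in params:
                    mean, sd = lut[p]
                    b = rng.normal(0.0, math.sqrt(spec.icc) * sd)
                    e = rng.normal(0.0, math.sqrt(1 - spec.icc) * sd,
                                   size=spec.cycles_per_subject)
                    draws[p] = mean + b + e
                for c in range(spec.cycles_per_subject):
                    row = {"subject": subject, "group": group,
                           "speed": speed, "cycle": c}
                    row.update({p: draws[p][c] for p in params})
                    cyc_rows.append(row)
            clin_rows.append(_draw_clinical(rng, spec, subject, group))

    return pd.DataFrame(cyc_rows), pd.DataFrame(clin_rows)


def _draw_clinical(rng, spec: CohortSpec, subject: str, group: str) -> dict:
    out = {"subject": subject, "group": group}
    mean, sd, lo, hi = spec.clinical["fga_total"][group]
    ability = float(_truncnorm(rng, mean / 10.0, sd / 10.0, 0.0, 3.0, 1)[0])
    if sd == 0:
        items = np.full(10, int(round(ability)))
    else:
        items = np.clip(np.round(rng.normal(ability, 0.5, size=10)), 0, 3)
    items = items.astype(int)
    for j, it in enumerate(items, start=1):
        out[f"fga_item_{j}"] = int(it)
    out["fga_total"] = int(items.sum())

    mean, sd, lo, hi = spec.clinical["tug_s"][group]
    out["tug_s"] = float(_truncnorm(rng, mean, sd, max(lo, 1e-6), hi, 1)[0])

    mean, sd, lo, hi = spec.clinical["tandem_steps"][group]
    steps = float(_truncnorm(rng, mean, sd, lo, hi, 1)[0])
    out["tandem_steps"] = round(steps * 2) / 2  # half-step credit

    mean, sd, lo, hi = spec.clinical["dhi_total"][group]
    if sd == 0:
        out["dhi_total"] = float(mean)
    else:
        out["dhi_total"] = float(np.round(_truncnorm(rng, mean, sd, lo, hi, 1)[0]))
    return out
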