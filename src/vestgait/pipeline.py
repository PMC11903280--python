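"""End-to-end orchestration: simulate/read → events → parameters → stats.

``run`` drives the full chain on either a simulated cohort (three groups,
three self-selected speeds, three trials each by default) or a directory of
trajectory CSVs, and writes per-cycle parameter tables (raw SI and
dimensionless), group summary tables shaped like the published clinical and
gait tables, the statistical report, cluster composition tables and an
exclusion audit log.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
import shutil
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .clinical import group_summary
from .cluster import cluster_report, two_step_cluster
from .events import TrialUnusableError, select_events
from .normalization import DIMENSIONLESS_NAMES, STANDARD_GRAVITY, to_dimensionless
from .spatiotemporal import PARAMETERS, build_cycles, compute_parameters
from .stats import kw_dunn, mixed_model_by_speed, shapiro_screen
from .synthetic import (CohortSpec, _draw_clinical, generate_walk,
                        walker_spec_from_dimensionless)
from .trajectories import Anthropometry, fill_gaps, read_trial

#: Parameters carried into the group statistics (the canonical seven).
CORE_PARAMETERS = ("walking_speed", "cadence", "step_length", "step_width",
                   "stance_pct_gc", "double_support_pct_gc",
                   "single_support_pct_gc")

CLINICAL_SCORES = ("fga_total", "tug_s", "tandem_steps", "dhi_total")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Validated options for one pipeline run."""

    output_dir: str = "vestgait_out"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None  # trajectory CSVs when simulate=False
    clinical_csv: str | None = None
    anthropometry_csv: str | None = None
    group_sizes: dict = field(default_factory=lambda: {g: 10 for g in datasets.GROUPS})
    speeds: tuple = datasets.SPEEDS
    trials_per_condition: int = 3
    g: float = STANDARD_GRAVITY
    icc: float = 0.5
    noise_sd_m: float = 0.0
    dropout_rate: float = 0.0
    smooth_hz: float = 6.0
    max_gap_frames: int = 50
    side_filter: str | None = None  # None pools both sides
    fdr_method: str = "fdr_bh"
    cluster_x: str = "dhi_total"
    cluster_y: str = "fga_total"
    cluster_kmax: int = 5
    walkway_length_m: float = 10.0


def validate_config(options: dict | RunConfig | None = None) -> RunConfig:
    """Normalize a config mapping: inject defaults, reject unknown keys."""
    if isinstance(options, RunConfig):
        cfg = options
    else:
        options = dict(options or {})
        known = {f.name for f in dc_fields(RunConfig)}
        unknown = sorted(set(options) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        cfg = RunConfig(**options)
    if cfg.g <= 0:
        raise ValueError("g must be > 0")
    if cfg.trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    bad = [s for s in cfg.speeds if s not in datasets.SPEEDS]
    if bad:
        raise ValueError(f"unknown speed conditions: {bad}")
    if not (0 <= cfg.icc <= 1):
        raise ValueError("icc must be in [0, 1]")
    if not cfg.simulate:
        if not cfg.input_dir or not Path(cfg.input_dir).is_dir():
            raise ValueError("input_dir must exist when simulate is false")
        for key in ("clinical_csv", "anthropometry_csv"):
            path = getattr(cfg, key)
            if path and not Path(path).is_file():
                raise ValueError(f"{key} does not exist: {path}")
    cfg.speeds = tuple(cfg.speeds)
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Cohort simulation (subject-level targets -> walker trials)
# ---------------------------------------------------------------------------

def _simulate_subjects(cfg: RunConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw anthropometry, clinical scores and dimensionless targets."""
    ref = datasets.dimensionless_reference()
    spec = CohortSpec(group_sizes=dict(cfg.group_sizes), icc=cfg.icc,
                      speeds=cfg.speeds, seed=cfg.seed)
    subj_rows, clin_rows = [], []
    for group, n in cfg.group_sizes.items():
        for i in range(1, n + 1):
            subject = f"{group}{i:02d}"
            height = float(rng.normal(1.68, 0.08))
            leg = 0.53 * height
            mass = float(rng.normal(26.0, 3.0)) * height**2  # BMI-based
            row = {"subject": subject, "group": group, "height_m": height,
                   "leg_length_m": leg, "body_mass_kg": mass}
            for speed in cfg.speeds:
                sub = ref[(ref.speed == speed) & (ref.group == group)]
                for r in sub.itertuples():
                    b = rng.normal(0.0, math.sqrt(cfg.icc) * r.sd)
                    row[f"{speed}:{r.parameter}"] = r.mean + b
            subj_rows.append(row)
            clin_rows.append(_draw_clinical(rng, spec, subject, group))
    return pd.DataFrame(subj_rows), pd.DataFrame(clin_rows)


def _trial_targets(subj_row, speed, cfg, ref, rng) -> dict:
    """Per-trial dimensionless walker targets around the subject mean."""
    out = {}
    sub = ref[(ref.speed == speed) & (ref.group == subj_row["group"])]
    for r in sub.itertuples():
        mean = subj_row[f"{speed}:{r.parameter}"]
        out[r.parameter] = mean + rng.normal(0.0, math.sqrt(1 - cfg.icc) * r.sd)
    # keep the walker constructible
    out["step_length"] = max(out["step_length"], 0.2)
    out["cadence"] = max(out["cadence"], 10.0)
    out["step_width"] = min(max(out["step_width"], 0.01), 0.4)
    out["stance_pct_gc"] = min(max(out["stance_pct_gc"], 52.0), 78.0)
    return out


def _process_trial(traj, anthro, cfg, meta) -> tuple[list[dict], pd.DataFrame, list[dict]]:
    """fill gaps → detect events → cycles → parameters → dimensionless."""
    exclusions: list[dict] = []
    filled, gap_report = fill_gaps(traj, cfg.max_gap_frames)
    for marker, start, stop, why in gap_report.left_missing:
        exclusions.append({**meta, "stage": "gap_fill",
                           "detail": f"{marker} frames {start}-{stop}: {why}"})
    report = select_events(filled)
    cycles = build_cycles(report.selected_events)
    rows = []
    for cyc in cycles:
        if not cyc.valid:
            exclusions.append({**meta, "stage": "cycles",
                               "detail": f"{cyc.side}@{cyc.initial_strike}: {cyc.reason}"})
            continue
        if cfg.side_filter and cyc.side != cfg.side_filter:
            continue
        rec = compute_parameters(cyc, filled)
        dim = to_dimensionless(rec, anthro, cfg.g)
        row = dict(meta)
        row.update({"side": rec.side, "cycle_start_frame": rec.start_frame,
                    "method": report.selected})
        for si in PARAMETERS:
            row[si] = getattr(rec, si)
            row["dimless:" + DIMENSIONLESS_NAMES[si]] = \
                getattr(dim, DIMENSIONLESS_NAMES[si])
        rows.append(row)
    return rows, gap_report, exclusions


def run(config: dict | RunConfig | None = None,
        output_dir: str | None = None) -> dict:
    """Execute the full pipeline; returns the report bundle in memory.

    Outputs written to ``output_dir``: ``cycles_raw.csv``,
    ``cycles_dimensionless.csv``, ``clinical.csv``, ``clinical_summary.csv``,
    ``parameter_summary.csv``, ``stats_report.csv``, ``cluster_*.csv``,
    ``exclusions.csv`` and ``run_config.json``.  A stage failure removes
    partial outputs and raises :class:`StageError` naming the stage.
    """
    cfg = validate_config(config)
    if output_dir is not None:
        cfg.output_dir = output_dir
    out = Path(cfg.output_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        bundle = _run_stages(cfg, out)
    except StageError:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise
    return bundle


def _run_stages(cfg: RunConfig, out: Path) -> dict:
    rng = np.random.default_rng(cfg.seed)
    exclusions: list[dict] = []

    # ---- acquire trials -------------------------------------------------
    try:
        if cfg.simulate:
            subjects, clinical = _simulate_subjects(cfg, rng)
            ref = datasets.dimensionless_reference()
            trials = []
            for _, srow in subjects.iterrows():
                anthro = Anthropometry(height_m=srow.height_m,
                                       body_mass_kg=srow.body_mass_kg,
                                       leg_length_m=srow.leg_length_m)
                for speed in cfg.speeds:
                    for tr in range(1, cfg.trials_per_condition + 1):
                        targets = _trial_targets(srow, speed, cfg, ref, rng)
                        wspec = walker_spec_from_dimensionless(
                            targets["step_length"], targets["cadence"],
                            targets["stance_pct_gc"], targets["step_width"],
                            srow.leg_length_m, cfg.g,
                            walkway_length_m=cfg.walkway_length_m,
                            noise_sd_m=cfg.noise_sd_m,
                            dropout_rate=cfg.dropout_rate,
                            direction=(-1) ** (tr - 1),
                            seed=int(rng.integers(2**31 - 1)))
                        traj, _ = generate_walk(wspec)
                        meta = {"subject": srow.subject, "group": srow.group,
                                "speed": speed, "trial": tr}
                        trials.append((traj, anthro, meta))
        else:
            trials, clinical = _load_trials(cfg)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("acquire", str(exc)) from exc

    # ---- trajectory processing -----------------------------------------
    cycle_rows: list[dict] = []
    for traj, anthro, meta in trials:
        try:
            rows, _, excl = _process_trial(traj, anthro, cfg, meta)
            exclusions.extend(excl)
            if not rows:
                exclusions.append({**meta, "stage": "trial",
                                   "detail": "no valid cycles; trial excluded"})
            cycle_rows.extend(rows)
        except TrialUnusableError as exc:
            exclusions.append({**meta, "stage": "events", "detail": str(exc)})
        except Exception as exc:
            raise StageError("process", f"{meta}: {exc}") from exc
    if not cycle_rows:
        raise StageError("process", "no valid gait cycles in any trial")
    cycles = pd.DataFrame(cycle_rows)

    # ---- statistics ------------------------------------------------------
    try:
        dim = cycles[["subject", "group", "speed", "trial"]].copy()
        for p in CORE_PARAMETERS:
            dim[p] = cycles["dimless:" + p]
        stats_report = mixed_model_by_speed(dim, CORE_PARAMETERS)
        normality = [{"speed": sp, "parameter": p, "group": g,
                      **shapiro_screen(dim.loc[(dim.speed == sp)
                                               & (dim.group == g), p])}
                     for sp in cfg.speeds for p in CORE_PARAMETERS
                     for g in dim.group.unique()]
        clin_stats = []
        for score in CLINICAL_SCORES:
            if score not in clinical.columns:
                continue
            by_group = {g: clinical.loc[clinical.group == g, score].dropna()
                        for g in clinical.group.unique()}
            res = kw_dunn(by_group, outcome=score)
            row = {"outcome": score, "H": res.statistic, "p": res.p_value}
            for pair, p in res.pairwise.items():
                row[f"p_{pair[0]}_vs_{pair[1]}"] = p
            clin_stats.append(row)
        clin_stats = pd.DataFrame(clin_stats)
    except Exception as exc:
        raise StageError("stats", str(exc)) from exc

    # ---- summary tables --------------------------------------------------
    try:
        param_summary = _parameter_summary(dim, stats_report)
        clin_summary = pd.concat(
            [group_summary(clinical, s,
                           "mean" if s == "dhi_total" else "median_minmax")
             .assign(score=s) for s in CLINICAL_SCORES
             if s in clinical.columns],
            ignore_index=True)
    except Exception as exc:
        raise StageError("summaries", str(exc)) from exc

    # ---- clustering ------------------------------------------------------
    try:
        cvars = [cfg.cluster_x, cfg.cluster_y]
        model = two_step_cluster(clinical, cvars, k_max=cfg.cluster_kmax)
        kept = clinical.loc[model.case_index]
        comp = cluster_report(model, kept["group"], values=kept[cvars])
        assignments = kept[["subject", "group", *cvars]].copy()
        assignments["cluster"] = model.assignments + 1
    except Exception as exc:
        raise StageError("cluster", str(exc)) from exc

    # ---- write ----------------------------------------------------------
    try:
        raw_cols = [c for c in cycles.columns if not c.startswith("dimless:")]
        cycles[raw_cols].to_csv(out / "cycles_raw.csv", index=False)
        cycles.to_csv(out / "cycles_dimensionless.csv", index=False)
        clinical.to_csv(out / "clinical.csv", index=False)
        clin_summary.to_csv(out / "clinical_summary.csv", index=False)
        param_summary.to_csv(out / "parameter_summary.csv", index=False)
        stats_report.to_csv(out / "stats_report.csv", index=False)
        pd.DataFrame(normality).to_csv(out / "normality.csv", index=False)
        clin_stats.to_csv(out / "clinical_stats.csv", index=False)
        comp.to_csv(out / "cluster_composition.csv", index=False)
        model.bic.to_csv(out / "cluster_bic.csv", index=False)
        assignments.to_csv(out / "cluster_assignments.csv", index=False)
        pd.DataFrame(exclusions,
                     columns=["subject", "group", "speed", "trial",
                              "stage", "detail"]).to_csv(
            out / "exclusions.csv", index=False)
        with open(out / "run_config.json", "w") as fh:
            json.dump(asdict(cfg), fh, indent=2, default=str)
    except Exception as exc:
        raise StageError("write", str(exc)) from exc

    return {"cycles": cycles, "clinical": clinical,
            "stats_report": stats_report, "clinical_stats": clin_stats,
            "parameter_summary": param_summary,
            "clinical_summary": clin_summary,
            "cluster_model": model, "cluster_composition": comp,
            "exclusions": pd.DataFrame(exclusions), "config": cfg}


def _parameter_summary(dim: pd.DataFrame, stats_report: pd.DataFrame,
                       ) -> pd.DataFrame:
    """Mean ± SD per group/speed/parameter with significance columns."""
    rows = []
    for sp in dim["speed"].unique():
        for p in CORE_PARAMETERS:
            row = {"speed": sp, "parameter": p}
            for g in dim["group"].unique():
                v = dim.loc[(dim.speed == sp) & (dim.group == g), p]
                row[f"{g}_mean"] = float(v.mean())
                row[f"{g}_sd"] = float(v.std(ddof=1))
            sel = stats_report[(stats_report.speed == sp)
                               & (stats_report.parameter == p)]
            if len(sel):
                row["p_raw"] = float(sel["p_raw"].iloc[0])
                row["p_adj"] = float(sel["p_adj"].iloc[0])
            rows.append(row)
    return pd.DataFrame(rows)


def _load_trials(cfg: RunConfig):
    """Read trajectory CSVs plus clinical and anthropometry side tables."""
    anthro_df = pd.read_csv(cfg.anthropometry_csv).set_index("subject") \
        if cfg.anthropometry_csv else None
    clinical = pd.read_csv(cfg.clinical_csv) if cfg.clinical_csv \
        else pd.DataFrame(columns=["subject", "group", *CLINICAL_SCORES])
    trials = []
    paths = sorted(Path(cfg.input_dir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trial CSVs in {cfg.input_dir}")
    for path in paths:
        traj = read_trial(path)
        meta = {"subject": traj.meta.subject_id, "group": traj.meta.group,
                "speed": traj.meta.speed, "trial": traj.meta.trial}
        if anthro_df is not None and traj.meta.subject_id in anthro_df.index:
            arow = anthro_df.loc[traj.meta.subject_id]
            anthro = Anthropometry(height_m=arow.height_m,
                                   body_mass_kg=arow.body_mass_kg,
                                   leg_length_m=arow.leg_length_m)
        else:
            anthro = Anthropometry(height_m=1.70, body_mass_kg=70.0,
                                   leg_length_m=0.90)
        trials.append((traj, anthro, meta))
    return trials, clinical
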