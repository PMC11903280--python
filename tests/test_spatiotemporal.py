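"""Cycle building and the 13 per-cycle parameters."""

import numpy as np
import pytest

from vestgait import (GaitEvent, MarkerTrajectorySet, WalkerSpec,
                      aggregate_trial, build_cycles, compute_parameters,
                      generate_walk, select_events)
from vestgait.spatiotemporal import DegenerateCycleError, records_table


def ev(side, kind, frame, fs=100.0):
    return GaitEvent(side, kind, frame, frame / fs)


def heel_print_set(prints, n_frames=101, fs=100.0):
    """Trajectory whose heel markers sit constantly at given (x, y) prints."""
    markers = ["LHEE", "RHEE", "LTOE", "RTOE", "SACR"]
    P = np.zeros((n_frames, 5, 3))
    for label, (x, y) in prints.items():
        P[:, markers.index(label), 0] = x
        P[:, markers.index(label), 1] = y
    P[:, markers.index("SACR"), 0] = np.linspace(0, 1.2, n_frames)
    return MarkerTrajectorySet(fs, markers, P)


class TestBuildCycles:
    def test_minimal_left_cycle(self):
        events = [ev("left", "foot_strike", 0), ev("right", "foot_off", 12),
                  ev("right", "foot_strike", 50), ev("left", "foot_off", 62),
                  ev("left", "foot_strike", 100)]
        cycles = build_cycles(events)
        left = [c for c in cycles if c.side == "left"]
        assert len(left) == 1 and left[0].valid
        assert left[0].event_frames() == (0, 12, 50, 62, 100)

    def test_missing_contralateral_off_invalid(self):
        events = [ev("left", "foot_strike", 0),
                  ev("right", "foot_strike", 50), ev("left", "foot_off", 62),
                  ev("left", "foot_strike", 100)]
        left = [c for c in build_cycles(events) if c.side == "left"]
        assert not left[0].valid
        assert "contralateral_off" in left[0].reason

    def test_empty_event_list(self):
        assert build_cycles([]) == []

    def test_exclusion_window_invalidates(self):
        events = [ev("left", "foot_strike", 0), ev("right", "foot_off", 12),
                  ev("right", "foot_strike", 50), ev("left", "foot_off", 62),
                  ev("left", "foot_strike", 100)]
        cycles = build_cycles(events, exclusion_windows=[(40, 60)])
        left = [c for c in cycles if c.side == "left"]
        assert not left[0].valid and "exclusion" in left[0].reason

    def test_ten_metre_walk_yields_enough_cycles(self):
        spec = WalkerSpec(step_length_m=0.60, cadence_spm=100.0)
        traj, _ = generate_walk(spec)
        cycles = build_cycles(select_events(traj).selected_events)
        assert sum(c.valid for c in cycles) >= 6


class TestComputeParameters:
    def test_hand_timing_example(self):
        # events at t = 0, 0.12, 0.50, 0.62, 1.00 s
        events = [ev("left", "foot_strike", 0), ev("right", "foot_off", 12),
                  ev("right", "foot_strike", 50), ev("left", "foot_off", 62),
                  ev("left", "foot_strike", 100)]
        t = heel_print_set({"LHEE": (0.0, 0.05), "RHEE": (0.60, -0.05)})
        cyc = [c for c in build_cycles(events) if c.side == "left"][0]
        # identical initial/terminal left prints -> widen: use moving left heel
        t.positions[100:, 0, 0] = 1.20
        r = compute_parameters(cyc, t)
        assert r.stance_pct_gc == pytest.approx(62.0)
        assert r.single_support_pct_gc == pytest.approx(38.0)
        assert r.double_support_pct_gc == pytest.approx(24.0)
        assert r.cadence_spm == pytest.approx(120.0)
        assert r.stride_time_s == pytest.approx(1.0)
        assert r.step_time_s == pytest.approx(0.50)
        assert r.stance_pct_gc + r.swing_pct_gc == 100.0

    def test_hand_geometry_example(self):
        # heel prints L(0, 0.05), R(0.60, -0.05), L(1.20, 0.05)
        events = [ev("left", "foot_strike", 0), ev("right", "foot_off", 12),
                  ev("right", "foot_strike", 50), ev("left", "foot_off", 62),
                  ev("left", "foot_strike", 100)]
        t = heel_print_set({"LHEE": (0.0, 0.05), "RHEE": (0.60, -0.05)})
        t.positions[100:, 0, 0] = 1.20
        cyc = [c for c in build_cycles(events) if c.side == "left"][0]
        r = compute_parameters(cyc, t)
        assert r.step_length_m == pytest.approx(0.60)
        assert r.step_width_m == pytest.approx(0.10)
        assert r.stride_length_m == pytest.approx(1.20)
        assert r.walking_speed_mps == pytest.approx(1.20)

    def test_periodic_walker_records_identical(self, default_walk):
        _, traj, _ = default_walk
        recs = [compute_parameters(c, traj)
                for c in build_cycles(select_events(traj).selected_events)
                if c.valid]
        df = records_table(recs)
        for p in ("step_length_m", "step_width_m", "stride_time_s"):
            assert df.groupby(df.side)[p].std().max() == pytest.approx(0, abs=1e-9)

    def test_degenerate_line_of_progression(self):
        events = [ev("left", "foot_strike", 0), ev("right", "foot_off", 12),
                  ev("right", "foot_strike", 50), ev("left", "foot_off", 62),
                  ev("left", "foot_strike", 100)]
        t = heel_print_set({"LHEE": (0.0, 0.05), "RHEE": (0.60, -0.05)})
        cyc = [c for c in build_cycles(events) if c.side == "left"][0]
        with pytest.raises(DegenerateCycleError):
            compute_parameters(cyc, t)  # identical L prints, no progression

    def test_rotation_and_translation_invariance(self, default_walk):
        _, traj, _ = default_walk
        events = select_events(traj).selected_events
        cycles = [c for c in build_cycles(events) if c.valid]
        base = records_table([compute_parameters(c, traj) for c in cycles])

        theta = np.deg2rad(37.0)
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        rotated = traj.copy()
        rotated.positions = rotated.positions @ R.T + np.array([5.0, -3.0, 0.0])
        rot = records_table([compute_parameters(c, rotated) for c in cycles])
        for p in ("step_length_m", "step_width_m", "stride_length_m",
                  "walking_speed_mps", "stance_pct_gc"):
            assert np.allclose(base[p], rot[p], atol=1e-9)


class TestAggregateTrial:
    def _recs(self, values):
        events = [ev("left", "foot_strike", 0), ev("right", "foot_off", 12),
                  ev("right", "foot_strike", 50), ev("left", "foot_off", 62),
                  ev("left", "foot_strike", 100)]
        out = []
        for v in values:
            t = heel_print_set({"LHEE": (0.0, 0.05), "RHEE": (v, -0.05)})
            t.positions[100:, 0, 0] = 2 * v
            cyc = [c for c in build_cycles(events) if c.side == "left"][0]
            out.append(compute_parameters(cyc, t))
        return out

    def test_two_cycle_mean_sd(self):
        agg = aggregate_trial(self._recs([0.60, 0.62]))
        row = agg[agg.parameter == "step_length_m"].iloc[0]
        assert row["mean"] == pytest.approx(0.61)
        assert row["sd"] == pytest.approx(0.014142, rel=1e-3)
        assert row["n_cycles"] == 2

    def test_single_cycle_sd_missing(self):
        agg = aggregate_trial(self._recs([0.60]))
        row = agg[agg.parameter == "step_length_m"].iloc[0]
        assert row["mean"] == pytest.approx(0.60)
        assert np.isnan(row["sd"])

    def test_identical_cycles_zero_sd(self):
        agg = aggregate_trial(self._recs([0.6, 0.6, 0.6]))
        assert agg.loc[agg.parameter == "step_length_m", "sd"].iloc[0] == 0.0

    def test_no_valid_cycles_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            aggregate_trial([])
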