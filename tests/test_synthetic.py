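"""Walker template and cohort generator: ground truth must be exact."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vestgait import CohortSpec, WalkerSpec, generate_cohort, generate_walk
from vestgait.datasets import dimensionless_reference
from vestgait.synthetic import WalkerParameterError, generate_back_and_forth


def test_implied_speed_identity():
    spec = WalkerSpec(step_length_m=0.60, cadence_spm=100.0, asymmetry=1.0)
    assert spec.walking_speed_mps == pytest.approx(0.60 * 100 / 60)
    assert spec.walking_speed_mps == pytest.approx(1.0)


def test_double_support_identity():
    spec = WalkerSpec(stance_fraction=0.62)
    assert spec.double_support_fraction == pytest.approx(2 * 0.62 - 1)
    _, truth = generate_walk(spec)
    assert truth.cycles["double_support_pct_gc"].unique() == pytest.approx(24.0)


@pytest.mark.parametrize("kwargs", [
    {"step_length_m": -0.1},
    {"cadence_spm": 0.0},
    {"stance_fraction": 0.45},
    {"stance_fraction": 0.85},
    {"noise_sd_m": -1e-3},
    {"dropout_rate": 1.0},
    {"double_support_fraction": 0.10, "stance_fraction": 0.62},
])
def test_invalid_specs_rejected(kwargs):
    with pytest.raises(WalkerParameterError):
        WalkerSpec(**kwargs)


def test_ground_truth_event_structure(default_walk):
    _, _, truth = default_walk
    ev = truth.events
    for kind in ("foot_strike", "foot_off"):
        sub = ev[ev.kind == kind]
        assert (np.diff(sub.time_s) > 0).all()
        assert (sub.side.values[1:] != sub.side.values[:-1]).all(), \
            "sides must alternate for each event kind"


def test_ground_truth_cycles_match_spec(default_walk):
    spec, _, truth = default_walk
    c = truth.cycles
    assert np.allclose(c.step_length_m, 0.60)
    assert np.allclose(c.cadence_spm, 100.0)
    assert np.allclose(c.stance_pct_gc, 62.0)
    assert np.allclose(c.walking_speed_mps, 1.0)
    assert np.allclose(c.single_support_pct_gc + c.double_support_pct_gc,
                       c.stance_pct_gc)


def test_stationary_stance_feet(default_walk):
    """During each stance the ipsilateral heel is fixed in the horizontal plane."""
    _, traj, truth = default_walk
    heel = {"left": traj.get("LHEE"), "right": traj.get("RHEE")}
    strikes = truth.events[truth.events.kind == "foot_strike"]
    offs = truth.events[truth.events.kind == "foot_off"]
    for srow in strikes.itertuples():
        later = offs[(offs.side == srow.side) & (offs.frame > srow.frame)]
        if later.empty:
            continue
        stop = int(later.frame.iloc[0])
        seg = heel[srow.side][srow.frame:stop + 1, :2]
        assert np.ptp(seg, axis=0).max() < 1e-9


def test_reproducible_under_seed():
    spec = WalkerSpec(noise_sd_m=0.002, dropout_rate=0.01, seed=42)
    a, _ = generate_walk(spec)
    b, _ = generate_walk(spec)
    assert np.array_equal(a.positions, b.positions, equal_nan=True)


def test_asymmetry_changes_step_ratio():
    spec = WalkerSpec(step_length_m=0.60, asymmetry=1.2)
    _, truth = generate_walk(spec)
    # mean step length preserved, left/right ratio planted
    assert truth.cycles.step_length_m.mean() == pytest.approx(0.60, rel=1e-9)
    ratios = sorted(set(np.round(truth.cycles.step_length_asymmetry, 9)))
    assert ratios == [pytest.approx(1 / 1.2), pytest.approx(1.2)]


def test_back_and_forth_alternates_direction():
    passes = generate_back_and_forth(WalkerSpec(seed=5), n_passes=3)
    assert len(passes) == 3
    x0 = [t.get("SACR")[-1, 0] - t.get("SACR")[0, 0] for t, _ in passes]
    assert x0[0] > 0 and x0[1] < 0 and x0[2] > 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(step=st.floats(0.4, 0.8), cad=st.floats(80, 130),
       stance=st.floats(0.55, 0.72))
def test_ground_truth_phase_identities_property(step, cad, stance):
    _, truth = generate_walk(WalkerSpec(step_length_m=step, cadence_spm=cad,
                                        stance_fraction=stance))
    c = truth.cycles
    assert np.allclose(c.single_support_pct_gc + c.double_support_pct_gc,
                       c.stance_pct_gc, atol=1e-9)
    assert np.allclose(c.stance_pct_gc + c.swing_pct_gc, 100.0)
    assert np.allclose(c.walking_speed_mps,
                       c.step_length_m * c.cadence_spm / 60, rtol=1e-9)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def test_cohort_zero_sd_degenerate():
    ref = dimensionless_reference().copy()
    ref["sd"] = 0.0
    spec = CohortSpec(parameter_reference=ref,
                      group_sizes={"HS": 2, "UV": 2, "BV": 2},
                      cycles_per_subject=3, seed=0)
    cycles, _ = generate_cohort(spec)
    hs = cycles[(cycles.group == "HS") & (cycles.speed == "comfortable")]
    assert np.allclose(hs["walking_speed"], 0.43)
    assert np.allclose(hs["stance_pct_gc"], 61.43)


def test_cohort_reproducible_and_bounded():
    spec = CohortSpec(group_sizes={"HS": 3, "UV": 3, "BV": 3}, seed=11)
    c1, k1 = generate_cohort(spec)
    c2, k2 = generate_cohort(spec)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(k1, k2)
    assert k1.fga_total.between(0, 30).all()
    assert k1.dhi_total.between(0, 100).all()
    assert (k1.tug_s > 0).all()
    assert k1.tandem_steps.between(0, 11).all()
    items = k1[[f"fga_item_{i}" for i in range(1, 11)]]
    assert items.sum(axis=1).equals(k1.fga_total)
    assert items.isin([0, 1, 2, 3]).all().all()


def test_cohort_subject_random_intercept_present():
    """Subject-level intercepts make within-subject cycles correlated."""
    spec = CohortSpec(group_sizes={"HS": 10, "UV": 1, "BV": 1},
                      cycles_per_subject=30, seed=2)
    cycles, _ = generate_cohort(spec)
    hs = cycles[(cycles.group == "HS") & (cycles.speed == "slow")]
    grand = hs["walking_speed"].var()
    within = hs.groupby("subject")["walking_speed"].var().mean()
    assert within < 0.75 * grand  # between-subject component visible


def test_cohort_rejects_bad_sizes():
    with pytest.raises(ValueError):
        CohortSpec(group_sizes={"HS": 0, "UV": 10, "BV": 10})
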