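"""Kruskal-Wallis/Dunn, mixed models, FDR and the normality screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vestgait import (CohortSpec, fdr_adjust, generate_cohort, kw_dunn,
                      mixed_model, shapiro_screen)


def brute_force_kw(groups):
    """Rank-based H from first principles (tie-free inputs only)."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    N = len(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (N + 1) / 2) ** 2
        start += len(g)
    return 12.0 / (N * (N + 1)) * h


class TestKWDunn:
    def test_identical_groups(self):
        res = kw_dunn({"HS": [1, 1, 1], "UV": [1, 1, 1], "BV": [1, 1, 1]})
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_rank_example(self):
        res = kw_dunn({"HS": [1, 2, 3], "UV": [4, 5, 6], "BV": [7, 8, 9]})
        assert res.statistic == pytest.approx(7.2)
        assert res.p_value == pytest.approx(0.0273, abs=1e-3)
        assert set(res.pairwise) == {("HS", "BV"), ("HS", "UV"), ("UV", "BV")}

    def test_matches_brute_force_on_tiefree_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sizes = rng.integers(3, 13, size=3)
            vals = rng.permutation(np.arange(1.0, sizes.sum() + 1))
            groups = np.split(vals, np.cumsum(sizes)[:-1])
            res = kw_dunn({f"G{i}": g for i, g in enumerate(groups)})
            assert res.statistic == pytest.approx(brute_force_kw(groups),
                                                  rel=1e-9)

    def test_small_group_excluded(self):
        res = kw_dunn({"HS": [1, 2, 3], "UV": [4, 5, 6], "BV": [9]})
        assert any("BV" in f for f in res.flags)
        assert set(res.n_per_group) == {"HS", "UV"}

    def test_power_for_two_sd_shift(self):
        """2-pooled-SD shift at n=10/group is detected >=90% of the time."""
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 200
        for _ in range(reps):
            res = kw_dunn({"HS": rng.normal(0, 1, 10),
                           "UV": rng.normal(0, 1, 10),
                           "BV": rng.normal(2, 1, 10)})
            rejections += res.p_value < 0.05
        assert rejections / reps >= 0.90


class TestMixedModel:
    @staticmethod
    def _cycles(rng, n_sub=10, n_cyc=20, offsets=(0, 0, 0), icc_sd=0.7):
        rows = []
        for gi, g in enumerate(("HS", "UV", "BV")):
            for s in range(n_sub):
                b = rng.normal(0, icc_sd)
                for c in range(n_cyc):
                    rows.append({"subject": f"{g}{s}", "group": g,
                                 "value": offsets[gi] + b + rng.normal()})
        return pd.DataFrame(rows)

    def test_reduces_to_anova_with_single_cycles(self):
        rng = np.random.default_rng(5)
        df = self._cycles(rng, n_cyc=1, icc_sd=0.0)
        res = mixed_model(df, "value")
        groups = [df[df.group == g]["value"] for g in ("HS", "UV", "BV")]
        _, p_anova = sps.f_oneway(*groups)
        assert res.p_value == pytest.approx(p_anova, abs=1e-6)
        assert any("ANOVA" in f for f in res.flags)

    def test_degenerate_constant_data_flagged(self):
        df = self._cycles(np.random.default_rng(0), n_sub=3, n_cyc=2)
        df["value"] = 1.0
        res = mixed_model(df, "value")
        assert np.isnan(res.p_value)
        assert any("degenerate" in f for f in res.flags)

    def test_offset_recovery(self):
        """A planted 1-between-SD group offset is estimated within 20%."""
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(50):
            df = self._cycles(rng, offsets=(0, 0, 0.7), icc_sd=0.7)
            res = mixed_model(df, "value")
            means = res.effect_direction
            estimates.append(means["BV"] - means["HS"])
        assert abs(np.median(estimates) - 0.7) <= 0.2 * 0.7

    def test_needs_two_participants_per_group(self):
        df = self._cycles(np.random.default_rng(1), n_sub=1)
        with pytest.raises(ValueError, match="participants"):
            mixed_model(df, "value")


class TestFDR:
    def test_hand_step_up_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert (adj <= 0.05).all()
        assert adj.max() == pytest.approx(0.04)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_upper_bound(self):
        assert fdr_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_empty(self):
        assert fdr_adjust([]).size == 0

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(2)
        p = rng.random(25)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_permutation_invariance(self):
        p = np.array([0.30, 0.01, 0.20, 0.04, 0.90])
        perm = np.array([3, 0, 4, 1, 2])
        assert fdr_adjust(p)[perm] == pytest.approx(fdr_adjust(p[perm]))

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestShapiro:
    def test_equal_spaced_triple(self):
        rep = shapiro_screen([1.0, 2.0, 3.0])
        assert rep["w"] == pytest.approx(1.0, abs=1e-6)

    def test_constant_sample_undefined(self):
        rep = shapiro_screen([2.0] * 10)
        assert np.isnan(rep["w"]) and "constant" in rep["note"]

    def test_too_small(self):
        assert "not computed" in shapiro_screen([1.0, 2.0])["note"]

    def test_heavy_tails_detected(self):
        rng = np.random.default_rng(3)
        hits = sum(shapiro_screen(rng.standard_cauchy(50))["p"] < 0.05
                   for _ in range(200))
        assert hits / 200 >= 0.90
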