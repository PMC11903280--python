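"""Two-step clustering: CF pre-clusters, log-likelihood merging, auto k."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from vestgait.cluster import (CFEntry, ZeroVarianceError, _distance,
                              merge_and_select, precluster, standardize,
                              two_step_cluster, cluster_report)


def planted_two(rng, n_per=15, sep=8.0):
    X = np.vstack([rng.normal(0.0, 1.0, (n_per, 2)),
                   rng.normal(sep, 1.0, (n_per, 2))])
    y = np.repeat([0, 1], n_per)
    return X, y


class TestPrecluster:
    def test_duplicates_merge(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        entries = precluster(X, threshold=1e-6)
        counts = sorted(e.n for e in entries)
        assert counts == [1, 2]

    def test_two_far_locations_order_independent(self):
        a, b = np.array([0.0, 0.0]), np.array([50.0, 50.0])
        X = np.array([a, b] * 10) + 1e-3  # alternating insertions
        for order in (slice(None), slice(None, None, -1)):
            entries = precluster(X[order], threshold=1.0)
            assert len(entries) == 2
            assert sorted(e.n for e in entries) == [10, 10]

    def test_leaf_cap_enforced(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (30, 2))
        entries = precluster(X, threshold=0.0, leaf_cap=15)
        assert len(entries) <= 15
        assert sum(e.n for e in entries) == 30

    def test_zero_variance_named(self):
        X = np.ones((5, 2))
        X[:, 0] = np.arange(5)
        with pytest.raises(ZeroVarianceError, match="flat"):
            standardize(X, columns=["ok", "flat"])


class TestMergeAndSelect:
    def test_planted_two_clusters_exact(self):
        rng = np.random.default_rng(1)
        X, y = planted_two(rng)
        df = pd.DataFrame({"subject": range(len(X)), "u": X[:, 0], "v": X[:, 1]})
        model = two_step_cluster(df, ["u", "v"], k_max=5)
        assert model.k == 2
        assert adjusted_rand_score(y, model.assignments) == 1.0

    def test_null_single_gaussian_selects_one(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"subject": range(30),
                               "u": rng.normal(0, 1, 30),
                               "v": rng.normal(0, 1, 30)})
            hits += two_step_cluster(df, ["u", "v"], k_max=5).k == 1
        assert hits >= 18

    def test_identical_cases_single_cluster(self):
        df = pd.DataFrame({"subject": range(8), "u": 3.0, "v": -1.0})
        model = two_step_cluster(df, ["u", "v"])
        assert model.k == 1
        assert (model.assignments == 0).all()

    def test_matches_brute_force_two_means(self):
        rng = np.random.default_rng(3)
        X, _ = planted_two(rng)
        df = pd.DataFrame({"subject": range(len(X)), "u": X[:, 0], "v": X[:, 1]})
        model = two_step_cluster(df, ["u", "v"], k_max=5)
        km = KMeans(2, n_init=10, random_state=0).fit_predict(X)
        assert adjusted_rand_score(km, model.assignments) == 1.0

    def test_identical_summaries_zero_distance(self):
        x = np.array([1.0, 2.0])
        a = CFEntry.of(x, 0).merged(CFEntry.of(x + 1, 1))
        b = CFEntry(a.n, a.s.copy(), a.ss.copy(), [2, 3])
        assert _distance(a, b, np.ones(2)) == pytest.approx(0.0, abs=1e-9)

    def test_kmax_validated(self):
        entries = precluster(np.random.default_rng(0).normal(0, 1, (6, 2)))
        with pytest.raises(ValueError):
            merge_and_select(entries, np.zeros((6, 2)), k_max=0)

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(4)
        X, y = planted_two(rng)
        df = pd.DataFrame({"subject": range(len(X)), "u": X[:, 0], "v": X[:, 1]})
        df.loc[3, "u"] = np.nan
        model = two_step_cluster(df, ["u", "v"], k_max=5)
        assert len(model.assignments) == len(X) - 1
        assert 3 not in model.case_index


class TestClusterReport:
    def test_pure_cluster_reads_100_percent(self):
        rng = np.random.default_rng(5)
        X, y = planted_two(rng, n_per=10)
        groups = np.where(y == 0, "HS", "BV")
        df = pd.DataFrame({"subject": range(len(X)), "u": X[:, 0], "v": X[:, 1]})
        model = two_step_cluster(df, ["u", "v"], k_max=5)
        rep = cluster_report(model, groups)
        hs_col = rep["pct_HS"].to_numpy()
        assert sorted(hs_col) == [0.0, 100.0]
        assert (rep["n"] > 0).all()  # merging never reports empty clusters

    def test_planted_composition_recovered(self):
        """A BV-heavy impaired cluster is reported within one subject."""
        rng = np.random.default_rng(6)
        healthy = rng.normal([5, 27], [4, 1.5], (13, 2))    # low DHI, high FGA
        impaired = rng.normal([50, 17], [8, 2.0], (9, 2))   # high DHI, low FGA
        X = np.vstack([healthy, impaired])
        groups = np.array(["HS"] * 10 + ["UV"] * 3 + ["BV"] * 9)
        df = pd.DataFrame({"subject": range(len(X)),
                           "dhi": X[:, 0], "fga": X[:, 1]})
        model = two_step_cluster(df, ["dhi", "fga"], k_max=5)
        assert model.k == 2
        rep = cluster_report(model, groups)
        bv_heavy = rep.loc[rep["pct_BV"].idxmax()]
        assert bv_heavy["pct_BV"] >= 100 * 8 / 9 - 1e-9
        assert bv_heavy["pct_HS"] <= 100 * 1 / 10 + 1e-9

    def test_label_mismatch_rejected(self):
        df = pd.DataFrame({"subject": range(6), "u": np.arange(6.0),
                           "v": np.arange(6.0)})
        model = two_step_cluster(df, ["u", "v"])
        with pytest.raises(ValueError):
            cluster_report(model, ["HS"] * 5)
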