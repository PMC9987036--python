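import numpy as np
import pandas as pd
import pytest

from ucrpanel import (assign_groups, hierarchical_cluster, km_estimate,
                      logrank_test, zscore_rows)
from ucrpanel.stratify import stratify_patients


def blob_matrix(n_per=6, n_features=10, separation=10.0, seed=0, k=2):
    """Features x samples with k well-separated Gaussian sample blobs."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, separation, size=(k, n_features))
    cols, labels = [], []
    for g in range(k):
        for j in range(n_per):
            cols.append(centers[g] + rng.normal(size=n_features))
            labels.append(g)
    samples = [f"S{i:02d}" for i in range(len(cols))]
    m = pd.DataFrame(np.array(cols).T, index=[f"f{i}"
                                              for i in range(n_features)],
                     columns=samples)
    return m, pd.Series(labels, index=samples)


class TestZscoreRows:
    def test_hand_arithmetic(self):
        m = pd.DataFrame([[2.0, 4.0, 6.0]], index=["f"],
                         columns=["a", "b", "c"])
        z, flags = zscore_rows(m)
        np.testing.assert_allclose(z.loc["f"], [-1.2247, 0.0, 1.2247],
                                   atol=1e-4)
        assert not flags.any()

    def test_constant_row_zeroed_and_flagged(self):
        m = pd.DataFrame([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]],
                         index=["c", "v"], columns=list("abc"))
        z, flags = zscore_rows(m)
        assert (z.loc["c"] == 0).all()
        assert flags["c"] and not flags["v"]

    def test_idempotent(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 6)))
        z1, _ = zscore_rows(m)
        z2, _ = zscore_rows(z1)
        pd.testing.assert_frame_equal(z1, z2)


class TestClusteringAndGroups:
    def test_identical_samples_merge_first_at_zero_distance(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0],
                          "c": [9.0, 9.0]}, index=["f1", "f2"])
        link = hierarchical_cluster(m, "samples")
        assert link[0, 0] == 0 and link[0, 1] == 1   # a merges b
        assert link[0, 2] == 0.0                     # at distance 0

    def test_two_blobs_recovered_over_seeds(self):
        for seed in range(20):
            m, labels = blob_matrix(seed=seed)
            link = hierarchical_cluster(m, "samples")
            groups = assign_groups(link, 2, list(m.columns))
            # partition equality up to label swap
            tab = pd.crosstab(groups, labels)
            assert (tab.max(axis=1) == tab.sum(axis=1)).all()

    def test_four_blobs_recovered(self):
        m, labels = blob_matrix(k=4, seed=1)
        groups = assign_groups(hierarchical_cluster(m, "samples"), 4,
                               list(m.columns))
        tab = pd.crosstab(groups, labels)
        assert (tab.max(axis=1) == tab.sum(axis=1)).all()

    def test_sample_order_invariance_after_canonicalization(self):
        m, _ = blob_matrix(seed=3)
        groups = assign_groups(hierarchical_cluster(m, "samples"), 2,
                               list(m.columns))
        perm = np.random.default_rng(0).permutation(m.shape[1])
        mp = m.iloc[:, perm]
        groups_p = assign_groups(hierarchical_cluster(mp, "samples"), 2,
                                 list(mp.columns))
        tab = pd.crosstab(groups.reindex(groups_p.index), groups_p)
        assert (tab.max(axis=1) == tab.sum(axis=1)).all()

    def test_k_boundaries(self):
        m, _ = blob_matrix(seed=0)
        link = hierarchical_cluster(m, "samples")
        ids = list(m.columns)
        assert assign_groups(link, 1, ids).nunique() == 1
        singletons = assign_groups(link, len(ids), ids)
        assert singletons.nunique() == len(ids)
        with pytest.raises(ValueError):
            assign_groups(link, len(ids) + 1, ids)

    def test_labels_canonical_by_first_appearance(self):
        m, _ = blob_matrix(seed=4)
        groups = assign_groups(hierarchical_cluster(m, "samples"), 2,
                               list(m.columns))
        assert groups.iloc[0] == 1
        assert sorted(groups.unique()) == [1, 2]


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        curve = km_estimate([3.0, 5.0, 8.0], [0, 0, 0])
        assert (curve["survival_prob"] == 1.0).all()
        assert curve["n_events"].sum() == 0

    def test_all_events_product_limit_arithmetic(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve["survival_prob"],
                                   [2 / 3, 1 / 3, 0.0])
        assert curve["at_risk"].tolist() == [3, 2, 1]

    def test_censored_subject_leaves_risk_set(self):
        # hand product-limit: S(1)=2/3; the t=2 censoring removes one
        # subject, so the t=3 event has risk set 1 and S(3)=0
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve.loc[1.0, "survival_prob"] == pytest.approx(2 / 3)
        assert curve.loc[3.0, "survival_prob"] == pytest.approx(0.0)
        assert curve.loc[3.0, "at_risk"] == 1

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=25).round(1)
        curve = km_estimate(times, np.ones_like(times))
        for t in curve.index:
            assert curve.loc[t, "survival_prob"] \
                == pytest.approx((times > t).mean())

    def test_negative_time_is_hard_error(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])


def brute_force_logrank(groups):
    """Independent observed/expected log-rank over the pooled event times."""
    from scipy.stats import chi2
    data = [(t, e, g) for g, (ts, es) in groups.items()
            for t, e in zip(ts, es)]
    labels = sorted(groups)
    event_times = sorted({t for t, e, _ in data if e})
    O = dict.fromkeys(labels, 0.0)
    E = dict.fromkeys(labels, 0.0)
    V = np.zeros((len(labels), len(labels)))
    for t in event_times:
        at_risk = [d for d in data if d[0] >= t]
        n = len(at_risk)
        d_t = sum(1 for d in data if d[0] == t and d[1])
        n_g = {g: sum(1 for d in at_risk if d[2] == g) for g in labels}
        for g in labels:
            O[g] += sum(1 for d in data if d[0] == t and d[1] and d[2] == g)
            E[g] += d_t * n_g[g] / n
        if n > 1:
            for i, gi in enumerate(labels):
                for j, gj in enumerate(labels):
                    same = 1.0 if i == j else 0.0
                    V[i, j] += (d_t * (n_g[gi] / n)
                                * (same - n_g[gj] / n)
                                * (n - d_t) / (n - 1))
    z = np.array([O[g] - E[g] for g in labels])[:-1]
    stat = float(z @ np.linalg.pinv(V[:-1, :-1]) @ z)
    return stat, float(chi2.sf(stat, len(labels) - 1))


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        g = (np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]))
        res = logrank_test({"A": g, "B": g})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_two_group_example(self):
        # frozen from an observed/expected table computed by hand over the
        # six event times of A=(1,2,3) and B=(4,5,6), all events
        res = logrank_test({"A": ([1, 2, 3], [1, 1, 1]),
                            "B": ([4, 5, 6], [1, 1, 1])})
        assert res.statistic == pytest.approx(5.051660516605167)
        assert res.p_value == pytest.approx(0.024602349953641744)
        assert res.df == 1

    def test_three_groups_have_two_df(self):
        rng = np.random.default_rng(1)
        groups = {g: (rng.exponential(10, 5), np.ones(5)) for g in "ABC"}
        assert logrank_test(groups).df == 2

    def test_no_events_is_hard_error(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test({"A": ([1.0], [0.0]), "B": ([2.0], [0.0])})

    def test_matches_brute_force_oracle_small_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            k = int(rng.integers(2, 4))
            groups = {}
            for g in range(k):
                n = int(rng.integers(2, 5))
                groups[f"g{g}"] = (rng.integers(1, 8, n).astype(float),
                                   rng.integers(0, 2, n).astype(float))
            if sum(e.sum() for _, e in groups.values()) == 0:
                continue
            res = logrank_test(groups)
            stat, p = brute_force_logrank(groups)
            assert res.statistic == pytest.approx(stat, rel=1e-6)
            assert res.p_value == pytest.approx(p, rel=1e-6)

    def test_null_permutation_p_values_roughly_uniform(self):
        """Permuting labels of exchangeable survival data gives ~U(0,1) p."""
        from scipy.stats import kstest
        rng = np.random.default_rng(17)
        times = rng.exponential(20, size=24)
        events = (rng.random(24) > 0.1).astype(float)
        ps = []
        for _ in range(500):
            labels = rng.permutation([1] * 12 + [2] * 12)
            groups = {g: (times[labels == g], events[labels == g])
                      for g in (1, 2)}
            ps.append(logrank_test(groups).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestStratifyPatients:
    def test_end_to_end_groups_and_curves(self, small_study):
        matrix, ann, truth = small_study
        panel = sorted(truth.de_probe_ids)
        res = stratify_patients(matrix, ann, panel, k=4)
        assert res["groups"].nunique() == 4
        assert set(res["groups"].index) \
            == set(ann.index[ann["group"] != "NBE"])
        assert res["logrank"] is not None
        assert res["logrank"].df == 3
        assert res["heatmap"].shape[0] == len(panel)

    def test_empty_panel_rejected(self, small_study):
        matrix, ann, _ = small_study
        with pytest.raises(ValueError, match="empty panel"):
            stratify_patients(matrix, ann, [], k=2)
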