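from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from netprop import (
    ScenarioConfig,
    build_feature_matrix,
    generate_scenario,
    hierarchical_cluster,
    kaplan_meier,
    logrank_test,
    run_case_study,
)
from netprop.stratification import PatientPathwayMatrix, load_clinical


def table(pathways, ps):
    return pd.DataFrame({"pathway": pathways, "p_empirical": ps})


class TestBuildFeatureMatrix:
    def test_minus_log10_transform_and_floor(self):
        fm = build_feature_matrix(
            {"s1": table(["a", "b"], [1.0, 1 / 10001])}
        )
        assert fm.F[0, 0] == 0.0
        assert fm.F[0, 1] == pytest.approx(np.log10(10001), abs=1e-9)

    def test_single_patient_shape(self):
        fm = build_feature_matrix({"s1": table(["a"], [0.5])})
        assert fm.F.shape == (1, 1)

    def test_mismatched_pathways_named_in_error(self):
        tabs = {"s1": table(["a", "b"], [0.5, 0.5]), "s2": table(["a", "c"], [0.5, 0.5])}
        with pytest.raises(ValueError, match="s2"):
            build_feature_matrix(tabs)


class TestHierarchicalCluster:
    def blobs(self, rng, n_per=20, sep=10.0, sd=1.0):
        """Two well-separated gaussian blobs (separation >= 5 within-blob SDs)."""
        a = rng.normal(0.0, sd, size=(n_per, 3))
        b = rng.normal(sep, sd, size=(n_per, 3))
        F = np.vstack([a, b])
        samples = tuple(f"s{i:03d}" for i in range(2 * n_per))
        return PatientPathwayMatrix(samples=samples, pathway_names=("x", "y", "z"),
                                    F=np.abs(F)), [0] * n_per + [1] * n_per

    def test_separated_blobs_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        fm, truth = self.blobs(np.random.default_rng(0))
        labels = hierarchical_cluster(fm, k=2)
        pred = [labels[s] for s in fm.samples]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_label_one_has_largest_mean_feature(self):
        fm, _ = self.blobs(np.random.default_rng(1))
        labels = hierarchical_cluster(fm, k=2)
        F = fm.to_frame()
        means = F.groupby(pd.Series(labels)).mean().mean(axis=1)
        assert means.idxmax() == 1

    def test_k_equals_n_each_sample_own_group(self):
        fm, _ = self.blobs(np.random.default_rng(2), n_per=3)
        labels = hierarchical_cluster(fm, k=6)
        assert sorted(labels.values()) == [1, 2, 3, 4, 5, 6]

    def test_duplicated_rows_co_cluster(self):
        F = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        fm = PatientPathwayMatrix(samples=("a", "b", "c", "d"),
                                  pathway_names=("x", "y"), F=F)
        labels = hierarchical_cluster(fm, k=2)
        assert labels["a"] == labels["b"] and labels["c"] == labels["d"]

    def test_k_above_n_rejected(self):
        fm, _ = self.blobs(np.random.default_rng(3), n_per=2)
        with pytest.raises(ValueError, match="exceeds"):
            hierarchical_cluster(fm, k=5)


def make_records(times_a, events_a, times_b, events_b):
    return pd.DataFrame(
        {
            "time": list(times_a) + list(times_b),
            "event": list(events_a) + list(events_b),
            "group": [1] * len(times_a) + [2] * len(times_b),
        }
    )


class TestLogRank:
    def test_mirror_image_groups_give_zero_statistic(self):
        rec = make_records([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        res = logrank_test(rec, 1, 2)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_statistic_symmetric_under_label_swap(self):
        rng = np.random.default_rng(4)
        rec = make_records(rng.exponential(1, 10), rng.integers(0, 2, 10),
                           rng.exponential(2, 12), rng.integers(0, 2, 12))
        a = logrank_test(rec, 1, 2)
        b = logrank_test(rec, 2, 1)
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-12)

    def test_four_sample_toy_matches_hand_derivation(self):
        # A: events at t=1,2; B: censored at 10,10.
        # t=1: O-E = 1 - 2/4, Var = (2/4)(2/4)(3)/3 = 1/4
        # t=2: O-E = 1 - 1/3, Var = (1/3)(2/3)(2)/2 = 2/9
        # chi = (7/6)^2 / (17/36) = 49/17
        rec = make_records([1, 2], [1, 1], [10, 10], [0, 0])
        res = logrank_test(rec, 1, 2)
        assert res.chi_square == pytest.approx(49 / 17, abs=1e-12)

    def test_four_sample_permutation_distribution(self):
        # enumerate all 4!/(2!2!)=6 relabelings; the paired-event assignment
        # (and its complement) attain 49/17, the mixed ones 1/17, so the
        # exact permutation p-value of the observed statistic is 2/6
        subjects = [(1, 1), (2, 1), (10, 0), (10, 0)]
        stats = []
        for idx_a in combinations(range(4), 2):
            rec = pd.DataFrame(
                {
                    "time": [s[0] for s in subjects],
                    "event": [s[1] for s in subjects],
                    "group": [1 if i in idx_a else 2 for i in range(4)],
                }
            )
            stats.append(logrank_test(rec, 1, 2).chi_square)
        stats = np.array(stats)
        obs = 49 / 17
        assert np.isclose(stats, obs).sum() == 2
        assert np.isclose(stats, 1 / 17).sum() == 4
        assert np.mean(stats >= obs - 1e-12) == pytest.approx(2 / 6)

    def test_matches_lifelines_on_random_data(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(5)
        for _ in range(5):
            ta, tb = rng.exponential(1, 15), rng.exponential(1.5, 20)
            ea, eb = rng.integers(0, 2, 15), rng.integers(0, 2, 20)
            if ea.sum() + eb.sum() == 0:
                continue
            rec = make_records(ta, ea, tb, eb)
            ours = logrank_test(rec, 1, 2)
            ref = lifelines_stats.logrank_test(ta, tb, event_observed_A=ea,
                                               event_observed_B=eb)
            assert ours.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
            assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_censoring_only_group_still_finite(self):
        rec = make_records([1, 2, 3], [1, 1, 1], [5, 6], [0, 0])
        res = logrank_test(rec, 1, 2)
        assert np.isfinite(res.chi_square)

    def test_empty_group_rejected(self):
        rec = make_records([1], [1], [2], [1])
        with pytest.raises(ValueError):
            logrank_test(rec, 1, 3)

    def test_pooled_groups_supported(self):
        rec = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 0],
                            "group": [1, 2, 3, 3]})
        res = logrank_test(rec, {1, 2}, 3)
        assert res.groups_compared[0] == frozenset({1, 2})


class TestKaplanMeier:
    def test_starts_at_one_and_is_nonincreasing(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(1, 30)
        e = rng.integers(0, 2, 30)
        km = kaplan_meier(t, e)
        assert km["survival"].iloc[0] == 1.0
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_small_example_hand_computed(self):
        # events at t=1 (2 at risk) then censoring at t=2: S = 1 -> 0.5
        km = kaplan_meier(np.array([1.0, 2.0]), np.array([1, 0]))
        assert list(km["survival"]) == [1.0, 0.5]


class TestRunCaseStudy:
    def test_emits_k_labels_and_is_deterministic(self, default_bundle):
        b = default_bundle
        r1 = run_case_study(b["cohort"], b["op"], b["pathways"], b["clinical"],
                            k=3, n_null=200, rng_seed=9)
        r2 = run_case_study(b["cohort"], b["op"], b["pathways"], b["clinical"],
                            k=3, n_null=200, rng_seed=9)
        assert set(r1.labels.values()) == {1, 2, 3}
        assert r1.labels == r2.labels
        assert np.array_equal(r1.features.F, r2.features.F)
        assert r1.km_curves.equals(r2.km_curves)
        pooled = [k for k in r1.logrank if "+" in k]
        assert pooled  # group 1+2 vs 3 comparison is present

    def test_km_curves_valid_step_functions(self, default_bundle):
        b = default_bundle
        res = run_case_study(b["cohort"], b["op"], b["pathways"], b["clinical"],
                             k=3, n_null=100, rng_seed=2)
        for _, grp in res.km_curves.groupby("group"):
            assert grp["survival"].iloc[0] == 1.0
            assert (np.diff(grp["survival"]) <= 1e-12).all()


def test_load_clinical_validates_schema(tmp_path):
    p = tmp_path / "clin.tsv"
    p.write_text("sample\ttime\tevent\ns1\t1.5\t1\ns2\t2.0\t0\n")
    df = load_clinical(p)
    assert list(df["sample"]) == ["s1", "s2"]
    bad = tmp_path / "bad.tsv"
    bad.write_text("sample\ttime\tevent\ns1\t-1\t1\n")
    with pytest.raises(ValueError, match="negative"):
        load_clinical(bad)
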