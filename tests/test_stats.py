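import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from imudex import datasets
from imudex.io import ValidationError
from imudex.simulate import generate_recording, preset
from imudex.stats import (DexterityAssessment, classify_dexterity,
                          group_summary, kruskal_wallis, round_half_away,
                          standardize, t_ratio, ward_cluster)


class TestTRatio:
    @pytest.mark.parametrize("t_span,total_task1,expected", [
        (42.2, 24.9, 1.69),   # most efficient volunteer
        (34.4, 18.1, 1.90),   # fastest volunteer
        (10.0, 10.0, 1.00),
    ])
    def test_examples(self, t_span, total_task1, expected):
        assert round_half_away(t_ratio(t_span, total_task1)) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            t_ratio(10.0, 0.0)


class TestStandardize:
    def test_zscores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, (20, 4))
        z = standardize(X)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_two_subject_case(self):
        z = standardize(np.array([[0.0], [2.0]]))
        assert np.allclose(z.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 2, (10, 3))
        assert np.allclose(standardize(standardize(X)), standardize(X))

    def test_zero_variance_names_variable(self):
        df = pd.DataFrame({"good": [1.0, 2.0, 3.0],
                           "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValidationError, match="flat"):
            standardize(df)


def ward_oracle_merges(X):
    """Exhaustive Ward agglomeration: at every step evaluate the
    within-cluster sum-of-squares increase of every possible merge and
    take the cheapest (lowest pair index on ties)."""
    X = np.asarray(X, dtype=float)
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                pa, pb = X[clusters[a]], X[clusters[b]]
                na, nb = len(pa), len(pb)
                cost = (na * nb / (na + nb)
                        * np.sum((pa.mean(0) - pb.mean(0)) ** 2))
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, a, b)
        _, a, b = best
        merges.append(frozenset([frozenset(clusters[a]),
                                 frozenset(clusters[b])]))
        clusters[a] = clusters[a] + clusters.pop(b)
    return merges


def linkage_merges(tree, n):
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for k, (a, b, _, _) in enumerate(tree):
        a, b = int(a), int(b)
        merges.append(frozenset([members[a], members[b]]))
        members[n + k] = members[a] | members[b]
    return merges


class TestWardCluster:
    def test_fixture_membership(self):
        """Clustering the pegboard-exercise metrics splits off exactly
        the six high-dexterity volunteers."""
        feats = datasets.exercise_features(3, 1)
        labels, _ = ward_cluster(standardize(feats), 2)
        groups = {lab: set(feats.index[labels == lab])
                  for lab in np.unique(labels)}
        assert set(datasets.TYPE1_GROUP) in groups.values()

    def test_separated_blobs_perfectly_split(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (10, 2)),
                       rng.normal(6, 0.3, (12, 2))])
        labels, _ = ward_cluster(X, 2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_cost_oracle(self, seed):
        """Every merge agrees with brute-force enumeration of Ward
        costs on small instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        X = rng.normal(0, 1, (n, 3))
        _, tree = ward_cluster(X, 2)
        assert linkage_merges(tree, n) == ward_oracle_merges(X)

    def test_row_permutation_invariance(self):
        feats = datasets.exercise_features(3, 1)
        z = standardize(feats)
        labels, _ = ward_cluster(z, 2)
        perm = np.random.default_rng(3).permutation(len(z))
        labels_p, _ = ward_cluster(z.iloc[perm], 2)
        part_a = {frozenset(np.flatnonzero(labels == lab))
                  for lab in np.unique(labels)}
        part_b = {frozenset(perm[np.flatnonzero(labels_p == lab)])
                  for lab in np.unique(labels_p)}
        assert part_a == part_b

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ward_cluster(np.zeros((5, 2)), 6)


class TestGroupSummary:
    def test_video_review_blue_group(self):
        vr = datasets.load_video_review()
        labels = ["Blue" if v in datasets.BLUE_GROUP else "Other"
                  for v in vr.index]
        summ = group_summary(vr, labels)
        assert round_half_away(summ.loc["Blue", "t_span_mean"]) == 45.42
        assert round_half_away(summ.loc["Blue", "errors_mean"]) == 3.00

    def test_exercise3_type1_movements(self):
        feats = datasets.exercise_features(3, 1)
        labels = ["Type 1" if v in datasets.TYPE1_GROUP else "Type 2"
                  for v in feats.index]
        summ = group_summary(feats, labels)
        assert round_half_away(
            summ.loc["Type 1", "movements_mean"]) == 31.67

    def test_singleton_group_sd_zero(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        summ = group_summary(df, ["a", "b", "b"])
        assert summ.loc["a", "x_sd"] == 0.0
        assert summ.loc["a", "n"] == 1

    def test_affine_equivariance(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(0, 1, 12)})
        labels = ["a"] * 6 + ["b"] * 6
        s1 = group_summary(df, labels)
        s2 = group_summary(df * 3.0 + 2.0, labels)
        assert np.allclose(s2["x_mean"], 3.0 * s1["x_mean"] + 2.0)
        assert np.allclose(s2["x_sd"], 3.0 * s1["x_sd"])


def _fixture_values_and_groups(var, exercise=3):
    feats = datasets.exercise_features(exercise, 1)
    groups = np.where(feats.index.isin(datasets.TYPE1_GROUP),
                      "Type 1", "Type 2")
    return feats[var].to_numpy(), groups


class TestKruskalWallis:
    def test_duration_exercise3(self):
        """The Type 1 durations occupy ranks 1-6 with no ties, so by
        direct rank arithmetic H = 12/(14*15)*(21^2/6 + 84^2/8) -
        3*15 = 9.6 exactly."""
        vals, groups = _fixture_values_and_groups("duration")
        res = kruskal_wallis(vals, groups)
        assert res.H == pytest.approx(9.6, abs=1e-9)
        assert round_half_away(res.p, 4) == 0.0019

    def test_movements_exercise3_with_ties(self):
        vals, groups = _fixture_values_and_groups("movements")
        res = kruskal_wallis(vals, groups)
        assert round_half_away(res.p, 4) == 0.0029

    def test_label_swap_symmetry(self):
        vals, groups = _fixture_values_and_groups("disp")
        a = kruskal_wallis(vals, groups)
        swapped = np.where(groups == "Type 1", "Type 2", "Type 1")
        b = kruskal_wallis(vals, swapped)
        assert (a.H, a.p) == (b.H, b.p)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, 15)
        groups = rng.permutation(["a"] * 7 + ["b"] * 8)
        a = kruskal_wallis(vals, groups)
        b = kruskal_wallis(np.exp(vals), groups)
        assert a.H == pytest.approx(b.H, rel=1e-12)

    def test_degenerate_all_identical(self):
        res = kruskal_wallis(np.ones(10), ["a"] * 5 + ["b"] * 5)
        assert res.degenerate and res.H == 0.0 and res.p == 1.0

    def test_bonferroni(self):
        vals, groups = _fixture_values_and_groups("duration")
        res = kruskal_wallis(vals, groups, m=4)
        assert res.p_bonferroni == pytest.approx(min(1.0, 4 * res.p))

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis(np.arange(4), ["a"] * 4)


class TestClassifyDexterity:
    def test_fixture_membership(self):
        labels = classify_dexterity(datasets.exercise_features(3, 1))
        assert set(labels[labels == "Type 1"].index) == \
            set(datasets.TYPE1_GROUP)

    def test_simulated_cohort_recovered(self):
        rows = []
        for k in range(7):
            for name in ("skilled", "novice"):
                _, truth = generate_recording(
                    preset(name, seed=100 + 2 * k + (name == "novice")),
                    n_sensors=1)
                rows.append({
                    "subject": f"{name}{k}",
                    "duration": truth.durations[2],
                    "movements": truth.movement_counts[2],
                    "disp": truth.disp_m[2],
                    "disp_theta": truth.disp_theta_deg[2]})
        df = pd.DataFrame(rows).set_index("subject")
        labels = classify_dexterity(df)
        for subj, lab in labels.items():
            expected = "Type 1" if subj.startswith("skilled") else "Type 2"
            assert lab == expected

    def test_uniform_cohort_flagged_unstable(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(10.0 + 0.001 * rng.normal(size=(14, 4)),
                          columns=["duration", "movements", "disp",
                                   "disp_theta"])
        _, _, stable = classify_dexterity(df, return_tree=True)
        assert not stable

    def test_fixture_split_is_stable(self):
        _, _, stable = classify_dexterity(
            datasets.exercise_features(3, 1), return_tree=True)
        assert stable


class TestDexterityAssessment:
    def test_fit_reproduces_membership_and_tests(self):
        model = DexterityAssessment(datasets.exercise_features(3, 1), k=2)
        res = model.fit(bonferroni_m=4)
        assert set(res.labels[res.labels == "Type 1"].index) == \
            set(datasets.TYPE1_GROUP)
        kw = res.kw_table
        assert round_half_away(kw.loc["duration", "p"], 4) == 0.0019
        assert round_half_away(
            res.group_summary.loc["Type 1", "duration_mean"]) == 45.87

    def test_summary_prints_groups_and_pvalues(self):
        res = DexterityAssessment(datasets.exercise_features(3, 1)).fit()
        text = res.summary()
        assert "Type 1" in text and "Kruskal-Wallis" in text

    def test_from_metrics_long_table(self):
        rows = []
        for name, seed in [("skilled", 0), ("novice", 1),
                           ("skilled", 2), ("novice", 3)]:
            _, truth = generate_recording(preset(name, seed=seed),
                                          n_sensors=1)
            rows.append({"subject": f"{name}{seed}", "exercise": 3,
                         "sensor": 1, "duration": truth.durations[2],
                         "movements": truth.movement_counts[2],
                         "disp": truth.disp_m[2],
                         "disp_theta": truth.disp_theta_deg[2]})
        model = DexterityAssessment.from_metrics(pd.DataFrame(rows))
        assert model.data.shape == (4, 4)
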