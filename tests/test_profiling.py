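"""Cluster profiles, deviation ranking, naming rules, heat-map export."""

import numpy as np
import pandas as pd
import pytest

from claimseg.profiling import (
    LabelRule,
    default_label_rules,
    export_heatmap_table,
    label_clusters,
    profile_clusters,
    rank_deviations,
    suggest_label,
)


class TestProfileClusters:
    def test_single_cluster_equals_grand_means(self, tiny_patient_years):
        profiles = profile_clusters(tiny_patient_years, np.ones(6, dtype=int))
        row = profiles.summary.set_index("cluster")
        assert row.loc[1, "age_mean"] == row.loc["overall", "age_mean"]
        assert row.loc[1, "ed_visits_mean"] == row.loc["overall", "ed_visits_mean"]
        assert row.loc[1, "share_pct"] == 100.0

    def test_hand_tabulated_two_cluster_means(self, tiny_patient_years):
        assignments = np.array([1, 1, 1, 2, 2, 2])
        profiles = profile_clusters(tiny_patient_years, assignments)
        row = profiles.summary.set_index("cluster")
        assert row.loc[1, "age_mean"] == pytest.approx((30 + 40 + 50) / 3)
        assert row.loc[2, "female_pct"] == pytest.approx(100 * 2 / 3)
        assert row.loc[1, "cond_diabetes_pct"] == pytest.approx(100 * 2 / 3)
        assert row.loc[2, "ed_visits_mean"] == pytest.approx((2 + 0 + 6) / 3)
        assert row.loc[2, "admissions_sd"] == pytest.approx(np.std([0, 0, 3], ddof=1))

    def test_shares_sum_to_hundred(self, tiny_patient_years):
        profiles = profile_clusters(tiny_patient_years, np.array([1, 2, 1, 3, 2, 1]))
        clusters = profiles.summary[profiles.summary["cluster"] != "overall"]
        assert clusters["share_pct"].sum() == pytest.approx(100.0)

    def test_weighted_means_recompose_grand_mean(self, fixture6_cohort):
        py = fixture6_cohort.patient_years
        assignments = fixture6_cohort.true_labels
        profiles = profile_clusters(py, assignments)
        w = np.array([(assignments == c).mean() for c in profiles.cluster_ids])
        recomposed = w @ profiles.input_means.to_numpy()
        np.testing.assert_allclose(recomposed, profiles.grand_means.to_numpy(),
                                   atol=1e-9)

    def test_merged_pair_profile_is_weighted_combination(self, fixture6_cohort):
        py = fixture6_cohort.patient_years
        a = fixture6_cohort.true_labels
        merged = np.where(np.isin(a, [5, 6]), 5, a)
        p_orig = profile_clusters(py, a)
        p_merged = profile_clusters(py, merged)
        n5, n6 = (a == 5).sum(), (a == 6).sum()
        expect = (n5 * p_orig.input_means.loc[5] + n6 * p_orig.input_means.loc[6]) / (n5 + n6)
        np.testing.assert_allclose(p_merged.input_means.loc[5].to_numpy(),
                                   expect.to_numpy(), atol=1e-12)

    def test_misaligned_assignments_rejected(self, tiny_patient_years):
        with pytest.raises(ValueError):
            profile_clusters(tiny_patient_years, np.array([1, 2]))


class TestRankDeviations:
    def test_uniform_cluster_scores_zero(self, tiny_patient_years):
        profiles = profile_clusters(tiny_patient_years, np.ones(6, dtype=int))
        devs = rank_deviations(profiles, top_m=5)
        assert np.allclose(devs[1]["score"], 0.0)

    def test_constructed_prevalence_score(self):
        # cluster prevalence 98% vs grand 13%: score = .85 / sqrt(.13*.87) ~ 2.5
        n = 400
        flags = np.zeros(n, dtype=int)
        flags[:50] = np.random.default_rng(0).random(50) < 0.98
        py = pd.DataFrame({
            "patient_id": [str(i) for i in range(n)],
            "age": 40, "female": 1,
            "eligibility": "TANF", "race_ethnicity": "White",
            "cond_pregnancy_complications": flags,
            "admissions": 0, "hospital_days": 0, "ed_visits": 0,
            "preventable_admissions": 0, "preventable_ed_visits": 0,
            "annual_spend": 0.0,
        })
        assignments = np.where(np.arange(n) < 50, 1, 2)
        profiles = profile_clusters(py, assignments)
        devs = rank_deviations(profiles, top_m=3)
        top = devs[1].iloc[0]
        assert top["feature"] == "cond_pregnancy_complications"
        p1 = flags[:50].mean()
        grand = flags.mean()
        sd = np.sqrt(grand * (1 - grand))
        assert top["score"] == pytest.approx((p1 - grand) / sd)
        assert top["score"] > 2

    def test_signs_flip_below_grand_mean(self, fixture6_cohort):
        profiles = profile_clusters(fixture6_cohort.patient_years,
                                    fixture6_cohort.true_labels)
        devs = rank_deviations(profiles, top_m=len(profiles.grand_means))
        d2 = devs[2].set_index("feature")["score"]  # pregnancy cluster
        assert d2["cond_pregnancy_complications"] > 0
        assert d2["cond_endocrine_disorders"] < 0  # below-average here

    def test_zero_variance_features_excluded(self, tiny_patient_years):
        py = tiny_patient_years.copy()
        py["female"] = 1  # constant
        profiles = profile_clusters(py, np.array([1, 1, 1, 2, 2, 2]))
        devs = rank_deviations(profiles, top_m=50)
        assert "female" not in set(devs[1]["feature"])


class TestSuggestLabel:
    def test_pregnancy_rule_fires(self):
        top = pd.DataFrame({"feature": ["cond_pregnancy_complications", "female"],
                            "score": [2.5, 1.2]})
        assert suggest_label(top, default_label_rules(), 2) == "Pregnancy Complications"

    def test_behavioral_rule_needs_both_features(self):
        top = pd.DataFrame({
            "feature": ["cond_mental_illness", "cond_neurologic_disorders"],
            "score": [2.0, 1.8]})
        assert suggest_label(top, default_label_rules(), 3) == "Behavioral Health"

    def test_fallback_contains_cluster_id(self):
        top = pd.DataFrame({"feature": ["cond_injury"], "score": [0.2]})
        label = suggest_label(top, default_label_rules(), 7)
        assert label == "Cluster 7: cond_injury"

    def test_negative_majority_names_relatively_healthy(self):
        top = pd.DataFrame({
            "feature": ["cond_endocrine_disorders", "cond_cardiovascular_disorders",
                        "cond_respiratory_disorders", "age"],
            "score": [-1.2, -1.0, -0.8, -0.5]})
        assert suggest_label(top, default_label_rules(), 1) == "Relatively Healthy"

    def test_user_label_always_wins(self):
        top = pd.DataFrame({"feature": ["cond_pregnancy_complications"],
                            "score": [3.0]})
        assert suggest_label(top, default_label_rules(), 2,
                             user_label="My Label") == "My Label"

    def test_first_matching_rule_wins(self):
        rules = [LabelRule("A", ["x"]), LabelRule("B", ["x"])]
        top = pd.DataFrame({"feature": ["x"], "score": [1.0]})
        assert suggest_label(top, rules, 1) == "A"

    def test_planted_fixture_clusters_named(self, fixture6_cohort):
        profiles = profile_clusters(fixture6_cohort.patient_years,
                                    fixture6_cohort.true_labels)
        labels = label_clusters(profiles)
        assert labels[2]["label"] == "Pregnancy Complications"
        assert labels[3]["label"] == "Behavioral Health"
        assert labels[4]["label"] == "Cardio-metabolic"
        assert labels[2]["provenance"] == "rule"


class TestHeatmap:
    def test_single_cluster_column_equals_cohort_prevalence(self, tiny_patient_years):
        profiles = profile_clusters(tiny_patient_years, np.ones(6, dtype=int))
        mat = export_heatmap_table(profiles)
        assert mat.loc["cond_diabetes", "1"] == pytest.approx(100 * 3 / 6)

    def test_matrix_consistent_with_profiles_and_bounded(self, fixture6_cohort):
        profiles = profile_clusters(fixture6_cohort.patient_years,
                                    fixture6_cohort.true_labels)
        mat = export_heatmap_table(profiles)
        assert mat.shape == (12, 6)
        assert ((mat >= 0) & (mat <= 100)).all().all()
        row = profiles.summary.set_index("cluster")
        for c in profiles.cluster_ids:
            assert mat.loc["cond_mental_illness", str(c)] == pytest.approx(
                row.loc[c, "cond_mental_illness_pct"])
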