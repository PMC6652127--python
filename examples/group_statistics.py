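"""Cohort statistics at study scale (145 community vs 9 hospital patients)
on a feature-level synthetic cohort: Kruskal-Wallis p-values, Cohen d, and
the cross-validated random-forest outcome model."""

from rehabsense import CohortConfig, cohens_d, compare_features, evaluate_rf, rank_features
from rehabsense.cohort import simulate_feature_cohort

cohort = simulate_feature_cohort(CohortConfig(seed=40))
comparisons = compare_features(
    cohort,
    features=["time_pct_standing", "time_pct_laying", "time_pct_active",
              "time_pct_sitting", "ei_resident_room", "ei_therapy_room"],
)
ranked = rank_features(comparisons)
print(ranked[["feature", "mean_c", "mean_h", "p_value", "cohen_d"]].round(3).to_string(index=False))
print()

model = evaluate_rf(cohort, ["ei_resident_room"])
print("resident-room intensity model (3-fold CV, max_depth 2, random_state 40):")
print(model.summary.round(3).to_string())
print()
print("effect size from printed group summaries (standing time %):",
      round(cohens_d(44.22, 7.94, 32.68, 7.30), 2))
# The programmed resident-room intensity difference (d = 1.25) and the
# posture-time differences surface as the top-ranked features; the
# single-feature forest separates the groups well above chance.  The last
# line shows the average-variance Cohen-d pooling reproducing 1.51 from
# group means/SDs alone.
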