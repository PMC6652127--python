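import numpy as np
import pandas as pd
import pytest

from rehabsense.cohort import CohortConfig, simulate_feature_cohort
from rehabsense.stats import (
    chi_square_test,
    cohens_d,
    cohens_d_from_samples,
    compare_features,
    evaluate_rf,
    kruskal_wallis,
    rank_features,
    spearman_matrix,
)


def hand_ranked_h(*groups):
    """Brute-force Kruskal-Wallis H from explicit mid-ranks."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size)
    sorted_vals = pooled[order]
    i = 0
    r = np.empty(pooled.size)
    while i < pooled.size:
        j = i
        while j < pooled.size and sorted_vals[j] == sorted_vals[i]:
            j += 1
        r[i:j] = 0.5 * (i + 1 + j)
        i = j
    ranks[order] = r
    n = pooled.size
    start = 0
    h = 0.0
    for g in groups:
        g = np.asarray(g)
        rsum = ranks[start:start + g.size].sum()
        h += rsum**2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    ct = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / ct if ct > 0 else 0.0


def test_kruskal_wallis_toy_and_degenerate_cases():
    h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
    assert h == pytest.approx(hand_ranked_h([1, 2, 3], [4, 5, 6]))
    assert h == pytest.approx(27.0 / 7.0)
    h0, p0 = kruskal_wallis([2.0, 2.0], [2.0, 2.0])
    assert h0 == 0.0 and p0 == 1.0
    with pytest.raises(ValueError):
        kruskal_wallis([1, 2], [])


def test_kruskal_wallis_equals_squared_ranksum_normal_approx():
    """For two tie-free groups, H equals the square of the standard-normal
    Wilcoxon rank-sum statistic (no continuity correction)."""
    a = [1.2, 3.4, 5.1, 7.7, 9.2]
    b = [2.5, 4.4, 6.3, 8.8]
    h, _ = kruskal_wallis(a, b)
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1, n2 = len(a), len(b)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    assert h == pytest.approx(((w - mu) / sd) ** 2)


def test_chi_square_hand_computation_and_guards():
    stat, p = chi_square_test([[10, 10], [20, 20]])
    assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
    stat, _ = chi_square_test([[10, 0], [0, 10]])
    assert stat == pytest.approx(20.0)  # sum (O-E)^2/E with E=5 everywhere
    with pytest.raises(ValueError):
        chi_square_test([[1.5, 2], [3, 4]])
    with pytest.raises(ValueError):
        chi_square_test([[0, 0], [3, 4]])


def test_cohens_d_reproduces_population_effect_sizes():
    """Average-variance pooling reproduces the printed baseline effect
    sizes from group means and SDs."""
    assert cohens_d(44.22, 7.94, 32.68, 7.30) == pytest.approx(1.51, abs=0.005)
    assert abs(cohens_d(46.83, 9.83, 60.99, 11.11)) == pytest.approx(1.35, abs=0.005)
    assert cohens_d(43.32, 17.44, 26.99, 6.05) == pytest.approx(1.25, abs=0.005)


def test_cohens_d_antisymmetry_and_guards():
    assert cohens_d(3, 1, 5, 2) == pytest.approx(-cohens_d(5, 2, 3, 1))
    assert cohens_d(4.0, 1.0, 4.0, 2.0) == 0.0
    with pytest.raises(ValueError):
        cohens_d(1, 0, 2, 0)


def test_spearman_matrix_properties():
    rng = np.random.default_rng(2)
    x = rng.normal(size=1000)
    df = pd.DataFrame({"x": x, "cube": x**3, "indep": rng.normal(size=1000), "const": 1.0})
    rho = spearman_matrix(df)
    assert rho.loc["x", "x"] == 1.0
    assert rho.loc["x", "cube"] == pytest.approx(1.0)  # monotone invariance
    assert abs(rho.loc["x", "indep"]) < 0.1
    assert np.isnan(rho.loc["const", "x"])
    assert np.allclose(rho.drop("const").drop(columns="const"),
                       rho.drop("const").drop(columns="const").T)


def _toy_table(n_c=48, n_h=3, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(0, 1, n_c), rng.normal(sep, 1, n_h)])
    return pd.DataFrame({"f": x, "outcome": ["community"] * n_c + ["hospital"] * n_h})


def test_rf_separable_limit_and_determinism():
    table = _toy_table(sep=10.0)
    ev = evaluate_rf(table, ["f"])
    s = ev.summary
    assert s.loc["auc", "mean"] == pytest.approx(1.0)
    assert s.loc["sensitivity", "mean"] == pytest.approx(100.0)
    ev2 = evaluate_rf(table, ["f"])
    assert ev.per_fold.equals(ev2.per_fold)
    assert ev.hyperparameters["max_depth"] == 2
    assert ev.hyperparameters["random_state"] == 40


def test_rf_stratified_folds_keep_minority_class():
    table = _toy_table(n_c=48, n_h=3, sep=2.0)
    ev = evaluate_rf(table, ["f"])
    assert ev.flagged_folds == []
    assert len(ev.per_fold) == 3


def test_rf_permutation_null_auc():
    """Permuting outcome labels drives the mean AUC to ~0.5."""
    rng = np.random.default_rng(7)
    base = _toy_table(n_c=40, n_h=12, sep=3.0)
    aucs = []
    for _ in range(40):
        t = base.copy()
        t["outcome"] = rng.permutation(t["outcome"].to_numpy())
        ev = evaluate_rf(t, ["f"], rf_params={"n_estimators": 30})
        aucs.append(ev.summary.loc["auc", "mean"])
    assert np.nanmean(aucs) == pytest.approx(0.5, abs=0.1)


def test_rank_features_order_and_ties():
    comp = pd.DataFrame(
        {
            "feature": ["a", "b", "c", "d"],
            "p_value": [0.001, 0.04, 0.0005, 0.001],
            "cohen_d": [0.4, 0.2, 1.0, 1.2],
        }
    )
    ranked = rank_features(comp)
    assert ranked["feature"].tolist() == ["c", "d", "a", "b"]
    assert rank_features(comp.iloc[0:0]).empty


def test_compare_features_on_programmed_cohort():
    df = simulate_feature_cohort(CohortConfig(seed=4))
    comp = compare_features(df, features=["ei_resident_room", "time_pct_laying"])
    res = comp.set_index("feature")
    assert res.loc["ei_resident_room", "p_value"] < 0.01
    assert res.loc["ei_resident_room", "cohen_d"] > 0.5
    assert res.loc["time_pct_laying", "cohen_d"] < 0  # hospital lies down more
    assert res.loc["ei_resident_room", "n_c"] == 145
    assert res.loc["ei_resident_room", "n_h"] == 9


def test_programmed_effect_sizes_recovered_in_median():
    """Cohorts programmed with standardized resident-room differences of
    0.5/1.0/1.5 recover the effect in the median over 200 replicates."""
    for delta in (0.5, 1.0, 1.5):
        cfg = CohortConfig(
            group_effect_map={
                **CohortConfig().group_effect_map,
                "ei_resident_room": (80.0, 80.0 - delta * 13.06, 13.06),
            }
        )
        ds = []
        for rep in range(200):
            df = simulate_feature_cohort(cfg, seed=10_000 * int(delta * 2) + rep)
            ds.append(
                cohens_d_from_samples(
                    df.loc[df.outcome == "community", "ei_resident_room"],
                    df.loc[df.outcome == "hospital", "ei_resident_room"],
                )
            )
        assert np.median(ds) == pytest.approx(delta, abs=0.1)
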