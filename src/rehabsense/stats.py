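"""Cohort-level statistics: group comparisons, effect sizes, correlations and
cross-validated outcome models.

Quantitative features are compared between outcome groups (community vs
hospital) with the Kruskal-Wallis rank test; categorical demographics with
Pearson chi-square.  Effect sizes are Cohen's d with the *unweighted*
average-variance pooling, d = (m1 - m2) / sqrt((s1^2 + s2^2)/2) — the
convention that reproduces the study-style printed effect sizes from group
means and SDs regardless of the 145:9 imbalance.  Predictive models are
shallow random forests (max_depth 2, random_state 40, class_weight balanced)
under stratified 3-fold cross-validation with the hospital group as the
positive class; sensitivity is the recall of that minority class only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

POSITIVE_CLASS = "hospital"
RF_PARAMS = {"max_depth": 2, "random_state": 40, "class_weight": "balanced"}
N_FOLDS = 3


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # all observations tied: H is 0 by definition
        return 0.0, 1.0
    h, p = sstats.kruskal(*arrays)
    return float(h), float(p)


def chi_square_test(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2-D contingency table of counts."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table must contain integer counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, _, _ = sstats.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Standardized mean difference with average-variance pooling."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    pooled = np.sqrt((sd1 * sd1 + sd2 * sd2) / 2.0)
    if pooled == 0:
        raise ValueError("both group SDs are zero; d is undefined")
    return (mean1 - mean2) / pooled


def cohens_d_from_samples(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cohens_d(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1))


@dataclass
class GroupComparison:
    feature: str
    mean_c: float
    sd_c: float
    n_c: int
    mean_h: float
    sd_h: float
    n_h: int
    p_value: float
    cohen_d: float


def compare_features(
    table: pd.DataFrame,
    outcome_col: str = "outcome",
    features: list[str] | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-feature community-vs-hospital comparison (Kruskal-Wallis p,
    Cohen d, group summaries and availability counts).

    No multiple-testing correction by default; ``bh_correction`` adds a
    Benjamini-Hochberg adjusted column.
    """
    if features is None:
        skip = {outcome_col, "patient_id", "baseline_day"}
        features = [
            c for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for feat in features:
        c = table.loc[table[outcome_col] == "community", feat].dropna()
        h = table.loc[table[outcome_col] == "hospital", feat].dropna()
        if len(c) >= 2 and len(h) >= 2:
            _, p = kruskal_wallis(c, h)
            try:
                d = cohens_d_from_samples(c, h)
            except ValueError:
                d = np.nan
        else:
            p, d = np.nan, np.nan
        rows.append(
            GroupComparison(
                feature=feat,
                mean_c=float(c.mean()) if len(c) else np.nan,
                sd_c=float(c.std(ddof=1)) if len(c) > 1 else np.nan,
                n_c=int(len(c)),
                mean_h=float(h.mean()) if len(h) else np.nan,
                sd_h=float(h.std(ddof=1)) if len(h) > 1 else np.nan,
                n_h=int(len(h)),
                p_value=p,
                cohen_d=d,
            )
        )
    out = pd.DataFrame([vars(r) for r in rows])
    if bh_correction and not out.empty:
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["p_bh"] = adj
    return out


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman-rho matrix over the numeric columns; pairs
    involving a constant column are NaN."""
    numeric = table.select_dtypes(include=[float, int])
    if len(numeric) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    cols = list(numeric.columns)
    rho = numeric.corr(method="spearman")
    for c in cols:
        col = numeric[c].dropna()
        if col.nunique() <= 1:
            rho.loc[c, :] = np.nan
            rho.loc[:, c] = np.nan
        else:
            rho.loc[c, c] = 1.0
    return rho


@dataclass
class ModelEvaluation:
    """3-fold cross-validated random-forest outcome model."""

    features: list[str]
    per_fold: pd.DataFrame  # sensitivity/specificity/accuracy in %, auc
    flagged_folds: list[int] = field(default_factory=list)
    hyperparameters: dict = field(default_factory=lambda: dict(RF_PARAMS))
    n_folds: int = N_FOLDS

    @property
    def summary(self) -> pd.DataFrame:
        """Mean and SD (over folds, population SD) of each metric."""
        return pd.DataFrame(
            {"mean": self.per_fold.mean(), "sd": self.per_fold.std(ddof=0)}
        )


def evaluate_rf(
    table: pd.DataFrame,
    features: list[str],
    outcome_col: str = "outcome",
    n_folds: int = N_FOLDS,
    rf_params: dict | None = None,
) -> ModelEvaluation:
    """Stratified k-fold CV of a shallow random forest on a feature subset.

    Rows with missing feature values are dropped.  Folds whose validation
    part lacks the positive (hospital) class are flagged (metrics NaN), not
    silently dropped.
    """
    params = dict(RF_PARAMS)
    params.update(rf_params or {})
    sub = table[features + [outcome_col]].dropna()
    y = (sub[outcome_col] == POSITIVE_CLASS).to_numpy()
    X = sub[features].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both outcome classes must be present")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=False)
    rows = []
    flagged = []
    for k, (tr, va) in enumerate(cv.split(X, y)):
        clf = RandomForestClassifier(**params)
        clf.fit(X[tr], y[tr])
        yv = y[va]
        if yv.sum() == 0 or yv.sum() == yv.size:
            flagged.append(k)
            rows.append({"sensitivity": np.nan, "specificity": np.nan,
                         "accuracy": np.nan, "auc": np.nan})
            continue
        pred = clf.predict(X[va])
        proba = clf.predict_proba(X[va])[:, list(clf.classes_).index(True)]
        sens = 100.0 * np.mean(pred[yv]) if yv.any() else np.nan
        spec = 100.0 * np.mean(~pred[~yv])
        acc = 100.0 * np.mean(pred == yv)
        auc = roc_auc_score(yv, proba)
        rows.append({"sensitivity": sens, "specificity": spec, "accuracy": acc, "auc": auc})
    return ModelEvaluation(
        features=list(features),
        per_fold=pd.DataFrame(rows),
        flagged_folds=flagged,
        hyperparameters=params,
        n_folds=n_folds,
    )


def rank_features(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Order features by ascending p, breaking ties by descending |d|."""
    if comparisons.empty:
        return comparisons
    out = comparisons.copy()
    out["_absd"] = out["cohen_d"].abs()
    out = out.sort_values(["p_value", "_absd"], ascending=[True, False], kind="mergesort")
    return out.drop(columns="_absd").reset_index(drop=True)
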