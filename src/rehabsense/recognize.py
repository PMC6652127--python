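"""Hierarchical activity recognition on 10-second windows.

Seven time/frequency features of the filtered signal magnitude (mean, median,
variance, skewness, kurtosis, peak frequency, peak power) feed a three-stage
hierarchy:

1. walking vs stationary (learned classifier);
2. stationary windows split into active vs idle by the windowed-MAD
   threshold (walking always counts as active downstream);
3. stationary windows assigned a posture (stand / sit / lay) by a second
   learned classifier.

The base learner is a random forest by default; the hierarchy only sees the
seven window features, so any tabular classifier can be plugged in by
algorithm id.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.tree import DecisionTreeClassifier

from .signal import MAD_THRESHOLD_MS2

FEATURE_NAMES = (
    "mean",
    "median",
    "variance",
    "skewness",
    "kurtosis",
    "peak_frequency",
    "peak_power",
)

LOCOMOTION_CLASSES = ("walking", "stationary")
POSTURE_CLASSES = ("stand", "sit", "lay")

_MODEL_FORMAT_VERSION = 1


def extract_window_features(windows: np.ndarray, sample_rate_hz: float = 16.0) -> pd.DataFrame:
    """Seven summary features per filtered-magnitude window.

    Moments are population moments of the window samples; the spectral peak
    is the argmax of the one-sided power spectrum over (0, Nyquist] (the DC
    bin is excluded).  Zero-variance windows get skewness/kurtosis 0 by
    convention so degenerate windows remain classifiable.
    """
    W = np.atleast_2d(np.asarray(windows, dtype=float))
    n = W.shape[1]
    var = W.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = sstats.skew(W, axis=1, bias=True)
        kurt = sstats.kurtosis(W, axis=1, bias=True)
    degenerate = var <= 1e-24
    skew = np.where(degenerate, 0.0, np.nan_to_num(skew))
    kurt = np.where(degenerate, 0.0, np.nan_to_num(kurt))
    spec = np.abs(np.fft.rfft(W, axis=1)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    spec_pos = spec[:, 1:]  # drop DC
    peak_idx = np.argmax(spec_pos, axis=1)
    return pd.DataFrame(
        {
            "mean": W.mean(axis=1),
            "median": np.median(W, axis=1),
            "variance": var,
            "skewness": skew,
            "kurtosis": kurt,
            "peak_frequency": freqs[1:][peak_idx],
            "peak_power": spec_pos[np.arange(W.shape[0]), peak_idx],
        }
    )


@dataclass
class ActivityLabel:
    """walking carries no posture; posture is present iff stationary."""

    locomotion: str
    motion_state: str
    posture: str | None

    def __post_init__(self) -> None:
        if self.locomotion == "walking" and self.posture is not None:
            raise ValueError("a walking label cannot carry a posture")
        if self.locomotion == "stationary" and self.posture is None:
            raise ValueError("a stationary label requires a posture")


def _make_learner(algorithm: str, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=60, max_depth=8, random_state=seed, class_weight="balanced_subsample"
        )
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(max_depth=8, random_state=seed, class_weight="balanced")
    raise ValueError(f"unknown algorithm id '{algorithm}'")


@dataclass
class HierarchicalModel:
    """Fitted two-classifier hierarchy plus training provenance."""

    stage1: object  # walking vs stationary
    stage3: object  # posture for stationary windows
    algorithm: str
    seed: int
    cv_scores: dict = field(default_factory=dict)
    mad_threshold_ms2: float = MAD_THRESHOLD_MS2
    format_version: int = _MODEL_FORMAT_VERSION

    @property
    def fitted(self) -> bool:
        return hasattr(self.stage1, "classes_") and hasattr(self.stage3, "classes_")


def _cv_report(est, X, y, folds: int, seed: int) -> dict:
    """Per-class precision/recall/F from k-fold cross-validated predictions."""
    folds = min(folds, int(pd.Series(y).value_counts().min()))
    if folds < 2:
        return {}
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(est, X, y, cv=cv)
    out: dict[str, dict[str, float]] = {}
    for cls in np.unique(y):
        tp = float(np.sum((pred == cls) & (y == cls)))
        fp = float(np.sum((pred == cls) & (y != cls)))
        fn = float(np.sum((pred != cls) & (y == cls)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[str(cls)] = {
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "accuracy": float(np.mean(pred[y == cls] == cls)),
            "support": int(np.sum(y == cls)),
        }
    weights = np.array([out[str(c)]["support"] for c in np.unique(y)], dtype=float)
    weights /= weights.sum()
    out["weighted_avg"] = {
        m: float(np.sum(weights * np.array([out[str(c)][m] for c in np.unique(y)])))
        for m in ("precision", "recall", "f1")
    }
    out["n_folds"] = folds
    return out


def train_hierarchical_classifier(
    features: pd.DataFrame,
    locomotion: np.ndarray,
    posture: np.ndarray,
    algorithm: str = "random_forest",
    seed: int = 0,
    cv_folds: int = 10,
) -> HierarchicalModel:
    """Fit the walking/stationary and posture stages on labelled windows.

    ``posture`` entries are ignored (may be None) for walking windows.  With
    ``cv_folds >= 2``, k-fold cross-validated precision/recall/F per class is
    recorded in ``cv_scores``.
    """
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    locomotion = np.asarray(locomotion, dtype=object)
    posture = np.asarray(posture, dtype=object)
    if len(np.unique(locomotion)) < 2:
        raise ValueError("stage 1 (walking/stationary) needs both classes in the labels")
    stat = locomotion == "stationary"
    post_labels = posture[stat].astype(str)
    if len(np.unique(post_labels)) < 2:
        raise ValueError("stage 3 (posture) needs at least two posture classes")

    stage1 = _make_learner(algorithm, seed)
    stage3 = _make_learner(algorithm, seed + 1)
    cv_scores = {}
    if cv_folds and cv_folds >= 2:
        cv_scores["stage1"] = _cv_report(stage1, X, locomotion.astype(str), cv_folds, seed)
        cv_scores["stage3"] = _cv_report(stage3, X[stat], post_labels, cv_folds, seed)
    stage1.fit(X, locomotion.astype(str))
    stage3.fit(X[stat], post_labels)
    return HierarchicalModel(
        stage1=stage1, stage3=stage3, algorithm=algorithm, seed=seed, cv_scores=cv_scores
    )


def classify_window(model: HierarchicalModel, features: pd.Series | dict, mad_ms2: float) -> ActivityLabel:
    """Label one window through the three-stage hierarchy."""
    row = pd.DataFrame([dict(features)])[list(FEATURE_NAMES)]
    out = classify_windows(model, row, np.array([mad_ms2]))
    return ActivityLabel(
        locomotion=str(out["locomotion"].iloc[0]),
        motion_state=str(out["motion_state"].iloc[0]),
        posture=None if out["posture"].iloc[0] is None else str(out["posture"].iloc[0]),
    )


def classify_windows(
    model: HierarchicalModel, features: pd.DataFrame, mad_ms2: np.ndarray
) -> pd.DataFrame:
    """Vectorised hierarchy over many windows."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    mad = np.asarray(mad_ms2, dtype=float)
    if X.shape[0] != mad.size:
        raise ValueError("features and MAD series must align")
    loco = model.stage1.predict(X).astype(object)
    posture = np.full(X.shape[0], None, dtype=object)
    stat = loco == "stationary"
    if np.any(stat):
        posture[stat] = model.stage3.predict(X[stat]).astype(object)
    # walking embodies active status; stationary windows split by the MAD threshold
    motion = np.where(
        loco == "walking", "active", np.where(mad >= model.mad_threshold_ms2, "active", "idle")
    ).astype(object)
    return pd.DataFrame({"locomotion": loco, "motion_state": motion, "posture": posture})


def scores_from_confusion(cm: np.ndarray, classes: list[str] | None = None) -> pd.DataFrame:
    """Per-class precision/recall/F from a confusion matrix (rows = truth)."""
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    classes = classes or [str(i) for i in range(cm.shape[0])]
    tp = np.diag(cm)
    prec = np.divide(tp, cm.sum(axis=0), out=np.zeros_like(tp), where=cm.sum(axis=0) > 0)
    rec = np.divide(tp, cm.sum(axis=1), out=np.zeros_like(tp), where=cm.sum(axis=1) > 0)
    denom = prec + rec
    f1 = np.divide(2 * prec * rec, denom, out=np.zeros_like(tp), where=denom > 0)
    return pd.DataFrame({"precision": prec, "recall": rec, "f1": f1}, index=classes)


def save_model(model: HierarchicalModel, path: str | Path) -> None:
    """Serialize the fitted hierarchy (single-file artifact with embedded
    version and seed)."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> HierarchicalModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, HierarchicalModel):
        raise ValueError("file does not contain a HierarchicalModel")
    if model.format_version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {model.format_version}")
    return model
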