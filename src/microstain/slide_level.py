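"""Model 2: ordered-aggregation features and the patient-level forest.

Each slide's ordered tile probabilities are compressed into 12 variables —
seven plain descriptive statistics (mean, median, min, max, sample SD,
quantiles 25/75) plus five statistics (min, max, q25, q75, SD) of the series
after 1-D average pooling with pool size 10 and stride 5, which capture the
local consistency of the staining signal. A 100-tree random forest classifies
the fixed-length vector at the patient level; validation performance is the
mean over repeated forest fits (AUC, closest-top-left threshold, sensitivity,
specificity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve

from .tile_classifier import TilePredictionSeries

__all__ = [
    "FEATURE_NAMES",
    "SlideFeatureVector",
    "ROCCurve",
    "avg_pool_1d",
    "aggregate",
    "features_frame",
    "train_slide_classifier",
    "roc_from_scores",
    "closest_top_left",
    "sensitivity_specificity_at",
    "evaluate_repeated",
    "RepeatedEvaluation",
]

FEATURE_NAMES = ("mean", "median", "min", "max", "sd", "q25", "q75",
                 "pooled_min", "pooled_max", "pooled_q25", "pooled_q75",
                 "pooled_sd")


@dataclass(frozen=True)
class SlideFeatureVector:
    """The 12 aggregation variables of one slide (fixed shape for any tile
    count)."""

    mean: float
    median: float
    min: float
    max: float
    sd: float
    q25: float
    q75: float
    pooled_min: float
    pooled_max: float
    pooled_q25: float
    pooled_q75: float
    pooled_sd: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=np.float64)


def avg_pool_1d(values: Sequence[float], pool_size: int = 10,
                stride: int = 5) -> np.ndarray:
    """Valid-mode 1-D average pooling over the ordered tile series.

    Windows start at positions 0, stride, 2*stride, ... while the full window
    fits; a series shorter than ``pool_size`` collapses to a single window
    covering all values (no zero padding — padding would fabricate low
    predictions).
    """
    if pool_size < 1 or stride < 1:
        raise ValueError("pool_size and stride must be >= 1")
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("series is empty")
    if v.size < pool_size:
        return np.array([v.mean()])
    n_windows = (v.size - pool_size) // stride + 1
    starts = np.arange(n_windows) * stride
    return np.array([v[s:s + pool_size].mean() for s in starts])


def _sd(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1)) if v.size > 1 else 0.0


def aggregate(series: TilePredictionSeries | Sequence[float],
              pool_size: int = 10, stride: int = 5) -> SlideFeatureVector:
    """Compute the 12-variable feature vector of one slide.

    Quantiles interpolate linearly between order statistics; SD is the sample
    SD (n-1 divisor), zero for a single value.
    """
    v = np.asarray(getattr(series, "probabilities", series), dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot aggregate an empty prediction series")
    pooled = avg_pool_1d(v, pool_size, stride)
    return SlideFeatureVector(
        mean=float(v.mean()),
        median=float(np.median(v)),
        min=float(v.min()),
        max=float(v.max()),
        sd=_sd(v),
        q25=float(np.quantile(v, 0.25)),
        q75=float(np.quantile(v, 0.75)),
        pooled_min=float(pooled.min()),
        pooled_max=float(pooled.max()),
        pooled_q25=float(np.quantile(pooled, 0.25)),
        pooled_q75=float(np.quantile(pooled, 0.75)),
        pooled_sd=_sd(pooled),
    )


def features_frame(series_list: Sequence[TilePredictionSeries],
                   labels: Sequence[str] | None = None,
                   pool_size: int = 10, stride: int = 5) -> pd.DataFrame:
    """Feature table (one row per slide) ready for CSV export / the forest."""
    rows = []
    for i, s in enumerate(series_list):
        fv = aggregate(s, pool_size, stride)
        row = {"patient_id": s.patient_id, "marker": s.marker}
        row.update({n: getattr(fv, n) for n in FEATURE_NAMES})
        if labels is not None:
            row["label"] = labels[i]
        rows.append(row)
    return pd.DataFrame(rows)


def train_slide_classifier(features: np.ndarray, labels: Sequence[int],
                           n_trees: int = 100, seed: int = 0,
                           ) -> RandomForestClassifier:
    """Fit the patient-level random forest (exactly ``n_trees`` trees)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"feature matrix must have {len(FEATURE_NAMES)} columns")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(X, y)
    return rf


@dataclass(frozen=True)
class ROCCurve:
    """ROC points with their decision thresholds (call positive iff score >=
    threshold) and the area under the curve."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_from_scores(y_true: Sequence[int], scores: Sequence[float]) -> ROCCurve:
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    # trapezoidal AUC over the full curve
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def closest_top_left(roc: ROCCurve) -> float:
    """Threshold of the ROC point minimising (1-TPR)^2 + FPR^2.

    Ties are broken toward higher specificity (lower FPR), then the higher
    threshold. Degenerate curves (fewer than two distinct scores) have no
    defined operating point.
    """
    finite = np.isfinite(roc.thresholds)
    if np.unique(roc.thresholds[finite]).size < 2:
        raise ValueError("operating point undefined: fewer than 2 distinct scores")
    d2 = (1.0 - roc.tpr) ** 2 + roc.fpr**2
    best = None
    for i in range(len(d2)):
        key = (d2[i], roc.fpr[i], -roc.thresholds[i])
        if best is None or key < best[0]:
            best = (key, roc.thresholds[i])
    return float(best[1])


def sensitivity_specificity_at(y_true, scores, threshold: float,
                               ) -> tuple[float, float]:
    """Se and Sp (percent) for the rule 'positive iff score >= threshold'."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    calls = s >= threshold
    tp = int(np.sum(calls & (y == 1)))
    fn = int(np.sum(~calls & (y == 1)))
    tn = int(np.sum(~calls & (y == 0)))
    fp = int(np.sum(calls & (y == 0)))
    se = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return se, sp


@dataclass
class RepeatedEvaluation:
    """Per-iteration and mean validation metrics of repeated forest fits."""

    aucs: np.ndarray
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def mean_threshold(self) -> float:
        return float(self.thresholds.mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.sensitivities.mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.specificities.mean())

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "mean_threshold": self.mean_threshold,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "per_iteration": {
                "auc": self.aucs.tolist(),
                "threshold": self.thresholds.tolist(),
                "sensitivity": self.sensitivities.tolist(),
                "specificity": self.specificities.tolist(),
            },
        }


def evaluate_repeated(features_train, labels_train, features_val, labels_val,
                      n_iter: int = 50, n_trees: int = 100, seed: int = 0,
                      ) -> RepeatedEvaluation:
    """Average validation AUC / threshold / Se / Sp over ``n_iter``
    independently seeded forest fits (only the forest seed varies)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    y_val = np.asarray(labels_val).astype(int)
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation set must contain both classes")
    aucs, thrs, ses, sps = [], [], [], []
    for i in range(n_iter):
        rf = train_slide_classifier(features_train, labels_train,
                                    n_trees=n_trees, seed=seed + i)
        scores = rf.predict_proba(np.asarray(features_val))[:, 1]
        roc = roc_from_scores(y_val, scores)
        aucs.append(roc.auc)
        try:
            thr = closest_top_left(roc)
        except ValueError:
            # constant scores: fall back to the majority cut at 0.5
            thr = 0.5
        se, sp = sensitivity_specificity_at(y_val, scores, thr)
        thrs.append(thr)
        ses.append(se)
        sps.append(sp)
    return RepeatedEvaluation(aucs=np.asarray(aucs), thresholds=np.asarray(thrs),
                              sensitivities=np.asarray(ses),
                              specificities=np.asarray(sps))
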