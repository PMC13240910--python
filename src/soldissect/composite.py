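"""The composite-delta solubility index.

An untrained linear score over redundancy-filtered descriptors: each feature
is robustly scaled by the pooled median and IQR and weighted by its Cliff's
delta,

    S = sum_j delta_j * (x_j - median_j) / IQR_j,

and a protein is classified soluble iff S > 0 (the boundary S = 0 goes to
insoluble). No optimization of any kind: medians/IQRs are empirical pooled
summaries and the weights are the effect sizes themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .univariate import UnivariateResult, roc_auc


@dataclass
class CompositeModel:
    features: tuple[str, ...]
    weights: np.ndarray
    medians: np.ndarray
    iqrs: np.ndarray

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        self.weights = np.asarray(self.weights, dtype=float)
        self.medians = np.asarray(self.medians, dtype=float)
        self.iqrs = np.asarray(self.iqrs, dtype=float)
        k = len(self.features)
        if not (self.weights.shape == self.medians.shape == self.iqrs.shape == (k,)):
            raise ValueError("features, weights, medians and iqrs must align")
        if (self.iqrs <= 0).any():
            bad = self.features[int(np.argmax(self.iqrs <= 0))]
            raise ValueError(f"feature {bad!r} has non-positive IQR (degenerate)")
        if (np.abs(self.weights) > 1).any():
            raise ValueError("delta weights must lie in [-1, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": list(self.features),
            "weights": self.weights.tolist(),
            "medians": self.medians.tolist(),
            "iqrs": self.iqrs.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CompositeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            features=tuple(d["features"]),
            weights=np.array(d["weights"]),
            medians=np.array(d["medians"]),
            iqrs=np.array(d["iqrs"]),
        )


@dataclass
class ClassificationMetrics:
    threshold: float
    auc: float
    accuracy: float
    f1: float
    mcc: float
    precision: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "auc": self.auc,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def to_dataframe(self) -> pd.DataFrame:
        d = self.to_dict()
        return pd.DataFrame(
            [
                {
                    "T": d["threshold"],
                    "AUC": d["auc"],
                    "Acc.": d["accuracy"],
                    "F1": d["f1"],
                    "MCC": d["mcc"],
                    "Prec.": d["precision"],
                    "Sens.": d["sensitivity"],
                    "Spec.": d["specificity"],
                }
            ]
        )


def robust_scale(x, median: float, iqr: float):
    """(x - median) / IQR; IQR must be positive."""
    if iqr <= 0:
        raise ValueError("IQR must be positive for robust scaling")
    return (np.asarray(x, dtype=float) - median) / iqr


def fit_composite(
    matrix: FeatureMatrix,
    results: Sequence[UnivariateResult],
    retained_features: Sequence[str],
) -> CompositeModel:
    """Assemble the index: pooled medians/IQRs + delta weights, no fitting."""
    by_name = {r.feature_name: r for r in results}
    feats, weights, medians, iqrs = [], [], [], []
    for name in retained_features:
        if name not in by_name:
            raise ValueError(f"retained feature {name!r} missing from results")
        col = matrix.column(name)
        q1, med, q3 = np.percentile(col, [25, 50, 75])
        feats.append(name)
        weights.append(by_name[name].delta)
        medians.append(float(med))
        iqrs.append(float(q3 - q1))
    return CompositeModel(
        features=tuple(feats),
        weights=np.array(weights),
        medians=np.array(medians),
        iqrs=np.array(iqrs),
    )


def composite_score(model: CompositeModel, matrix_or_values) -> np.ndarray:
    """S for each row: delta-weighted sum of robust-scaled features.

    Accepts a FeatureMatrix or a plain (n, k) array in model feature order;
    a single feature vector (k,) yields a scalar array of shape ().
    """
    if isinstance(matrix_or_values, FeatureMatrix):
        X = np.column_stack([matrix_or_values.column(f) for f in model.features])
    else:
        X = np.asarray(matrix_or_values, dtype=float)
    scaled = (X - model.medians) / model.iqrs
    return scaled @ model.weights


def classify(scores) -> np.ndarray:
    """1 (soluble) iff S > 0; 0 (insoluble) for S <= 0."""
    return (np.asarray(scores, dtype=float) > 0).astype(int)


def evaluate(scores, labels, threshold: float = 0.0) -> ClassificationMetrics:
    """Confusion-matrix metrics at S > threshold, soluble as positive class.

    MCC uses the standard product formula with the 0-by-convention rule when
    any marginal is empty; AUC is the tie-aware rank AUC of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / sqrt(denom) if denom else 0.0
    auc = roc_auc(scores, labels)
    return ClassificationMetrics(
        threshold=float(threshold),
        auc=float(auc),
        accuracy=float(accuracy),
        f1=float(f1),
        mcc=float(mcc),
        precision=float(precision),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
    )
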