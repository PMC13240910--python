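"""Redundancy analysis: Spearman correlations, clustering, representatives.

Feature pairs with |rho| >= threshold (default 0.85) are treated as proxies
of one latent physicochemical axis. Clusters are the connected components of
the thresholded correlation graph — deterministic and parameter-free — and a
single representative per cluster is retained: a preference-listed feature
if the cluster contains one (default preference: sequence length, for its
direct structural interpretability), otherwise the member with the largest
|delta|, ties broken by feature-name order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

DEFAULT_RHO_THRESHOLD = 0.85


@dataclass
class RedundancyReport:
    feature_names: tuple[str, ...]
    rho: np.ndarray
    threshold: float
    clusters: list[list[str]]
    retained: list[str]

    def rho_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rho, index=list(self.feature_names), columns=list(self.feature_names)
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold": self.threshold,
            "clusters": self.clusters,
            "retained": self.retained,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def spearman_matrix(matrix, features: Sequence[str]) -> np.ndarray:
    """Tie-aware (average-rank) Spearman rho for each feature pair."""
    features = list(features)
    if len(features) < 2:
        raise ValueError("need at least two features")
    data = np.column_stack([matrix.column(f) for f in features])
    rho = stats.spearmanr(data).statistic
    if np.ndim(rho) == 0:  # scipy collapses the two-column case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    # constant columns yield NaN correlations; they share no monotone signal
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def cluster_redundant(
    rho: np.ndarray,
    feature_names: Sequence[str],
    threshold: float = DEFAULT_RHO_THRESHOLD,
) -> list[list[str]]:
    """Connected components of the graph with edges |rho_ij| >= threshold."""
    rho = np.asarray(rho, dtype=float)
    adj = (np.abs(rho) >= threshold).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for name, comp in zip(feature_names, labels):
        clusters[comp].append(name)
    for c in clusters:
        c.sort()
    # deterministic cluster order: by first member
    clusters.sort(key=lambda c: c[0])
    return clusters


def select_representatives(
    clusters: Sequence[Sequence[str]],
    delta_by_feature: Mapping[str, float],
    preference: Sequence[str] = ("length",),
) -> list[str]:
    """One retained feature per cluster (preferred feature, else max |delta|)."""
    retained = []
    for cluster in clusters:
        pick = None
        for pref in preference:
            if pref in cluster:
                pick = pref
                break
        if pick is None:
            pick = max(sorted(cluster), key=lambda f: abs(delta_by_feature.get(f, 0.0)))
        retained.append(pick)
    return retained


def build_report(
    matrix,
    features: Sequence[str],
    delta_by_feature: Mapping[str, float],
    threshold: float = DEFAULT_RHO_THRESHOLD,
    preference: Sequence[str] = ("length",),
) -> RedundancyReport:
    features = tuple(features)
    rho = spearman_matrix(matrix, features)
    clusters = cluster_redundant(rho, features, threshold)
    retained = select_representatives(clusters, delta_by_feature, preference)
    return RedundancyReport(
        feature_names=features,
        rho=rho,
        threshold=threshold,
        clusters=clusters,
        retained=retained,
    )
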