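"""Rank-based two-group statistics: one full report row per feature.

For each descriptor, soluble (group 1 / positive class) vs insoluble
(group 2) is summarized by:

* per-class median and quartiles (linear-interpolation sample quantiles);
* Mann-Whitney U and two-sided p, Benjamini-Hochberg q across features;
* Cliff's delta = P(X>Y) - P(X<Y), with percentile-bootstrap CI (B=2,000);
* Hodges-Lehmann shift (median of all pairwise differences, computed by
  k-th-element selection without materializing the n1*n2 pairs) with a
  distribution-free CI from inversion of the rank-sum statistic;
* tie-aware ROC AUC, which satisfies AUC = (delta+1)/2 exactly;
* Youden's J maximized over all observed thresholds in both decision
  orientations, with the achieving threshold T*.

U, delta and AUC all derive from one shared rank computation, so the
delta/AUC identity holds to machine precision by construction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, fields as dataclass_fields
from math import floor, nan, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix

_Z_975 = float(stats.norm.ppf(0.975))


@dataclass
class StatsConfig:
    """Knobs for the univariate stage.

    bootstrap_B: resamples for the delta CI; 0 disables it (CI = NaN).
    ci_level: two-sided confidence level for delta and HL intervals.
    seed: pipeline-level seed; per-feature substreams are derived from the
        feature name so results do not depend on feature order.
    """

    bootstrap_B: int = 2000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_B != 0 and self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be 0 or >= 100")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class UnivariateResult:
    """One report row for one feature (soluble vs insoluble)."""

    feature_name: str
    n_soluble: int
    n_insoluble: int
    soluble_median: float
    soluble_q1: float
    soluble_q3: float
    insoluble_median: float
    insoluble_q1: float
    insoluble_q3: float
    hl_shift: float
    hl_ci_low: float
    hl_ci_high: float
    delta: float
    delta_ci_low: float
    delta_ci_high: float
    p_value: float
    q_value: float
    auc: float
    youden_j: float
    threshold: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


def _rank_u(x: np.ndarray, y: np.ndarray) -> float:
    """U = #(x_i > y_j) + 0.5 #(x_i = y_j) via midranks (O(n log n))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = x.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (ties counted half) and two-sided p.

    Exact p when n1+n2 <= 50 and there are no ties; otherwise normal
    approximation with tie-corrected variance and continuity correction.
    Both groups jointly constant -> p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u = _rank_u(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return u, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return u, float(res.pvalue)


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """delta = P(x>y) - P(x<y) = 2U/(n1 n2) - 1, via joint ranking."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    return 2.0 * _rank_u(x, y) / (x.size * y.size) - 1.0


def roc_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Tie-aware rank AUC with the positive class marked by labels == 1.

    Not orientation-corrected: a feature lower in positives reports AUC < 0.5.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels != 1]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative")
    return _rank_u(pos, neg) / (pos.size * neg.size)


def feature_seed(base_seed: int, feature_name: str) -> np.random.SeedSequence:
    """Deterministic per-feature substream independent of feature order."""
    return np.random.SeedSequence([int(base_seed), zlib.crc32(feature_name.encode())])


def bootstrap_delta_ci(
    x: np.ndarray,
    y: np.ndarray,
    B: int = 2000,
    seed: int | np.random.SeedSequence = 0,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Percentile-bootstrap CI for Cliff's delta (within-group resampling)."""
    if B < 100:
        raise ValueError("B must be >= 100")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    boots = np.empty(B)
    for b in range(B):
        xb = x[rng.integers(0, x.size, x.size)]
        yb = y[rng.integers(0, y.size, y.size)]
        boots[b] = cliffs_delta(xb, yb)
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _count_diffs_le(xs: np.ndarray, ys: np.ndarray, t: float) -> int:
    """#{(i,j): x_i - y_j <= t} for sorted xs, ys, in O(n log n)."""
    pos = np.searchsorted(ys, xs - t, side="left")
    return int((ys.size - pos).sum())


def kth_pairwise_difference(xs: np.ndarray, ys: np.ndarray, k: int) -> float:
    """k-th smallest (1-based) of the n1*n2 differences x_i - y_j.

    Binary search over the value range with rank counting; each step snaps
    the bracket to realized difference values, so the pair set is never
    materialized.
    """
    xs = np.sort(np.asarray(xs, dtype=float))
    ys = np.sort(np.asarray(ys, dtype=float))
    total = xs.size * ys.size
    if not 1 <= k <= total:
        raise ValueError(f"k must be in [1, {total}], got {k}")
    lo = xs[0] - ys[-1]
    hi = xs[-1] - ys[0]
    while lo < hi:
        mid = 0.5 * (lo + hi)
        if not lo < mid < hi:  # bracket exhausted at float resolution
            break
        pos = np.searchsorted(ys, xs - mid, side="left")
        count = int((ys.size - pos).sum())
        # Snap the bracket to realized difference values when that makes
        # progress; otherwise fall back to mid so the interval always halves
        # (float rounding can put the snapped value on the wrong side).
        if count >= k:
            valid = pos < ys.size
            cand = float((xs[valid] - ys[pos[valid]]).max())
            hi = cand if lo <= cand < hi else mid
        else:
            valid = pos > 0
            cand = float((xs[valid] - ys[pos[valid] - 1]).min())
            lo = cand if lo < cand <= hi else mid
    if lo < hi:
        return lo if _count_diffs_le(xs, ys, lo) >= k else hi
    return lo


def hodges_lehmann(
    x: np.ndarray, y: np.ndarray, ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Hodges-Lehmann shift estimate with rank-inversion confidence interval.

    Shift = median of all pairwise differences x_i - y_j (selection, not
    enumeration). The CI is the classical distribution-free interval obtained
    by inverting the rank-sum test with the large-sample critical value:
    k = floor(n1 n2 / 2 - z * sqrt(n1 n2 (n1+n2+1)/12)), bounds at the
    (k+1)-th smallest and (N-k)-th smallest difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    total = n1 * n2
    if total % 2 == 1:
        shift = kth_pairwise_difference(x, y, (total + 1) // 2)
    else:
        a = kth_pairwise_difference(x, y, total // 2)
        b = kth_pairwise_difference(x, y, total // 2 + 1)
        shift = 0.5 * (a + b)
    z = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    sigma = sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    k = floor(total / 2.0 - z * sigma)
    k = max(k, 0)
    low = kth_pairwise_difference(x, y, min(k + 1, total))
    high = kth_pairwise_difference(x, y, max(total - k, 1))
    return float(shift), float(low), float(high)


def youden_optimal(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(J, T*): max sensitivity+specificity-1 over all observed thresholds.

    Both orientations are scanned (predict positive if value >= T and if
    value <= T), because a feature may separate classes in either direction.
    On ties, the smallest achieving threshold is returned.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = np.sort(values[labels == 1])
    neg = np.sort(values[labels != 1])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative")
    ts = np.unique(values)
    if ts.size == 1:
        return 0.0, float(ts[0])
    # predict positive if value >= t
    sens_ge = 1.0 - np.searchsorted(pos, ts, side="left") / pos.size
    spec_ge = np.searchsorted(neg, ts, side="left") / neg.size
    j_ge = sens_ge + spec_ge - 1.0
    # predict positive if value <= t
    sens_le = np.searchsorted(pos, ts, side="right") / pos.size
    spec_le = 1.0 - np.searchsorted(neg, ts, side="right") / neg.size
    j_le = sens_le + spec_le - 1.0
    j_all = np.concatenate([j_ge, j_le])
    t_all = np.concatenate([ts, ts])
    best = float(j_all.max())
    achieving = t_all[j_all >= best - 1e-12]
    return max(best, 0.0), float(achieving.min())


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _quartiles(v: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


def analyze_feature(
    matrix: FeatureMatrix,
    feature_name: str,
    config: StatsConfig | None = None,
    q_value: float = nan,
) -> UnivariateResult:
    """Full report row for one feature (q filled by :func:`analyze_all`)."""
    config = config or StatsConfig()
    x, y = matrix.class_values(feature_name)
    if x.size == 0 or y.size == 0:
        raise ValueError("matrix must contain both soluble and insoluble records")
    med1, q1_1, q3_1 = _quartiles(x)
    med2, q1_2, q3_2 = _quartiles(y)
    u, p = mann_whitney(x, y)
    delta = cliffs_delta(x, y)
    if config.bootstrap_B:
        d_lo, d_hi = bootstrap_delta_ci(
            x, y, config.bootstrap_B, feature_seed(config.seed, feature_name),
            config.ci_level,
        )
    else:
        d_lo = d_hi = nan
    shift, h_lo, h_hi = hodges_lehmann(x, y, config.ci_level)
    values = np.concatenate([x, y])
    labels = np.concatenate([np.ones(x.size, dtype=int), np.zeros(y.size, dtype=int)])
    auc = roc_auc(values, labels)
    j, t_star = youden_optimal(values, labels)
    return UnivariateResult(
        feature_name=feature_name,
        n_soluble=int(x.size),
        n_insoluble=int(y.size),
        soluble_median=med1,
        soluble_q1=q1_1,
        soluble_q3=q3_1,
        insoluble_median=med2,
        insoluble_q1=q1_2,
        insoluble_q3=q3_2,
        hl_shift=shift,
        hl_ci_low=h_lo,
        hl_ci_high=h_hi,
        delta=delta,
        delta_ci_low=d_lo,
        delta_ci_high=d_hi,
        p_value=p,
        q_value=q_value,
        auc=auc,
        youden_j=j,
        threshold=t_star,
    )


def analyze_all(
    matrix: FeatureMatrix, config: StatsConfig | None = None
) -> list[UnivariateResult]:
    """One result per feature with BH adjustment applied jointly across all."""
    config = config or StatsConfig()
    results = [analyze_feature(matrix, name, config) for name in matrix.feature_names]
    q = bh_fdr(np.array([r.p_value for r in results]))
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def results_to_dataframe(results: list[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def format_results_table(results: list[UnivariateResult]) -> pd.DataFrame:
    """Human-readable report: median [Q1, Q3] per class, HL [CI], delta [CI],
    q, AUC, J, T* — one row per feature, sorted by |delta| descending."""
    rows = []
    for r in sorted(results, key=lambda r: -abs(r.delta)):
        rows.append(
            {
                "Feature": r.feature_name,
                "Soluble (median [Q1,Q3])": f"{r.soluble_median:.5g} [{r.soluble_q1:.5g}, {r.soluble_q3:.5g}]",
                "Insoluble (median [Q1,Q3])": f"{r.insoluble_median:.5g} [{r.insoluble_q1:.5g}, {r.insoluble_q3:.5g}]",
                "HL [95% CI]": f"{r.hl_shift:.4g} [{r.hl_ci_low:.4g}, {r.hl_ci_high:.4g}]",
                "delta [95% CI]": f"{r.delta:.3f} [{r.delta_ci_low:.3f}, {r.delta_ci_high:.3f}]",
                "FDR q": f"{r.q_value:.3g}",
                "AUC": f"{r.auc:.3f}",
                "J": f"{r.youden_j:.3f}",
                "T*": f"{r.threshold:.5g}",
            }
        )
    return pd.DataFrame(rows)
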