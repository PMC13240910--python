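import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import soldissect as sd
from soldissect.features import FeatureMatrix, FEATURE_NAMES
from soldissect.univariate import (
    StatsConfig,
    analyze_all,
    analyze_feature,
    bh_fdr,
    bootstrap_delta_ci,
    cliffs_delta,
    hodges_lehmann,
    kth_pairwise_difference,
    mann_whitney,
    roc_auc,
    youden_optimal,
)

# ---------------------------------------------------------------- oracles


def brute_u(x, y):
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u


def brute_delta(x, y):
    gt = sum(xi > yj for xi in x for yj in y)
    lt = sum(xi < yj for xi in x for yj in y)
    return (gt - lt) / (len(x) * len(y))


def brute_hl(x, y):
    return float(np.median([xi - yj for xi in x for yj in y]))


def brute_youden(values, labels):
    pos = values[labels == 1]
    neg = values[labels != 1]
    best_j, best_t = -np.inf, None
    for t in sorted(set(values)):
        for orient in ("ge", "le"):
            if orient == "ge":
                sens = np.mean(pos >= t)
                spec = np.mean(neg < t)
            else:
                sens = np.mean(pos <= t)
                spec = np.mean(neg > t)
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, t
            elif abs(j - best_j) <= 1e-12 and t < best_t:
                best_t = t
    return max(best_j, 0.0), best_t


group = st.lists(
    st.integers(min_value=-20, max_value=20).map(float), min_size=1, max_size=30
)

# ---------------------------------------------------------------- tests


class TestMannWhitney:
    def test_fully_separated_exact_p(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/C(6,3) * 2-sided enumeration

    def test_identical_multisets(self):
        x = [1.0, 2.0, 5.0]
        u, p = mann_whitney(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == 1.0

    def test_half_tie_counting(self):
        u, _ = mann_whitney([1, 2], [1, 3])
        assert u == 1.5

    def test_jointly_constant_groups(self):
        u, p = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    @given(group, group)
    def test_u_equals_pair_count_oracle(self, x, y):
        u, _ = mann_whitney(x, y)
        assert u == pytest.approx(brute_u(x, y), abs=1e-9)


class TestCliffsDelta:
    def test_complete_dominance(self):
        assert cliffs_delta([5, 6], [1, 2]) == 1.0

    def test_identical_constants(self):
        assert cliffs_delta([3, 3], [3, 3, 3]) == 0.0

    def test_small_tie_example(self):
        assert cliffs_delta([1, 2], [1, 3]) == pytest.approx(-0.25)

    @given(group, group)
    def test_matches_brute_force(self, x, y):
        assert cliffs_delta(x, y) == pytest.approx(brute_delta(x, y), abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        v = np.array([0.1, 0.2, 0.8, 0.9])
        lab = np.array([0, 0, 1, 1])
        assert roc_auc(v, lab) == 1.0

    def test_constant_values_give_half(self):
        v = np.ones(10)
        lab = np.array([0, 1] * 5)
        assert roc_auc(v, lab) == 0.5

    def test_matches_sklearn_with_ties(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            v = rng.integers(0, 6, size=40).astype(float)
            lab = rng.integers(0, 2, size=40)
            if lab.min() == lab.max():
                continue
            assert roc_auc(v, lab) == pytest.approx(roc_auc_score(lab, v), abs=1e-12)

    def test_auc_delta_identity(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 40))
            y = rng.normal(size=rng.integers(2, 40))
            v = np.concatenate([x, y])
            lab = np.concatenate([np.ones(x.size, int), np.zeros(y.size, int)])
            assert abs(roc_auc(v, lab) - (cliffs_delta(x, y) + 1) / 2) <= 1e-12


class TestBootstrap:
    def test_degenerate_no_overlap(self):
        lo, hi = bootstrap_delta_ci([10.0] * 5, [1.0] * 5, B=200, seed=0)
        assert lo == 1.0 and hi == 1.0

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert bootstrap_delta_ci(x, y, B=300, seed=42) == bootstrap_delta_ci(
            x, y, B=300, seed=42
        )

    def test_brackets_point_estimate_on_shifted_data(self, rng):
        x = rng.normal(1.0, 1, size=80)
        y = rng.normal(0.0, 1, size=80)
        lo, hi = bootstrap_delta_ci(x, y, B=500, seed=1)
        assert lo <= cliffs_delta(x, y) <= hi


class TestHodgesLehmann:
    def test_unit_shift(self):
        shift, _, _ = hodges_lehmann([1, 2, 3], [0, 1, 2])
        assert shift == 1.0

    def test_translation_equivariance(self, rng):
        x = rng.normal(size=25)
        c = 3.7
        shift, _, _ = hodges_lehmann(x, x + c)
        assert shift == pytest.approx(-c, abs=1e-9)

    @given(group, group)
    def test_selection_equals_brute_force_median(self, x, y):
        shift, _, _ = hodges_lehmann(x, y)
        assert shift == pytest.approx(brute_hl(x, y), abs=1e-9)

    @given(group, group, st.integers(min_value=1, max_value=900))
    def test_kth_selection_oracle(self, x, y, kraw):
        k = 1 + (kraw - 1) % (len(x) * len(y))
        diffs = np.sort([xi - yj for xi in x for yj in y])
        assert kth_pairwise_difference(x, y, k) == pytest.approx(
            diffs[k - 1], abs=1e-9
        )

    def test_ci_brackets_shift_and_orders(self, rng):
        x = rng.normal(0.5, 1, size=60)
        y = rng.normal(0.0, 1, size=50)
        shift, lo, hi = hodges_lehmann(x, y)
        assert lo <= shift <= hi


class TestYouden:
    def test_perfect_separation(self):
        v = np.array([1, 2, 8, 9.0])
        lab = np.array([0, 0, 1, 1])
        j, t = youden_optimal(v, lab)
        assert j == 1.0 and t == 8

    def test_identical_distributions(self):
        v = np.array([1.0, 2, 3, 1, 2, 3])
        lab = np.array([1, 1, 1, 0, 0, 0])
        j, _ = youden_optimal(v, lab)
        assert j == 0.0

    def test_single_distinct_value(self):
        j, t = youden_optimal(np.ones(6), np.array([0, 1, 0, 1, 0, 1]))
        assert j == 0.0 and t == 1.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(40):
            v = rng.integers(0, 8, size=rng.integers(6, 25)).astype(float)
            lab = rng.integers(0, 2, size=v.size)
            if lab.min() == lab.max():
                continue
            j, t = youden_optimal(v, lab)
            oj, ot = brute_youden(v, lab)
            assert j == pytest.approx(oj, abs=1e-12)
            assert t == ot


class TestBhFdr:
    def test_hand_stepped_example(self):
        q = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_passthrough(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=36)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_sm, atol=1e-12)

    def test_monotone_vs_input(self, rng):
        p = rng.uniform(size=20)
        assert (bh_fdr(p) >= p - 1e-15).all()


def make_matrix(rng, n_per_class=60, shift_feature=None, shift=0.0):
    n = 2 * n_per_class
    values = rng.normal(size=(n, len(FEATURE_NAMES)))
    labels = np.array(["soluble"] * n_per_class + ["insoluble"] * n_per_class, dtype=object)
    if shift_feature is not None:
        j = FEATURE_NAMES.index(shift_feature)
        values[:n_per_class, j] += shift
    return FeatureMatrix(
        ids=[f"r{i}" for i in range(n)], labels=labels, values=values
    )


class TestAnalyze:
    def test_identical_classes_give_zero_delta(self, rng):
        half = rng.normal(size=(40, len(FEATURE_NAMES)))
        values = np.vstack([half, half])
        labels = np.array(["soluble"] * 40 + ["insoluble"] * 40, dtype=object)
        m = FeatureMatrix(ids=[f"r{i}" for i in range(80)], labels=labels, values=values)
        results = analyze_all(m, StatsConfig(bootstrap_B=0))
        for r in results:
            assert r.delta == 0.0
            assert r.q_value > 0.5

    def test_injected_shift_has_smallest_q(self, rng):
        m = make_matrix(rng, shift_feature="neg_ratio", shift=1.0)
        results = analyze_all(m, StatsConfig(bootstrap_B=0))
        best = min(results, key=lambda r: (r.q_value, -abs(r.delta)))
        assert best.feature_name == "neg_ratio"

    def test_row_permutation_invariance(self, rng):
        m = make_matrix(rng, shift_feature="length", shift=0.5)
        perm = rng.permutation(len(m.ids))
        m2 = FeatureMatrix(
            ids=[m.ids[i] for i in perm], labels=m.labels[perm], values=m.values[perm]
        )
        cfg = StatsConfig(bootstrap_B=0, seed=3)
        r1 = analyze_all(m, cfg)
        r2 = analyze_all(m2, cfg)
        for a, b in zip(r1, r2):
            assert a.to_dict() == b.to_dict()

    def test_result_invariants(self, rng):
        m = make_matrix(rng, shift_feature="freq_E", shift=0.8)
        results = analyze_all(m, StatsConfig(bootstrap_B=150, seed=5))
        for r in results:
            assert abs(r.auc - (r.delta + 1) / 2) <= 1e-12
            assert r.delta_ci_low <= r.delta <= r.delta_ci_high
            assert r.q_value >= r.p_value - 1e-15
            assert r.youden_j >= 0
            assert r.hl_ci_low <= r.hl_shift <= r.hl_ci_high

    def test_unknown_feature_is_error(self, rng):
        m = make_matrix(rng)
        with pytest.raises(KeyError):
            analyze_feature(m, "not_a_feature", StatsConfig(bootstrap_B=0))
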