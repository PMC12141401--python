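"""AUROC, DeLong comparison, NRI/IDI, and cutpoint search."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from frailtyfalls.discrimination import (
    auc,
    continuous_nri,
    delong_compare,
    idi,
    optimal_cutoff,
    reclassification,
)
from frailtyfalls.errors import DataError


def auc_brute(scores, labels):
    """Independent oracle: enumerate all (event, non-event) pairs with 0.5
    credit for ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ((1, 2, 3, 4), (0, 0, 1, 1), 1.0),
            ((1, 3, 2, 4), (0, 0, 1, 1), 0.75),
            ((5, 5, 5, 5), (0, 1, 0, 1), 0.5),
            ((9, 8, 1, 2), (1, 1, 0, 0), 1.0),
        ],
    )
    def test_small_cases_match_enumeration(self, scores, labels, expected):
        result = auc(scores, labels)
        assert result.auc == pytest.approx(expected, abs=1e-15)
        assert result.auc == pytest.approx(auc_brute(scores, labels), abs=1e-15)

    @given(
        st.lists(st.integers(min_value=0, max_value=5), min_size=2, max_size=12).filter(
            lambda v: len(v) >= 2
        ),
        st.data(),
    )
    def test_pair_count_equals_trapezoid_and_brute_force(self, values, data):
        n = len(values)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < n
            )
        )
        scores = np.array(values, dtype=float)
        result = auc(scores, labels)
        assert result.auc == pytest.approx(auc_brute(scores, labels), abs=1e-12)
        trap = np.trapezoid(result.curve[1], result.curve[0])
        assert result.auc == pytest.approx(trap, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=200)
        y = (rng.random(200) < 0.3).astype(int)
        base = auc(s, y).auc
        assert auc(np.exp(s), y).auc == pytest.approx(base, abs=1e-15)
        assert auc(3 * s - 7, y).auc == pytest.approx(base, abs=1e-15)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            auc([1.0, 2.0], [1, 1])


class TestDelong:
    def test_identical_scores_degenerate(self):
        y = [0, 1, 0, 1, 1, 0]
        s = [0.1, 0.8, 0.3, 0.7, 0.9, 0.2]
        cmp_ = delong_compare(s, s, y)
        assert cmp_.delta == 0.0
        assert cmp_.p == 1.0
        assert cmp_.degenerate

    def test_monotone_transform_gives_zero_delta(self):
        rng = np.random.default_rng(11)
        s = rng.normal(size=100)
        y = (rng.random(100) < 0.4).astype(int)
        cmp_ = delong_compare(s, np.exp(s), y)
        assert cmp_.delta == pytest.approx(0.0, abs=1e-15)
        assert cmp_.degenerate  # rank-identical scores share placements

    def test_matches_proc_reference_values(self):
        """Frozen oracle: pROC roc.test(method='delong') on this fixture."""
        rng = np.random.default_rng(20240915)
        n = 60
        y = (rng.random(n) < 0.4).astype(int)
        a = y * 0.8 + rng.normal(size=n)
        b = y * 0.5 + 0.5 * a + rng.normal(size=n)
        cmp_ = delong_compare(a, b, y)
        assert cmp_.auc_a == pytest.approx(0.653198653198653, abs=1e-12)
        assert cmp_.auc_b == pytest.approx(0.676767676767677, abs=1e-12)
        assert cmp_.cov[0, 0] == pytest.approx(0.005024688596518, abs=1e-12)
        assert cmp_.cov[1, 1] == pytest.approx(0.004845717528097, abs=1e-12)
        assert abs(cmp_.z) == pytest.approx(0.312365464645344, abs=1e-10)
        assert cmp_.p == pytest.approx(0.754762793406061, abs=1e-10)

    def test_variance_agrees_with_bootstrap(self):
        """DeLong SE of a single AUC vs a 20 000-rep bootstrap on 30 subjects."""
        rng = np.random.default_rng(13)
        n = 30
        y = np.r_[np.ones(12), np.zeros(18)].astype(int)
        s = y * 1.0 + rng.normal(size=n)
        se_delong = auc(s, y).se

        def auc_rank(sb, yb):  # same tie-credit statistic, curve-free
            from scipy.stats import rankdata

            r = rankdata(sb)
            m = yb.sum()
            return (r[yb == 1].sum() - m * (m + 1) / 2) / (m * (len(yb) - m))

        reps = []
        for _ in range(20_000):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            reps.append(auc_rank(s[idx], yb))
        se_boot = np.std(reps, ddof=1)
        assert se_delong == pytest.approx(se_boot, rel=0.15)


class TestReclassification:
    def test_self_comparison_is_zero(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([0, 1, 0, 1])
        assert continuous_nri(p, p, y).nri == 0.0
        assert idi(p, p, y).idi == 0.0

    def test_nri_enumeration_oracle(self):
        """4 events (3 up, 1 down), 6 non-events (4 down, 2 up):
        (3-1)/4 + (4-2)/6 = 5/6."""
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        p_old = np.full(10, 0.5)
        p_new = np.array([0.6, 0.7, 0.8, 0.4, 0.3, 0.2, 0.1, 0.4, 0.6, 0.7])
        res = continuous_nri(p_old, p_new, y)
        assert res.nri == pytest.approx(2 / 4 + 2 / 6, abs=1e-12)
        assert res.nri_events == pytest.approx(0.5, abs=1e-12)
        assert res.nri_nonevents == pytest.approx(1 / 3, abs=1e-12)
        assert res.nri == res.nri_events + res.nri_nonevents

    def test_nri_bound_attained(self):
        y = np.array([1, 1, 0, 0])
        p_old = np.array([0.5, 0.5, 0.5, 0.5])
        p_new = np.array([0.9, 0.8, 0.1, 0.2])
        assert continuous_nri(p_old, p_new, y).nri == pytest.approx(2.0)

    def test_ties_count_for_neither_direction(self):
        y = np.array([1, 1, 0, 0])
        p_old = np.array([0.2, 0.3, 0.2, 0.3])
        p_new = np.array([0.2, 0.5, 0.2, 0.1])  # one tie per class
        res = continuous_nri(p_old, p_new, y)
        assert res.nri_events == pytest.approx(0.5)
        assert res.nri_nonevents == pytest.approx(0.5)

    def test_idi_hand_arithmetic(self):
        """Events: 0.2->0.3, 0.4->0.5; non-events 0.3->0.2, 0.1->0.1:
        IDI = 0.1 - (-0.05) = 0.15."""
        y = np.array([1, 1, 0, 0])
        p_old = np.array([0.2, 0.4, 0.3, 0.1])
        p_new = np.array([0.3, 0.5, 0.2, 0.1])
        assert idi(p_old, p_new, y).idi == pytest.approx(0.15, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_nri_idi_ranges(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        y = np.r_[np.ones(10), np.zeros(20)].astype(int)
        p_old, p_new = rng.random(n), rng.random(n)
        res = reclassification(p_old, p_new, y)
        assert -2.0 <= res.nri.nri <= 2.0
        assert -1.0 <= res.idi.idi <= 1.0
        assert res.nri.nri == res.nri.nri_events + res.nri.nri_nonevents

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            continuous_nri([0.1], [0.1, 0.2], [0, 1])

    def test_bootstrap_ci_available(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.ones(30), np.zeros(70)].astype(int)
        p_old = rng.random(100)
        p_new = np.clip(p_old + 0.15 * y + rng.normal(0, 0.1, 100), 0, 1)
        res = continuous_nri(p_old, p_new, y, bootstrap=200, seed=1)
        assert res.ci[0] <= res.nri <= res.ci[1]
        assert res.ci[1] - res.ci[0] > 0


class TestOptimalCutoff:
    def cutoff_brute(self, scores, labels):
        scores, labels = np.asarray(scores, float), np.asarray(labels, int)
        uniq = np.unique(scores)
        best = (None, -np.inf)
        for c in (uniq[:-1] + uniq[1:]) / 2:
            sens = ((scores > c) & (labels == 1)).sum() / (labels == 1).sum()
            spec = ((scores <= c) & (labels == 0)).sum() / (labels == 0).sum()
            j = sens + spec - 1
            if j > best[1]:
                best = (c, j)
        return best

    def test_ten_subject_fixture_matches_exhaustive_scan(self):
        scores = [0.1, 0.15, 0.2, 0.3, 0.32, 0.35, 0.4, 0.45, 0.5, 0.6]
        labels = [0, 0, 0, 0, 1, 0, 1, 0, 1, 1]
        res = optimal_cutoff(scores, labels)
        c, j = self.cutoff_brute(scores, labels)
        assert res.cutoff == pytest.approx(c)
        assert res.youden == pytest.approx(j)

    def test_perfect_separation_midpoint(self):
        res = optimal_cutoff([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.cutoff == pytest.approx(6.5)
        assert res.youden == pytest.approx(1.0)

    def test_all_tied_scores(self):
        res = optimal_cutoff([2, 2, 2, 2], [0, 1, 0, 1])
        assert res.youden == 0.0

    def test_tie_breaks_toward_lower_cutoff(self):
        # cutoffs 1.5 and 2.5 both give J = 0.5; the lower wins
        res = optimal_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        brute_c, brute_j = self.cutoff_brute([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.youden == pytest.approx(1.0)
        assert res.cutoff == pytest.approx(brute_c)
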