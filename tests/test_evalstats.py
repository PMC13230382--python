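import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spsct.evalstats import (
    CaseClassification,
    ReaderRecord,
    classify_case,
    confusion_summary,
    delong_auc,
    delong_test,
    dice,
    dose_fraction,
    effective_dose,
    shapiro_wilk,
    wilcoxon_signed_rank,
)


def _mask(shape, coords):
    m = np.zeros(shape, dtype=bool)
    for c in coords:
        m[c] = True
    return m


class TestDice:
    def test_identical_nonempty(self):
        m = _mask((8, 8), [(1, 1), (2, 2)])
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = _mask((8, 8), [(0, 0)])
        b = _mask((8, 8), [(5, 5)])
        assert dice(a, b) == 0.0

    def test_partial_overlap_formula(self):
        a = _mask((8, 8), [(0, 0), (0, 1), (0, 2), (0, 3)])
        b = _mask((8, 8), [(0, 1), (0, 2), (0, 3), (1, 0), (1, 1), (1, 2)])
        assert dice(a, b) == pytest.approx(0.6)

    def test_both_empty_is_agreement(self):
        z = np.zeros((4, 4), dtype=bool)
        assert dice(z, z) == 1.0

    def test_one_empty_is_zero(self):
        z = np.zeros((4, 4), dtype=bool)
        assert dice(z, _mask((4, 4), [(0, 0)])) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4)), np.zeros((5, 5)))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6)) > 0.6
        b = rng.random((6, 6)) > 0.6
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0


class TestClassifyCase:
    shape = (8, 8)

    def _gold(self, positive):
        return _mask(self.shape, [(3, 3), (3, 4)]) if positive else np.zeros(
            self.shape, dtype=bool
        )

    def _rec(self, positive, quality, seg):
        return ReaderRecord(
            case_id="c", truth_positive=positive, quality=quality,
            confidence=2, artifacts=2, segmentation=seg,
        )

    def test_non_diagnostic_positive_is_fn(self):
        seg = _mask(self.shape, [(3, 3)])
        out = classify_case(self._rec(True, 0, seg), self._gold(True))
        assert out.outcome == "FN" and out.non_diagnostic

    def test_non_diagnostic_negative_is_fp(self):
        out = classify_case(self._rec(False, 0, None), self._gold(False))
        assert out.outcome == "FP" and out.non_diagnostic

    def test_overlapping_segmentation_is_tp(self):
        seg = _mask(self.shape, [(3, 4), (6, 6)])
        out = classify_case(self._rec(True, 3, seg), self._gold(True))
        assert out.outcome == "TP"
        assert 0 < out.sdc < 1

    def test_extra_healthy_vessel_marked_still_tp(self):
        # embolus found plus a spurious mark elsewhere: counted as TP
        seg = self._gold(True) | _mask(self.shape, [(0, 0), (0, 1)])
        out = classify_case(self._rec(True, 4, seg), self._gold(True))
        assert out.outcome == "TP"

    def test_positive_with_non_overlapping_segmentation_is_fn(self):
        seg = _mask(self.shape, [(7, 7)])
        out = classify_case(self._rec(True, 3, seg), self._gold(True))
        assert out.outcome == "FN" and out.sdc == 0.0

    def test_positive_without_segmentation_is_fn(self):
        out = classify_case(self._rec(True, 3, None), self._gold(True))
        assert out.outcome == "FN"

    def test_negative_without_segmentation_is_tn(self):
        out = classify_case(self._rec(False, 4, None), self._gold(False))
        assert out.outcome == "TN"

    def test_negative_with_segmentation_is_fp(self):
        seg = _mask(self.shape, [(2, 2)])
        out = classify_case(self._rec(False, 4, seg), self._gold(False))
        assert out.outcome == "FP"

    def test_every_rule_combination_maps_to_one_outcome(self):
        for positive, quality, with_seg, overlap in itertools.product(
            (True, False), (0, 3), (True, False), (True, False)
        ):
            if with_seg:
                seg = self._gold(True) if overlap else _mask(self.shape, [(7, 0)])
            else:
                seg = None
            out = classify_case(
                self._rec(positive, quality, seg), self._gold(positive)
            )
            assert out.outcome in ("TP", "FP", "TN", "FN")
            if quality == 0:
                assert out.outcome == ("FN" if positive else "FP")

    def test_inconsistent_gold_rejected(self):
        with pytest.raises(ValueError):
            classify_case(self._rec(True, 3, None), self._gold(False))

    def test_scale_ranges_enforced(self):
        with pytest.raises(ValueError):
            ReaderRecord("c", True, quality=6, confidence=0, artifacts=0)
        with pytest.raises(ValueError):
            ReaderRecord("c", True, quality=3, confidence=5, artifacts=0)
        with pytest.raises(ValueError):
            ReaderRecord("c", True, quality=3, confidence=0, artifacts=4)


class TestConfusionSummary:
    def test_reported_confusion_cells_give_expected_accuracy(self):
        cls = (
            ["TP"] * 29 + ["FP"] * 2 + ["FN"] * 1 + ["TN"] * 28
        )
        s = confusion_summary(cls)
        assert s.n == 60
        assert s.accuracy == pytest.approx(57 / 60)
        assert s.sensitivity == pytest.approx(29 / 30)
        assert s.specificity == pytest.approx(28 / 30)

    def test_all_tp_specificity_undefined(self):
        s = confusion_summary(["TP"] * 5)
        assert s.sensitivity == 1.0
        assert s.specificity is None

    def test_degenerate_all_non_diagnostic_pattern(self):
        s = confusion_summary(["FN"] * 30 + ["TN"] * 30)
        assert s.sensitivity == 0.0
        assert s.specificity == 1.0

    def test_counts_always_sum_to_n(self):
        rng = np.random.default_rng(0)
        cls = rng.choice(["TP", "FP", "TN", "FN"], size=37).tolist()
        assert confusion_summary(cls).n == 37

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_summary([])


class TestWilcoxon:
    def _brute_force_p(self, x, y):
        d = x - y
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = np.array(
            [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([0, 1], repeat=d.size)
            ]
        )
        return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_p_matches_exhaustive_enumeration_n8(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(self._brute_force_p(x, y), abs=1e-12)

    def test_exact_handles_ties_via_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = x - np.array([0.5, 0.5, 0.5, 1.0, 1.0, 2.0, 3.0, -0.5])
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(self._brute_force_p(x, y), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(
            stats.wilcoxon(x, y, method="exact").pvalue, abs=1e-12
        )

    def test_constant_shift_gives_extreme_p(self):
        x = np.arange(10, dtype=float)
        _, p = wilcoxon_signed_rank(x + 1.0, x)
        assert p == pytest.approx(2 / 2**10)

    def test_symmetric_alternating_differences_not_significant(self):
        x = np.arange(10, dtype=float)
        delta = np.array([1.0, -1.0] * 5)
        _, p = wilcoxon_signed_rank(x + delta, x)
        assert p > 0.5

    def test_normal_approximation_matches_scipy_large_n(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=60)
        y = x + rng.normal(0.2, 1.0, size=60)
        _, p = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, method="approx", correction=False).pvalue
        assert p == pytest.approx(ref, abs=1e-10)

    def test_all_zero_differences_rejected(self):
        x = np.ones(8)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(x, x)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 5.0, size=9)
        y = rng.uniform(0.1, 5.0, size=9)
        _, p1 = wilcoxon_signed_rank(x, y)
        _, p2 = wilcoxon_signed_rank(3.0 * x + 2.0, 3.0 * y + 2.0)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestShapiroWilk:
    def test_bimodal_sample_rejected_as_normal(self):
        x = np.array([0.0] * 25 + [1.0] * 25)
        _, p = shapiro_wilk(x)
        assert p < 0.01

    def test_near_normal_sample_passes(self):
        x = np.random.default_rng(0).normal(size=100)
        _, p = shapiro_wilk(x)
        assert p > 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.ones(10))

    def test_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.array([1.0, 2.0]))


class TestDeLong:
    def test_perfect_separation_auc_one(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        r = delong_auc(scores, labels)
        assert r.auc == 1.0
        assert r.ci95[1] == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert delong_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_concordance_count(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.normal(size=12), 1)  # rounding invites ties
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0], bool)
        pos, neg = scores[labels], scores[~labels]
        conc = sum(
            (p > n) + 0.5 * (p == n) for p in pos for n in neg
        ) / (pos.size * neg.size)
        assert delong_auc(scores, labels).auc == pytest.approx(conc, abs=1e-12)

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        assert delong_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        a = delong_auc(scores, labels)
        b = delong_auc(np.exp(scores), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.variance == pytest.approx(b.variance, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_auc(np.arange(5.0), np.ones(5, bool))

    def test_identical_classifiers_give_z0_p1(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=20)
        labels = rng.random(20) < 0.5
        z, p = delong_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_opposite_classifiers_give_large_z(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        z, p = delong_test(scores, -scores, labels)
        assert abs(z) > 3 or p < 0.01

    def test_mismatched_lengths_rejected(self):
        labels = np.array([0, 1, 0, 1], bool)
        with pytest.raises(ValueError):
            delong_test(np.arange(4.0), np.arange(5.0), labels)


class TestDose:
    @pytest.mark.parametrize("dlp,msv", [(100.0, 1.4), (0.0, 0.0), (131.4, 1.8396)])
    def test_effective_dose_values(self, dlp, msv):
        assert effective_dose(dlp) == pytest.approx(msv, abs=1e-12)

    def test_negative_dlp_rejected(self):
        with pytest.raises(ValueError):
            effective_dose(-1.0)

    @pytest.mark.parametrize(
        "views,frac", [(128, 0.0625), (2048, 1.0), (16, 1 / 128)]
    )
    def test_dose_fraction_values(self, views, frac):
        assert dose_fraction(views) == pytest.approx(frac, abs=1e-15)

    def test_views_above_full_rejected(self):
        with pytest.raises(ValueError):
            dose_fraction(4096)
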