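import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvdrisk.validation import (
    CutpointRow,
    DegenerateClassesError,
    compare_auc,
    confusion_at_cutoff,
    cutpoint_table,
    optimal_cutoff,
    ranksum_ordinal,
    roc_auc,
    roc_curve_points,
    trend_chi2,
)


class TestConfusionAtCutoff:
    def test_hand_built_six_records(self):
        # cases at r = 2, 3; controls at r = 0, 1, 1, 3; cutoff 2
        r = [2, 3, 0, 1, 1, 3]
        y = [1, 1, 0, 0, 0, 0]
        row = confusion_at_cutoff(r, y, 2)
        assert (row.tp, row.fn, row.fp, row.tn) == (2, 0, 1, 3)
        assert row.sensitivity == pytest.approx(1.0)
        assert row.specificity == pytest.approx(0.75)

    def test_youden_identity_at_printed_operating_point(self):
        # vectors engineered to give sens 0.818 and spec 0.470 exactly
        r = [1] * 818 + [0] * 182 + [1] * 530 + [0] * 470
        y = [1] * 1000 + [0] * 1000
        row = confusion_at_cutoff(r, y, 1)
        assert row.sensitivity == pytest.approx(0.818)
        assert row.specificity == pytest.approx(0.470)
        assert row.youden == pytest.approx(0.288)

    def test_perfect_separation(self):
        row = confusion_at_cutoff([5, 6, 1, 2], [1, 1, 0, 0], 5)
        assert row.sensitivity == 1.0
        assert row.specificity == 1.0
        assert row.youden == pytest.approx(1.0)

    def test_undefined_ppv_is_none(self):
        # cutoff above every value: no predicted positives
        row = confusion_at_cutoff([1, 2], [1, 0], 10)
        assert row.ppv is None
        assert row.npv == pytest.approx(0.5)

    def test_degenerate_classes_rejected(self):
        with pytest.raises(DegenerateClassesError):
            confusion_at_cutoff([1, 2], [1, 1], 1)

    @given(
        data=st.lists(
            st.tuples(st.floats(0, 5), st.booleans()), min_size=4, max_size=40
        ).filter(lambda d: any(y for _, y in d) and not all(y for _, y in d)),
        cutoffs=st.lists(st.floats(0, 5), min_size=2, max_size=8, unique=True),
    )
    @settings(max_examples=50)
    def test_monotone_in_cutoff(self, data, cutoffs):
        r = [v for v, _ in data]
        y = [int(c) for _, c in data]
        rows = cutpoint_table(r, y, sorted(cutoffs))
        for a, b in itertools.pairwise(rows):
            assert a.sensitivity >= b.sensitivity
            assert a.specificity <= b.specificity


class TestCutpointTable:
    def test_default_grid_matches_achievable(self, score_model):
        from cvdrisk.index import achievable_r_grid

        grid = achievable_r_grid(score_model)
        printed = [0.45, 0.90, 1.13, 1.35, 1.58, 1.80, 2.03, 2.25, 2.48, 2.70, 3.15]
        assert set(printed) <= set(grid)

    def test_singleton_equals_confusion(self):
        r = [2, 3, 0, 1]
        y = [1, 1, 0, 0]
        assert cutpoint_table(r, y, [2]) == [confusion_at_cutoff(r, y, 2)]

    def test_empty_cutoffs_empty_table(self):
        assert cutpoint_table([1, 0], [1, 0], []) == []


def row(cutoff, sens, spec):
    return CutpointRow(cutoff_r=cutoff, sensitivity=sens, specificity=spec,
                       youden=sens + spec - 1, ppv=None, npv=None,
                       tp=0, fn=0, fp=0, tn=0)


class TestOptimalCutoff:
    def test_printed_total_columns(self):
        # printed validation-table total rows: Youden peaks at cutoff 1.80
        table = [
            row(0.45, 0.977, 0.156), row(0.90, 0.977, 0.242),
            row(1.13, 0.977, 0.265), row(1.35, 0.955, 0.281),
            row(1.58, 0.818, 0.468), row(1.80, 0.818, 0.470),
            row(2.03, 0.409, 0.798), row(2.25, 0.386, 0.802),
            row(2.48, 0.341, 0.816), row(2.70, 0.205, 0.906),
            row(3.15, 0.068, 0.979),
        ]
        assert optimal_cutoff(table).cutoff_r == 1.80

    def test_single_row(self):
        r = row(1.0, 0.5, 0.5)
        assert optimal_cutoff([r]) is r

    def test_tie_goes_to_larger_cutoff(self):
        table = [row(1.0, 0.8, 0.5), row(2.0, 0.5, 0.8)]
        assert optimal_cutoff(table).cutoff_r == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff([])


class TestRocAuc:
    def test_perfectly_separated(self):
        res = roc_auc([3, 4, 1, 2], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert res.ci_high == 1.0

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=4000)
        y = np.repeat([1, 0], 2000)
        res = roc_auc(v, y)
        assert abs(res.auc - 0.5) < 0.03

    def test_bruteforce_pairs_with_ties(self):
        # cases {2,3}, controls {1,2,4}: pairwise wins 1+.5+0 and 1+1+0 over 6
        res = roc_auc([2, 3, 1, 2, 4], [1, 1, 0, 0, 0])
        assert res.auc == pytest.approx((1 + 0.5 + 0 + 1 + 1 + 0) / 6)

    @given(
        data=st.lists(st.tuples(st.integers(0, 6), st.booleans()),
                      min_size=4, max_size=60).filter(
            lambda d: any(y for _, y in d) and not all(y for _, y in d))
    )
    @settings(max_examples=60)
    def test_mann_whitney_oracle(self, data):
        v = np.array([x for x, _ in data], dtype=float)
        y = np.array([int(c) for _, c in data])
        res = roc_auc(v, y)
        cases, controls = v[y == 1], v[y == 0]
        wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
        assert res.auc == pytest.approx(wins / (len(cases) * len(controls)))

    @given(
        data=st.lists(st.tuples(st.integers(0, 8), st.booleans()),
                      min_size=4, max_size=60).filter(
            lambda d: any(y for _, y in d) and not all(y for _, y in d))
    )
    @settings(max_examples=60)
    def test_two_route_equivalence_with_trapezoid(self, data):
        v = [x for x, _ in data]
        y = [int(c) for _, c in data]
        res = roc_auc(v, y)
        fpr, tpr = roc_curve_points(v, y)
        assert res.auc == pytest.approx(float(np.trapezoid(tpr, fpr)))

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 100)])
        y = np.repeat([1, 0], [50, 100])
        res = roc_auc(v, y)
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.n_cases == 50 and res.n_controls == 100

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateClassesError):
            roc_auc([1, 2], [0, 0])


class TestCompareAuc:
    def test_identical_groups_p_one(self):
        v = [1, 2, 3, 4, 2, 5]
        y = [0, 0, 1, 0, 1, 1]
        z, p = compare_auc(v, y, v, y)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_extreme_separation_significant(self):
        rng = np.random.default_rng(2)
        va = np.concatenate([np.arange(20) + 100, np.arange(20)])  # AUC 1
        ya = np.repeat([1, 0], 20)
        vb = rng.normal(size=40)
        yb = np.repeat([1, 0], 20)
        _, p = compare_auc(va, ya, vb, yb)
        assert p < 0.05

    def test_type_i_error_rate(self):
        # equal-AUC null: rejection rate should be near 5%
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 400
        for _ in range(reps):
            va = rng.normal(size=60)
            vb = rng.normal(size=60)
            y = np.repeat([1, 0], 30)
            _, p = compare_auc(va, y, vb, y)
            rejections += p < 0.05
        rate = rejections / reps
        assert 0.02 < rate < 0.09


class TestTrendChi2:
    def test_flat_prevalence_near_zero(self):
        res = trend_chi2([(100, 10), (100, 10), (100, 10)])
        assert res.chi2_trend == pytest.approx(0.0, abs=1e-10)

    def test_two_levels_equals_pearson(self):
        from cvdrisk.regression import TwoByTwoTable, crude_chi2

        res = trend_chi2([(100, 10), (150, 30)])
        chi2, p = crude_chi2(TwoByTwoTable(30, 120, 10, 90))
        assert res.chi2_trend == pytest.approx(chi2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_three_level_toy_against_individual_correlation(self):
        # independent oracle: CA trend chi2 equals N * r^2 with r the
        # Pearson correlation of (score, outcome) over individual records
        counts = [(100, 1), (100, 5), (100, 20)]
        scores = np.repeat([0.0, 1.0, 2.0], 100)
        outcomes = np.concatenate(
            [np.repeat([1.0, 0.0], [r, n - r]) for n, r in counts]
        )
        r = np.corrcoef(scores, outcomes)[0, 1]
        expected = len(scores) * r**2
        res = trend_chi2(counts)
        assert res.chi2_trend == pytest.approx(expected, rel=1e-10)
        assert res.p_value < 0.001

    def test_zero_enrolment_levels_dropped(self):
        a = trend_chi2([(100, 5), (0, 0), (100, 20)])
        b = trend_chi2([(100, 5), (100, 20)])
        assert a.chi2_trend == pytest.approx(b.chi2_trend)

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            trend_chi2([(100, 5)])

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            trend_chi2([(10, 11), (10, 2)])


class TestRanksumOrdinal:
    def test_identical_samples_z_zero(self):
        res = ranksum_ordinal([1, 2, 3], [1, 2, 3])
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_full_separation_large_z(self):
        res = ranksum_ordinal([0] * 6, [5] * 6)
        # maximum |z| for n1=n2=6 with no ties within the cross-group pooling
        assert abs(res.z) > 2.5
        assert res.p_value < 0.01

    def test_exhaustive_permutation_oracle_with_ties(self):
        # exact null moments of the rank sum enumerated over all
        # C(8,4) assignments; tie-corrected z must match exactly
        pooled = [0, 0, 1, 1, 1, 2, 2, 3]
        a = [0, 1, 1, 2]
        b = [0, 1, 2, 3]
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        n1 = len(a)
        sums = [sum(combo) for combo in itertools.combinations(ranks, n1)]
        mean_w = np.mean(sums)
        var_w = np.var(sums, ddof=0)
        # observed W for sample a against pooled ranks
        obs = ranksum_ordinal(a, b)
        w = 0.0
        remaining = list(pooled)
        rank_of = {}
        vals, counts = np.unique(pooled, return_counts=True)
        start = 1
        for v, c in zip(vals, counts):
            rank_of[v] = start + (c - 1) / 2
            start += c
        w = sum(rank_of[v] for v in a)
        z_exact = (w - mean_w) / math.sqrt(var_w)
        assert obs.z == pytest.approx(z_exact, rel=1e-10)

    def test_all_tied_degenerate(self):
        res = ranksum_ordinal([2, 2], [2, 2, 2])
        assert res.z == 0.0
        assert res.p_value == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ranksum_ordinal([], [1])
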