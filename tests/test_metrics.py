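"""Confusion counts, diagnostic metrics and the 2x2 chi-square test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from depthfuse import (
    ConfusionCounts,
    chi_square_2x2,
    confusion_from_labels,
    confusion_from_operating_point,
    metrics_from_confusion,
)

counts_st = st.tuples(
    st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
).filter(lambda t: sum(t) >= 1)


class TestConfusionFromLabels:
    def test_exhaustive_four_cases(self):
        c = confusion_from_labels(["SM", "SM", "M", "M"], ["SM", "M", "M", "SM"])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_identity_has_no_errors(self):
        truth = ["SM", "M", "SM", "M", "M"]
        c = confusion_from_labels(truth, truth)
        assert c.fp == c.fn == 0 and c.n == 5

    def test_balanced_200_case_vector(self):
        # 76 correct SM calls of 100 SM, 80 correct M calls of 100 M
        truth = ["SM"] * 100 + ["M"] * 100
        pred = ["SM"] * 76 + ["M"] * 24 + ["M"] * 80 + ["SM"] * 20
        c = confusion_from_labels(truth, pred)
        assert (c.tp, c.fp, c.fn, c.tn) == (76, 20, 24, 80)

    @pytest.mark.parametrize(
        "truth,pred",
        [(["SM"], ["SM", "M"]), ([], []), (["SM"], ["bogus"]), (["deep"], ["SM"])],
    )
    def test_input_errors(self, truth, pred):
        with pytest.raises(ValueError):
            confusion_from_labels(truth, pred)


class TestMetricsFromConfusion:
    def test_cooperation_test_operating_point(self):
        m = metrics_from_confusion(ConfusionCounts(76, 20, 24, 80))
        assert m.sensitivity == pytest.approx(0.760)
        assert m.specificity == pytest.approx(0.800)
        assert m.ppv == pytest.approx(0.7917, abs=5e-5)
        assert m.f1 == pytest.approx(0.7755, abs=5e-5)

    def test_ai_test_operating_point(self):
        m = metrics_from_confusion(ConfusionCounts(74, 29, 26, 71))
        assert m.ppv == pytest.approx(0.7184, abs=5e-5)
        assert m.npv == pytest.approx(0.7320, abs=5e-5)
        assert m.f1 == pytest.approx(0.7291, abs=5e-5)

    @pytest.mark.parametrize("k,m_", [(1, 1), (5, 3)])
    def test_perfect_classifier(self, k, m_):
        m = metrics_from_confusion(ConfusionCounts(k, 0, 0, m_))
        assert (
            m.accuracy,
            m.sensitivity,
            m.specificity,
            m.ppv,
            m.npv,
            m.f1,
        ) == (1, 1, 1, 1, 1, 1)

    def test_undefined_ratios_are_none_not_zero(self):
        # no SM calls at all: PPV has a zero denominator
        m = metrics_from_confusion(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert m.ppv is None
        assert m.sensitivity == 0.0
        assert m.f1 == 0.0  # positives exist in truth, none found

    def test_f1_zero_when_no_true_positives(self):
        m = metrics_from_confusion(ConfusionCounts(tp=0, fp=3, fn=2, tn=5))
        assert m.f1 == 0.0

    def test_f1_undefined_without_positive_class(self):
        m = metrics_from_confusion(ConfusionCounts(tp=0, fp=0, fn=0, tn=7))
        assert m.f1 is None and m.npv == 1.0

    @given(counts_st)
    def test_metrics_bounded_and_f1_between_sens_and_ppv(self, counts):
        tp, fp, fn, tn = counts
        m = metrics_from_confusion(ConfusionCounts(tp, fp, fn, tn))
        for v in m.as_dict().values():
            assert v is None or 0.0 <= v <= 1.0
        if m.sensitivity is not None and m.ppv is not None and m.sensitivity + m.ppv > 0:
            assert min(m.sensitivity, m.ppv) - 1e-12 <= m.f1
            assert m.f1 <= max(m.sensitivity, m.ppv) + 1e-12


class TestPerRaterTableReconstruction:
    """The printed per-rater accuracy table reconstructs from each rater's
    own operating point at 250/250. Its F1 column was evidently computed
    from the percentage-rounded sensitivity and PPV, so the F1 check
    reproduces that rounding pipeline."""

    ROWS = [
        # rater, sens%, spec%, acc%, ppv%, npv%, f1
        ("A", 61.6, 76.0, 68.8, 72.0, 66.4, 0.664),
        ("B", 54.4, 89.2, 71.8, 83.4, 66.2, 0.658),
        ("C", 43.2, 90.0, 66.6, 81.2, 61.3, 0.564),
        ("D", 60.0, 69.6, 64.8, 66.4, 63.5, 0.630),
        ("E", 46.8, 77.2, 62.0, 67.2, 59.2, 0.552),
        ("F", 54.8, 75.6, 65.2, 69.2, 62.6, 0.612),
        ("G", 52.0, 68.8, 60.4, 62.5, 58.9, 0.568),
        ("H", 62.4, 63.2, 62.8, 62.9, 62.7, 0.626),
    ]

    @pytest.mark.parametrize("rater,sens,spec,acc,ppv,npv,f1", ROWS,
                             ids=[r[0] for r in ROWS])
    def test_rater_row(self, rater, sens, spec, acc, ppv, npv, f1):
        c = confusion_from_operating_point(sens / 100, spec / 100, 250, 250)
        m = metrics_from_confusion(c)
        assert m.accuracy * 100 == pytest.approx(acc, abs=0.05)
        assert m.ppv * 100 == pytest.approx(ppv, abs=0.05)
        assert m.npv * 100 == pytest.approx(npv, abs=0.05)
        sens_r, ppv_r = round(m.sensitivity, 3), round(m.ppv, 3)
        f1_from_rounded = 2 * sens_r * ppv_r / (sens_r + ppv_r)
        assert f1_from_rounded == pytest.approx(f1, abs=0.0005)


class TestOperatingPointReconstruction:
    @pytest.mark.parametrize(
        "sens,spec,n_pos,n_neg,expected",
        [
            (0.76, 0.78, 250, 250, (190, 55, 60, 195)),
            (0.536, 0.916, 250, 250, (134, 21, 116, 229)),
            (1.0, 1.0, 5, 5, (5, 0, 0, 5)),
        ],
    )
    def test_known_reconstructions(self, sens, spec, n_pos, n_neg, expected):
        c = confusion_from_operating_point(sens, spec, n_pos, n_neg)
        assert (c.tp, c.fp, c.fn, c.tn) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_operating_point(1.2, 0.5, 10, 10)
        with pytest.raises(ValueError):
            confusion_from_operating_point(0.5, 0.5, 0, 10)

    @given(
        st.integers(1, 400).flatmap(
            lambda n_pos: st.tuples(
                st.just(n_pos),
                st.integers(1, 400),
                st.integers(0, n_pos),
            )
        ),
        st.integers(0, 400),
    )
    def test_round_trip_recovers_operating_point(self, pos_part, tn_raw):
        n_pos, n_neg, tp = pos_part
        tn = min(tn_raw, n_neg)
        sens, spec = tp / n_pos, tn / n_neg
        c = confusion_from_operating_point(sens, spec, n_pos, n_neg)
        assert (c.tp, c.tn) == (tp, tn)
        m = metrics_from_confusion(c)
        assert m.sensitivity == pytest.approx(sens)
        assert m.specificity == pytest.approx(spec)

    @given(st.integers(1, 300), st.integers(0, 300), st.integers(0, 300))
    def test_balanced_design_accuracy_identity(self, n, tp_raw, tn_raw):
        tp, tn = min(tp_raw, n), min(tn_raw, n)
        c = confusion_from_operating_point(tp / n, tn / n, n, n)
        m = metrics_from_confusion(c)
        assert m.accuracy == pytest.approx((m.sensitivity + m.specificity) / 2)


class TestChiSquare2x2:
    def test_equal_proportions_gives_zero(self):
        r = chi_square_2x2([[10, 10], [10, 10]])
        assert r.chi_square_statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        # n (ad - bc)^2 / prod(marginals) = 20 * 100^2 / 10^4
        r = chi_square_2x2([[10, 0], [0, 10]])
        assert r.chi_square_statistic == pytest.approx(20.0)

    @pytest.mark.parametrize(
        "table",
        [[[91, 9], [73, 27]], [[263, 31], [116, 90]], [[5, 1], [2, 8]]],
    )
    @pytest.mark.parametrize("correction", [False, True])
    def test_matches_scipy(self, table, correction):
        ours = chi_square_2x2(table, correction=correction)
        ref = chi2_contingency(np.asarray(table), correction=correction)
        assert ours.chi_square_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
    def test_symmetric_under_row_and_column_swap(self, cells):
        a, b, c, d = cells
        base = chi_square_2x2([[a, b], [c, d]]).chi_square_statistic
        rows = chi_square_2x2([[c, d], [a, b]]).chi_square_statistic
        cols = chi_square_2x2([[b, a], [d, c]]).chi_square_statistic
        assert base == pytest.approx(rows) and base == pytest.approx(cols)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 5], [0, 5]])
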