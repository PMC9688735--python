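import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mivmsim import (
    FluorescenceSample,
    MivmError,
    OutcomeTable,
    SignificanceGrade,
    anova_dunnett,
    chi_square_2x2,
    grade_table,
    overlap_coefficient,
    percent_report,
)
from mivmsim.tables import get_table


class TestChiSquare:
    def test_maturation_contrast_is_highly_significant(self):
        # MII vs non-MII, control vs 50 uL/min perfusion
        stat, p = chi_square_2x2(49, 26, 20, 55)
        assert stat == pytest.approx(22.6, abs=0.05)
        assert p < 0.001

    def test_identical_proportions_give_zero_statistic(self):
        stat, p = chi_square_2x2(10, 10, 10, 10)
        assert stat == 0.0 and p == 1.0

    def test_zero_margin_is_undefined(self):
        with pytest.raises(MivmError):
            chi_square_2x2(0, 0, 5, 5)

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_matches_scipy_contingency(self, abcd):
        a, b, c, d = abcd
        table = np.array([[a, b], [c, d]])
        if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
            with pytest.raises(MivmError):
                chi_square_2x2(a, b, c, d)
            return
        stat, p = chi_square_2x2(a, b, c, d)
        ref = sps.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_yates_correction_flag(self):
        stat_u, _ = chi_square_2x2(16, 58, 7, 65)
        stat_c, p_c = chi_square_2x2(16, 58, 7, 65, corrected=True)
        assert stat_c < stat_u
        assert p_c > 0.05  # the corrected test loses this published contrast


class TestPercentReport:
    @pytest.mark.parametrize(
        "count,n,expected", [(49, 75, 65), (31, 59, 53), (0, 50, 0), (27, 72, 38), (19, 69, 28)]
    )
    def test_half_up_rounding(self, count, n, expected):
        assert percent_report(count, n) == expected

    def test_invalid_inputs(self):
        with pytest.raises(MivmError):
            percent_report(1, 0)
        with pytest.raises(MivmError):
            percent_report(5, 4)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(1, 500).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n))))
    def test_within_half_percent_of_exact(self, n_count):
        n, count = n_count
        pct = percent_report(count, n)
        assert abs(pct - 100.0 * count / n) <= 0.5


class TestGradeTable:
    def test_alginate_abnormal_reduction_is_significant(self):
        grades, pvals = grade_table(get_table("nuclear_alginate"), "CTRL")
        assert grades.loc["alginate", "Abnormal"] == "*"
        assert 0.01 < pvals.loc["alginate", "Abnormal"] < 0.05

    def test_alginate_mitochondria_table_not_significant(self):
        grades, _ = grade_table(get_table("mito_alginate"), "CTRL")
        assert (grades == "ns").all().all()

    def test_control_against_its_copy_is_all_ns(self):
        t = OutcomeTable(
            groups=["CTRL", "copy"], categories=["a", "b", "c"],
            counts=[[10, 20, 30], [10, 20, 30]],
        )
        grades, _ = grade_table(t, "CTRL")
        assert (grades == "ns").all().all()

    def test_missing_control_raises(self):
        with pytest.raises(MivmError):
            grade_table(get_table("nuclear_native"), "nope")

    def test_full_table_pooling_variant(self):
        grades, pvals = grade_table(get_table("nuclear_native"), "CTRL", pooling="full_table")
        # omnibus contrast control vs perfused is strong at both flow rates
        assert (pvals < 0.001).all().all()


class TestSignificanceGrade:
    @pytest.mark.parametrize(
        "p,grade", [(0.2, "ns"), (0.049, "*"), (0.009, "**"), (0.0009, "***")]
    )
    def test_thresholds(self, p, grade):
        assert SignificanceGrade(p).grade == grade


class TestAnovaDunnett:
    def test_large_shift_is_asymptotically_certain(self):
        rng = np.random.default_rng(0)
        base = rng.normal(100, 10, 200)
        samples = [
            FluorescenceSample("CTRL", np.clip(base, 0, 255)),
            FluorescenceSample("shifted", np.clip(base + 40, 0, 255)),
        ]
        res = anova_dunnett(samples, "CTRL")
        assert res["dunnett"]["shifted"] < 0.001
        assert res["anova_p"] < 0.001

    def test_degenerate_and_undersized_inputs_raise(self):
        with pytest.raises(MivmError):
            anova_dunnett([FluorescenceSample("CTRL", [1.0, 1.0]),
                           FluorescenceSample("g", [1.0, 1.0])], "CTRL")
        with pytest.raises(MivmError):
            anova_dunnett([FluorescenceSample("CTRL", [1.0]),
                           FluorescenceSample("g", [1.0, 2.0])], "CTRL")
        with pytest.raises(MivmError):
            anova_dunnett([FluorescenceSample("CTRL", [1.0, 2.0])], "CTRL")


class TestOverlapCoefficient:
    def test_identical_signals_give_one(self):
        v = np.array([1.0, 5.0, 2.0])
        assert overlap_coefficient(v, v) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert overlap_coefficient([1, 0, 2, 0], [0, 3, 0, 4]) == 0.0

    def test_hand_computed_example(self):
        assert overlap_coefficient([1, 2], [2, 1]) == pytest.approx(4 / 5)

    def test_all_zero_is_undefined(self):
        with pytest.raises(MivmError):
            overlap_coefficient([0, 0], [1, 2])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0, 255), min_size=2, max_size=16),
        st.floats(0.1, 10.0),
    )
    def test_bounded_and_scale_invariant(self, vals, scale):
        a = np.asarray(vals)
        b = a[::-1].copy()
        if a.sum() == 0:
            return
        r = overlap_coefficient(a, b)
        assert 0.0 <= r <= 1.0 + 1e-12
        assert overlap_coefficient(a * scale, b) == pytest.approx(r, rel=1e-9)
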