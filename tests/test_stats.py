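import numpy as np
import pytest
from scipy import stats as sps

from toothssm.errors import InvalidInputError
from toothssm.stats import (bland_altman, boxplot_stats, compare_groups,
                            fit_line, pc_measurement_regressions)


class TestBlandAltman:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a)
        assert res.bias == 0.0
        assert res.lower == res.upper == 0.0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a + 1.0)
        assert res.bias == pytest.approx(-1.0)
        assert res.lower == pytest.approx(-1.0)
        assert res.upper == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        a = np.array([1, 2, 3, 4.0])
        b = np.array([1.1, 1.9, 3.2, 3.8])
        res = bland_altman(a, b)
        assert res.bias == pytest.approx(0.0, abs=1e-12)
        assert res.sd == pytest.approx(0.1826, abs=1e-4)
        assert res.upper == pytest.approx(0.358, abs=1e-3)
        assert res.lower == pytest.approx(-0.358, abs=1e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        ab, ba = bland_altman(a, b), bland_altman(b, a)
        assert ab.bias == pytest.approx(-ba.bias)
        assert ab.lower == pytest.approx(-ba.upper)
        assert ab.upper == pytest.approx(-ba.lower)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            bland_altman([1, 2], [1, 2, 3])


class TestFitLine:
    def test_exact_line(self):
        x = np.arange(7.0)
        res = fit_line(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_closed_form_hand_case(self):
        res = fit_line([1, 2, 3], [1, 2, 4])
        assert res.slope == pytest.approx(1.5)
        assert res.r_squared == pytest.approx(27 / 28)

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        y = 0.7 * x + rng.normal(size=25)
        mine = fit_line(x, y)
        ref = sps.linregress(x, y)
        assert mine.slope == pytest.approx(ref.slope, rel=1e-12)
        assert mine.r_squared == pytest.approx(ref.rvalue**2, rel=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = fit_line(x, y)
        assert res.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(1000):
            x = np.arange(7.0)
            y = rng.normal(size=7)
            if fit_line(x, y).p_value < 0.01:
                rejections += 1
        assert 0.005 <= rejections / 1000 <= 0.02

    def test_constant_x_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_line([1, 1, 1], [1, 2, 3])

    def test_constant_y(self):
        res = fit_line([1, 2, 3], [5, 5, 5])
        assert res.slope == 0.0
        assert res.r_squared == 0.0


class TestPCRegressions:
    def _rows(self, values, pc=1):
        names = ("LDCc", "LDC", "MDCc", "MDC", "LORla", "LOCla", "vol", "area")
        rows = []
        for level, v in zip((-3, -2, -1, 0, 1, 2, 3), values):
            row = {"pc": pc, "level": float(level), "error": None}
            row.update({n: v for n in names})
            rows.append(row)
        return rows

    def test_perfectly_linear_significant(self):
        out = pc_measurement_regressions([self._rows([1, 2, 3, 4, 5, 6, 7.0])])
        for cell in out:
            assert cell["r_squared"] == pytest.approx(1.0)
            assert cell["significant"] is True

    def test_constant_not_significant(self):
        out = pc_measurement_regressions([self._rows([2.0] * 7)])
        for cell in out:
            assert cell["r_squared"] == 0.0
            assert cell["significant"] is False

    def test_failed_rows_propagate_as_missing(self):
        rows = self._rows([1, 2, 3, 4, 5, 6, 7.0])
        for r in rows[:5]:
            r["error"] = "landmark failure"
        out = pc_measurement_regressions([rows])
        assert all(cell["r_squared"] is None for cell in out)


class TestCompareGroups:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        w = np.concatenate([rng.normal(size=8), rng.normal(loc=1.0, size=10)])
        g = ["a"] * 8 + ["b"] * 10
        res = compare_groups(w, g)
        t, p = sps.ttest_ind(w[:8], w[8:], equal_var=True)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=27)
        g = ["a"] * 9 + ["b"] * 13 + ["c"] * 5
        res = compare_groups(w, g)
        ref = sps.f_oneway(w[:9], w[9:22], w[22:])
        assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tukey_matches_scipy(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=9), rng.normal(loc=2.0, size=13), rng.normal(size=5)]
        w = np.concatenate(groups)
        g = ["a"] * 9 + ["b"] * 13 + ["c"] * 5
        res = compare_groups(w, g, alpha=0.05)
        ref = sps.tukey_hsd(*groups)
        pairs = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
        assert res.posthoc
        for row in res.posthoc:
            i, j = pairs[(row["group_a"], row["group_b"])]
            assert row["p_adjusted"] == pytest.approx(ref.pvalue[i, j], abs=1e-9)

    def test_shifted_group_flagged_exactly(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        c = rng.normal(size=10) + 10 * np.std(np.concatenate([a, b]))
        res = compare_groups(np.concatenate([a, b, c]),
                             ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        assert res.p_value < 1e-6
        flagged = {(r["group_a"], r["group_b"]) for r in res.posthoc if r["significant"]}
        assert flagged == {("a", "c"), ("b", "c")}

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(12)
        rejections = 0
        g = ["a"] * 9 + ["b"] * 13 + ["c"] * 5
        for _ in range(1000):
            w = rng.normal(size=27)
            if compare_groups(w, g).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / 1000 <= 0.065

    def test_invariance_to_labels_and_shift(self):
        rng = np.random.default_rng(9)
        w = rng.normal(size=20)
        g = ["x"] * 10 + ["y"] * 10
        res1 = compare_groups(w, g)
        res2 = compare_groups(w + 42.0, ["y" if x == "x" else "x" for x in g])
        assert res1.f_statistic == pytest.approx(res2.f_statistic, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestBoxplotStats:
    def test_matches_iqr_rule(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100.0])
        bs = boxplot_stats(vals)
        assert bs["outliers"] == [100.0]
        assert bs["whisker_high"] == 9.0
        assert bs["q1"] == pytest.approx(np.percentile(vals, 25))
        iqr = bs["q3"] - bs["q1"]
        assert bs["notch_high"] - bs["median"] == pytest.approx(1.57 * iqr / np.sqrt(10))
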