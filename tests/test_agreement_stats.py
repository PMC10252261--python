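"""ICC, Bland-Altman, rank tests and the regression correction factor."""

import numpy as np
import pytest

from lacs import (
    agreement_analysis,
    bland_altman,
    correction_factor,
    icc_single_two_way_mixed,
    paired_rank_test,
    reliability_label,
)
from lacs.errors import DegenerateTestError, UndefinedICCError, ValidationError

from _oracles import anova_icc, exact_mannwhitney_p, exact_wilcoxon_p

# a small fixed ratings table (6 subjects x 4 raters)
TABLE_6x4 = np.array(
    [
        [9.0, 2.0, 5.0, 8.0],
        [6.0, 1.0, 3.0, 2.0],
        [8.0, 4.0, 6.0, 8.0],
        [7.0, 1.0, 2.0, 6.0],
        [10.0, 5.0, 6.0, 9.0],
        [6.0, 2.0, 4.0, 7.0],
    ]
)


class TestICC:
    def test_identical_columns_give_exactly_one_with_tight_ci(self, rng):
        col = rng.uniform(0, 400, size=12)
        table = np.column_stack([col, col])
        for definition in ("consistency", "absolute_agreement"):
            icc, lo, hi = icc_single_two_way_mixed(table, definition)
            assert (icc, lo, hi) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("definition", ["consistency", "absolute_agreement"])
    def test_matches_anova_mean_squares_oracle(self, definition):
        icc, lo, hi = icc_single_two_way_mixed(TABLE_6x4, definition)
        assert icc == pytest.approx(anova_icc(TABLE_6x4, definition), abs=1e-6)
        assert lo <= icc <= hi

    @pytest.mark.parametrize("definition", ["consistency", "absolute_agreement"])
    def test_matches_pingouin_estimates_and_ci(self, definition, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(5):
            n, k = int(rng.integers(5, 15)), int(rng.integers(2, 5))
            base = rng.normal(100, 30, size=(n, 1))
            table = base + rng.normal(0, 10, size=(n, k))
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n), k),
                    "rater": np.tile(np.arange(k), n),
                    "score": table.ravel(),
                }
            )
            res = pg.intraclass_corr(df, "subject", "rater", "score")
            which = "ICC(C,1)" if definition == "consistency" else "ICC(A,1)"
            row = res[res["Type"] == which].iloc[0]
            ci_col = "CI95" if "CI95" in res.columns else "CI95%"
            icc, lo, hi = icc_single_two_way_mixed(table, definition)
            assert icc == pytest.approx(row["ICC"], abs=1e-6)
            # pingouin rounds its CI bounds to two decimals
            assert lo == pytest.approx(row[ci_col][0], abs=6e-3)
            assert hi == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_constant_shift_separates_definitions(self, rng):
        col = rng.uniform(0, 400, size=10)
        table = np.column_stack([col, col + 25.0])
        icc_c, *_ = icc_single_two_way_mixed(table, "consistency")
        icc_a, *_ = icc_single_two_way_mixed(table, "absolute_agreement")
        assert icc_c == pytest.approx(1.0)
        assert icc_a < 1.0

    def test_affine_rescaling_of_all_columns_is_invariant(self, rng):
        table = rng.normal(100, 30, size=(8, 3))
        icc1, *_ = icc_single_two_way_mixed(table)
        icc2, *_ = icc_single_two_way_mixed(3.0 * table + 17.0)
        assert icc2 == pytest.approx(icc1, abs=1e-12)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValidationError):
            icc_single_two_way_mixed(np.ones((2, 2)))
        with pytest.raises(ValidationError):
            icc_single_two_way_mixed(np.ones((5, 1)))
        with pytest.raises(UndefinedICCError):
            icc_single_two_way_mixed(np.ones((5, 2)))


def test_reliability_labels_follow_cut_points():
    assert reliability_label(0.49) == "poor"
    assert reliability_label(0.5) == "moderate"
    assert reliability_label(0.75) == "moderate"
    assert reliability_label(0.76) == "good"
    assert reliability_label(0.9) == "good"
    assert reliability_label(0.91) == "excellent"
    assert reliability_label(1.0) == "excellent"


class TestBlandAltman:
    def test_identical_series(self, rng):
        x = rng.uniform(0, 400, size=15)
        res = bland_altman(x, x)
        assert tuple(res) == (0.0, 0.0, 0.0)

    def test_antisymmetry(self, rng):
        x = rng.uniform(0, 400, size=20)
        y = rng.uniform(0, 400, size=20)
        a = bland_altman(x, y)
        b = bland_altman(y, x)
        assert a.mean_difference == pytest.approx(-b.mean_difference)
        assert a.loa_low == pytest.approx(-b.loa_high)
        assert a.loa_high == pytest.approx(-b.loa_low)

    def test_known_moments_simulation(self, rng):
        n = 10_000
        y = rng.uniform(50, 100, size=n)
        x = y + rng.normal(2.0, 1.0, size=n)
        res = bland_altman(x, y)
        assert res.mean_difference == pytest.approx(2.0, abs=0.05)
        assert res.loa_low == pytest.approx(2 - 1.96, abs=0.08)
        assert res.loa_high == pytest.approx(2 + 1.96, abs=0.08)
        inside = np.mean(
            (res.differences >= res.loa_low) & (res.differences <= res.loa_high)
        )
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman(np.arange(4.0), np.arange(5.0))


class TestPairedRankTest:
    def test_identical_series_is_degenerate(self):
        x = np.arange(8.0)
        with pytest.raises(DegenerateTestError):
            paired_rank_test(x, x)

    def test_wilcoxon_matches_exhaustive_enumeration(self, rng):
        for n in (6, 8, 10):
            for _ in range(5):
                x = rng.normal(10, 3, size=n)
                y = x + rng.normal(1.0, 2.0, size=n)
                if np.any(x == y):
                    continue
                p = paired_rank_test(x, y, "wilcoxon_signed_rank")
                assert p == pytest.approx(exact_wilcoxon_p(x, y), abs=1e-12)

    def test_mann_whitney_matches_exhaustive_enumeration(self, rng):
        x = rng.normal(0, 1, size=6)
        y = rng.normal(1, 1, size=7)
        p = paired_rank_test(x, y, "mann_whitney_u")
        assert p == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-9)

    def test_detects_stochastic_dominance(self, rng):
        x = rng.normal(0, 1, size=200)
        y = x + np.abs(rng.normal(1.0, 0.5, size=200))
        assert paired_rank_test(x, y) < 0.05
        assert paired_rank_test(x, y, "mann_whitney_u") < 0.05


class TestCorrectionFactor:
    def test_exact_proportional_series_recover_the_slope(self, rng):
        x = rng.uniform(10, 400, size=30)
        factor, r2 = correction_factor(x, 1.9 * x)
        assert factor == pytest.approx(1.9, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_identical_series_give_slope_one(self, rng):
        x = rng.uniform(10, 400, size=10)
        factor, _ = correction_factor(x, x)
        assert factor == pytest.approx(1.0)

    def test_scale_equivariance_through_origin(self, rng):
        x = rng.uniform(10, 400, size=25)
        y = 1.9 * x + rng.normal(0, 10, size=25)
        f1, _ = correction_factor(x, y)
        f2, _ = correction_factor(5.0 * x, 5.0 * y)
        assert f2 == pytest.approx(f1, rel=1e-12)

    def test_free_intercept_mode(self, rng):
        x = rng.uniform(10, 400, size=40)
        y = 1.9 * x + 25.0
        factor, r2 = correction_factor(x, y, intercept="free")
        assert factor == pytest.approx(1.9, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError):
            correction_factor(np.full(5, 3.0), np.arange(5.0))


def test_agreement_analysis_bundles_everything(rng):
    x = rng.uniform(10, 400, size=20)
    y = x * 1.05 + rng.normal(0, 5, size=20)
    res = agreement_analysis(x, y)
    assert res.reliability == reliability_label(res.icc)
    assert res.ci_low <= res.icc <= res.ci_high
    assert res.bland_altman.loa_low <= res.bland_altman.mean_difference <= res.bland_altman.loa_high
    assert res.p_value is not None
    same = agreement_analysis(x, x)
    assert same.icc == 1.0
    assert same.p_value is None
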