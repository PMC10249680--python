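"""ICC and Bland-Altman: oracle checks, invariances, interpretation scales."""

import numpy as np
import pandas as pd
import pytest

from vrsft import (
    RatingsMatrix,
    anova_mean_squares,
    bland_altman,
    icc_agreement,
    icc_consistency,
    interpret_icc,
)


def brute_force_mean_squares(x):
    """Definitional two-way sums of squares, computed cell by cell."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    ss_rows = sum(k * (sum(x[i, :]) / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (sum(x[:, j]) / n - grand) ** 2 for j in range(k))
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    return (ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1)))


def oracle_icc(x):
    """ICC(C,1) and ICC(A,1) from the definitional mean squares."""
    n, k = x.shape
    msr, msc, mse = brute_force_mean_squares(x)
    c = (msr - mse) / (msr + (k - 1) * mse)
    a = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return c, a


class TestAnovaMeanSquares:
    def test_identical_rows_no_subject_variance(self):
        x = np.tile([1.0, 2.0, 3.0], (5, 1))
        msr, msc, mse = anova_mean_squares(x)
        assert msr == pytest.approx(0.0, abs=1e-12)
        assert msc > 0

    def test_identical_columns_no_occasion_or_error_variance(self):
        col = np.array([1.0, 4.0, 2.0, 5.0])
        x = np.column_stack([col, col])
        msr, msc, mse = anova_mean_squares(x)
        assert msc == pytest.approx(0.0, abs=1e-12)
        assert mse == pytest.approx(0.0, abs=1e-12)
        assert msr > 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(0, 1, (5, 2))
            got = anova_mean_squares(x)
            want = brute_force_mean_squares(x)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_zero_variance_degenerate(self):
        msr, msc, mse = anova_mean_squares(np.full((4, 2), 3.0))
        assert (msr, msc, mse) == (0.0, 0.0, 0.0)


class TestICC:
    def test_identical_columns_perfect_reliability(self):
        col = np.array([1.0, 4.0, 2.0, 5.0, 3.0])
        x = np.column_stack([col, col])
        assert icc_consistency(x).value == pytest.approx(1.0)
        assert icc_agreement(x).value == pytest.approx(1.0)

    def test_fixed_offset_consistency_one_agreement_below(self):
        col = np.array([1.0, 4.0, 2.0, 5.0, 3.0])
        x = np.column_stack([col, col + 0.5])
        c, a = icc_consistency(x), icc_agreement(x)
        assert c.value == pytest.approx(1.0)
        assert a.value < 1.0

    def test_matches_definitional_oracle_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 25))
            k = int(rng.integers(2, 5))
            x = (rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
                 + rng.normal(0, 0.4, (1, k)))
            c_o, a_o = oracle_icc(x)
            assert icc_consistency(x).value == pytest.approx(c_o, abs=1e-8)
            assert icc_agreement(x).value == pytest.approx(a_o, abs=1e-8)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        for _ in range(20):
            n, k = int(rng.integers(5, 20)), int(rng.integers(2, 4))
            x = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
            df = (pd.DataFrame(x).reset_index()
                  .melt("index", var_name="rater", value_name="y"))
            ref = pg.intraclass_corr(df, "index", "rater", "y").set_index("Type")
            c, a = icc_consistency(x), icc_agreement(x)
            assert c.value == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-8)
            assert a.value == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-8)
            assert c.p_value == pytest.approx(ref.loc["ICC(C,1)", "pval"], rel=1e-6)
            lo, hi = ref.loc["ICC(A,1)", "CI95"]
            assert a.ci_low == pytest.approx(lo, abs=5.1e-3)  # pg rounds to 2dp
            assert a.ci_high == pytest.approx(hi, abs=5.1e-3)

    def test_common_constant_invariance_and_column_permutation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (8, 2)) + rng.normal(0, 1, (8, 1))
        for fn in (icc_consistency, icc_agreement):
            assert fn(x + 5.0).value == pytest.approx(fn(x).value, abs=1e-10)
            assert fn(x[:, ::-1]).value == pytest.approx(fn(x).value, abs=1e-10)
            assert fn(x[::-1]).value == pytest.approx(fn(x).value, abs=1e-10)

    def test_one_column_offset_affects_only_agreement(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (10, 2)) + rng.normal(0, 2, (10, 1))
        shifted = x.copy()
        shifted[:, 1] += 1.0
        assert icc_consistency(shifted).value == pytest.approx(
            icc_consistency(x).value, abs=1e-10)
        assert icc_agreement(shifted).value < icc_agreement(x).value

    def test_consistency_dominates_agreement_when_occasion_variance_present(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(0, 1, (10, 3)) + rng.normal(0, 1, (10, 1))
            c, a = icc_consistency(x), icc_agreement(x)
            # holds exactly when ms_cols >= ms_error; the inequality can
            # invert when the sample occasion mean square happens to fall
            # below the error mean square
            if c.ms_cols >= c.ms_error:
                assert c.value >= a.value - 1e-12

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.1, (15, 2)) + rng.normal(0, 0.2, (15, 1))
        for fn in (icc_consistency, icc_agreement):
            res = fn(x)
            assert res.ci_low <= res.value <= res.ci_high
            assert 0.0 <= res.p_value <= 1.0

    def test_variance_component_recovery(self):
        """Estimates converge to sigma_b^2/(sigma_b^2+sigma_e^2) = 0.8."""
        rng = np.random.default_rng(8)
        est = [
            icc_consistency(rng.normal(0, 0.1, (27, 2))
                            + rng.normal(0, 0.2, (27, 1))).value
            for _ in range(500)
        ]
        assert abs(float(np.mean(est)) - 0.8) < 0.05

    def test_degenerate_matrix_flagged(self):
        res = icc_consistency(np.full((4, 2), 1.0))
        assert not res.defined

    def test_matrix_shape_constraints(self):
        with pytest.raises(ValueError):
            icc_consistency(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            icc_consistency(np.zeros((5, 1)))


class TestRatingsMatrix:
    def test_listwise_deletion_counted(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "b", "c", "c", "d"],
                "session_id": [1, 2, 1, 2, 1, 2, 1],
                "score": [0.1, 0.2, 0.0, -0.1, 0.3, 0.2, 0.5],
            }
        )
        m = RatingsMatrix.from_long(df)
        assert m.values.shape == (3, 2)
        assert m.n_dropped == 1
        assert "d" not in m.subject_ids


class TestBlandAltman:
    def test_perfect_agreement(self):
        t = np.array([0.1, -0.2, 0.3, 0.0])
        res = bland_altman(t, t)
        assert res.bias == 0.0
        assert res.sd_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_hand_computed_example(self):
        # differences {0.1, -0.1, 0.1, -0.1}: bias 0, sample SD 0.11547
        t2 = np.zeros(4)
        t1 = np.array([0.1, -0.1, 0.1, -0.1])
        res = bland_altman(t1, t2)
        assert res.bias == pytest.approx(0.0, abs=1e-12)
        assert res.sd_diff == pytest.approx(0.11547, abs=1e-5)
        assert res.loa_high == pytest.approx(0.22632, abs=1e-5)
        assert res.loa_low == pytest.approx(-0.22632, abs=1e-5)

    def test_loa_width_is_2x196_sd_always(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            t1, t2 = rng.normal(0, 0.2, (2, n))
            res = bland_altman(t1, t2)
            assert res.loa_high - res.loa_low == pytest.approx(
                2 * 1.96 * res.sd_diff, abs=1e-12)
            assert res.bias_ci_low <= res.bias <= res.bias_ci_high

    def test_swap_negates_bias_preserves_spread(self):
        rng = np.random.default_rng(9)
        t1, t2 = rng.normal(0, 0.2, (2, 12))
        a, b = bland_altman(t1, t2), bland_altman(t2, t1)
        assert b.bias == pytest.approx(-a.bias, abs=1e-12)
        assert b.sd_diff == pytest.approx(a.sd_diff, abs=1e-12)

    def test_bias_ci_coverage(self):
        """The 95% t-CI of the bias covers 0 near nominal rate under H0."""
        rng = np.random.default_rng(10)
        hits = 0
        reps = 1000
        for _ in range(reps):
            t1 = rng.normal(0, 0.15, 27)
            t2 = t1 + rng.normal(0, 0.1, 27)  # zero session offset
            res = bland_altman(t1, t2)
            hits += res.bias_ci_low <= 0.0 <= res.bias_ci_high
        assert hits / reps >= 0.93

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([0.1, 0.2, 0.3], [0.1, 0.2])
        with pytest.raises(ValueError):
            bland_altman([0.1, 0.2], [0.1, 0.2])


class TestInterpretICC:
    @pytest.mark.parametrize(
        "value, scheme, label",
        [
            (0.44, "cicchetti", "fair"),
            (0.83, "koo_li", "good"),
            (1.0, "cicchetti", "excellent"),
            (1.0, "koo_li", "excellent"),
            (0.39, "cicchetti", "poor"),
            (0.4, "cicchetti", "fair"),
            (0.6, "cicchetti", "good"),
            (0.75, "cicchetti", "excellent"),
            (0.49, "koo_li", "poor"),
            (0.5, "koo_li", "moderate"),
            (0.75, "koo_li", "good"),
            (0.9, "koo_li", "excellent"),
            (-0.2, "koo_li", "poor"),
        ],
    )
    def test_published_bins(self, value, scheme, label):
        assert interpret_icc(value, scheme) == label

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            interpret_icc(1.5, "koo_li")
        with pytest.raises(ValueError):
            interpret_icc(0.5, "other")
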