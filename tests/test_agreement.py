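"""Agreement-engine behaviour: worked examples, symmetries, oracle checks."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from onesitebf.agreement import (
    PairedSample,
    bland_altman,
    constant_error,
    correlation_metrics,
    error_metrics,
    full_report,
    lin_ccc,
    ols_fit,
    paired_t_test,
)
from oracles import brute_force_metrics

THREE_POINT = PairedSample([2.0, 4.0, 6.0], [1.0, 2.0, 3.0], "BF%")


def vectors(n_min=3, n_max=20):
    """Strategy: paired non-constant vectors of equal modest length."""
    return st.integers(min_value=n_min, max_value=n_max).flatmap(
        lambda n: st.tuples(
            arrays(float, n, elements=st.floats(-100, 100, width=32)),
            arrays(float, n, elements=st.floats(-100, 100, width=32)),
        )
    ).filter(lambda pr: np.std(pr[0]) > 1e-3 and np.std(pr[1]) > 1e-3)


class TestConstantError:
    def test_identity_sample(self):
        v = [1.0, 2.0, 3.0]
        assert constant_error(PairedSample(v, v)) == (0.0, 0.0)

    def test_three_point_hand_values(self):
        ce, sd = constant_error(THREE_POINT)
        assert ce == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_constant_shift(self):
        ref = np.array([5.0, 9.0, 11.0, 20.0])
        ce, sd = constant_error(PairedSample(ref + 3.2, ref))
        assert ce == pytest.approx(3.2)
        assert sd == pytest.approx(0.0, abs=1e-12)


class TestPairedT:
    def test_symmetric_differences_give_p_one(self):
        s = PairedSample([1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0])
        t, p, df = paired_t_test(s)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 3

    def test_hand_value_diffs_1_2_3(self):
        s = PairedSample([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        t, p, df = paired_t_test(s)
        assert t == pytest.approx(2.0 * math.sqrt(3), abs=1e-4)  # 3.4641
        assert df == 2

    def test_t_scale_invariant_in_differences(self):
        # mean and SD of the differences scale together, so t is unchanged
        ref = np.array([10.0, 12.0, 15.0, 18.0, 21.0])
        d = np.array([1.0, -0.5, 2.0, 0.3, -1.2])
        t1, _, _ = paired_t_test(PairedSample(ref + d, ref))
        t2, _, _ = paired_t_test(PairedSample(ref + 2 * d, ref))
        assert t2 == pytest.approx(t1, rel=1e-9)

    def test_degenerate_constant_nonzero_difference(self):
        s = PairedSample([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        t, p, _ = paired_t_test(s)
        assert math.isinf(t) and t > 0
        assert p == 0.0
        assert "degenerate_t" in full_report(s).flags


class TestCorrelationAndCCC:
    def test_affine_relation_perfect_r(self):
        ref = np.array([1.0, 2.0, 5.0])
        r, r2 = correlation_metrics(PairedSample(2 * ref + 1, ref))
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        ref = np.array([1.0, 2.0, 5.0])
        r, _ = correlation_metrics(PairedSample(-ref, ref))
        assert r == pytest.approx(-1.0)

    def test_hand_value(self):
        r, _ = correlation_metrics(PairedSample([1.0, 2.0, 4.0], [1.0, 2.0, 3.0]))
        assert r == pytest.approx(0.98198, abs=1e-5)

    def test_identity_gives_ccc_one(self):
        v = [1.0, 4.0, 9.0]
        assert lin_ccc(PairedSample(v, v)) == pytest.approx(1.0)

    def test_location_shift_penalised(self):
        ref = np.array([1.0, 2.0, 3.0])
        ccc = lin_ccc(PairedSample(ref + 2.0, ref))
        assert ccc < 1.0
        r, _ = correlation_metrics(PairedSample(ref + 2.0, ref))
        assert r == pytest.approx(1.0)

    def test_three_point_hand_value(self):
        # n-1 denominators: cov 2, vars 4 and 1, mean shift^2 = 4 -> 4/9
        assert lin_ccc(THREE_POINT) == pytest.approx(4.0 / 9.0, abs=1e-12)

    @given(vectors())
    def test_ccc_bounded_by_r(self, pair):
        s = PairedSample(*pair)
        assert abs(lin_ccc(s)) <= abs(correlation_metrics(s)[0]) + 1e-12

    def test_ccc_equals_r_for_equal_mean_and_variance(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([2.0, 1.0, 4.0, 3.0])  # same mean, same variance
        s = PairedSample(pred, ref)
        assert lin_ccc(s) == pytest.approx(correlation_metrics(s)[0], abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            lin_ccc(PairedSample([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestErrorMetrics:
    def test_identity_sample_zeroes(self):
        v = [1.0, 2.0, 3.0]
        assert error_metrics(PairedSample(v, v)) == (0.0, 0.0, 0.0)

    def test_unit_diffs(self):
        ref = np.array([10.0, 20.0, 30.0, 40.0])
        s = PairedSample(ref + np.array([1.0, -1.0, 1.0, -1.0]), ref)
        _, rmse, mae = error_metrics(s)
        assert rmse == pytest.approx(1.0)
        assert mae == pytest.approx(1.0)

    def test_three_point_hand_values(self):
        see, rmse, mae = error_metrics(THREE_POINT)
        assert rmse == pytest.approx(math.sqrt(14 / 3), abs=1e-4)  # 2.1602
        assert mae == pytest.approx(2.0)
        assert see == pytest.approx(0.0, abs=1e-9)  # exact fit pred = 2*ref


class TestBlandAltman:
    def test_printed_loa_arithmetic(self):
        # ce 0.1, sd 5.2 -> half-width 1.96*5.2 = 10.192, one decimal 10.2
        d = np.array([-1.5, -0.5, 0.5, 1.5])
        d = (d - d.mean()) / d.std(ddof=1) * 5.2 + 0.1
        ref = np.array([20.0, 25.0, 30.0, 35.0])
        rep = full_report(PairedSample(ref + d, ref))
        assert rep.loa_half_width == pytest.approx(10.192, abs=1e-9)
        assert round(rep.loa_half_width, 1) == 10.2

    def test_identity_collapses(self):
        v = [1.0, 2.0, 3.0]
        lo, hi, slope, intercept, p = bland_altman(PairedSample(v, v))
        assert (lo, hi, slope) == (0.0, 0.0, 0.0)

    def test_noiseless_proportional_bias_recovery(self):
        means = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        d = -0.4 * means + 2.0
        # construct pred/ref with given pairwise means and differences
        pred, ref = means + d / 2, means - d / 2
        _, _, slope, intercept, p = bland_altman(PairedSample(pred, ref))
        assert slope == pytest.approx(-0.4, abs=1e-9)
        assert intercept == pytest.approx(2.0, abs=1e-9)
        assert p < 1e-6

    def test_reference_regressor_option(self):
        ref = np.array([10.0, 20.0, 30.0, 40.0])
        pred = ref + np.array([1.0, 0.5, -0.5, -1.0])
        s = PairedSample(pred, ref)
        _, _, slope_ref, _, _ = bland_altman(s, bias_regressor="reference")
        bf = brute_force_metrics(list(pred), list(ref))
        assert slope_ref != pytest.approx(bf["ba_slope"])  # differs from mean-based


class TestOls:
    def test_exact_line(self):
        ref = np.array([1.0, 2.0, 5.0])
        slope, intercept, resid = ols_fit(PairedSample(3 * ref - 2, ref))
        assert slope == pytest.approx(3.0)
        assert intercept == pytest.approx(-2.0)
        assert np.allclose(resid, 0.0)

    def test_three_point_hand_values(self):
        slope, intercept, _ = ols_fit(THREE_POINT)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=12)
        pred = 1.5 * ref + rng.normal(size=12)
        s = PairedSample(pred, ref)
        perm = rng.permutation(12)
        s2 = PairedSample(pred[perm], ref[perm])
        assert ols_fit(s)[:2] == pytest.approx(ols_fit(s2)[:2])


class TestFullReportSymmetries:
    @given(vectors())
    def test_swap_negates_ce_preserves_scale_free_metrics(self, pair):
        s = PairedSample(*pair)
        a, b = full_report(s), full_report(s.swapped())
        assert b.constant_error == pytest.approx(-a.constant_error, abs=1e-9)
        assert b.sd_diff == pytest.approx(a.sd_diff, abs=1e-9)
        assert b.rmse == pytest.approx(a.rmse, abs=1e-9)
        assert b.mae == pytest.approx(a.mae, abs=1e-9)
        assert abs(b.pearson_r) == pytest.approx(abs(a.pearson_r), abs=1e-9)
        assert b.ccc == pytest.approx(a.ccc, abs=1e-9)

    def test_invariants_on_noisy_sample(self):
        rng = np.random.default_rng(11)
        ref = rng.normal(25, 6, 80)
        pred = 0.8 * ref + 5 + rng.normal(0, 3, 80)
        rep = full_report(PairedSample(pred, ref))
        assert rep.loa_half_width == pytest.approx(1.96 * rep.sd_diff)
        assert rep.loa_upper - rep.loa_lower == pytest.approx(2 * rep.loa_half_width)
        assert -1 <= rep.ccc <= 1
        assert abs(rep.ccc) <= abs(rep.pearson_r)
        assert rep.rmse >= abs(rep.constant_error)
        assert rep.rmse >= rep.mae

    def test_matches_brute_force_on_one_sample(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(30, 5, 25)
        pred = ref + rng.normal(1, 2, 25)
        rep = full_report(PairedSample(pred, ref))
        bf = brute_force_metrics(list(pred), list(ref))
        for key, expected in bf.items():
            assert getattr(rep, key) == pytest.approx(expected, abs=1e-10), key


class TestPairedSampleValidation:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            PairedSample([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_too_short(self):
        with pytest.raises(ValueError):
            PairedSample([1.0, 2.0], [1.0, 2.0])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            PairedSample([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])
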