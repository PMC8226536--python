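"""CT calling, Livak fold change, efficiency, dPCR, and group statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudoquant.quant import (
    CtMeasurement,
    compare_groups,
    ct_from_curve,
    delta_ct,
    dpcr_quantify,
    efficiency_from_dilution,
    fold_change,
    mmp_fold_change,
    pool_fraction,
)


class TestCtFromCurve:
    def test_exact_crossing(self):
        f = [0.0, 0.05, 0.15, 0.4]
        assert ct_from_curve(f, threshold=0.15).ct == 3.0

    def test_linear_interpolation(self):
        call = ct_from_curve([0.10, 0.20], threshold=0.15, cycles=[20, 21])
        assert call.ct == 20.5 and not call.censored

    def test_censored_flat_curve(self):
        call = ct_from_curve([0.01] * 40, threshold=0.15)
        assert call.censored and call.ct == 40.0

    def test_logistic_closed_form(self):
        """Linear interpolation of a logistic sampled at integer cycles
        matches the analytic inversion near the inflection point."""
        A, k, c0, thr = 1.0, 0.6, 23.3, 0.5
        cycles = np.arange(1, 41)
        f = A / (1 + np.exp(-k * (cycles - c0)))
        true_ct = c0 - math.log(A / thr - 1) / k
        assert ct_from_curve(f, threshold=thr).ct == pytest.approx(true_ct, abs=0.01)


class TestDeltaCt:
    def test_triplicate_means(self):
        d = delta_ct(
            CtMeasurement("s1", "T", (25, 25, 25)),
            CtMeasurement("s1", "R", (20, 20, 20)),
        )
        assert d.delta_ct == 5.0

    def test_identical_triplicates_zero(self):
        m = CtMeasurement("s1", "T", (22.1, 22.1, 22.1))
        r = CtMeasurement("s1", "R", (22.1, 22.1, 22.1))
        assert delta_ct(m, r).delta_ct == 0.0

    def test_no_outlier_trimming(self):
        d = delta_ct(
            CtMeasurement("s1", "T", (24.0, 24.2, 30.0)),
            CtMeasurement("s1", "R", (20.0, 20.0, 20.0)),
        )
        assert d.delta_ct == pytest.approx((24.0 + 24.2 + 30.0) / 3 - 20.0)

    def test_sample_mismatch(self):
        with pytest.raises(ValueError):
            delta_ct(
                CtMeasurement("s1", "T", (25,)), CtMeasurement("s2", "R", (20,))
            )


class TestFoldChange:
    def test_equal_means_unity(self):
        assert fold_change([3.0, 4.0], [3.5]).fold_change == 1.0

    def test_one_cycle_doubles(self):
        assert fold_change([4.0], [5.0]).fold_change == pytest.approx(2.0)

    def test_two_and_a_half_fold(self):
        assert fold_change([-1.3219], [0.0]).fold_change == pytest.approx(2.50, abs=1e-4)

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=6),
        st.lists(st.floats(-5, 5), min_size=1, max_size=6),
    )
    @settings(max_examples=40, deadline=None)
    def test_reciprocal_property(self, a, b):
        assert fold_change(a, b).fold_change * fold_change(b, a).fold_change == pytest.approx(1.0)

    def test_shift_property(self):
        """Adding c to every target replicate shifts dCT by exactly c."""
        target = CtMeasurement("s", "T", (24.0, 24.3, 24.1))
        ref = CtMeasurement("s", "R", (20.0, 20.1, 19.9))
        base = delta_ct(target, ref).delta_ct
        shifted = CtMeasurement("s", "T", tuple(ct + 1.7 for ct in target.cts))
        assert delta_ct(shifted, ref).delta_ct == pytest.approx(base + 1.7)

    def test_monotone_in_ddct(self):
        fcs = [fold_change([d], [0.0]).fold_change for d in (-2, -1, 0, 1, 2)]
        assert fcs == sorted(fcs, reverse=True)


class TestEfficiency:
    def test_perfect_doubling(self):
        slope = -1 / math.log10(2)
        pts = [(x, 20 + slope * x) for x in (0, -1, -2, -3)]
        res = efficiency_from_dilution(pts)
        assert res.efficiency == pytest.approx(1.0, abs=1e-6)
        assert res.r_squared == pytest.approx(1.0)

    def test_formula_evaluation(self):
        pts = [(x, 20 - 3.456 * x) for x in (0, -1, -2)]
        res = efficiency_from_dilution(pts)
        assert res.slope == pytest.approx(-3.456)
        assert res.efficiency == pytest.approx(0.947, abs=1e-3)

    def test_round_trip_planted_efficiency(self):
        """A noiseless series generated at E = 0.92 returns E = 0.92."""
        e = 0.92
        slope = -1 / math.log10(1 + e)
        pts = [(x, 25 + slope * x) for x in (0, -1, -2, -3, -4)]
        assert efficiency_from_dilution(pts).efficiency == pytest.approx(e, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            efficiency_from_dilution([(0, 20), (-1, 23)])

    def test_zero_input_variance(self):
        with pytest.raises(ValueError):
            efficiency_from_dilution([(0, 20), (0, 21), (0, 22)])


class TestDpcr:
    def test_zero_positives_zero_copies(self):
        res = dpcr_quantify(0, 26000, 0.00091)
        assert res.lam == 0.0 and res.copies_per_ul == 0.0

    def test_half_positive_ln2(self):
        res = dpcr_quantify(13000, 26000, 1.0)
        assert res.lam == pytest.approx(math.log(2))

    def test_saturated_flagged(self):
        res = dpcr_quantify(100, 100, 1.0)
        assert res.saturated and math.isinf(res.copies_per_ul)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            dpcr_quantify(5, 4, 1.0)

    def test_monte_carlo_ci_coverage(self):
        """The Clopper-Pearson CI contains the true concentration in at
        least 93 of 100 seeded simulations."""
        conc, vol, n = 800.0, 0.00091, 26000
        p = 1 - math.exp(-conc * vol)
        hits = 0
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = rng.binomial(n, p)
            res = dpcr_quantify(int(k), n, vol)
            if res.ci_low <= conc <= res.ci_high:
                hits += 1
        assert hits >= 93

    def test_poisson_fixed_point(self):
        """Re-simulating from the estimate and re-estimating converges back
        (the estimator is the ML inverse of the partition model)."""
        res = dpcr_quantify(9000, 26000, 0.00091)
        p = 1 - math.exp(-res.copies_per_ul * 0.00091)
        k = round(p * 26000)
        res2 = dpcr_quantify(k, 26000, 0.00091)
        assert res2.copies_per_ul == pytest.approx(res.copies_per_ul, rel=1e-4)


class TestPoolFraction:
    def test_target_equals_pool(self):
        a = dpcr_quantify(9000, 26000, 0.00091)
        assert pool_fraction(a, a).fraction == 1.0

    def test_zero_target(self):
        assert pool_fraction(
            dpcr_quantify(0, 26000, 0.00091), dpcr_quantify(9000, 26000, 0.00091)
        ).fraction == 0.0

    def test_zero_pool_is_error(self):
        with pytest.raises(ValueError):
            pool_fraction(
                dpcr_quantify(10, 26000, 0.00091), dpcr_quantify(0, 26000, 0.00091)
            )


class TestMmp:
    def test_identical_ratios_unity(self):
        assert mmp_fold_change(900, 300, 600, 200) == pytest.approx(1.0)

    def test_halved_ratio(self):
        assert mmp_fold_change(450, 300, 600, 200) == pytest.approx(0.5)

    @given(st.tuples(*[st.floats(0.1, 1e4) for _ in range(4)]))
    @settings(max_examples=40, deadline=None)
    def test_equals_ratio_of_ratios(self, vals):
        rt, gt, ru, gu = vals
        assert mmp_fold_change(rt, gt, ru, gu) == pytest.approx((rt / gt) / (ru / gu))

    def test_nonpositive_intensity(self):
        with pytest.raises(ValueError):
            mmp_fold_change(0, 1, 1, 1)


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        res = compare_groups([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_textbook_example(self):
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.p == pytest.approx(0.0213, abs=5e-4)
        assert res.df == 4

    def test_welch_variant(self):
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 5.5, 9.0], variant="welch")
        assert res.variant == "welch" and res.df < 4

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            compare_groups([2, 2, 2], [2, 2, 2])

    def test_agrees_with_permutation_oracle(self):
        """Student p within 0.05 of the exhaustive permutation p (n = 4+4,
        the smallest size at which the permutation grid is fine enough)."""
        a, b = [1.0, 2.1, 3.2, 4.0], [3.1, 4.2, 5.0, 6.1]
        obs = abs(compare_groups(a, b).t)
        pooled = a + b
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(8) if i not in idx]
            t = abs(compare_groups(ga, gb).t)
            total += 1
            if t >= obs - 1e-12:
                count += 1
        perm_p = count / total
        assert abs(compare_groups(a, b).p - perm_p) < 0.05
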