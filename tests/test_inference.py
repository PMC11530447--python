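"""Circular-shuffle permutation inference, FDR, t-tests, power arithmetic."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from audsync.inference import (
    PowerSpec,
    bh_fdr,
    circular_shift,
    group_isc_test,
    participant_permutation_test,
    power_t,
    welch_t,
)


class TestCircularShift:
    @pytest.mark.parametrize("offset", [0, 4])
    def test_identity_offsets(self, offset):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(circular_shift(x, offset), x)

    def test_enumeration(self):
        np.testing.assert_array_equal(
            circular_shift(np.array([1, 2, 3, 4]), 1), [4, 1, 2, 3]
        )

    def test_multiset_preserved(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_array_equal(np.sort(circular_shift(x, 37)), np.sort(x))

    def test_autocorrelation_roughly_preserved(self, rng):
        # rotation only perturbs the autocovariance at the wraparound seam
        x = np.convolve(rng.normal(size=2000), np.ones(5) / 5, mode="same")
        def lag1(v):
            return np.corrcoef(v[:-1], v[1:])[0, 1]
        assert abs(lag1(circular_shift(x, 700)) - lag1(x)) < 0.05


class TestParticipantPermutation:
    def test_identical_target_gets_minimum_p(self, rng):
        x = rng.normal(size=120)
        res = participant_permutation_test(x, np.stack([x, x]), n_iter=199, rng_seed=1)
        assert res.p_value == pytest.approx(1.0 / 200.0)
        assert res.n_iter == 199

    def test_null_p_values_are_uniform(self):
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            x = rng.normal(size=200)
            partners = rng.normal(size=(4, 200))
            res = participant_permutation_test(x, partners, n_iter=199, rng_seed=rep)
            ps.append(res.p_value)
        # Kolmogorov band at alpha = 0.01
        stat = stats.kstest(ps, "uniform").statistic
        assert stat < 1.63 / np.sqrt(len(ps))

    def test_shifting_partners_is_equivalent(self):
        """Rotating all partners jointly instead of the target flips the
        frame of reference; decisions at q = 0.05 should almost always agree."""
        agree = 0
        for rep in range(100):
            rng = np.random.default_rng(7000 + rep)
            shared = rng.normal(size=150) * (0.8 if rep % 2 else 0.0)
            x = shared + rng.normal(size=150)
            partners = shared + rng.normal(size=(3, 150))
            res = participant_permutation_test(x, partners, n_iter=199, rng_seed=rep)
            p_target, obs = res.p_value, res.observed_isc
            # shift the frame: rotate the target by the negated offsets
            rng2 = np.random.default_rng(10_000 + rep)
            offsets = rng2.integers(15, 150 - 15 + 1, size=199)
            from audsync._sliding import circularly_shifted_matrix, shifted_pair_scalars

            XS = circularly_shifted_matrix(x, -offsets)
            null = np.nanmedian(shifted_pair_scalars(XS, partners, 15), axis=0)
            p_partner = (1 + np.sum(null >= obs)) / 200.0
            agree += (p_target < 0.05) == (p_partner < 0.05)
        assert agree >= 95

    def test_too_short_series_rejected(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(ValueError, match="twice the window"):
            participant_permutation_test(x, np.stack([x]), n_iter=199, rng_seed=0)

    def test_reproducible_given_seed(self, rng):
        x = rng.normal(size=100)
        partners = rng.normal(size=(3, 100))
        a = participant_permutation_test(x, partners, n_iter=199, rng_seed=42)
        b = participant_permutation_test(x, partners, n_iter=199, rng_seed=42)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_iscs, b.null_iscs)


class TestBHFDR:
    def test_hand_executed_example(self):
        # sorted p: .001 <= 1*.05/3, .02 <= 2*.05/3, .9 > 3*.05/3
        np.testing.assert_array_equal(
            bh_fdr(np.array([0.001, 0.02, 0.9]), 0.05), [True, True, False]
        )

    def test_all_ones_rejects_nothing(self):
        assert not bh_fdr(np.ones(5), 0.05).any()

    def test_matches_reference_implementation(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            ours = bh_fdr(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(ours, ref)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))


class TestGroupISCTest:
    def test_all_zero_iscs(self):
        res = group_isc_test(np.zeros(5))
        assert res.t == 0.0 and res.d == 0.0 and res.p == 0.5

    def test_hand_arithmetic(self):
        res = group_isc_test(np.array([0.1, 0.2, 0.3, 0.2, 0.2]))
        assert res.mean_r == pytest.approx(0.2)
        assert res.t == pytest.approx(0.2 / (np.std([0.1, 0.2, 0.3, 0.2, 0.2], ddof=1) / np.sqrt(5)))
        assert res.t == pytest.approx(6.3246, abs=1e-3)
        assert res.d == pytest.approx(res.mean_r / np.std([0.1, 0.2, 0.3, 0.2, 0.2], ddof=1))
        lo, hi = res.d_ci
        assert lo < res.d < hi

    def test_one_tailed_p_matches_scipy(self, rng):
        x = rng.normal(0.1, 0.2, size=30)
        res = group_isc_test(x, tails=1)
        t_ref, p_ref = stats.ttest_1samp(x, 0.0, alternative="greater")
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)


class TestPower:
    def test_sensitivity_d_for_large_sample(self):
        spec = power_t(PowerSpec(test="one_sample_t", tails=1, alpha=0.05, n=870, power=0.95))
        assert spec.d == pytest.approx(0.11, abs=0.005)

    def test_achieved_power_two_sample(self):
        spec = power_t(PowerSpec(test="two_sample_t", tails=2, alpha=0.05, n=30, d=0.52))
        assert spec.power == pytest.approx(0.52, abs=0.02)

    def test_minimal_detectable_two_sample_d(self):
        spec = power_t(PowerSpec(test="two_sample_t", tails=2, alpha=0.05, n=30, power=0.80))
        assert spec.d == pytest.approx(0.74, abs=0.01)

    def test_null_effect_power_equals_alpha(self):
        for tails in (1, 2):
            spec = power_t(PowerSpec(test="one_sample_t", tails=tails, alpha=0.05, n=50, d=0.0))
            assert spec.power == pytest.approx(0.05, abs=1e-9)

    def test_solve_n_roundtrip(self):
        spec = power_t(PowerSpec(test="two_sample_t", tails=2, alpha=0.05, d=0.5, power=0.8))
        achieved = power_t(PowerSpec(test="two_sample_t", tails=2, alpha=0.05,
                                     d=0.5, n=spec.n)).power
        just_below = power_t(PowerSpec(test="two_sample_t", tails=2, alpha=0.05,
                                       d=0.5, n=spec.n - 1)).power
        assert achieved >= 0.8 > just_below

    def test_infeasible_request(self):
        with pytest.raises(ValueError, match="exceed alpha"):
            power_t(PowerSpec(n=10, power=0.04, d=None))


class TestWelch:
    def test_identical_groups(self):
        res = welch_t(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_computation(self):
        res = welch_t(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == pytest.approx(4.0)

    def test_matches_scipy_on_random_inputs(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 40))
            b = rng.normal(0.3, 2, size=rng.integers(3, 40))
            res = welch_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
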