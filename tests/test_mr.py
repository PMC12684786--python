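"""MR estimator suite: Wald ratio, IVW, Cochran Q, Egger, median, mode."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from cismr import mr
from cismr.sumstats import HarmonizedInstrument

from conftest import equal_weight_instruments


def hi(beta_exp, se_exp, beta_out, se_out, vid="v"):
    return HarmonizedInstrument(
        variant_id=vid, beta_exp=beta_exp, se_exp=se_exp,
        beta_out=beta_out, se_out=se_out, eaf=0.3, action="match",
    )


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = mr.wald_ratio(hi(0.1, 0.01, -0.05, 0.02))
        assert est.beta == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.2)
        assert est.n_variants == 1

    def test_null_outcome(self):
        est = mr.wald_ratio(hi(0.1, 0.01, 0.0, 0.02))
        assert est.beta == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_allele_flip_invariance(self):
        a = mr.wald_ratio(hi(0.1, 0.01, -0.05, 0.02))
        b = mr.wald_ratio(hi(-0.1, 0.01, 0.05, 0.02))
        assert a.beta == pytest.approx(b.beta)
        assert a.se == pytest.approx(b.se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            mr.wald_ratio(hi(0.0, 0.01, 0.1, 0.02))


class TestIVW:
    def test_two_ratio_hand_computation(self, two_ratio_instruments):
        est = mr.ivw_fixed(two_ratio_instruments)
        assert est.beta == pytest.approx(-0.26)
        assert est.se == pytest.approx(1 / np.sqrt(125))

    def test_all_null_outcomes(self):
        est = mr.ivw_fixed(equal_weight_instruments([0.0, 0.0, 0.0]))
        assert est.beta == 0.0

    def test_duplicated_instrument_matches_wald(self):
        h = hi(0.1, 0.01, -0.05, 0.02)
        est = mr.ivw_fixed([h, h])
        wald = mr.wald_ratio(h)
        assert est.beta == pytest.approx(wald.beta)

    def test_single_instrument_rejected(self):
        with pytest.raises(ValueError, match="wald_ratio"):
            mr.ivw_fixed(equal_weight_instruments([0.5]))

    def test_equals_wls_through_origin(self):
        """IVW is algebraically WLS of b_Y on b_X through the origin, weights 1/se_Y^2."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(2, 30)
            df = pd.DataFrame(
                {
                    "beta_exp": rng.normal(0.1, 0.05, n) + 0.05,
                    "se_exp": rng.uniform(0.005, 0.02, n),
                    "beta_out": rng.normal(0, 0.1, n),
                    "se_out": rng.uniform(0.01, 0.1, n),
                }
            )
            est = mr.ivw_fixed(df)
            wls = sm.WLS(
                df["beta_out"], df[["beta_exp"]], weights=1.0 / df["se_out"] ** 2
            ).fit()
            assert est.beta == pytest.approx(float(wls.params.iloc[0]), abs=1e-10)

    def test_allele_flip_invariance(self, two_ratio_instruments):
        flipped = two_ratio_instruments.copy()
        flipped["beta_exp"] *= -1
        flipped["beta_out"] *= -1
        a, b = mr.ivw_fixed(two_ratio_instruments), mr.ivw_fixed(flipped)
        assert a.beta == pytest.approx(b.beta) and a.se == pytest.approx(b.se)


class TestCochranQ:
    def test_two_ratio_hand_arithmetic(self, two_ratio_instruments):
        est = mr.ivw_fixed(two_ratio_instruments)
        q = mr.cochran_q(two_ratio_instruments, est)
        assert q.q == pytest.approx(1.80)
        assert q.df == 1
        assert q.pvalue == pytest.approx(0.1797, abs=2e-4)

    def test_identical_ratios_zero_q(self):
        df = equal_weight_instruments([0.3, 0.3, 0.3])
        est = mr.ivw_fixed(df)
        q = mr.cochran_q(df, est)
        assert q.q == pytest.approx(0.0, abs=1e-12)
        assert q.pvalue == pytest.approx(1.0)

    def test_duplication_doubles_q(self, two_ratio_instruments):
        est = mr.ivw_fixed(two_ratio_instruments)
        q1 = mr.cochran_q(two_ratio_instruments, est)
        doubled = pd.concat([two_ratio_instruments] * 2, ignore_index=True)
        doubled["variant_id"] = [f"v{i}" for i in range(4)]
        est2 = mr.ivw_fixed(doubled)
        q2 = mr.cochran_q(doubled, est2)
        assert q2.q == pytest.approx(2 * q1.q)
        assert q2.df == 3

    def test_size_mismatch_rejected(self, two_ratio_instruments):
        est = mr.ivw_fixed(two_ratio_instruments)
        with pytest.raises(ValueError):
            mr.cochran_q(equal_weight_instruments([0.1, 0.2, 0.3]), est)


class TestEgger:
    def test_exact_line_through_origin(self):
        df = pd.DataFrame(
            {
                "beta_exp": [0.1, 0.2, 0.3],
                "se_exp": [0.01] * 3,
                "beta_out": [0.01, 0.02, 0.03],
                "se_out": [0.05] * 3,
            }
        )
        res = mr.mr_egger(df)
        assert res.slope.beta == pytest.approx(0.1, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_constant_shift_moves_intercept_only(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "beta_exp": rng.uniform(0.05, 0.3, 10),
                "se_exp": [0.01] * 10,
                "beta_out": rng.normal(0, 0.02, 10),
                "se_out": rng.uniform(0.02, 0.05, 10),
            }
        )
        base = mr.mr_egger(df)
        shifted = df.copy()
        shifted["beta_out"] += 0.05
        res = mr.mr_egger(shifted)
        assert res.intercept == pytest.approx(base.intercept + 0.05, abs=1e-10)
        assert res.slope.beta == pytest.approx(base.slope.beta, abs=1e-10)

    def test_orientation_makes_it_flip_invariant(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "beta_exp": rng.uniform(0.05, 0.3, 8),
                "se_exp": [0.01] * 8,
                "beta_out": rng.normal(0.02, 0.03, 8),
                "se_out": rng.uniform(0.02, 0.05, 8),
            }
        )
        flipped = df.copy()
        flipped.loc[::2, ["beta_exp", "beta_out"]] *= -1
        a, b = mr.mr_egger(df), mr.mr_egger(flipped)
        assert a.slope.beta == pytest.approx(b.slope.beta)
        assert a.intercept == pytest.approx(b.intercept)

    def test_too_few_instruments(self, two_ratio_instruments):
        with pytest.raises(ValueError):
            mr.mr_egger(two_ratio_instruments)


class TestWeightedMedian:
    def test_equal_weights_interpolation(self):
        df = equal_weight_instruments([0.1, 0.2, 0.9])
        est = mr.weighted_median(df, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_identical_ratios(self):
        df = equal_weight_instruments([0.4, 0.4, 0.4], se_out=0.01)
        est = mr.weighted_median(df, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.4)
        assert est.se < 0.05

    def test_outlier_with_minority_weight(self):
        """A 49%-weight outlier leaves the estimate near the majority cluster."""
        n_valid = 20
        ratios = np.concatenate([np.linspace(0.18, 0.22, n_valid), [5.0]])
        # equal per-valid weights summing to 51%, outlier carries 49%
        w_valid = 0.51 / n_valid
        bx = np.sqrt(np.concatenate([np.full(n_valid, w_valid), [0.49]]))
        df = pd.DataFrame(
            {
                "beta_exp": bx,
                "se_exp": np.full(n_valid + 1, 1e-8),
                "beta_out": ratios * bx,
                "se_out": np.ones(n_valid + 1),
            }
        )
        est = mr.weighted_median(df, n_boot=200, seed=1)
        ivw = mr.ivw_fixed(df)
        assert 0.15 < est.beta < 0.35
        assert ivw.beta > 2.0  # IVW is dragged to the outlier; the median is not

    def test_seed_reproducibility(self):
        df = equal_weight_instruments([0.1, 0.3, 0.5, 0.7], se_out=0.1)
        a = mr.weighted_median(df, n_boot=300, seed=9)
        b = mr.weighted_median(df, n_boot=300, seed=9)
        assert a == b

    def test_low_boot_warns(self):
        df = equal_weight_instruments([0.1, 0.2, 0.3])
        with pytest.warns(UserWarning):
            mr.weighted_median(df, n_boot=50, seed=1)


class TestWeightedMode:
    def test_cluster_dominates(self):
        df = equal_weight_instruments([0.10, 0.11, 0.12, 0.50], se_out=0.05)
        est = mr.weighted_mode(df, phi=1.0, n_boot=200, seed=1)
        assert 0.10 <= est.beta <= 0.12 + 1e-6

    def test_single_cluster(self):
        df = equal_weight_instruments([0.3, 0.3, 0.3], se_out=0.05)
        est = mr.weighted_mode(df, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.3)

    def test_translation_equivariance(self):
        base = [0.05, 0.1, 0.12, 0.6]
        delta = 0.25
        df1 = equal_weight_instruments(base, se_out=0.05)
        df2 = equal_weight_instruments([r + delta for r in base], se_out=0.05)
        a = mr.weighted_mode(df1, n_boot=100, seed=4)
        b = mr.weighted_mode(df2, n_boot=100, seed=4)
        assert b.beta - a.beta == pytest.approx(delta, abs=1e-9)


class TestLeaveOneOut:
    def test_identical_instruments_identical_estimates(self):
        df = equal_weight_instruments([0.3, 0.3, 0.3])
        full = mr.ivw_fixed(df)
        loo = mr.leave_one_out(df)
        assert len(loo) == 3
        np.testing.assert_allclose(loo["beta"], full.beta)

    def test_single_outlier_detected(self):
        # five concordant instruments and one gross outlier with large weight
        ratios = [0.5, 0.5, 0.5, 0.5, 0.5, 4.0]
        df = equal_weight_instruments(ratios, se_out=0.3)
        full = mr.ivw_fixed(df)
        loo = mr.leave_one_out(df)
        shifts = np.abs(loo["beta"] - full.beta) > 2 * full.se
        assert int(shifts.sum()) == 1
        assert loo.loc[shifts, "omitted_variant"].iloc[0] == "v5"

    def test_output_length(self):
        df = equal_weight_instruments(np.linspace(0, 1, 7))
        df = df[df["beta_exp"] != 0]
        assert len(mr.leave_one_out(df)) == len(df)


class TestRescale:
    def test_decrement_scaled_or(self):
        est = mr.make_estimate("ivw_fixed", 0.661, 0.05, 26)
        scaled = mr.rescale_estimate(est, np.log(0.70))
        assert scaled.odds_ratio == pytest.approx(0.790, abs=1.5e-3)
        assert scaled.or_ci_low == pytest.approx(0.763, abs=2e-3)
        assert scaled.or_ci_high == pytest.approx(0.818, abs=2e-3)

    def test_null_effect_or_one(self):
        est = mr.make_estimate("ivw_fixed", 0.0, 0.1, 5)
        assert mr.rescale_estimate(est, -2.7).odds_ratio == 1.0

    def test_pvalue_invariant(self):
        est = mr.make_estimate("ivw_fixed", 0.2, 0.05, 5)
        assert mr.rescale_estimate(est, np.log(0.7)).pvalue == pytest.approx(est.pvalue)

    def test_zero_scale_rejected(self):
        est = mr.make_estimate("ivw_fixed", 0.2, 0.05, 5)
        with pytest.raises(ValueError):
            mr.rescale_estimate(est, 0.0)


class TestEstimateInvariants:
    def test_ci_and_p_consistency(self):
        est = mr.make_estimate("ivw_fixed", 0.3, 0.1, 4)
        assert est.ci_low == pytest.approx(0.3 - 1.959964 * 0.1)
        assert est.ci_high == pytest.approx(0.3 + 1.959964 * 0.1)
        assert est.pvalue == pytest.approx(2 * stats.norm.sf(3.0))
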