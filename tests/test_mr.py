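"""Univariable estimators against closed-form and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrmediate import (egger, funnel_data, ivw, leave_one_out, wald_ratios,
                       weighted_median)
from mrmediate.summary_io import HarmonizedSet

from conftest import make_harmonized


class TestWaldRatios:
    def test_closed_form(self):
        h = make_harmonized([0.5], [0.1], beta_exp=[0.2])
        wr = wald_ratios(h)
        assert wr["ratio"].iloc[0] == pytest.approx(0.5)
        assert wr["ratio_se"].iloc[0] == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        h = make_harmonized([0.0], [0.1])
        assert wald_ratios(h)["ratio"].iloc[0] == 0.0

    def test_simultaneous_sign_flip_invariance(self):
        h = make_harmonized([0.5], [0.1], beta_exp=[0.2])
        hf = make_harmonized([0.5], [0.1], beta_exp=[-0.2])  # (-0.2, -0.1)
        assert (wald_ratios(h)["ratio"].iloc[0]
                == wald_ratios(hf)["ratio"].iloc[0] == pytest.approx(0.5))

    def test_zero_exposure_beta_raises(self):
        h = make_harmonized([0.5, 0.2], [0.1, 0.1])
        h.rows.loc[1, "beta_exp"] = 0.0
        with pytest.raises(ValueError, match="rs1"):
            wald_ratios(h)


class TestIvw:
    def test_equal_ratios_give_zero_q(self):
        est, het = ivw(make_harmonized([0.5, 0.5], [0.1, 0.2]))
        assert est.beta == pytest.approx(0.5)
        assert het.q == pytest.approx(0.0, abs=1e-24)

    def test_two_snp_hand_oracle(self):
        # weights 1/0.2^2=25 and 1/0.1^2=100 -> (25*0.5+100*0.4)/125 = 0.42
        est, _ = ivw(make_harmonized([0.5, 0.4], [0.2, 0.1]), model="fixed")
        assert est.beta == pytest.approx(0.42, abs=1e-8)
        assert est.se == pytest.approx(125 ** -0.5, abs=1e-8)

    def test_fixed_and_mre_share_point_estimate(self):
        h = make_harmonized([0.3, 0.5, 0.9, 0.1], [0.1, 0.2, 0.15, 0.3])
        f, _ = ivw(h, model="fixed")
        m, _ = ivw(h, model="multiplicative_random")
        assert f.beta == m.beta
        assert m.se >= f.se

    def test_single_instrument_degenerates_to_wald(self):
        est, het = ivw(make_harmonized([0.7], [0.2]))
        assert est.method == "wald"
        assert est.beta == pytest.approx(0.7)
        assert est.se == pytest.approx(0.2)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_row_sign_flip_invariance(self, seed):
        """Flipping (beta_exp, beta_out) jointly on any subset of rows is a
        pure re-orientation and must not move any estimator."""
        rng = np.random.default_rng(seed)
        n = 6
        ratios = rng.normal(0.4, 0.2, n)
        ses = rng.uniform(0.05, 0.3, n)
        be = rng.uniform(0.05, 0.2, n)
        h = make_harmonized(ratios, ses, beta_exp=be)
        flip = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        h2 = make_harmonized(ratios, ses, beta_exp=be * flip)
        for model in ("fixed", "multiplicative_random"):
            a, qa = ivw(h, model=model)
            b, qb = ivw(h2, model=model)
            assert a.beta == pytest.approx(b.beta, rel=1e-12)
            assert qa.q == pytest.approx(qb.q, rel=1e-9, abs=1e-12)
        ea, _, _ = egger(h)
        eb, _, _ = egger(h2)
        assert ea.beta == pytest.approx(eb.beta, rel=1e-9)


class TestEgger:
    def test_exact_line_recovers_slope_and_intercept(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(0.5 + 0.1 / be, np.full(4, 0.2), beta_exp=be)
        # beta_out = 0.1 + 0.5*beta_exp exactly
        est, pleio, het = egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert pleio.intercept == pytest.approx(0.1, abs=1e-10)
        assert het.q == pytest.approx(0.0, abs=1e-18)

    def test_line_through_origin_has_null_intercept(self):
        be = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(np.full(3, 0.5), np.full(3, 0.2), beta_exp=be)
        _, pleio, _ = egger(h)
        assert pleio.intercept == pytest.approx(0.0, abs=1e-12)
        assert pleio.pval == pytest.approx(1.0, abs=1e-6)

    def test_weighted_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0.05, 0.3, 6)
        y = 0.05 + 0.4 * x + rng.normal(0, 0.02, 6)
        se_out = rng.uniform(0.05, 0.2, 6)
        h = make_harmonized(y / x, se_out / x, beta_exp=x)
        est, pleio, _ = egger(h)
        # independent solve of the 2x2 weighted normal equations
        w = 1 / se_out ** 2
        a = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x ** 2).sum()]])
        b = np.array([(w * y).sum(), (w * x * y).sum()])
        intercept, slope = np.linalg.solve(a, b)
        assert est.beta == pytest.approx(slope, abs=1e-8)
        assert pleio.intercept == pytest.approx(intercept, abs=1e-8)

    def test_refuses_fewer_than_three_instruments(self):
        with pytest.raises(ValueError, match=">= 3"):
            egger(make_harmonized([0.5, 0.4], [0.1, 0.1]))


def grid_oracle_weighted_median(ratios, weights):
    """Invert the weighted-percentile interpolant by bisection on its
    cumulative-probability definition (independent of the implementation,
    which inverts it analytically)."""
    order = np.argsort(ratios)
    v, w = np.asarray(ratios, float)[order], np.asarray(weights, float)[order]
    p = (np.cumsum(w) - 0.5 * w) / w.sum()

    def cdf(x):
        return np.interp(x, v, p, left=0.0, right=1.0)

    lo, hi = v[0], v[-1]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cdf(mid) < 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        est = weighted_median(make_harmonized([0.3, 0.5, 0.7], [0.1, 0.1, 0.1]),
                              seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_dominant_weight_returns_dominant_ratio(self):
        # middle ratio carries 60% of total weight, flanks symmetric
        ses = 1 / np.sqrt(np.array([0.2, 0.6, 0.2]))
        est = weighted_median(make_harmonized([0.3, 0.7, 0.9], ses), seed=1)
        assert est.beta == pytest.approx(0.7, abs=1e-10)

    def test_unequal_weights_match_grid_oracle(self):
        ratios = [0.12, 0.35, 0.50, 0.61, 0.92]
        ses = [0.30, 0.10, 0.22, 0.15, 0.40]
        est = weighted_median(make_harmonized(ratios, ses), seed=1)
        w = 1 / np.asarray(ses) ** 2
        assert est.beta == pytest.approx(
            grid_oracle_weighted_median(ratios, w), abs=1e-8)

    def test_bootstrap_se_reproducible_with_seed(self):
        h = make_harmonized([0.3, 0.5, 0.7, 0.4], [0.1, 0.2, 0.1, 0.3],
                            se_exp=0.05)
        a = weighted_median(h, n_boot=300, seed=7)
        b = weighted_median(h, n_boot=300, seed=7)
        assert a.se == b.se > 0

    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(make_harmonized([0.3, 0.5, 0.7], [0.1] * 3))


class TestDiagnostics:
    def test_identical_ratios_loo_all_equal_full(self):
        h = make_harmonized([0.5, 0.5, 0.5], [0.1, 0.2, 0.15])
        full, _ = ivw(h)
        loo = leave_one_out(h)
        assert len(loo) == 3
        assert np.allclose(loo["loo_beta"], full.beta)
        assert not loo["influential"].any()

    def test_gross_outlier_produces_largest_shift(self):
        ratios = [0.5] * 10 + [5.0]
        h = make_harmonized(ratios, [0.1] * 11)
        full, _ = ivw(h)
        loo = leave_one_out(h)
        shifts = (loo["loo_beta"] - full.beta).abs()
        assert shifts.idxmax() == 10  # the planted outlier's omission
        assert len(loo) == 11

    def test_funnel_precisions_consistent_with_wald_ratios(self):
        h = make_harmonized([0.4, 0.6], [0.1, 0.2], beta_exp=[0.2, 0.3])
        f = funnel_data(h)
        wr = wald_ratios(h)
        assert np.allclose(f["precision"], 1 / wr["ratio_se"])
        assert len(f) == 2

    def test_equal_se_and_exposure_magnitude_give_equal_precision(self):
        h = make_harmonized([0.4, -0.6], [0.1, 0.1], beta_exp=[0.2, -0.2])
        f = funnel_data(h)
        assert f["precision"].iloc[0] == pytest.approx(f["precision"].iloc[1])


class TestHomogeneousAgreement:
    def test_all_estimators_agree_when_ratios_identical(self):
        h = make_harmonized([0.5] * 4, [0.1, 0.2, 0.15, 0.12],
                            beta_exp=[0.1, 0.2, 0.3, 0.4])
        est_i, het = ivw(h)
        est_e, _, _ = egger(h)
        est_m = weighted_median(h, seed=1)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert est_i.beta == pytest.approx(0.5, abs=1e-12)
        assert est_m.beta == pytest.approx(0.5, abs=1e-12)
        # Egger on exactly proportional data: slope = ratio, intercept 0
        assert est_e.beta == pytest.approx(0.5, abs=1e-9)
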