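"""Causal estimators: Wald ratios, IVW, Egger, weighted median, LOO."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_hset, random_hset
from mrkit.estimators import (
    egger,
    format_estimate,
    format_or_ci,
    ivw,
    ivw_arrays,
    leave_one_out,
    wald_ratio,
    weighted_median,
    weighted_median_arrays,
)
from mrkit.exceptions import DomainError, InsufficientInstrumentsError


class TestWaldRatio:
    def test_direct_division(self):
        hset = make_hset([0.05], [0.01], [-0.002], [0.001])
        est = wald_ratio(hset.instruments[0])
        assert est.beta == pytest.approx(-0.04)
        assert est.se == pytest.approx(0.02)

    def test_zero_outcome_effect(self):
        hset = make_hset([0.05], [0.01], [0.0], [0.001])
        assert wald_ratio(hset.instruments[0]).beta == 0.0

    def test_sign_symmetry(self):
        hset = make_hset([-0.1], [0.01], [0.004], [0.002])
        est = wald_ratio(hset.instruments[0])
        assert est.beta == pytest.approx(-0.04)
        assert est.se == pytest.approx(0.02)

    def test_zero_exposure_effect_rejected(self):
        hset = make_hset([0.0], [0.01], [0.004], [0.002])
        with pytest.raises(DomainError):
            wald_ratio(hset.instruments[0])


class TestIVW:
    def test_three_instrument_worked_example(self):
        hset = make_hset(
            bx=[0.1, 0.2, 0.1], sx=[0.01] * 3,
            by=[0.01, 0.018, 0.012], sy=[0.01, 0.01, 0.02],
        )
        est, _ = ivw(hset, model="fixed")
        assert est.beta == pytest.approx(49.0 / 525.0, rel=1e-12)
        assert est.se == pytest.approx(525.0**-0.5, rel=1e-12)

    def test_identical_ratios_give_zero_q_and_equal_ses(self):
        c = 0.7
        bx = np.array([0.05, 0.1, 0.2])
        hset = make_hset(bx, [0.01] * 3, c * bx, [0.01, 0.02, 0.03])
        fixed, het_f = ivw(hset, model="fixed")
        random, het_r = ivw(hset, model="random")
        assert fixed.beta == pytest.approx(c, rel=1e-12)
        assert het_f.q_stat == pytest.approx(0.0, abs=1e-20)
        assert random.se == fixed.se  # max(1, sqrt(Q/df)) clamps at 1

    def test_single_instrument_rejected(self):
        hset = make_hset([0.1], [0.01], [0.01], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(hset)

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(50):
            hset = random_hset(rng, j=8)
            fixed, _ = ivw(hset, model="fixed")
            random, _ = ivw(hset, model="random")
            assert random.se >= fixed.se

    def test_matches_wls_through_origin(self, rng):
        import statsmodels.api as sm

        for _ in range(25):
            hset = random_hset(rng, j=12)
            bx, _, by, sy = hset.arrays()
            fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
            est, _ = ivw(hset, model="fixed")
            assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_equals_weighted_mean_of_wald_ratios(self, rng):
        for _ in range(25):
            hset = random_hset(rng, j=9)
            bx, _, by, sy = hset.arrays()
            w = bx**2 / sy**2
            ratios = by / bx
            est, _ = ivw(hset, model="fixed")
            assert est.beta == pytest.approx(np.average(ratios, weights=w), abs=1e-10)

    def test_q_zero_iff_ratios_equal(self, rng):
        bx = np.array([0.05, 0.1, 0.2, 0.15])
        hset_eq = make_hset(bx, [0.01] * 4, 0.3 * bx, [0.01] * 4)
        _, het = ivw(hset_eq)
        assert het.q_stat == pytest.approx(0.0, abs=1e-18)
        hset_ne = make_hset(bx, [0.01] * 4, 0.3 * bx + [0, 0, 0.01, 0], [0.01] * 4)
        _, het_ne = ivw(hset_ne)
        assert het_ne.q_stat > 1e-6


class TestEgger:
    def test_exact_linear_data_recovered(self, rng):
        bx = rng.uniform(0.05, 0.3, 10)
        by = 0.005 + 0.5 * bx
        hset = make_hset(bx, [0.01] * 10, by, rng.uniform(0.005, 0.05, 10))
        est, pleio = egger(hset)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert pleio.intercept == pytest.approx(0.005, abs=1e-10)

    def test_orientation_invariance(self, rng):
        """Negating both betas of any instrument (allele relabel) leaves
        Egger unchanged."""
        hset = random_hset(rng, j=8)
        bx, sx, by, sy = hset.arrays()
        flip = rng.random(8) < 0.5
        sign = np.where(flip, -1.0, 1.0)
        hset2 = make_hset(bx * sign, sx, by * sign, sy)
        e1, p1 = egger(hset)
        e2, p2 = egger(hset2)
        assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
        assert p1.intercept == pytest.approx(p2.intercept, rel=1e-12)

    def test_matches_statsmodels_wls_when_overdispersed(self, rng):
        import statsmodels.api as sm

        bx = rng.uniform(0.05, 0.3, 30)
        by = 0.002 + 0.3 * bx + rng.normal(0, 0.05, 30)  # residual scale >> 1
        sy = np.full(30, 0.01)
        hset = make_hset(bx, [0.01] * 30, by, sy)
        est, pleio = egger(hset)
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
        assert fit.scale > 1  # scaling branch active
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert pleio.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.se == pytest.approx(fit.bse[1], rel=1e-10)
        assert pleio.intercept_se == pytest.approx(fit.bse[0], rel=1e-10)

    def test_too_few_instruments_rejected(self):
        hset = make_hset([0.1, 0.2], [0.01] * 2, [0.01, 0.02], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(hset)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        hset = make_hset([0.1] * 3, [0.01] * 3, [0.1, 0.2, 0.3], [0.01] * 3)
        est = weighted_median(hset, n_boot=50, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_dominant_instrument_sets_estimate(self):
        # weights proportional to {0.2, 0.6, 0.2}: the middle instrument's
        # cumulative midpoint lands exactly on 0.5
        bx = np.sqrt(np.array([0.2, 0.6, 0.2]))
        hset = make_hset(bx, [0.01] * 3, bx * np.array([1.0, 2.0, 3.0]), [1.0] * 3)
        est = weighted_median(hset, n_boot=50, seed=0)
        assert est.beta == pytest.approx(2.0, rel=1e-12)

    def test_matches_bruteforce_cumulative_grid(self, rng):
        """Independent oracle: explicit bracketing on the cumulative-weight
        grid followed by manual linear interpolation."""
        for _ in range(50):
            hset = random_hset(rng, j=11)
            bx, _, by, sy = hset.arrays()
            ratios, w = by / bx, bx**2 / sy**2
            order = np.argsort(ratios)
            r, wn = ratios[order], w[order] / w.sum()
            s = np.cumsum(wn) - wn / 2
            if 0.5 <= s[0]:
                expected = r[0]
            elif 0.5 >= s[-1]:
                expected = r[-1]
            else:
                k = int(np.searchsorted(s, 0.5)) - 1
                frac = (0.5 - s[k]) / (s[k + 1] - s[k])
                expected = r[k] + frac * (r[k + 1] - r[k])
            assert weighted_median_arrays(bx, by, sy) == pytest.approx(
                expected, rel=1e-10
            )

    def test_estimate_within_ratio_range(self, rng):
        """The interpolated weighted median always lies inside the span of
        the Wald ratios."""
        for _ in range(50):
            hset = random_hset(rng, j=7)
            bx, _, by, sy = hset.arrays()
            est = weighted_median_arrays(bx, by, sy)
            ratios = by / bx
            assert ratios.min() - 1e-12 <= est <= ratios.max() + 1e-12

    def test_bootstrap_deterministic_given_seed(self, rng):
        hset = random_hset(rng, j=10)
        a = weighted_median(hset, n_boot=200, seed=7)
        b = weighted_median(hset, n_boot=200, seed=7)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_resists_directional_pleiotropy_better_than_ivw(self):
        """With 30% of instruments carrying large directional pleiotropy,
        the weighted-median bias stays under a third of the IVW bias."""
        rng = np.random.default_rng(11)
        theta, j, reps = 0.1, 100, 100
        ivw_err, wm_err = [], []
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.2, j)
            sy = np.full(j, 0.002)
            alpha = np.zeros(j)
            alpha[: j // 10 * 3] = 0.02  # 30% invalid, strong positive offsets
            by = theta * bx + alpha + rng.normal(0, sy)
            t, _, _ = ivw_arrays(bx, by, sy)
            ivw_err.append(t - theta)
            wm_err.append(weighted_median_arrays(bx, by, sy) - theta)
        assert abs(np.mean(wm_err)) < abs(np.mean(ivw_err)) / 3


class TestLeaveOneOut:
    def test_identical_ratios_leave_estimate_unchanged(self):
        bx = np.array([0.05, 0.1, 0.2, 0.15])
        hset = make_hset(bx, [0.01] * 4, 0.3 * bx, [0.01] * 4)
        full, _ = ivw(hset)
        for _, est in leave_one_out(hset):
            assert est.beta == pytest.approx(full.beta, rel=1e-12)

    def test_cardinality(self, rng):
        hset = random_hset(rng, j=9)
        assert len(leave_one_out(hset)) == 9

    def test_outlier_has_largest_influence(self, rng):
        bx = rng.uniform(0.05, 0.2, 20)
        sy = np.full(20, 0.002)
        by = 0.1 * bx + rng.normal(0, sy)
        by[7] += 30 * sy[7]  # gross pleiotropic offset
        hset = make_hset(bx, [0.01] * 20, by, sy)
        full, _ = ivw(hset)
        deltas = {vid: abs(est.beta - full.beta) for vid, est in leave_one_out(hset)}
        assert max(deltas, key=deltas.get) == "rs7"


class TestFormatEstimate:
    def test_published_ivw_row(self):
        or_, lo, hi = format_estimate(-0.040, 0.0072)
        assert (round(or_, 2), round(lo, 2), round(hi, 2)) == (0.96, 0.95, 0.97)
        assert format_or_ci(-0.040, 0.0072) == "0.96 (0.95, 0.97)"

    def test_null_effect_symmetric_about_one(self):
        or_, lo, hi = format_estimate(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_width_collapses_to_point(self):
        or_, lo, hi = format_estimate(np.log(2.0), 0.0)
        assert lo == or_ == hi == pytest.approx(2.0, rel=1e-12)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(k=st.floats(0.1, 10), seed=st.integers(0, 2**16))
def test_scale_equivariance(k, seed):
    """Scaling outcome betas/SEs by k scales every estimate by k; scaling
    exposure betas by k divides the estimates by k."""
    rng = np.random.default_rng(seed)
    hset = random_hset(rng, j=8)
    bx, sx, by, sy = hset.arrays()

    out_scaled = make_hset(bx, sx, k * by, k * sy)
    exp_scaled = make_hset(k * bx, sx, by, sy)

    base_ivw, _ = ivw(hset)
    s_ivw, _ = ivw(out_scaled)
    d_ivw, _ = ivw(exp_scaled)
    assert s_ivw.beta == pytest.approx(k * base_ivw.beta, rel=1e-9)
    assert s_ivw.se == pytest.approx(k * base_ivw.se, rel=1e-9)
    assert d_ivw.beta == pytest.approx(base_ivw.beta / k, rel=1e-9)

    base_eg, _ = egger(hset)
    s_eg, _ = egger(out_scaled)
    assert s_eg.beta == pytest.approx(k * base_eg.beta, rel=1e-9)
    assert s_eg.se == pytest.approx(k * base_eg.se, rel=1e-9)

    assert weighted_median_arrays(bx, k * by, k * sy) == pytest.approx(
        k * weighted_median_arrays(bx, by, sy), rel=1e-9
    )
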