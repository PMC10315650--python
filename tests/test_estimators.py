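"""Estimator battery: Wald ratios, IVW, Egger, weighted median, maximum
likelihood, and the cross-estimator invariants."""

import numpy as np
import pytest

from mrchain import (
    InsufficientInstrumentsError,
    all_estimators,
    egger,
    ivw,
    max_likelihood,
    wald_ratios,
    weighted_median,
)
from tests.conftest import make_harmonized


class TestWaldRatios:
    def test_basic_arithmetic(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        r = wald_ratios(h)
        assert r["ratio"].iloc[0] == pytest.approx(0.5)
        assert r["ratio_se"].iloc[0] == pytest.approx(0.2)
        assert r["weight"].iloc[0] == pytest.approx(25.0)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        h = make_harmonized([0.1], [0.01], [0.0], [0.02])
        assert wald_ratios(h)["ratio"].iloc[0] == 0.0

    def test_sign_invariance(self):
        h1 = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.04], [0.02] * 2)
        h2 = make_harmonized([-0.1, -0.2], [0.01] * 2, [-0.05, -0.04], [0.02] * 2)
        np.testing.assert_allclose(
            wald_ratios(h1)["ratio"], wald_ratios(h2)["ratio"]
        )

    def test_zero_exposure_beta_excluded(self):
        h = make_harmonized([0.0, 0.1], [0.01] * 2, [0.05, 0.05], [0.02] * 2)
        assert len(wald_ratios(h)) == 1


class TestIvw:
    def test_two_point_closed_form(self):
        h = make_harmonized([1.0, 1.0], [1e-6] * 2, [0.5, 0.3], [0.2, 0.1])
        res = ivw(wald_ratios(h), mode="fixed")
        assert res.beta == pytest.approx(0.34)
        assert res.se == pytest.approx(0.08944, abs=1e-4)
        assert res.or_value == pytest.approx(np.exp(0.34), rel=1e-12)

    def test_equal_ratios_degenerate(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3, [0.03, 0.06, 0.12], [0.02] * 3)
        r = wald_ratios(h)
        fixed = ivw(r, mode="fixed")
        mre = ivw(r, mode="multiplicative_random_effects")
        assert fixed.beta == pytest.approx(0.3)
        assert fixed.extras["q"] == pytest.approx(0.0, abs=1e-20)
        assert mre.se == pytest.approx(fixed.se)

    def test_insufficient_instruments(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(wald_ratios(h))

    def test_closed_form_equals_wls_through_origin(self):
        """IVW equals no-intercept WLS of beta_out on beta_exp with weights
        1/se_out^2 (independent statsmodels route), to 1e-10."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        for _ in range(100):
            j = rng.integers(3, 20)
            bx = rng.normal(0.08, 0.03, j)
            bx[np.abs(bx) < 0.01] = 0.02
            by = 0.25 * bx + rng.normal(0, 0.02, j)
            sy = rng.uniform(0.005, 0.05, j)
            h = make_harmonized(bx, np.full(j, 0.005), by, sy)
            ours = ivw(wald_ratios(h), mode="fixed")
            ref = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
            assert ours.beta == pytest.approx(ref.params[0], abs=1e-10)

    def test_mre_never_deflates_se(self):
        h = make_harmonized([0.1, 0.1, 0.1], [0.01] * 3, [0.031, 0.03, 0.029], [0.02] * 3)
        r = wald_ratios(h)
        assert ivw(r).se >= ivw(r, mode="fixed").se


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = [0.05, 0.10, 0.20]
        by = [0.4 * b for b in bx]
        res = egger(make_harmonized(bx, [0.01] * 3, by, [0.02] * 3))
        assert res.beta == pytest.approx(0.4, abs=1e-10)
        assert res.extras["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_affine_relationship_recovered(self):
        bx = [0.05, 0.10, 0.20, 0.15]
        by = [0.02 + 0.4 * b for b in bx]
        res = egger(make_harmonized(bx, [0.01] * 4, by, [0.02] * 4))
        assert res.beta == pytest.approx(0.4, abs=1e-10)
        assert res.extras["intercept"] == pytest.approx(0.02, abs=1e-10)

    def test_orientation_invariance(self):
        """Flipping the sign of (beta_exp, beta_out) pairs leaves the Egger
        fit unchanged thanks to the positive-exposure orientation."""
        bx = np.array([0.05, 0.10, 0.20, 0.15])
        by = 0.02 + 0.4 * bx
        res1 = egger(make_harmonized(bx, [0.01] * 4, by, [0.02] * 4))
        res2 = egger(make_harmonized(-bx, [0.01] * 4, -by, [0.02] * 4))
        assert res1.beta == pytest.approx(res2.beta, abs=1e-12)
        assert res1.extras["intercept"] == pytest.approx(res2.extras["intercept"], abs=1e-12)

    def test_coefficients_match_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        bx = rng.uniform(0.03, 0.2, 15)
        by = 0.01 + 0.3 * bx + rng.normal(0, 0.02, 15)
        sy = rng.uniform(0.01, 0.05, 15)
        ours = egger(make_harmonized(bx, np.full(15, 0.005), by, sy))
        ref = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert ours.beta == pytest.approx(ref.params[1], abs=1e-10)
        assert ours.extras["intercept"] == pytest.approx(ref.params[0], abs=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2))


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = make_harmonized([1.0] * 3, [1e-9] * 3, [0.1, 0.2, 0.3], [0.1] * 3)
        res = weighted_median(wald_ratios(h), n_boot=200, seed=1)
        assert res.beta == pytest.approx(0.2)

    def test_unequal_weights_interpolation(self):
        """Weights 0.6/0.2/0.2 on ratios 0.1/0.2/0.3: standardized cumulative
        weights are (0.3, 0.7, 0.9), so interpolating the weighted CDF at 0.5
        lands at 0.1 + (0.5-0.3)/(0.7-0.3)*(0.2-0.1) = 0.15 (hand-derived)."""
        ratios = np.array([0.1, 0.2, 0.3])
        weights = np.array([0.6, 0.2, 0.2])
        ses = 1.0 / np.sqrt(weights)
        h = make_harmonized([1.0] * 3, [1e-9] * 3, ratios, ses)
        res = weighted_median(wald_ratios(h), n_boot=200, seed=1)
        assert res.beta == pytest.approx(0.15)

    def test_bootstrap_seed_determinism(self):
        h = make_harmonized([0.1, 0.2, 0.15, 0.12], [0.01] * 4,
                            [0.03, 0.05, 0.04, 0.02], [0.02] * 4)
        r = wald_ratios(h)
        a = weighted_median(r, n_boot=300, seed=9)
        b = weighted_median(r, n_boot=300, seed=9)
        assert a.beta == b.beta and a.se == b.se


class TestMaxLikelihood:
    def test_single_snp_equals_wald_ratio(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        res = max_likelihood(h)
        assert res.beta == pytest.approx(0.5, abs=1e-8)

    def test_small_exposure_noise_limit_is_fixed_ivw(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.2, 20)
        by = 0.3 * bx + rng.normal(0, 0.01, 20)
        sy = rng.uniform(0.01, 0.03, 20)
        h = make_harmonized(bx, np.full(20, 1e-8), by, sy)
        ml = max_likelihood(h)
        fe = ivw(wald_ratios(h), mode="fixed")
        assert ml.beta == pytest.approx(fe.beta, abs=1e-6)

    def test_clean_simulation_recovery(self, chain, harmonized_xz):
        cfg, *_ , truth = chain
        res = max_likelihood(harmonized_xz)
        fe = ivw(wald_ratios(harmonized_xz), mode="fixed")
        true_xz = truth.beta_xz + truth.beta_xy * truth.beta_yz
        assert abs(res.beta - true_xz) < 3 * res.se + 0.02
        assert res.beta == pytest.approx(fe.beta, abs=0.01)


def test_scale_equivariance_all_estimators():
    """Multiplying all exposure betas and SEs by c divides every causal
    estimate by c."""
    rng = np.random.default_rng(8)
    bx = rng.uniform(0.05, 0.2, 12)
    by = 0.25 * bx + rng.normal(0, 0.01, 12)
    sx = np.full(12, 0.005)
    sy = rng.uniform(0.01, 0.03, 12)
    c = 2.5
    base = all_estimators(make_harmonized(bx, sx, by, sy), seed=3)
    scaled = all_estimators(make_harmonized(c * bx, c * sx, by, sy), seed=3)
    for name in base:
        assert scaled[name].beta == pytest.approx(base[name].beta / c, rel=1e-6), name


def test_estimators_agree_on_clean_simulation(harmonized_xz, chain):
    """All five estimators land within joint Monte-Carlo error of each other
    on a clean (no-pleiotropy) chain."""
    cfg, *_ = chain
    res = all_estimators(harmonized_xz, seed=4)
    betas = {k: v.beta for k, v in res.items()}
    ses = {k: v.se for k, v in res.items()}
    for a in betas:
        for b in betas:
            tol = 3 * np.hypot(ses[a], ses[b]) + 1e-6
            assert abs(betas[a] - betas[b]) < tol, (a, b)


def test_or_and_ci_consistency(harmonized_xz):
    res = ivw(wald_ratios(harmonized_xz))
    assert res.ci_low <= res.or_value <= res.ci_high
    assert res.or_value == pytest.approx(np.exp(res.beta), rel=1e-12)
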