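import numpy as np
import pytest
import sympy as sp
from scipy.stats import chi2

from chainmatch import (
    EfficiencyModel,
    build_theta_mu,
    confidence_region,
    corrected_abundance_curve,
    covariance_sigma,
    estimate_true_abundances,
    simulate_misdetection_counts,
    substructure_probabilities,
    xi_statistic,
)
from chainmatch.correction import detection_patterns
from chainmatch.matching import AbundanceCurve, AbundanceVector


def symbolic_model_k3():
    """The three-channel observation model with symbolic efficiencies."""
    sA, sB, sC = sp.symbols("sA sB sC", positive=True)
    p = {
        "ABC": [sA * sB * sC, sA * sB * (1 - sC), (1 - sA) * sB * sC,
                sA * (1 - sB) * sC, sA * (1 - sB) * (1 - sC),
                (1 - sA) * sB * (1 - sC), (1 - sA) * (1 - sB) * sC,
                (1 - sA) * (1 - sB) * (1 - sC)],
        "AB": [0, sA * sB, 0, 0, sA * (1 - sB), (1 - sA) * sB, 0,
               (1 - sA) * (1 - sB)],
        "BC": [0, 0, sB * sC, 0, 0, sB * (1 - sC), (1 - sB) * sC,
               (1 - sB) * (1 - sC)],
        "A": [0, 0, 0, 0, sA, 0, 0, 1 - sA],
        "B": [0, 0, 0, 0, 0, sB, 0, 1 - sB],
        "C": [0, 0, 0, 0, 0, 0, sC, 1 - sC],
    }
    inv = sp.Matrix([
        [1 / (sA * sB * sC), 0, 0, 0, 0, 0],
        [(sC - 1) / (sA * sB * sC), 1 / (sA * sB), 0, 0, 0, 0],
        [(sA - 1) / (sA * sB * sC), 0, 1 / (sB * sC), 0, 0, 0],
        [(sB - 1) / (sA * sB), (sB - 1) / (sA * sB), 0, 1 / sA, 0, 0],
        [(1 - sA) * (1 - sC) / (sA * sB * sC), (sA - 1) / (sA * sB),
         (sC - 1) / (sB * sC), 0, 1 / sB, 0],
        [(sB - 1) / (sB * sC), 0, (sB - 1) / (sB * sC), 0, 0, 1 / sC],
    ])
    return (sA, sB, sC), p, inv


class TestSubstructureModel:
    def test_pattern_order_k3(self):
        assert detection_patterns(3) == [
            (0, 1, 2), (0, 1), (1, 2), (0, 2), (0,), (1,), (2,), ()]

    def test_theta_k3_credits_split_patterns_to_singlets(self):
        model = build_theta_mu(EfficiencyModel([0.9, 0.9, 0.9]))
        expected = np.array([
            [1, 0, 0, 0, 0, 0, 0, 0],
            [0, 1, 0, 0, 0, 0, 0, 0],
            [0, 0, 1, 0, 0, 0, 0, 0],
            [0, 0, 0, 1, 1, 0, 0, 0],   # W_A: A·C pattern + A pattern
            [0, 0, 0, 0, 0, 1, 0, 0],
            [0, 0, 0, 1, 0, 0, 1, 0],   # W_C: A·C pattern + C pattern
        ])
        assert np.array_equal(model.theta, expected)

    @pytest.mark.parametrize("s", [(0.7, 0.8, 0.9), (0.31, 0.95, 0.5)])
    def test_probabilities_and_inverse_match_closed_forms(self, s):
        """Generated p vectors, μ and (Θμ)⁻¹ equal the symbolic model."""
        syms, p_sym, inv_sym = symbolic_model_k3()
        subs = dict(zip(syms, s))
        model = build_theta_mu(EfficiencyModel(s))
        for i, name in enumerate(model.structures):
            expected = [float(sp.sympify(v).subs(subs)) for v in p_sym[name]]
            np.testing.assert_allclose(model.p_vectors[i], expected, atol=1e-12)
        inv_expected = np.array(inv_sym.subs(subs)).astype(float)
        np.testing.assert_allclose(model.inverse_map, inv_expected, atol=1e-10)

    def test_pair_probabilities_at_half_efficiency(self):
        p = substructure_probabilities("AB", EfficiencyModel([0.5, 0.5, 0.5]))
        # (AB, A, B, none) each 1/4; all other patterns impossible
        assert p[1] == p[4] == p[5] == p[7] == pytest.approx(0.25)
        assert p.sum() == pytest.approx(1.0)

    def test_full_efficiency_is_deterministic(self):
        p = substructure_probabilities("ABC", EfficiencyModel([1, 1, 1]))
        assert p[0] == 1.0 and p[1:].sum() == 0.0

    def test_each_p_vector_sums_to_one_general_k(self, rng):
        for k in (2, 3, 4, 5):
            model = build_theta_mu(EfficiencyModel(rng.uniform(0.3, 1.0, k)))
            np.testing.assert_allclose(model.p_vectors.sum(axis=1), 1.0)

    def test_k4_split_pattern_credits_runs(self):
        # pattern A·CD of a true ABCD chain yields one A singlet + one CD pair
        model = build_theta_mu(EfficiencyModel([0.9] * 4))
        patterns = model.patterns
        col = patterns.index((0, 2, 3))
        a_row = model.structures.index("A")
        cd_row = model.structures.index("CD")
        assert model.theta[a_row, col] == 1
        assert model.theta[cd_row, col] == 1
        assert model.theta[:, col].sum() == 2

    def test_zero_efficiency_rejected(self):
        with pytest.raises(ValueError, match="non-invertible"):
            EfficiencyModel([0.9, 0.0, 0.9])


class TestEstimator:
    def test_full_efficiency_returns_observations_exactly(self):
        W = np.array([7, 3, 2, 5, 1, 4], float)
        est = estimate_true_abundances(W, EfficiencyModel([1, 1, 1]))
        np.testing.assert_allclose(est.n_hat, W)

    def test_single_triplet_estimate_row(self):
        W = np.array([1, 0, 0, 0, 0, 0], float)
        est = estimate_true_abundances(W, EfficiencyModel([0.95] * 3))
        assert est.n_hat[0] == pytest.approx(1 / 0.95**3)
        assert est.n_hat[1] == pytest.approx((0.95 - 1) / 0.95**3)
        assert est.n_hat[1] == pytest.approx(-0.05832, abs=1e-4)

    def test_unbiased_under_multinomial_model_k3(self):
        rng = np.random.default_rng(11)
        s = rng.uniform(0.5, 1.0, 3)
        n = rng.integers(20, 500, size=6).astype(float)
        model = build_theta_mu(EfficiencyModel(s))
        draws = np.stack([model.inverse_map @ simulate_misdetection_counts(
            n, model, rng) for _ in range(5000)])
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - n) <= 3 * se + 1e-9)

    def test_unbiased_under_multinomial_model_k2(self):
        rng = np.random.default_rng(13)
        model = build_theta_mu(EfficiencyModel([0.8, 0.6]))
        assert model.theta_mu.shape == (3, 3)
        n = np.array([200.0, 80.0, 120.0])  # AB, A, B
        draws = np.stack([model.inverse_map @ simulate_misdetection_counts(
            n, model, rng) for _ in range(5000)])
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - n) <= 3 * se)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            estimate_true_abundances(np.ones(5), EfficiencyModel([0.9] * 3))


class TestCovarianceAndXi:
    def test_sigma_matches_empirical_covariance_of_observations(self):
        rng = np.random.default_rng(21)
        n = np.array([500, 50, 50, 50, 50, 50], float)
        model = build_theta_mu(EfficiencyModel([0.95] * 3))
        sigma = covariance_sigma(n, model)
        W = np.stack([simulate_misdetection_counts(n, model, rng)
                      for _ in range(4000)])
        emp = np.cov(W.T)
        expected = model.theta @ sigma @ model.theta.T
        np.testing.assert_allclose(emp, expected, rtol=0.25, atol=3.0)

    def test_sigma_psd_and_negative_entries_floored(self):
        model = build_theta_mu(EfficiencyModel([0.9] * 3))
        sigma = covariance_sigma(np.array([10, -5, 3, 0, 1, 2.0]), model)
        np.testing.assert_allclose(sigma, sigma.T)
        assert np.all(np.linalg.eigvalsh(sigma) >= -1e-10)

    def test_xi_zero_at_center_and_nonnegative(self, rng):
        model = build_theta_mu(EfficiencyModel([0.9, 0.8, 0.7]))
        n_hat = np.array([100, 20, 30, 10, 10, 10], float)
        xi0, r = xi_statistic(n_hat, n_hat, model)
        assert xi0 == pytest.approx(0.0, abs=1e-9)
        assert r == 6
        for _ in range(10):
            n0 = n_hat + rng.normal(0, 5, 6)
            xi, _ = xi_statistic(n_hat, n0, model)
            assert xi >= 0

    def test_xi_approximately_chi_squared(self):
        """Upper-tail calibration of Ξ at moderate sample size."""
        rng = np.random.default_rng(31)
        n = np.array([500, 50, 50, 50, 50, 50], float)
        model = build_theta_mu(EfficiencyModel([0.95] * 3))
        xis = []
        for _ in range(2000):
            W = simulate_misdetection_counts(n, model, rng)
            n_hat = model.inverse_map @ W
            xis.append(xi_statistic(n_hat, n, model)[0])
        frac = np.mean(np.asarray(xis) <= chi2.ppf(0.9, 6))
        assert frac == pytest.approx(0.9, abs=0.03)


class TestConfidenceRegion:
    def test_interval_halfwidth_is_ellipsoid_slice(self):
        W = np.array([400, 60, 55, 45, 50, 40], float)
        est = estimate_true_abundances(W, EfficiencyModel([0.9, 0.85, 0.95]))
        region = confidence_region(est, alpha=0.1)
        crit = chi2.ppf(0.9, est.rank)
        for j, name in enumerate(est.structures):
            lo, hi = region.intervals[name]
            half = np.sqrt(crit / est.quad_form[j, j])
            assert hi - lo == pytest.approx(2 * half, rel=1e-9)
            assert (lo + hi) / 2 == pytest.approx(est.n_hat[j])
        # the slice endpoints lie exactly on the ellipsoid boundary
        j = 0
        n0 = est.n_hat.copy()
        n0[j] += (region.intervals[est.structures[0]][1] - est.n_hat[0])
        xi, _ = xi_statistic(est.n_hat, n0, est.model, est.sigma)
        assert xi == pytest.approx(crit, rel=1e-9)

    def test_region_shrinks_to_point_as_alpha_grows(self):
        W = np.array([400, 60, 55, 45, 50, 40], float)
        est = estimate_true_abundances(W, EfficiencyModel([0.9] * 3))
        wide = confidence_region(est, alpha=0.1)
        narrow = confidence_region(est, alpha=0.999)
        # widths scale with sqrt of the chi-squared critical value
        shrink = np.sqrt(chi2.ppf(1 - 0.999, est.rank) / chi2.ppf(0.9, est.rank))
        for name in est.structures:
            w_wide = wide.intervals[name][1] - wide.intervals[name][0]
            w_narrow = narrow.intervals[name][1] - narrow.intervals[name][0]
            assert w_narrow == pytest.approx(w_wide * shrink, rel=1e-9)

    def test_alpha_out_of_range_rejected(self):
        est = estimate_true_abundances(np.ones(6), EfficiencyModel([0.9] * 3))
        with pytest.raises(ValueError, match="alpha"):
            confidence_region(est, 1.5)


class TestCorrectedCurve:
    @staticmethod
    def _curve(vectors):
        k = 3
        vecs = [AbundanceVector(k=k, w=dict(zip(
            ["ABC", "AB", "BC", "A", "B", "C"], v))) for v in vectors]
        return AbundanceCurve(k=k, t_grid=np.arange(1.0, 1.0 + len(vecs)),
                              vectors=vecs, mode="I")

    def test_full_efficiency_leaves_curve_unchanged(self):
        curve = self._curve([[5, 2, 1, 0, 3, 1], [8, 1, 0, 0, 2, 0]])
        corrected = corrected_abundance_curve(curve, EfficiencyModel([1, 1, 1]))
        np.testing.assert_allclose(corrected.n_hat, corrected.w)

    def test_bands_contain_point_estimate(self):
        curve = self._curve([[50, 10, 8, 5, 6, 4], [60, 8, 6, 4, 5, 3]])
        corrected = corrected_abundance_curve(
            curve, EfficiencyModel([0.9, 0.9, 0.9]), alpha=0.1)
        assert np.all(corrected.lo <= corrected.n_hat + 1e-12)
        assert np.all(corrected.hi >= corrected.n_hat - 1e-12)

    def test_correction_raises_underestimated_chain_counts(self):
        # thinning removes chain members, deflating observed full-chain
        # counts; the corrected estimate should move back above W
        curve = self._curve([[80, 12, 11, 9, 3, 8]])
        corrected = corrected_abundance_curve(
            curve, EfficiencyModel([0.95] * 3), alpha=0.1)
        assert corrected.n_hat[0, 0] > corrected.w[0, 0]
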