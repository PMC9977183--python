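"""Projected variance, integration, divergence, and angle statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from morphollr import synthetic
from morphollr.llr import (
    angle_significance,
    divergence_magnitude,
    divergence_vector,
    ecology_axis,
    integration_effect_size,
    ks_angles_vs_null,
    p_matrix,
    projected_variance,
    random_angle_null,
    random_unit_vectors,
    random_vector_null,
    relative_eigenvalue_variance,
    trend_surface,
    vector_angle,
)
from conftest import random_psd


class TestPMatrix:
    def test_two_point_covariance(self):
        v = np.array([1.0, -2.0, 0.5])
        X = np.stack([v, -v])
        P = p_matrix(X, "sp")
        np.testing.assert_allclose(P.P, 2 * np.outer(v, v), atol=1e-12)
        assert np.linalg.matrix_rank(P.P) == 1

    def test_identical_specimens_give_zero(self):
        X = np.tile([0.3, 0.7], (5, 1))
        np.testing.assert_allclose(p_matrix(X).P, 0.0, atol=1e-15)

    def test_single_specimen_errors(self):
        with pytest.raises(ValueError):
            p_matrix(np.array([[1.0, 2.0]]))

    def test_estimates_known_gaussian(self, rng):
        k = 4
        P0 = random_psd(rng, k)
        L = np.linalg.cholesky(P0 + 1e-12 * np.eye(k))
        err = []
        for n in (50, 5000):
            X = rng.standard_normal((n, k)) @ L.T
            err.append(np.linalg.norm(p_matrix(X).P - P0))
        assert err[1] < err[0]  # Frobenius error shrinks with n


class TestProjectedVariance:
    def test_identity_matrix_any_direction(self, rng):
        k = 6
        x = random_unit_vectors(k, 1, rng)[0]
        assert projected_variance(np.eye(k), x) == pytest.approx(1.0)
        assert projected_variance(np.eye(k), x, normalize=True) == pytest.approx(1 / k)

    def test_leading_eigenvector_attains_lambda_max(self, rng):
        P = random_psd(rng, 5)
        evals, evecs = np.linalg.eigh(P)
        assert projected_variance(P, evecs[:, -1]) == pytest.approx(evals[-1])

    def test_matches_double_loop_sum(self, rng):
        P = random_psd(rng, 6)
        x = random_unit_vectors(6, 1, rng)[0]
        brute = sum(x[i] * P[i, j] * x[j] for i in range(6) for j in range(6))
        assert projected_variance(P, x) == pytest.approx(brute, abs=1e-12)

    def test_rayleigh_bounds(self, rng):
        P = random_psd(rng, 7)
        lo, hi = np.linalg.eigvalsh(P)[[0, -1]]
        for x in random_unit_vectors(7, 25, rng):
            v = projected_variance(P, x)
            assert lo - 1e-10 <= v <= hi + 1e-10

    def test_orthonormal_basis_fractions_sum_to_one(self, rng):
        P = random_psd(rng, 5)
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        total = sum(projected_variance(P, Q[:, j], normalize=True) for j in range(5))
        assert total == pytest.approx(1.0)

    def test_non_unit_direction_renormalized_with_warning(self, rng):
        P = random_psd(rng, 4)
        x = np.array([2.0, 0, 0, 0])
        with pytest.warns(UserWarning, match="unit"):
            v = projected_variance(P, x)
        assert v == pytest.approx(P[0, 0])


class TestRandomVectorNull:
    def test_mean_approaches_trace_over_k(self, rng):
        """E[x'Px] over uniform unit x is tr(P)/k (analytic expectation)."""
        P = random_psd(rng, 8)
        mean, vals = random_vector_null(P, n_vectors=20000, seed=1)
        assert mean == pytest.approx(np.trace(P) / 8, rel=0.02)

    def test_isotropic_p_gives_constant(self):
        mean, vals = random_vector_null(3.2 * np.eye(5), n_vectors=100, seed=0)
        np.testing.assert_allclose(vals, 3.2, atol=1e-10)

    def test_seeded_reproducibility(self, rng):
        P = random_psd(rng, 4)
        _, v1 = random_vector_null(P, n_vectors=50, seed=9)
        _, v2 = random_vector_null(P, n_vectors=50, seed=9)
        np.testing.assert_array_equal(v1, v2)


class TestIntegration:
    def test_isotropic_vrel_zero(self):
        assert relative_eigenvalue_variance(2.5 * np.eye(6)) == pytest.approx(0.0)

    def test_rank_one_vrel_one(self, rng):
        v = rng.standard_normal(5)
        assert relative_eigenvalue_variance(np.outer(v, v)) == pytest.approx(1.0)

    @pytest.mark.parametrize("r", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_two_trait_equal_variance_vrel_is_r_squared(self, r):
        """For 2 traits of equal variance and correlation r, Vrel = r^2
        (verified against direct eigenvalue computation)."""
        P = np.array([[1.0, r], [r, 1.0]])
        lam = np.linalg.eigvalsh(P)
        var = np.mean((lam - lam.mean()) ** 2)
        vmax = lam.sum() ** 2 * (2 - 1) / 4
        assert relative_eigenvalue_variance(P) == pytest.approx(var / vmax)
        assert relative_eigenvalue_variance(P) == pytest.approx(r**2, abs=1e-12)

    def test_effect_size_grows_with_sample_size(self, rng):
        from morphollr.llr import PMatrix

        P = np.array([[1.0, 0.5], [0.5, 1.0]])
        _, z10 = integration_effect_size(PMatrix("a", P, 10))
        _, z100 = integration_effect_size(PMatrix("a", P, 100))
        assert z100 > z10

    def test_k1_undefined(self):
        with pytest.raises(ValueError):
            relative_eigenvalue_variance(np.array([[2.0]]))


class TestDivergence:
    def test_identical_scores_zero(self):
        assert divergence_magnitude(np.ones(4), np.ones(4)) == 0.0

    def test_pythagoras(self):
        assert divergence_magnitude(np.array([3.0, 4.0]), np.zeros(2)) == 5.0

    def test_matches_sqrt_sum_oracle(self, rng):
        a, b = rng.standard_normal(6), rng.standard_normal(6)
        brute = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
        assert divergence_magnitude(a, b) == pytest.approx(brute, abs=1e-12)

    def test_vector_is_componentwise_difference(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        d, u = divergence_vector(a, b)
        np.testing.assert_allclose(d, a - b, atol=1e-15)
        np.testing.assert_allclose(u, (a - b) / np.linalg.norm(a - b))

    def test_zero_divergence_flagged(self):
        d, u = divergence_vector(np.ones(3), np.ones(3))
        assert u is None

    def test_displacement_along_crea_has_zero_angle(self, rng):
        crea = random_unit_vectors(10, 1, rng)[0]
        anc = rng.standard_normal(10)
        d, u = divergence_vector(anc + 0.3 * crea, anc)
        assert vector_angle(d, crea) == pytest.approx(0.0, abs=1e-6)


class TestVectorAngle:
    def test_closed_forms(self):
        assert vector_angle([1, 0], [1, 0]) == pytest.approx(0.0)
        assert vector_angle([1, 0], [0, 1]) == pytest.approx(90.0)
        assert vector_angle([1, 0], [1, 1]) == pytest.approx(45.0)
        assert vector_angle([1, 0], [-1, 0]) == pytest.approx(180.0)
        assert vector_angle([1, 0], [-1, 0], fold=True) == pytest.approx(0.0)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            vector_angle([0, 0], [1, 0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10**6), st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    def test_symmetric_and_scale_invariant(self, seed, s1, s2):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal(5), r.standard_normal(5)
        t1 = vector_angle(a, b)
        assert t1 == pytest.approx(vector_angle(b, a), abs=1e-9)
        assert t1 == pytest.approx(vector_angle(s1 * a, s2 * b), abs=1e-7)
        assert 0.0 <= t1 <= 180.0


class TestAngleNull:
    def test_two_dimensional_angles_uniform(self):
        """At k=2 the angle between random unit vectors is uniform on
        [0, 180] (known closed form; KS test must not reject at alpha=0.01)."""
        null = random_angle_null(2, n=10000, seed=3)
        stat = kstest(null.samples / 180.0, "uniform")
        assert stat.pvalue > 0.01

    def test_high_dimensional_mean_near_ninety(self):
        null = random_angle_null(75, n=10000, seed=4)
        assert abs(null.mean - 90.0) < 0.5

    def test_sd_decreases_with_dimension(self):
        sds = [random_angle_null(k, n=10000, seed=5).sd for k in (3, 10, 30, 75)]
        assert all(b < a for a, b in zip(sds, sds[1:]))


class TestAngleSignificance:
    def test_identical_vectors_minimum_p(self, rng):
        a = rng.standard_normal(10)
        theta, P = angle_significance(a, a, n_random=999, seed=0)
        assert theta == pytest.approx(0.0, abs=1e-8)
        assert P == pytest.approx(1 / 1000)

    def test_orthogonal_observation_p_half(self, rng):
        """A 90-degree observed angle sits at the null's median: P ~ 0.5."""
        a = np.zeros(40)
        a[0] = 1.0
        b = np.zeros(40)
        b[1] = 1.0
        _, P = angle_significance(a, b, n_random=9999, seed=1)
        assert P == pytest.approx(0.5, abs=0.03)

    def test_seeded_reproducibility(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        r1 = angle_significance(a, b, n_random=999, seed=7)
        r2 = angle_significance(a, b, n_random=999, seed=7)
        assert r1 == r2


class TestKS:
    def test_matches_max_ecdf_gap_oracle(self, rng):
        obs = rng.normal(80, 10, 50)
        null = random_angle_null(20, n=2000, seed=2)
        D, P = ks_angles_vs_null(obs, null)
        # brute-force max ECDF gap over the pooled support
        pool = np.concatenate([obs, null.samples])
        gaps = [
            abs((obs <= v).mean() - (null.samples <= v).mean()) for v in pool
        ]
        assert D == pytest.approx(max(gaps), abs=1e-12)

    def test_degenerate_observed_angles(self):
        null = random_angle_null(20, n=2000, seed=2)
        D, P = ks_angles_vs_null(np.zeros(10), null)
        assert D > 0.99
        assert P < 1e-6

    def test_type_one_error_near_nominal(self):
        """Observed angles drawn from the null itself: rejection rate at
        alpha=0.05 within 3 MC SE over 400 replicates."""
        null = random_angle_null(15, n=5000, seed=11)
        rej = 0
        n_sim = 400
        for s in range(n_sim):
            r = np.random.default_rng(3000 + s)
            obs = r.choice(null.samples, size=100, replace=True)
            _, P = ks_angles_vs_null(obs, null)
            rej += P <= 0.05
        rate = rej / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3 * se + 1e-9

    def test_too_few_angles_errors(self):
        null = random_angle_null(5, n=100, seed=0)
        with pytest.raises(ValueError):
            ks_angles_vs_null(np.array([10.0, 20.0]), null)


class TestEcologyAxis:
    def test_recovers_linear_diet_direction(self, rng):
        """Diet generated as an exact linear readout of position along a
        direction u: recovered axis within 5 degrees of u."""
        tree = synthetic.simulate_tree(60, seed=12)
        C = tree.vcv()
        L = np.linalg.cholesky(C)
        k = 8
        u = random_unit_vectors(k, 1, rng)[0]
        Y = L @ rng.standard_normal((60, k)) * 0.1
        Y += 0.5 * np.outer(L @ rng.standard_normal(60), u)  # strong diet axis
        grass = 50 + 40 * (Y @ u)
        axis, fit = ecology_axis(Y, grass, C)
        assert vector_angle(axis, u, fold=True) < 5.0

    def test_constant_diet_errors(self, rng):
        tree = synthetic.simulate_tree(12, seed=1)
        Y = rng.standard_normal((12, 4))
        with pytest.raises(ValueError, match="constant"):
            ecology_axis(Y, np.full(12, 50.0), tree.vcv())

    def test_missing_diet_species_excluded(self, rng):
        tree = synthetic.simulate_tree(30, seed=13)
        Y = rng.standard_normal((30, 4))
        grass = rng.uniform(0, 100, 30)
        grass[:10] = np.nan
        axis, fit = ecology_axis(Y, grass, tree, taxa=tree.taxa)
        assert fit.Yw.shape[0] == 20


class TestTrendSurface:
    def test_exact_quadratic_recovered(self, rng):
        S = rng.standard_normal((30, 2))
        coef0 = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.25])
        u, v = S[:, 0], S[:, 1]
        y = coef0 @ np.stack([np.ones(30), u, v, u**2, u * v, v**2])
        surf = trend_surface(S, y, n_perm=49, seed=0)
        np.testing.assert_allclose(surf.coefficients, coef0, atol=1e-8)
        assert surf.R2 == pytest.approx(1.0)
        np.testing.assert_allclose(surf(u, v), y, atol=1e-8)

    def test_constant_response_flat_surface(self, rng):
        S = rng.standard_normal((20, 2))
        surf = trend_surface(S, np.full(20, 7.0), n_perm=49, seed=0)
        np.testing.assert_allclose(surf.coefficients[1:], 0.0, atol=1e-8)

    def test_matches_generic_least_squares_oracle(self, rng):
        S = rng.standard_normal((25, 2))
        y = rng.standard_normal(25)
        surf = trend_surface(S, y, n_perm=49, seed=0)
        u, v = S[:, 0], S[:, 1]
        B = np.column_stack([np.ones(25), u, v, u**2, u * v, v**2])
        coef_oracle = np.linalg.solve(B.T @ B, B.T @ y)
        np.testing.assert_allclose(surf.coefficients, coef_oracle, atol=1e-8)
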