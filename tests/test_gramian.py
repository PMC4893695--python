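import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctrlgram import (ContractError, GibbsGramianModel, SimConfig,
                      direction_gain, eigen_analysis, empirical_gramian,
                      finite_horizon_gramian, make_linear_system,
                      quadratic_gibbs_gramian, simulate_noise_response)

from conftest import random_stable_linear


class TestEmpiricalGramian:
    def test_two_point_second_moment(self):
        res = empirical_gramian(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        np.testing.assert_allclose(res.matrix, [[1, 0], [0, 0]], atol=1e-15)

    def test_ou_matches_T_times_linear_gramian(self, ou_endpoints_10k):
        res = empirical_gramian(ou_endpoints_10k)
        target = finite_horizon_gramian([[-1]], [[1]], 1.0).G_tau
        dev = abs(res.matrix[0, 0] - target[0, 0])
        assert dev < 3 * res.std_errors[0, 0] + 0.01 * target[0, 0]

    def test_mean_centering_identity(self, rng):
        """origin moment = mean-centered moment + mean outer product."""
        x = rng.normal(size=(500, 3)) + [1.0, -2.0, 0.5]
        origin = empirical_gramian(x, center="origin").matrix
        centered = empirical_gramian(x, center="mean").matrix
        mu = x.mean(axis=0)
        np.testing.assert_allclose(origin, centered + np.outer(mu, mu),
                                   atol=1e-12)

    def test_given_center_vector(self, rng):
        x = rng.normal(size=(200, 2))
        c = np.array([0.5, -0.5])
        res = empirical_gramian(x, center=c)
        dev = x - c
        np.testing.assert_allclose(res.matrix, dev.T @ dev / 200, atol=1e-12)

    def test_degenerate_ensemble_gives_zero_matrix(self):
        x = np.zeros((50, 3))
        res = empirical_gramian(x)
        np.testing.assert_array_equal(res.matrix, np.zeros((3, 3)))
        assert np.isinf(res.condition_number)

    def test_model_results_summary(self, ou_endpoints_10k):
        res = GibbsGramianModel(ou_endpoints_10k).fit()
        text = res.summary()
        assert "cond(G)" in text and "eigenvalue" in text
        assert res.meta["temperature"] == 1.0

    def test_linear_system_equivalence_many_fixtures(self, rng):
        """MC Gramian = T * G_tau within 5 MC standard errors (n <= 4)."""
        T = 0.5
        for k in range(3):
            n = int(rng.integers(2, 5))
            spec = random_stable_linear(rng, n)
            sys_ = make_linear_system(spec)
            cfg = SimConfig(tau=1.0, dt=0.005, temperature=T,
                            n_paths=20000, seed=100 + k)
            res = empirical_gramian(simulate_noise_response(sys_, cfg))
            target = T * finite_horizon_gramian(spec.A, spec.B, 1.0).G_tau
            dev = np.abs(res.matrix - target)
            assert np.all(dev < 5 * res.std_errors
                          + 0.01 * np.max(np.abs(target)))


class TestQuadraticGibbsGramian:
    @pytest.mark.parametrize("Q", [np.eye(3), np.array([[4.0]]),
                                   np.array([[2.0, 1.0], [1.0, 2.0]])])
    def test_returns_Q_exactly(self, Q):
        np.testing.assert_array_equal(quadratic_gibbs_gramian(Q), Q)

    def test_non_pd_rejected(self):
        with pytest.raises(ContractError):
            quadratic_gibbs_gramian(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_gaussian_sampling_cross_check(self, rng):
        """Sampling the Gibbs density of (1/2) x^T Q^{-1} x recovers Q."""
        Q = np.array([[2.0, 1.0], [1.0, 2.0]])
        x = rng.multivariate_normal(np.zeros(2), Q, size=100000)
        emp = x.T @ x / x.shape[0]
        se = (x[:, :, None] * x[:, None, :]).std(axis=0) / np.sqrt(x.shape[0])
        assert np.all(np.abs(emp - quadratic_gibbs_gramian(Q)) < 3 * se)


class TestEigenAnalysis:
    def test_diagonal_examples(self):
        vals, vecs, cond = eigen_analysis(np.diag([3.0, 1.0]))
        np.testing.assert_allclose(vals, [3, 1])
        np.testing.assert_allclose(np.abs(vecs[:, 0]), [1, 0], atol=1e-15)
        assert cond == pytest.approx(3.0)
        assert eigen_analysis(np.diag([4.0, 2.0]))[2] == pytest.approx(2.0)

    def test_reconstruction(self, rng):
        M = rng.normal(size=(5, 5))
        M = (M + M.T) / 2
        vals, vecs, _ = eigen_analysis(M)
        np.testing.assert_allclose((vecs * vals) @ vecs.T, M, atol=1e-10)

    def test_asymmetric_rejected(self):
        with pytest.raises(ContractError):
            eigen_analysis(np.array([[1.0, 1.0], [0.0, 1.0]]))

    def test_sign_convention(self, rng):
        M = rng.normal(size=(4, 4))
        _, vecs, _ = eigen_analysis((M + M.T) / 2)
        for j in range(4):
            i = np.argmax(np.abs(vecs[:, j]))
            assert vecs[i, j] > 0


class TestDirectionGain:
    def test_axis_directions(self):
        G = np.diag([3.0, 1.0])
        assert direction_gain(G, np.array([1.0, 0.0])) == pytest.approx(3.0)
        assert direction_gain(G, np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_non_unit_rejected(self):
        with pytest.raises(ContractError):
            direction_gain(np.eye(2), np.array([1.0, 1.0]))

    def test_grid_search_maximum_at_principal_eigenvector(self, rng):
        """Brute-force angle grid confirms the principal-eigenvector law."""
        for _ in range(5):
            M = rng.normal(size=(2, 2))
            G = M @ M.T + 0.1 * np.eye(2)
            vals, vecs, _ = eigen_analysis(G)
            if vals[0] - vals[1] < 0.05 * vals[0]:
                continue     # nearly degenerate: direction ill-conditioned
            angles = np.linspace(0.0, np.pi, 3600, endpoint=False)
            gains = [direction_gain(G, np.array([np.cos(a), np.sin(a)]))
                     for a in angles]
            best = angles[int(np.argmax(gains))]
            principal = np.arctan2(vecs[1, 0], vecs[0, 0]) % np.pi
            diff = min(abs(best - principal),
                       np.pi - abs(best - principal))
            assert np.degrees(diff) < 0.1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rayleigh_quotient_bounds(self, seed):
        """e^T G e lies in [lambda_min, lambda_max] for every unit e."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        M = rng.normal(size=(n, n))
        G = M @ M.T
        vals, _, _ = eigen_analysis(G)
        e = rng.normal(size=n)
        e /= np.linalg.norm(e)
        gain = direction_gain(G, e)
        assert vals[-1] - 1e-9 <= gain <= vals[0] + 1e-9
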