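import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import subspace_angles
from scipy.stats import ortho_group

from ctrlgram import (ContractError, ProjectionBasis, SimConfig,
                      empirical_gramian, fhn_benchmark_spec, galerkin_reduce,
                      make_fhn_network, make_linear_system, pod_basis,
                      pod_basis_from_snapshots, projection_error,
                      simulate_noise_response)
from ctrlgram.fhn import T_HIGH
from ctrlgram.systems import LinearSystemSpec

from conftest import random_stable_linear


def random_orthonormal(rng, n, k):
    M = rng.normal(size=(n, k))
    Q, _ = np.linalg.qr(M)
    return ProjectionBasis(rho=Q[:, :k])


class TestPodBasis:
    def test_diagonal_gramian_selects_top_coordinates(self):
        basis = pod_basis(np.diag([3.0, 2.0, 1.0]), k=2)
        trace = np.trace(basis.rho.T @ np.diag([3.0, 2.0, 1.0]) @ basis.rho)
        assert trace == pytest.approx(5.0)
        assert np.max(np.abs(basis.rho[2, :])) < 1e-12

    def test_discarded_subspace_is_smallest_mode(self):
        basis = pod_basis(np.diag([3.0, 2.0, 1.0]), k=2)
        resid = np.eye(3) - basis.rho @ basis.rho.T
        e3 = np.array([0.0, 0.0, 1.0])
        np.testing.assert_allclose(resid @ e3, e3, atol=1e-12)

    @pytest.mark.parametrize("k", [0, 4, 5])
    def test_k_out_of_range(self, k):
        with pytest.raises(ContractError):
            pod_basis(np.eye(4), k=k)

    def test_beats_random_bases_on_trace(self, rng):
        M = rng.normal(size=(4, 4))
        G = M @ M.T
        best = pod_basis(G, k=2)
        best_trace = np.trace(best.rho.T @ G @ best.rho)
        for _ in range(1000):
            rnd = random_orthonormal(rng, 4, 2)
            assert np.trace(rnd.rho.T @ G @ rnd.rho) <= best_trace + 1e-10


class TestProjectionError:
    def test_aligned_points_have_zero_error(self):
        basis = ProjectionBasis(rho=np.array([[1.0], [0.0]]))
        mean_sq, trace_form = projection_error(
            np.array([[1.0, 0.0], [-1.0, 0.0]]), basis)
        assert mean_sq == pytest.approx(0.0, abs=1e-15)
        assert trace_form == pytest.approx(0.0, abs=1e-15)

    def test_single_off_axis_point(self):
        basis = ProjectionBasis(rho=np.array([[1.0], [0.0]]))
        mean_sq, _ = projection_error(np.array([[1.0, 1.0]]), basis)
        assert mean_sq == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_residual_equals_trace_form(self, seed):
        """Sample-level identity: mean residual = Trace((I - P) M_hat)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        k = int(rng.integers(1, n))
        x = rng.normal(size=(int(rng.integers(2, 50)), n))
        basis = random_orthonormal(rng, n, k)
        mean_sq, trace_form = projection_error(x, basis)
        assert abs(mean_sq - trace_form) < 1e-10 * max(1.0, mean_sq)

    def test_pod_error_equals_tail_eigenvalue(self, rng):
        """2-D linear fixture: optimal k=1 error is exactly lambda_2."""
        spec = random_stable_linear(rng, 2)
        sys_ = make_linear_system(spec)
        cfg = SimConfig(tau=1.0, dt=0.01, temperature=1.0, n_paths=20000,
                        seed=77)
        ens = simulate_noise_response(sys_, cfg)
        res = empirical_gramian(ens)
        basis = pod_basis(res, k=1)
        mean_sq, _ = projection_error(ens, basis)
        assert mean_sq == pytest.approx(res.eigenvalues[1], rel=1e-10)
        for _ in range(500):
            rnd = random_orthonormal(rng, 2, 1)
            assert projection_error(ens, rnd)[0] >= mean_sq - 1e-12

    def test_eigen_and_snapshot_routes_agree(self, rng):
        """POD from the Gramian and from raw snapshots span the same space."""
        x = rng.normal(size=(300, 4)) * np.array([3.0, 2.0, 1.0, 0.5])
        from_gram = pod_basis(empirical_gramian(x), k=2)
        from_snap = pod_basis_from_snapshots(x, k=2)
        angles = subspace_angles(from_gram.rho, from_snap.rho)
        assert np.max(angles) < 1e-8


class TestGalerkin:
    def test_full_order_rotation_is_exact(self, rng):
        spec = random_stable_linear(rng, 3)
        sys_ = make_linear_system(spec)
        Q = ortho_group.rvs(3, random_state=np.random.default_rng(5))
        basis = ProjectionBasis(rho=Q)
        reduced = galerkin_reduce(sys_, basis)
        cfg = SimConfig(tau=1.0, dt=0.01, temperature=1.0, n_paths=100,
                        seed=13)
        full = simulate_noise_response(sys_, cfg)
        red = simulate_noise_response(reduced, cfg)
        np.testing.assert_allclose(red.endpoints @ Q.T, full.endpoints,
                                   atol=1e-10)

    def test_linear_reduction_matrices(self, rng):
        spec = random_stable_linear(rng, 4)
        sys_ = make_linear_system(spec)
        basis = random_orthonormal(rng, 4, 2)
        reduced = galerkin_reduce(sys_, basis)
        Ar = basis.rho.T @ spec.A @ basis.rho
        Br = basis.rho.T @ spec.B
        for _ in range(5):
            z = rng.normal(size=2)
            np.testing.assert_allclose(reduced.drift(z), Ar @ z, atol=1e-12)
        np.testing.assert_allclose(reduced.input_map(np.zeros(2)), Br,
                                   atol=1e-12)

    def test_fhn_reduced_moment_matches_dominant_subspace(self):
        """k=2 Galerkin model reproduces the full second moment on span(rho).

        The tolerance (25% relative Frobenius) reflects Galerkin
        approximation error on a strongly nonlinear system; the check is
        structural, not tight.
        """
        sys_ = make_fhn_network(fhn_benchmark_spec())
        fit_cfg = SimConfig(tau=120.0, dt=0.005, temperature=T_HIGH,
                            n_paths=1000, seed=201)
        full_ens = simulate_noise_response(sys_, fit_cfg)
        res = empirical_gramian(full_ens)
        basis = pod_basis(res, k=2)
        reduced = galerkin_reduce(sys_, basis)
        red_cfg = SimConfig(tau=120.0, dt=0.005, temperature=T_HIGH,
                            n_paths=2000, seed=202)
        red_ens = simulate_noise_response(reduced, red_cfg)
        M_red_lifted = basis.rho @ (
            red_ens.endpoints.T @ red_ens.endpoints / red_cfg.n_paths
        ) @ basis.rho.T
        P = basis.rho @ basis.rho.T
        M_full_proj = P @ res.matrix @ P
        err = np.linalg.norm(M_red_lifted - M_full_proj) \
            / np.linalg.norm(M_full_proj)
        assert err < 0.25
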