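import numpy as np
import pytest

from ctrlgram import (LinearSystemSpec, SimConfig, make_linear_system,
                      make_ou_system, simulate_noise_response)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ou_system():
    """Stable scalar Ornstein-Uhlenbeck fixture (theta = 1, unit channel)."""
    return make_ou_system(theta=1.0, sigma_channel=1.0, x0=0.0)


@pytest.fixture
def double_integrator():
    return make_linear_system(LinearSystemSpec(A=[[0, 1], [0, 0]],
                                               B=[[0], [1]]))


@pytest.fixture(scope="session")
def ou_endpoints_10k():
    """10000 OU noise-response endpoints at T=1, tau=1 (session-cached)."""
    system = make_ou_system(theta=1.0)
    cfg = SimConfig(tau=1.0, dt=0.005, temperature=1.0, n_paths=10000,
                    seed=2024)
    return simulate_noise_response(system, cfg)


def random_stable_linear(rng, n, m=1, margin=0.3):
    """Random linear system with spectrum strictly in the left half plane."""
    M = rng.normal(size=(n, n))
    shift = np.max(np.linalg.eigvals(M).real) + margin
    A = M - shift * np.eye(n)
    B = rng.normal(size=(n, m))
    return LinearSystemSpec(A=A, B=B)
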