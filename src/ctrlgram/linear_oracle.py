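"""Closed-form linear-system ground truth.

For dx/dt = A x + B u the finite-horizon controllability Gramian

    G_tau = int_0^tau e^{A s} B B^T e^{A^T s} ds

is computed exactly (up to ``expm`` accuracy) with Van Loan's block
matrix-exponential method and cross-checked against integration of the
differential Lyapunov equation dG/dt = A G + G A^T + B B^T, G(0) = 0.

The companion quantities are the minimum-energy controllability function
L(x_f) = (1/2) d^T G_tau^{-1} d with d = x_f - e^{A tau} x0, the open-loop
minimum-energy input u(t) = B^T e^{A^T (tau - t)} G_tau^{-1} d, and the
exact mean/covariance of the input-channel noise response
(mean = e^{A tau} x0, covariance = T * G_tau).  These serve as the oracles
against which the Monte-Carlo machinery is validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np
from scipy import linalg
from scipy.integrate import solve_ivp

from .exceptions import (ContractError, NumericalConsistencyError,
                         ShapeError, UnreachableDirectionError)

__all__ = ["LinearGramian", "finite_horizon_gramian",
           "min_energy_controllability_function", "min_energy_input",
           "linear_noise_moments"]

#: Condition numbers above this mark G_tau as numerically singular.
SINGULARITY_COND = 1e12


@dataclass
class LinearGramian:
    """Finite-horizon controllability Gramian with its generating data."""

    G_tau: np.ndarray
    A: np.ndarray
    B: np.ndarray
    tau: float

    @property
    def n(self) -> int:
        return self.G_tau.shape[0]

    def condition_number(self) -> float:
        vals = linalg.eigvalsh(self.G_tau)
        if vals[0] <= 0:
            return np.inf
        return vals[-1] / vals[0]


def _check_AB(A, B):
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] != A.shape[1]:
        raise ShapeError(f"A must be square, got {A.shape}")
    if B.shape[0] != A.shape[0]:
        raise ShapeError(
            f"B has {B.shape[0]} rows but A is {A.shape[0]}x{A.shape[1]}")
    return A, B


def _gramian_expm_block(A, B, tau):
    """Van Loan block method: exp([[ -A, BB^T], [0, A^T]] tau) yields G_tau."""
    n = A.shape[0]
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = -A
    M[:n, n:] = B @ B.T
    M[n:, n:] = A.T
    F = linalg.expm(M * tau)
    F22 = F[n:, n:]             # = e^{A^T tau}
    F12 = F[:n, n:]
    return F22.T @ F12


def _gramian_lyapunov_ode(A, B, tau, rtol=1e-10, atol=1e-12):
    n = A.shape[0]
    BBt = B @ B.T

    def rhs(t, g):
        G = g.reshape(n, n)
        return (A @ G + G @ A.T + BBt).ravel()

    sol = solve_ivp(rhs, (0.0, tau), np.zeros(n * n), rtol=rtol, atol=atol,
                    method="RK45")
    return sol.y[:, -1].reshape(n, n)


def finite_horizon_gramian(A, B, tau: float,
                           cross_check: bool = True) -> LinearGramian:
    """Compute G_tau = int_0^tau e^{As} B B^T e^{A^T s} ds.

    Uses the matrix-exponential block method; when ``cross_check`` is true
    the result is verified against differential-Lyapunov integration to a
    1e-6 relative tolerance (raising ``NumericalConsistencyError`` on
    disagreement).
    """
    A, B = _check_AB(A, B)
    if tau <= 0:
        raise ContractError(f"tau must be positive, got {tau}")
    G = _gramian_expm_block(A, B, tau)
    G = (G + G.T) / 2.0
    if cross_check:
        G_ode = _gramian_lyapunov_ode(A, B, tau)
        scale = max(np.max(np.abs(G)), 1e-300)
        if np.max(np.abs(G - G_ode)) > 1e-6 * scale:
            raise NumericalConsistencyError(
                "expm-block and Lyapunov-ODE Gramians disagree beyond 1e-6")
    return LinearGramian(G_tau=G, A=A, B=B, tau=tau)


def _solve_gramian(G: LinearGramian, d: np.ndarray) -> np.ndarray:
    vals, vecs = linalg.eigh(G.G_tau)
    lam_max = vals[-1]
    if lam_max <= 0 or vals[0] < lam_max / SINGULARITY_COND:
        null_mask = vals < max(lam_max, 1e-300) / SINGULARITY_COND
        raise UnreachableDirectionError(
            "G_tau is numerically singular; the listed null-space directions "
            "are unreachable by finite-energy input",
            null_basis=vecs[:, null_mask])
    return linalg.solve(G.G_tau, d, assume_a="pos")


def min_energy_controllability_function(G: LinearGramian, x_f,
                                        x0=None) -> float:
    """Minimum control effort (1/2) inf int |u|^2 dt to reach x_f at tau.

    Equals (1/2) d^T G_tau^{-1} d with d = x_f - e^{A tau} x0 (the free
    response is the zero-effort reference point; x0 defaults to 0).
    """
    x_f = np.asarray(x_f, dtype=float).reshape(-1)
    if x_f.shape != (G.n,):
        raise ShapeError(f"x_f has shape {x_f.shape}, expected ({G.n},)")
    if x0 is None:
        x0 = np.zeros(G.n)
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    d = x_f - linalg.expm(G.A * G.tau) @ x0
    return float(0.5 * d @ _solve_gramian(G, d))


def min_energy_input(A, B, tau: float, x_f, x0=None
                     ) -> Callable[[float], np.ndarray]:
    """Open-loop minimum-energy input steering x0 to x_f over [0, tau].

    Returns u(t) = B^T e^{A^T (tau - t)} G_tau^{-1} (x_f - e^{A tau} x0).
    Driving the noise-free system with it reaches x_f, with realized energy
    (1/2) int |u|^2 dt equal to the minimum-energy controllability function.
    """
    A, B = _check_AB(A, B)
    G = finite_horizon_gramian(A, B, tau, cross_check=False)
    x_f = np.asarray(x_f, dtype=float).reshape(-1)
    if x0 is None:
        x0 = np.zeros(A.shape[0])
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    d = x_f - linalg.expm(A * tau) @ x0
    w = _solve_gramian(G, d)

    def u(t: float) -> np.ndarray:
        return B.T @ linalg.expm(A.T * (tau - t)) @ w

    return u


def linear_noise_moments(A, B, T: float, tau: float, x0=None
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Exact endpoint moments of the linear input-channel noise response.

    mean = e^{A tau} x0, covariance = T * G_tau.
    """
    A, B = _check_AB(A, B)
    if x0 is None:
        x0 = np.zeros(A.shape[0])
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    mean = linalg.expm(A * tau) @ x0
    if T == 0:
        cov = np.zeros((A.shape[0], A.shape[0]))
    else:
        cov = T * finite_horizon_gramian(A, B, tau, cross_check=False).G_tau
    return mean, cov
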