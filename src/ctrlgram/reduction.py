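"""Controllability-aware model reduction (POD / Galerkin projection).

A reduced model of order k < n is defined by an orthonormal basis
rho in Pi_k = {rho : rho^T rho = I_k}: the reduced state is z = rho^T x and
the original state is recovered as x ~ rho z.  Two classical selection
routes coincide on noise-response data:

* the snapshot (POD) route minimises the mean squared projection error
  (1/N) sum_k |(I - rho rho^T) x_k|^2 over the ensemble;
* the Gramian route maximises Trace(rho^T G rho) over Pi_k, solved by the
  top-k eigenvectors of G.

At the sample level the two objectives are linked by the exact identity

    (1/N) sum_k |(I - rho rho^T) x_k|^2 = Trace((I - rho rho^T) M_hat),

with M_hat the empirical second moment of the snapshots, so the minimising
subspace is the span of the dominant eigenvectors of the estimated Gibbs
Gramian — the projection keeps exactly the directions reachable with small
control energy.  The Galerkin projection then yields the reduced dynamics
dz/dt = rho^T f(rho z) + rho^T g(rho z) u.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .exceptions import ContractError, ShapeError
from .gramian import GramianResult, empirical_gramian
from .sde import PathEnsemble
from .systems import DynamicalSystem

__all__ = ["ProjectionBasis", "pod_basis", "pod_basis_from_snapshots",
           "projection_error", "galerkin_reduce"]


@dataclass
class ProjectionBasis:
    """An n x k matrix with orthonormal columns (element of Pi_k)."""

    rho: np.ndarray

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.ndim != 2:
            raise ShapeError("rho must be a 2-D (n, k) matrix")
        k = self.rho.shape[1]
        gram = self.rho.T @ self.rho
        if np.max(np.abs(gram - np.eye(k))) > 1e-10:
            raise ContractError(
                "rho columns are not orthonormal within 1e-10")

    @property
    def n(self) -> int:
        return self.rho.shape[0]

    @property
    def k(self) -> int:
        return self.rho.shape[1]

    def project(self, x: np.ndarray) -> np.ndarray:
        """Reduced coordinates z = rho^T x (acts on the last axis)."""
        return np.asarray(x, dtype=float) @ self.rho

    def lift(self, z: np.ndarray) -> np.ndarray:
        """Lift reduced coordinates back: x ~ rho z (acts on the last axis)."""
        return np.asarray(z, dtype=float) @ self.rho.T


def pod_basis(gramian: Union[GramianResult, np.ndarray],
              k: int) -> ProjectionBasis:
    """Top-k eigenvector basis of a Gramian — the Trace(rho^T G rho) maximiser.

    The achieved trace is lambda_1 + ... + lambda_k.  When
    lambda_k = lambda_{k+1} the basis is well defined only as a subspace;
    ties are broken by the eigen-solver ordering.
    """
    if isinstance(gramian, GramianResult):
        n = gramian.n
        vecs = gramian.eigenvectors
    else:
        from .gramian import eigen_analysis
        G = np.asarray(gramian, dtype=float)
        n = G.shape[0]
        _, vecs, _ = eigen_analysis(G)
    if not (1 <= k < n):
        raise ContractError(f"k must satisfy 1 <= k < n = {n}, got {k}")
    return ProjectionBasis(rho=vecs[:, :k].copy())


def pod_basis_from_snapshots(snapshots: np.ndarray, k: int,
                             center: Union[str, np.ndarray] = "origin"
                             ) -> ProjectionBasis:
    """Method-of-snapshots POD: top-k eigenvectors of the snapshot second
    moment.  ``snapshots`` is (N, n); multi-time snapshot matrices should be
    stacked along the first axis before the call."""
    res = empirical_gramian(np.asarray(snapshots, dtype=float), center=center)
    return pod_basis(res, k)


def projection_error(ensemble: Union[PathEnsemble, np.ndarray],
                     basis: ProjectionBasis) -> Tuple[float, float]:
    """Mean squared projection residual of the snapshots onto span(rho).

    Returns ``(residual, trace_form)`` where

        residual   = (1/N) sum_k |(I - rho rho^T) x_k|^2,
        trace_form = Trace((I - rho rho^T) M_hat),

    with M_hat the origin-centered empirical second moment.  The two are the
    same quantity by an exact algebraic identity and must agree to 1e-10.
    """
    x = ensemble.endpoints if isinstance(ensemble, PathEnsemble) else \
        np.asarray(ensemble, dtype=float)
    if x.ndim != 2:
        raise ShapeError("snapshots must be a 2-D (N, n) array")
    if x.shape[1] != basis.n:
        raise ShapeError(
            f"snapshots have dimension {x.shape[1]}, basis expects {basis.n}")
    rho = basis.rho
    resid = x - (x @ rho) @ rho.T
    mean_sq = float(np.mean(np.sum(resid ** 2, axis=1)))
    M = x.T @ x / x.shape[0]
    P = np.eye(basis.n) - rho @ rho.T
    trace_form = float(np.trace(P @ M))
    return mean_sq, trace_form


def galerkin_reduce(system: DynamicalSystem,
                    basis: ProjectionBasis) -> DynamicalSystem:
    """Galerkin projection of a system onto span(rho).

    The reduced order-k model has drift z -> rho^T f(rho z), input map
    z -> rho^T g(rho z) and initial state rho^T x0; the lifting map
    z -> rho z is attached as ``meta['lift']`` (and via the basis itself at
    ``meta['basis']``).  For a linear system the reduction is again linear
    with A_r = rho^T A rho, B_r = rho^T B.
    """
    if basis.n != system.n:
        raise ShapeError(
            f"basis is for dimension {basis.n}, system has n = {system.n}")
    rho = basis.rho
    k = basis.k

    def drift(z):
        return system.drift(np.asarray(z, dtype=float) @ rho.T) @ rho

    if system.constant_input:
        Br = rho.T @ system.input_map(system.x0)

        def input_map(z):
            return Br
    else:
        def input_map(z):
            return rho.T @ system.input_map(basis.lift(z))

    reduced = DynamicalSystem(
        n=k, m=system.m, drift=drift, input_map=input_map,
        x0=rho.T @ system.x0,
        labels=[f"z{i + 1}" for i in range(k)],
        linear=system.linear, constant_input=system.constant_input,
        vectorized=system.vectorized,
        A=rho.T @ system.A @ rho if system.linear and system.A is not None
        else None,
        B=rho.T @ system.B if system.linear and system.B is not None
        else None,
        name=f"{system.name}_galerkin_k{k}",
        meta={"basis": basis, "lift": basis.lift})
    return reduced
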