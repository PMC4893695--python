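"""Gibbs controllability Gramians and their Monte-Carlo estimation.

The Gibbs Gramian of a controllability function L is the second-moment
matrix of the probability density proportional to exp(-L(x)).  For linear
dynamics with the quadratic L(x) = (1/2) x^T G_tau^{-1} x the Gaussian
integral gives back the classical finite-horizon controllability Gramian
G_tau, so the definition is a proper nonlinear extension.

When the system is excited only through its input channel by white noise of
level T, the endpoint density of the uncontrolled dynamics is the Gibbs
density of the stochastic controllability function divided by T.  The
stochastic Gibbs Gramian is therefore the plain second moment of the
noise-response endpoints and is estimated here by Monte Carlo:

    G_hat = (1/N) sum_k (x_k - c)(x_k - c)^T,

with centering c = 0 by default (the second moment about the origin), the
sample mean (travelling-distance variant), or any given reference point.
For linear dynamics with x0 = 0 this estimator converges to T * G_tau.

The estimation surface follows the model/results idiom: build a
:class:`GibbsGramianModel` from an ensemble (or raw endpoints) and call
``fit()`` to obtain a :class:`GramianResult` carrying the matrix, its sorted
eigen-decomposition, Monte-Carlo standard errors, condition number and a
``summary()`` table.  ``empirical_gramian`` is the one-call functional form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import linalg

from .exceptions import ContractError, NumericalConsistencyError, ShapeError
from .sde import PathEnsemble

__all__ = ["GramianResult", "GibbsGramianModel", "empirical_gramian",
           "quadratic_gibbs_gramian", "eigen_analysis", "direction_gain"]

#: Relative eigenvalue floor for PSD repair; more negative values error out.
PSD_CLIP_REL = 1e-10


def _fix_sign(vecs: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each column positive."""
    vecs = vecs.copy()
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs


def eigen_analysis(matrix: np.ndarray):
    """Sorted eigen-decomposition of a symmetric matrix.

    Returns (eigenvalues descending, sign-fixed orthonormal eigenvectors as
    columns, condition number lambda_1/lambda_n; infinite when lambda_n is
    zero within relative tolerance).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ShapeError(f"matrix must be square, got {matrix.shape}")
    scale = max(1.0, float(np.max(np.abs(matrix))))
    if np.max(np.abs(matrix - matrix.T)) > 1e-9 * scale:
        raise ContractError("matrix is not symmetric within 1e-9")
    vals, vecs = linalg.eigh((matrix + matrix.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = _fix_sign(vecs[:, order])
    lam1 = vals[0]
    lamn = vals[-1]
    if lamn <= max(abs(lam1), 1.0) * 1e-15 or lamn <= 0:
        cond = np.inf
    else:
        cond = lam1 / lamn
    return vals, vecs, cond


@dataclass
class GramianResult:
    """A symmetric PSD Gramian with its eigenstructure and provenance.

    Attributes
    ----------
    matrix : (n, n) symmetric positive-semidefinite matrix.
    eigenvalues : sorted descending, nonnegative after PSD repair.
    eigenvectors : orthonormal columns, column i paired with eigenvalue i,
        sign-fixed so the largest-magnitude component is positive.
    condition_number : lambda_1 / lambda_n (inf for singular matrices).
    std_errors : entrywise Monte-Carlo standard errors (None when the
        matrix was not estimated from samples).
    meta : temperature, horizon, path count, centering mode.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    condition_number: float
    std_errors: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def eigen_ratios(self) -> np.ndarray:
        """lambda_i / lambda_1 for i = 1..n (all-zero spectrum -> zeros)."""
        lam1 = self.eigenvalues[0]
        if lam1 <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / lam1

    def eigen_table(self) -> pd.DataFrame:
        """Tidy eigen-structure table: index, eigenvalue, ratio, vectors."""
        n = self.n
        df = pd.DataFrame({
            "index": np.arange(1, n + 1),
            "eigenvalue": self.eigenvalues,
            "ratio_to_largest": self.eigen_ratios,
        })
        for i in range(n):
            df[f"evec_{i + 1}"] = self.eigenvectors[i, :]
        return df

    def summary(self) -> str:
        """Human-readable summary of the estimated Gramian."""
        lines = ["Gibbs Gramian estimate",
                 "=" * 40]
        for key in ("temperature", "tau", "n_paths", "centering", "label"):
            if key in self.meta:
                lines.append(f"{key:>12}: {self.meta[key]}")
        lines.append(f"{'dimension':>12}: {self.n}")
        cond = self.condition_number
        lines.append(f"{'cond(G)':>12}: "
                     + ("inf" if np.isinf(cond) else f"{cond:.6g}"))
        lines.append("")
        with pd.option_context("display.float_format", "{:.6g}".format):
            lines.append(self.eigen_table()
                         .loc[:, ["index", "eigenvalue", "ratio_to_largest"]]
                         .to_string(index=False))
        return "\n".join(lines)


class GibbsGramianModel:
    """Monte-Carlo estimator of the stochastic Gibbs Gramian.

    Parameters
    ----------
    data
        A :class:`PathEnsemble` or a plain (N, n) endpoint array.
    center
        ``"origin"`` (default; the second moment about the origin),
        ``"mean"`` (sample-mean centering, measuring travelling distance
        instead of distance from the origin), or an explicit length-n
        reference vector.
    """

    def __init__(self, data: Union[PathEnsemble, np.ndarray],
                 center: Union[str, np.ndarray] = "origin"):
        if isinstance(data, PathEnsemble):
            self.endpoints = data.endpoints
            self.meta = {"temperature": data.config.temperature,
                         "tau": data.config.tau,
                         "n_paths": data.config.n_paths,
                         "label": data.system_label}
        else:
            self.endpoints = np.asarray(data, dtype=float)
            self.meta = {"n_paths": self.endpoints.shape[0]}
        if self.endpoints.ndim != 2:
            raise ShapeError("endpoints must be a 2-D (N, n) array")
        if self.endpoints.shape[0] < 2:
            raise ContractError("need at least 2 samples")
        if not np.all(np.isfinite(self.endpoints)):
            raise ContractError("endpoints contain non-finite values")
        self.center = center

    def _center_vector(self) -> np.ndarray:
        n = self.endpoints.shape[1]
        if isinstance(self.center, str):
            if self.center == "origin":
                return np.zeros(n)
            if self.center == "mean":
                return self.endpoints.mean(axis=0)
            raise ContractError(
                f"unknown centering mode {self.center!r}; "
                "use 'origin', 'mean', or a vector")
        c = np.asarray(self.center, dtype=float).reshape(-1)
        if c.shape != (n,):
            raise ShapeError(f"center has shape {c.shape}, expected ({n},)")
        return c

    def fit(self) -> GramianResult:
        c = self._center_vector()
        dev = self.endpoints - c
        N = dev.shape[0]
        M = dev.T @ dev / N
        M = (M + M.T) / 2.0
        # entrywise MC standard error of (1/N) sum d_i d_j
        prods = dev[:, :, None] * dev[:, None, :]
        se = prods.std(axis=0, ddof=1) / np.sqrt(N)

        vals, vecs, _ = eigen_analysis(M)
        lam1 = max(vals[0], 0.0)
        floor = -PSD_CLIP_REL * max(lam1, 1e-300)
        if vals[-1] < floor:
            raise NumericalConsistencyError(
                f"second-moment matrix has eigenvalue {vals[-1]:.3e} below "
                f"the PSD tolerance {floor:.3e}")
        vals = np.clip(vals, 0.0, None)
        matrix = (vecs * vals) @ vecs.T
        matrix = (matrix + matrix.T) / 2.0
        lamn = vals[-1]
        cond = np.inf if lamn <= max(lam1, 1.0) * 1e-15 else lam1 / lamn
        meta = dict(self.meta)
        meta["centering"] = (self.center if isinstance(self.center, str)
                             else "given")
        return GramianResult(matrix=matrix, eigenvalues=vals,
                             eigenvectors=vecs, condition_number=cond,
                             std_errors=se, meta=meta)


def empirical_gramian(ensemble: Union[PathEnsemble, np.ndarray],
                      center: Union[str, np.ndarray] = "origin"
                      ) -> GramianResult:
    """Monte-Carlo second moment of noise-response endpoints.

    Functional form of :class:`GibbsGramianModel`; see that class for the
    centering modes.  For a linear system at noise level T with x0 = 0 the
    result converges to T times the finite-horizon controllability Gramian.
    """
    return GibbsGramianModel(ensemble, center=center).fit()


def quadratic_gibbs_gramian(Q: np.ndarray) -> np.ndarray:
    """Gibbs Gramian of the quadratic L(x) = (1/2) x^T Q^{-1} x, in closed form.

    The Gibbs density exp(-L) is then the Gaussian N(0, Q), whose second
    moment is Q itself — the analytic anchor tying the Gibbs Gramian to the
    classical controllability Gramian for linear dynamics.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ShapeError(f"Q must be square, got {Q.shape}")
    if np.max(np.abs(Q - Q.T)) > 1e-9 * max(1.0, np.max(np.abs(Q))):
        raise ContractError("Q must be symmetric")
    vals = linalg.eigvalsh((Q + Q.T) / 2.0)
    if vals[0] <= 0:
        raise ContractError(
            f"Q must be positive definite; smallest eigenvalue {vals[0]:.3e}")
    return Q.copy()


def direction_gain(gramian: Union[GramianResult, np.ndarray],
                   e: np.ndarray) -> float:
    """Reachability gain e^T G e along a unit direction e.

    Over the unit sphere this Rayleigh quotient is maximized exactly at the
    principal eigenvector of G, which is the direction the state can be
    driven furthest (on average) per unit control energy.
    """
    G = gramian.matrix if isinstance(gramian, GramianResult) else \
        np.asarray(gramian, dtype=float)
    e = np.asarray(e, dtype=float).reshape(-1)
    if e.shape[0] != G.shape[0]:
        raise ShapeError(
            f"direction has length {e.shape[0]}, Gramian is {G.shape[0]}-dim")
    nrm = np.linalg.norm(e)
    if abs(nrm - 1.0) > 1e-9:
        raise ContractError(f"e must be a unit vector; |e| = {nrm}")
    return float(e @ G @ e)
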