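"""Pointwise controllability-function estimation from noise-response data.

The endpoint of the input-channel noise response at level T is distributed
with density proportional to exp(-L(x)/T), where L is the stochastic
controllability function (the minimum expected control effort to reach x at
the horizon).  Inverting this relation,

    L(x) = -T log p(x) + const,

so a kernel density estimate p_hat of the endpoint samples yields L up to an
additive constant — the density's normalizer is never identified, and only
differences of L between states are meaningful.  Reported values are pinned
so the minimum over the query points is zero.

Density estimation limits this route to low dimension (n <= 3 here); the
Gramian (a spatial integral rather than a pointwise quantity) is the
scalable summary and lives in :mod:`ctrlgram.gramian`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.stats import gaussian_kde

from .exceptions import ContractError, ShapeError
from .sde import PathEnsemble

__all__ = ["CtrlFunctionEstimate", "estimate_ctrl_function"]

#: Densities below this are masked (L would overflow) with a warning.
DENSITY_FLOOR = 1e-300


@dataclass
class CtrlFunctionEstimate:
    """Estimated controllability-function values at query points.

    ``values`` are defined up to a shared additive constant and reported
    relative to their minimum over the unmasked queries; masked entries
    (density below the floor) are NaN with ``mask`` set.
    """

    query_points: np.ndarray
    values: np.ndarray
    density: np.ndarray
    mask: np.ndarray
    temperature: float
    bandwidth: float
    n_samples: int


def _silverman_factor(n_samples: int, dim: int) -> float:
    return (n_samples * (dim + 2) / 4.0) ** (-1.0 / (dim + 4))


def estimate_ctrl_function(ensemble: Union[PathEnsemble, np.ndarray],
                           query_points,
                           bandwidth: Union[str, float] = "auto",
                           temperature: float = None
                           ) -> CtrlFunctionEstimate:
    """Estimate L(x) = -T log p_hat(x) at the query points.

    Parameters
    ----------
    ensemble
        Noise-response endpoints, as a :class:`PathEnsemble` (temperature
        taken from its config) or an (N, n) array (then ``temperature`` is
        required).  N >= 100 and n <= 3 are enforced: below that the density
        estimate is unreliable, above it kernel density estimation over the
        state space is ineffective.
    query_points
        (Q, n) array (or length-Q vector for n = 1).
    bandwidth
        ``"auto"`` for Silverman's rule, or a positive kernel-covariance
        factor passed to the Gaussian KDE (multiplies the sample standard
        deviation per dimension).
    """
    if isinstance(ensemble, PathEnsemble):
        endpoints = ensemble.endpoints
        if temperature is None:
            temperature = ensemble.config.temperature
    else:
        endpoints = np.asarray(ensemble, dtype=float)
        if temperature is None:
            raise ContractError(
                "temperature is required when passing raw endpoints")
    if endpoints.ndim != 2:
        raise ShapeError("endpoints must be a 2-D (N, n) array")
    N, n = endpoints.shape
    if n > 3:
        raise ContractError(
            f"density-based estimation supports n <= 3, got n = {n}; "
            "use the Gramian for higher-dimensional systems")
    if N < 100:
        raise ContractError(f"need at least 100 samples, got {N}")

    q = np.asarray(query_points, dtype=float)
    if q.ndim == 1:
        q = q.reshape(-1, 1) if n == 1 else q.reshape(1, -1)
    if q.shape[1] != n:
        raise ShapeError(
            f"query_points have dimension {q.shape[1]}, endpoints {n}")

    if bandwidth == "auto":
        bw_method = "silverman"
        bw_factor = _silverman_factor(N, n)
    else:
        bw_factor = float(bandwidth)
        if bw_factor <= 0:
            raise ContractError("bandwidth must be positive")
        bw_method = bw_factor

    kde = gaussian_kde(endpoints.T, bw_method=bw_method)
    dens = kde(q.T)

    mask = dens < DENSITY_FLOOR
    if np.any(mask):
        warnings.warn(
            f"{int(mask.sum())} query point(s) have density below "
            f"{DENSITY_FLOOR:g}; their values are masked", RuntimeWarning)
    values = np.full(q.shape[0], np.nan)
    ok = ~mask
    values[ok] = -temperature * np.log(dens[ok])
    if np.any(ok):
        values[ok] -= np.min(values[ok])

    return CtrlFunctionEstimate(query_points=q, values=values, density=dens,
                                mask=mask, temperature=float(temperature),
                                bandwidth=float(bw_factor), n_samples=N)
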