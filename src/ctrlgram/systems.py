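"""Controlled dynamical systems and builders for the fixture families.

A :class:`DynamicalSystem` packages the drift field ``f``, the input map
``g``, and the initial state ``x0`` of the controlled dynamics

    dx/dt = f(x) + g(x) u(t),    x(0) = x0,

with ``x`` of dimension ``n`` and ``u`` of dimension ``m``.  Builders are
provided for general linear systems (``f(x) = A x``, ``g = B``), the scalar
Ornstein-Uhlenbeck process, and networks of diffusively coupled
FitzHugh-Nagumo neuronal oscillators driven through a common input channel.

Drift callables produced by the builders are vectorised over a leading batch
axis: they accept ``(n,)`` or ``(N, n)`` arrays and act on the last axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .exceptions import ContractError, ShapeError

__all__ = [
    "DynamicalSystem",
    "LinearSystemSpec",
    "FHNNetworkSpec",
    "FHNParams",
    "make_linear_system",
    "make_ou_system",
    "make_fhn_network",
    "fhn_benchmark_spec",
]


@dataclass
class DynamicalSystem:
    """A controlled dynamical system dx/dt = f(x) + g(x) u.

    Parameters
    ----------
    n, m
        State and input dimensions.
    drift
        Map from state to state derivative, vectorised over a leading batch
        axis when ``vectorized`` is true.
    input_map
        Map from state to the ``(n, m)`` input matrix ``g(x)``.
    x0
        Initial state, shape ``(n,)``.
    labels
        Optional per-coordinate names (defaults to ``x1..xn``).
    linear
        True when ``drift(x) = A x`` and ``input_map`` is the constant ``B``;
        then ``A`` and ``B`` hold those matrices.
    constant_input
        True when ``g(x)`` does not depend on ``x`` (enables the fast
        simulation path).
    """

    n: int
    m: int
    drift: Callable[[np.ndarray], np.ndarray]
    input_map: Callable[[np.ndarray], np.ndarray]
    x0: np.ndarray
    labels: Sequence[str] = None
    linear: bool = False
    constant_input: bool = False
    vectorized: bool = False
    A: Optional[np.ndarray] = None
    B: Optional[np.ndarray] = None
    name: str = "system"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float).reshape(-1)
        if self.x0.shape != (self.n,):
            raise ShapeError(
                f"x0 has shape {self.x0.shape}, expected ({self.n},)")
        if self.labels is None:
            self.labels = [f"x{i + 1}" for i in range(self.n)]
        f0 = np.asarray(self.drift(self.x0), dtype=float)
        if f0.shape != (self.n,):
            raise ShapeError(
                f"drift(x0) has shape {f0.shape}, expected ({self.n},)")
        if not np.all(np.isfinite(f0)):
            raise ContractError("drift(x0) is not finite")
        g0 = np.asarray(self.input_map(self.x0), dtype=float)
        if g0.shape != (self.n, self.m):
            raise ShapeError(
                f"input_map(x0) has shape {g0.shape}, "
                f"expected ({self.n}, {self.m})")


@dataclass
class LinearSystemSpec:
    """Specification of a linear system: A (n x n), B (n x m), x0 (n,)."""

    A: np.ndarray
    B: np.ndarray
    x0: np.ndarray = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ShapeError(f"A must be square, got shape {self.A.shape}")
        if self.B.ndim != 2 or self.B.shape[0] != self.A.shape[0]:
            raise ShapeError(
                f"B has {self.B.shape[0] if self.B.ndim == 2 else '?'} rows "
                f"but A is {self.A.shape[0]}x{self.A.shape[0]}")
        if self.x0 is None:
            self.x0 = np.zeros(self.A.shape[0])
        self.x0 = np.asarray(self.x0, dtype=float).reshape(-1)
        if self.x0.shape != (self.A.shape[0],):
            raise ShapeError(
                f"x0 has shape {self.x0.shape}, "
                f"expected ({self.A.shape[0]},)")

    def to_json(self) -> str:
        return json.dumps({
            "kind": "linear",
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "x0": self.x0.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "LinearSystemSpec":
        d = json.loads(text)
        return cls(A=np.array(d["A"]), B=np.array(d["B"]),
                   x0=np.array(d["x0"]))


#: FitzHugh-Nagumo constants.  The oscillatory regime used throughout:
#: dv/dt = v - v^3/3 - w + I,  dw/dt = eps (v + a - b w),
#: with a stable limit cycle for a=0.7, b=0.8, eps=0.08, I=0.8.
@dataclass
class FHNParams:
    a: float = 0.7
    b: float = 0.8
    eps: float = 0.08
    current: float = 0.8

    def to_dict(self):
        return {"a": self.a, "b": self.b, "eps": self.eps,
                "current": self.current}


@dataclass
class FHNNetworkSpec:
    """Network of p diffusively coupled FitzHugh-Nagumo neurons.

    ``eta`` is the symmetric, zero-diagonal, nonnegative coupling matrix
    (entry ``eta[i, j]`` couples the voltage variables of neurons i and j).
    ``input_selector`` is a 0/1 vector marking the neurons whose voltage
    equation receives the common scalar input.  The built state is ordered
    ``[v1, w1, v2, w2, ..., vp, wp]``.
    """

    p: int
    eta: np.ndarray
    input_selector: np.ndarray = None
    neuron_params: FHNParams = field(default_factory=FHNParams)
    v0: np.ndarray = None

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=float)
        if self.eta.shape != (self.p, self.p):
            raise ShapeError(
                f"eta has shape {self.eta.shape}, expected ({self.p}, {self.p})")
        if not np.allclose(self.eta, self.eta.T, atol=1e-12):
            raise ContractError("coupling matrix eta must be symmetric")
        if np.any(np.abs(np.diag(self.eta)) > 0):
            raise ContractError("coupling matrix eta must have zero diagonal")
        if np.any(self.eta < 0):
            raise ContractError("coupling strengths must be nonnegative")
        if self.input_selector is None:
            self.input_selector = np.ones(self.p)
        self.input_selector = np.asarray(self.input_selector, dtype=float)
        if self.input_selector.shape != (self.p,):
            raise ShapeError(
                f"input_selector has shape {self.input_selector.shape}, "
                f"expected ({self.p},)")
        if self.v0 is None:
            self.v0 = np.zeros((self.p, 2))
        self.v0 = np.asarray(self.v0, dtype=float)
        if self.v0.shape != (self.p, 2):
            raise ShapeError(
                f"v0 has shape {self.v0.shape}, expected ({self.p}, 2)")

    def to_json(self) -> str:
        return json.dumps({
            "kind": "fhn",
            "p": self.p,
            "eta": self.eta.tolist(),
            "input_selector": self.input_selector.tolist(),
            "neuron_params": self.neuron_params.to_dict(),
            "v0": self.v0.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "FHNNetworkSpec":
        d = json.loads(text)
        return cls(p=d["p"], eta=np.array(d["eta"]),
                   input_selector=np.array(d["input_selector"]),
                   neuron_params=FHNParams(**d["neuron_params"]),
                   v0=np.array(d["v0"]))


def make_linear_system(spec: LinearSystemSpec) -> DynamicalSystem:
    """Build the linear system dx/dt = A x + B u from its spec."""
    A = spec.A
    B = spec.B
    n, m = B.shape

    def drift(x):
        return np.asarray(x, dtype=float) @ A.T

    def input_map(x):
        return B

    return DynamicalSystem(n=n, m=m, drift=drift, input_map=input_map,
                           x0=spec.x0, linear=True, constant_input=True,
                           vectorized=True, A=A, B=B, name="linear")


def make_ou_system(theta: float, sigma_channel: float = 1.0,
                   x0: float = 0.0) -> DynamicalSystem:
    """One-dimensional Ornstein-Uhlenbeck system dx = -theta x dt + sigma u dt.

    ``theta`` must be positive: downstream fixtures rely on the stationary
    limit existing.
    """
    if theta <= 0:
        raise ContractError(f"theta must be positive, got {theta}")
    sys = make_linear_system(LinearSystemSpec(
        A=[[-theta]], B=[[sigma_channel]], x0=[x0]))
    sys.name = "ou"
    return sys


def make_fhn_network(spec: FHNNetworkSpec) -> DynamicalSystem:
    """Build the coupled FitzHugh-Nagumo network as a DynamicalSystem.

    Per-neuron dynamics with diffusive voltage coupling:

        dv_i/dt = v_i - v_i^3/3 - w_i + I + sum_j eta_ij (v_j - v_i) + b_i u
        dw_i/dt = eps (v_i + a - b w_i)

    The common input (and the input-channel noise in the stochastic setting)
    enters the voltage equation of every selected neuron, so m = 1.
    """
    p = spec.p
    n = 2 * p
    prm = spec.neuron_params
    eta = spec.eta
    degree = eta.sum(axis=1)           # row sums: total coupling onto neuron i
    v_idx = np.arange(0, n, 2)
    w_idx = np.arange(1, n, 2)

    B = np.zeros((n, 1))
    B[v_idx, 0] = spec.input_selector

    def drift(x):
        x = np.asarray(x, dtype=float)
        v = x[..., v_idx]
        w = x[..., w_idx]
        coupling = v @ eta.T - degree * v
        dv = v - v ** 3 / 3.0 - w + prm.current + coupling
        dw = prm.eps * (v + prm.a - prm.b * w)
        out = np.empty_like(x)
        out[..., v_idx] = dv
        out[..., w_idx] = dw
        return out

    def input_map(x):
        return B

    labels = []
    for i in range(p):
        labels += [f"v{i + 1}", f"w{i + 1}"]

    return DynamicalSystem(n=n, m=1, drift=drift, input_map=input_map,
                           x0=spec.v0.reshape(-1), labels=labels,
                           constant_input=True, vectorized=True,
                           name=f"fhn_p{p}",
                           meta={"p": p, "params": prm.to_dict()})


def fhn_benchmark_spec(**overrides) -> FHNNetworkSpec:
    """The four-neuron benchmark network used throughout the examples.

    Couplings eta_12 = eta_34 = 0.1, eta_23 = 0.005, zero otherwise; a common
    input into every neuron; initial states v1(0) = -v3(0) = [-1, 0],
    v2(0) = -v4(0) = [0, 2].
    """
    eta = np.zeros((4, 4))
    eta[0, 1] = eta[1, 0] = 0.1
    eta[2, 3] = eta[3, 2] = 0.1
    eta[1, 2] = eta[2, 1] = 0.005
    v0 = np.array([[-1.0, 0.0], [0.0, 2.0], [1.0, 0.0], [0.0, -2.0]])
    kw = dict(p=4, eta=eta, input_selector=np.ones(4), v0=v0)
    kw.update(overrides)
    return FHNNetworkSpec(**kw)
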