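"""Euler-Maruyama ensemble simulation of input-channel noise.

The noise response is the uncontrolled system excited only through its input
channel,

    dx = f(x) dt + g(x) sqrt(T) dW,

with ``T >= 0`` the noise level ("temperature") and ``W`` an m-dimensional
standard Wiener process.  The Ito convention is used; for the constant-g
fixtures in this package Ito and Stratonovich coincide.  The controlled
variant adds a feedback input through the same channel,

    dx = f(x) dt + g(x) (u dt + sqrt(T) dW),

and accumulates the quadratic control effort (1/2) * int |u|^2 dt per path.

All ensembles are reproducible: increments are drawn from a single
``numpy.random.Generator`` seeded by ``SimConfig.seed``, so two calls with
identical arguments return bit-identical arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np

from .exceptions import ContractError, DivergenceError, ShapeError
from .systems import DynamicalSystem

__all__ = ["SimConfig", "PathEnsemble", "simulate_noise_response",
           "simulate_controlled"]

#: Any coordinate exceeding this magnitude aborts the run as divergent.
DIVERGENCE_GUARD = 1e6


@dataclass
class SimConfig:
    """Simulation configuration: horizon tau, step dt, temperature T,
    path count N, seed, and whether to store full trajectories.

    ``save_every`` thins trajectory storage to every that-many steps (the
    endpoint is always stored); it must divide the step count.  Thinned
    snapshots feed the pooled-snapshot Gramian estimate without holding
    every integration step in memory."""

    tau: float
    dt: float
    temperature: float
    n_paths: int
    seed: int
    store_full: bool = False
    save_every: int = 1

    def __post_init__(self):
        if self.tau <= 0 or self.dt <= 0:
            raise ContractError("tau and dt must be positive")
        if self.temperature < 0:
            raise ContractError("temperature must be nonnegative")
        if self.n_paths < 1:
            raise ContractError("n_paths must be a positive integer")
        if self.save_every < 1:
            raise ContractError("save_every must be a positive integer")
        steps = self.tau / self.dt
        if abs(steps - round(steps)) > 1e-9 * max(1.0, steps):
            raise ContractError(
                f"tau/dt = {steps} is not an integer step count")

    @property
    def n_steps(self) -> int:
        return int(round(self.tau / self.dt))

    def to_dict(self) -> dict:
        return {"tau": self.tau, "dt": self.dt,
                "temperature": self.temperature, "n_paths": self.n_paths,
                "seed": self.seed, "store_full": self.store_full,
                "save_every": self.save_every}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class PathEnsemble:
    """Endpoint (and optionally full-trajectory) samples of an ensemble.

    ``endpoints`` has shape (N, n); ``trajectories``, when stored, has shape
    (N, n_steps + 1, n) with ``trajectories[:, -1] == endpoints`` exactly.
    """

    endpoints: np.ndarray
    config: SimConfig
    trajectories: Optional[np.ndarray] = None
    times: Optional[np.ndarray] = None
    system_label: str = ""
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.endpoints = np.asarray(self.endpoints, dtype=float)
        if self.endpoints.ndim != 2:
            raise ShapeError("endpoints must be a 2-D (N, n) array")
        if self.endpoints.shape[0] != self.config.n_paths:
            raise ShapeError(
                f"endpoints has {self.endpoints.shape[0]} rows but config "
                f"declares n_paths={self.config.n_paths}")

    @property
    def n(self) -> int:
        return self.endpoints.shape[1]

    @property
    def n_paths(self) -> int:
        return self.endpoints.shape[0]


def _drift_batch(system: DynamicalSystem, x: np.ndarray) -> np.ndarray:
    if system.vectorized:
        return system.drift(x)
    return np.stack([np.asarray(system.drift(row), dtype=float)
                     for row in x])


def _check_finite(x: np.ndarray, t: float) -> None:
    bad = ~np.all(np.isfinite(x), axis=1) | (
        np.max(np.abs(x), axis=1) > DIVERGENCE_GUARD)
    if np.any(bad):
        idx = int(np.nonzero(bad)[0][0])
        raise DivergenceError(
            f"path {idx} diverged at t={t:.6g} "
            f"(non-finite or |x| > {DIVERGENCE_GUARD:g})")


def _run_em(system: DynamicalSystem, config: SimConfig,
            feedback: Optional[Callable] = None
            ) -> Tuple[PathEnsemble, np.ndarray]:
    n, m = system.n, system.m
    N = config.n_paths
    dt = config.dt
    n_steps = config.n_steps
    sqrt_T = float(np.sqrt(config.temperature))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    x = np.tile(system.x0, (N, 1))
    costs = np.zeros(N)
    times = np.linspace(0.0, config.tau, n_steps + 1)
    traj = None
    saved_times = times
    if config.store_full:
        if n_steps % config.save_every != 0:
            raise ContractError(
                f"save_every={config.save_every} does not divide the "
                f"step count {n_steps}")
        saved_times = times[::config.save_every]
        traj = np.empty((N, len(saved_times), n))
        traj[:, 0] = x

    const_g = system.input_map(system.x0) if system.constant_input else None

    for k in range(n_steps):
        t = times[k]
        dW = rng.normal(0.0, np.sqrt(dt), size=(N, m))
        u = None
        if feedback is not None:
            u = np.asarray(feedback(x, t), dtype=float)
            if u.shape == (m,) and N != m:
                u = np.tile(u, (N, 1))
            if u.ndim == 1 and m == 1:
                u = u.reshape(-1, 1)
            if u.shape != (N, m):
                raise ShapeError(
                    f"feedback returned shape {u.shape}, expected ({N}, {m})")
        fx = _drift_batch(system, x)
        incr = sqrt_T * dW
        if u is not None:
            incr = incr + u * dt
            costs += 0.5 * np.sum(u ** 2, axis=1) * dt
        if const_g is not None:
            noise = incr @ const_g.T
        elif system.vectorized:
            g = np.asarray(system.input_map(x), dtype=float)
            noise = np.einsum("pij,pj->pi", g, incr)
        else:
            noise = np.stack([
                np.asarray(system.input_map(row), dtype=float) @ inc
                for row, inc in zip(x, incr)])
        x = x + fx * dt + noise
        _check_finite(x, times[k + 1])
        if traj is not None and (k + 1) % config.save_every == 0:
            traj[:, (k + 1) // config.save_every] = x

    ens = PathEnsemble(endpoints=x, config=config, trajectories=traj,
                       times=saved_times, system_label=system.name,
                       labels=list(system.labels))
    return ens, costs


def simulate_noise_response(system: DynamicalSystem,
                            config: SimConfig) -> PathEnsemble:
    """Simulate the uncontrolled, input-channel-noise-excited dynamics.

    Each path follows x_{k+1} = x_k + f(x_k) dt + g(x_k) sqrt(T) dW_k with
    dW_k ~ Normal(0, dt I_m) and x_0 = system.x0.  Deterministic given
    (seed, dt, N).
    """
    ens, _ = _run_em(system, config, feedback=None)
    return ens


def simulate_controlled(system: DynamicalSystem,
                        feedback: Callable[[np.ndarray, float], np.ndarray],
                        config: SimConfig
                        ) -> Tuple[PathEnsemble, np.ndarray]:
    """Simulate dx = f dt + g (u dt + sqrt(T) dW) under a feedback law.

    ``feedback(x, t)`` receives the (N, n) batch of current states and the
    time, and returns per-path inputs of shape (N, m) (an (m,) vector is
    broadcast to all paths).  Returns the ensemble and the per-path realized
    control effort (1/2) sum_k |u_k|^2 dt.

    With ``feedback=None`` or a feedback returning zeros this reproduces
    ``simulate_noise_response`` bit-exactly under the same seed.
    """
    if feedback is None:
        feedback = lambda x, t: np.zeros((x.shape[0], system.m))
    return _run_em(system, config, feedback=feedback)
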