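"""Plain-text artifact I/O: matrix CSV, ensemble CSV + JSON sidecar.

All numeric artifacts are CSV (comma separator, '.' decimal, UTF-8, header
row required) written with 17 significant digits so that write -> read
round-trips are bit exact.  Every stochastic artifact carries a JSON sidecar
with the full :class:`~ctrlgram.sde.SimConfig`, so it can be regenerated
from seed + config alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .exceptions import ContractError
from .gramian import GramianResult
from .reduction import ProjectionBasis
from .sde import PathEnsemble, SimConfig

__all__ = ["write_matrix_csv", "read_matrix_csv", "write_ensemble",
           "read_ensemble", "write_gramian", "write_basis"]

_FMT = "%.17g"


def write_matrix_csv(matrix: np.ndarray, path, labels=None) -> None:
    """Write a 2-D matrix as CSV with a header of column labels."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    ncol = matrix.shape[1]
    if labels is None:
        labels = [f"x{i + 1}" for i in range(ncol)]
    header = ",".join(str(c) for c in labels)
    np.savetxt(path, matrix, fmt=_FMT, delimiter=",", header=header,
               comments="")


def read_matrix_csv(path) -> np.ndarray:
    """Read a matrix CSV written by :func:`write_matrix_csv`.

    A header-only file yields a 0 x k matrix; an empty file or ragged rows
    raise a parse error naming the line.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise ContractError(f"{path}: empty file, expected a header row")
    ncol = len(lines[0].split(","))
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) != ncol:
            raise ContractError(
                f"{path}: line {lineno} has {len(parts)} fields, "
                f"expected {ncol}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ContractError(f"{path}: line {lineno}: {exc}") from exc
    return np.array(rows, dtype=float).reshape(len(rows), ncol)


def write_ensemble(ensemble: PathEnsemble, prefix: Union[str, Path]) -> None:
    """Write an ensemble: <prefix>.csv (endpoints), <prefix>.json (config),
    and <prefix>_trajectories.csv (long format) when trajectories exist."""
    prefix = Path(prefix)
    labels = ensemble.labels or [f"x{i + 1}" for i in range(ensemble.n)]
    write_matrix_csv(ensemble.endpoints, prefix.with_suffix(".csv"), labels)
    sidecar = {"config": ensemble.config.to_dict(),
               "system_label": ensemble.system_label,
               "labels": list(labels)}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2),
                                           encoding="utf-8")
    if ensemble.trajectories is not None:
        N, steps1, n = ensemble.trajectories.shape
        flat = np.empty((N * steps1, n + 2))
        flat[:, 0] = np.repeat(np.arange(N), steps1)
        flat[:, 1] = np.tile(ensemble.times, N)
        flat[:, 2:] = ensemble.trajectories.reshape(N * steps1, n)
        write_matrix_csv(flat, prefix.parent / (prefix.name
                                                + "_trajectories.csv"),
                         ["path", "time"] + list(labels))


def read_ensemble(prefix: Union[str, Path]) -> PathEnsemble:
    """Read an ensemble written by :func:`write_ensemble`."""
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text(
        encoding="utf-8"))
    config = SimConfig.from_dict(sidecar["config"])
    endpoints = read_matrix_csv(prefix.with_suffix(".csv"))
    traj = None
    times = None
    traj_path = prefix.parent / (prefix.name + "_trajectories.csv")
    if traj_path.exists():
        flat = read_matrix_csv(traj_path)
        N = config.n_paths
        steps1 = flat.shape[0] // N
        times = flat[:steps1, 1]
        traj = flat[:, 2:].reshape(N, steps1, endpoints.shape[1])
    return PathEnsemble(endpoints=endpoints, config=config,
                        trajectories=traj, times=times,
                        system_label=sidecar.get("system_label", ""),
                        labels=sidecar.get("labels", []))


def write_gramian(result: GramianResult, prefix: Union[str, Path]) -> None:
    """Write a Gramian: matrix CSV, eigen-table CSV, JSON metadata."""
    prefix = Path(prefix)
    labels = [f"x{i + 1}" for i in range(result.n)]
    write_matrix_csv(result.matrix, prefix.parent / (prefix.name
                                                     + "_matrix.csv"), labels)
    result.eigen_table().to_csv(prefix.parent / (prefix.name + "_eigen.csv"),
                                index=False, float_format=_FMT)
    meta = dict(result.meta)
    meta["condition_number"] = (None if np.isinf(result.condition_number)
                                else result.condition_number)
    (prefix.parent / (prefix.name + "_meta.json")).write_text(
        json.dumps(meta, indent=2, default=str), encoding="utf-8")


def write_basis(basis: ProjectionBasis, prefix: Union[str, Path],
                meta: dict = None) -> None:
    """Write a projection basis as CSV plus JSON metadata."""
    prefix = Path(prefix)
    write_matrix_csv(basis.rho, prefix.parent / (prefix.name + "_basis.csv"),
                     [f"mode{i + 1}" for i in range(basis.k)])
    info = {"n": basis.n, "k": basis.k}
    if meta:
        info.update(meta)
    (prefix.parent / (prefix.name + "_basis.json")).write_text(
        json.dumps(info, indent=2, default=str), encoding="utf-8")
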