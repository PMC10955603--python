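"""Tasks for two-layer linear network learning dynamics.

A *task* is a finite supervised dataset of P input/target pairs, summarised by
its correlation statistics: the input correlation ``Sigma_xx = (1/P) X X^T``
and the input-output correlation ``Sigma_yx = (1/P) Y X^T``.  The exact
gradient-flow solutions in :mod:`lindyn.riccati` consume only these statistics
(plus the compact SVD of ``Sigma_yx``), under the standing assumptions of
whitened inputs and full-rank correlations.

This module provides the dataset container, correlation/SVD computations,
synthetic task generators (hierarchical semantic trees and random whitened
tasks), numeric validation of the solver assumptions, and CSV/JSON
serialisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "TaskCorrelations",
    "TaskSVD",
    "AssumptionReport",
    "compute_correlations",
    "compact_svd",
    "make_hierarchy_task",
    "make_random_whitened_task",
    "validate_assumptions",
    "save_dataset",
    "load_dataset",
    "RANK_TOL",
]

#: Default relative tolerance for dropping singular values (relative to the
#: largest one).  Far below any singular value used in experiments, far above
#: double-precision noise.
RANK_TOL = 1e-10


@dataclass(frozen=True)
class Dataset:
    """Paired input/target matrices, samples as columns.

    Attributes
    ----------
    X : ndarray of shape (Ni, P)
        Input vectors, one per column.
    Y : ndarray of shape (No, P)
        Target vectors, one per column.
    """

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-D matrices")
        if X.shape[1] != Y.shape[1]:
            raise ValueError(
                f"X and Y must share the sample dimension: "
                f"P_x={X.shape[1]} != P_y={Y.shape[1]}"
            )
        if X.shape[1] < 1:
            raise ValueError("need at least one sample (P >= 1)")
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("dataset entries must be finite")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)

    @property
    def Ni(self) -> int:
        return self.X.shape[0]

    @property
    def No(self) -> int:
        return self.Y.shape[0]

    @property
    def P(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class TaskCorrelations:
    """Sample-average correlation statistics of a dataset.

    ``Sigma_xx = (1/P) sum_n x_n x_n^T``, ``Sigma_yx = (1/P) sum_n y_n x_n^T``
    and ``mean_sq_target = (1/P) sum_n ||y_n||^2``.
    """

    Sigma_xx: np.ndarray
    Sigma_yx: np.ndarray
    mean_sq_target: float

    @property
    def whitening_deviation(self) -> float:
        """Frobenius distance of Sigma_xx from the identity."""
        return float(
            np.linalg.norm(self.Sigma_xx - np.eye(self.Sigma_xx.shape[0]))
        )


@dataclass(frozen=True)
class TaskSVD:
    """Compact SVD ``M = Utilde diag(Stilde) Vtilde^T`` with complements.

    The orthogonal complements enter the closed-form dynamics only through the
    projectors ``Pu_perp = I - Utilde Utilde^T`` and
    ``Pv_perp = I - Vtilde Vtilde^T``; the complement bases themselves are
    never materialised (any completion yields the same products).
    """

    Utilde: np.ndarray
    Stilde: np.ndarray
    Vtilde: np.ndarray

    @property
    def rank(self) -> int:
        return len(self.Stilde)

    @property
    def Pu_perp(self) -> np.ndarray:
        U = self.Utilde
        return np.eye(U.shape[0]) - U @ U.T

    @property
    def Pv_perp(self) -> np.ndarray:
        V = self.Vtilde
        return np.eye(V.shape[0]) - V @ V.T

    def reconstruct(self) -> np.ndarray:
        return (self.Utilde * self.Stilde) @ self.Vtilde.T


@dataclass(frozen=True)
class AssumptionReport:
    """Numeric evidence for each assumption behind the exact solvers.

    Flags mirror the standing assumptions: equal input/output dimensions,
    whitened inputs, zero-balanced weights, full-rank task and initial
    function, and non-singular alignment matrix B.  Every flag carries the
    number that justified it.
    """

    equal_dims: bool
    dims: tuple[int, int]
    whitened: bool
    whitening_deviation: float
    balanced: bool
    balancedness_gap: float
    full_rank: bool
    rank_task: int
    rank_init: int
    b_nonsingular: bool
    min_sv_B: float

    @property
    def fukumizu_applicable(self) -> bool:
        """Whether the original matrix-Riccati form applies (needs 2.1-2.4)."""
        return self.equal_dims and self.whitened and self.balanced and self.full_rank

    @property
    def stable_form_applicable(self) -> bool:
        """Whether the stable general solution applies (2.2-2.4 + B invertible)."""
        return self.whitened and self.balanced and self.full_rank and self.b_nonsingular


def compute_correlations(data: Dataset) -> TaskCorrelations:
    """Compute the task's correlation statistics from samples.

    Returns the exact sample averages ``(1/P) X X^T``, ``(1/P) Y X^T`` and the
    mean squared target norm, which fix the mean squared error loss up to the
    irreducible constant.
    """
    P = data.P
    return TaskCorrelations(
        Sigma_xx=data.X @ data.X.T / P,
        Sigma_yx=data.Y @ data.X.T / P,
        mean_sq_target=float(np.sum(data.Y**2) / P),
    )


def compact_svd(M: np.ndarray, rank_tol: float = RANK_TOL) -> TaskSVD:
    """Compact SVD of ``M``, dropping singular values <= rank_tol * s_max.

    Raises
    ------
    ValueError
        If ``M`` is all-zero (rank 0 breaks the full-rank assumption that all
        downstream solvers require).
    """
    M = np.asarray(M, dtype=float)
    if not np.isfinite(M).all():
        raise ValueError("matrix entries must be finite")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] <= 0.0:
        raise ValueError("cannot take the compact SVD of an all-zero matrix")
    keep = s > rank_tol * s[0]
    return TaskSVD(Utilde=U[:, keep], Stilde=s[keep], Vtilde=Vt[keep].T)


def _hierarchy_features(depth: int) -> np.ndarray:
    """Signed-Haar feature matrix (P features x P items) for a binary tree.

    Feature 0 is a shared root-ancestry feature (+1 for every item).  Each
    internal node of the balanced binary tree contributes one feature: items
    below its left child get ``+sigma_l``, items below its right child get
    ``-sigma_l``, others 0, with per-level magnitude ``sigma_l =
    1/sqrt(level + 2)`` (the constant feature is level 0 with magnitude 1).
    Rows are mutually orthogonal, so the matrix has full rank P.
    """
    P = 2**depth
    Yrows = [np.ones(P)]
    for level in range(depth):
        n_nodes = 2**level
        seg = P // n_nodes  # leaves under each node at this level
        sigma = 1.0 / np.sqrt(level + 2)
        for node in range(n_nodes):
            row = np.zeros(P)
            start = node * seg
            row[start : start + seg // 2] = sigma
            row[start + seg // 2 : start + seg] = -sigma
            Yrows.append(row)
    return np.array(Yrows)


def make_hierarchy_task(depth: int, seed: int = 0) -> Dataset:
    """Hierarchical semantic-tree task (items of a living kingdom).

    Builds a balanced binary tree with ``P = 2**depth`` leaf items.  Inputs are
    one-hot item codes scaled by ``sqrt(P)`` so that ``Sigma_xx = I`` exactly.
    Targets assign each item a P-dimensional feature vector encoding its
    root-to-leaf path (one shared root feature plus one signed feature per
    internal node, magnitudes decaying with depth), giving ``Ni = No = P`` and
    a full-rank ``Sigma_yx`` whose input-side similarity ``Vtilde Stilde
    Vtilde^T`` exposes the nested tree structure: items under the same subtree
    are more similar.

    The ``seed`` parameter is accepted for interface uniformity; the
    construction is deterministic.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    P = 2**depth
    X = np.sqrt(P) * np.eye(P)
    Y = _hierarchy_features(depth)
    return Dataset(X=X, Y=Y)


def make_random_whitened_task(
    Ni: int,
    No: int,
    seed: int,
    singular_values: np.ndarray | list[float] | None = None,
) -> Dataset:
    """Random task with exactly whitened inputs and full-rank Sigma_yx.

    P = Ni samples; ``X = sqrt(P) * O`` for a random orthogonal O, so
    ``Sigma_xx = I`` holds exactly by construction.  ``Sigma_yx`` is
    synthesised from its SVD with random orthonormal factors; its nonzero
    singular values are drawn uniformly from [0.5, 1.5] (descending, order
    one) unless ``singular_values`` prescribes them.
    """
    if Ni < 1 or No < 1:
        raise ValueError("Ni and No must be >= 1")
    rng = np.random.default_rng(seed)
    Nm = min(Ni, No)
    if singular_values is not None:
        sv = np.sort(np.asarray(singular_values, dtype=float))[::-1]
        if sv.size > Nm:
            raise ValueError(
                f"requested {sv.size} singular values but rank is at most {Nm}"
            )
        if np.any(sv <= 0):
            raise ValueError("singular values must be positive")
    else:
        sv = np.sort(rng.uniform(0.5, 1.5, size=Nm))[::-1]
    Nm = sv.size
    Ox = np.linalg.qr(rng.standard_normal((Ni, Ni)))[0]
    Uy = np.linalg.qr(rng.standard_normal((No, Nm)))[0]
    Vy = np.linalg.qr(rng.standard_normal((Ni, Nm)))[0]
    Sigma_yx = (Uy * sv) @ Vy.T
    P = Ni
    X = np.sqrt(P) * Ox
    # Sigma_yx = (1/P) Y X^T  =>  Y = Sigma_yx X since X X^T = P I.
    Y = Sigma_yx @ X
    return Dataset(X=X, Y=Y)


def validate_assumptions(data: Dataset, state, tol: float = 1e-8) -> AssumptionReport:
    """Numerically evaluate every assumption behind the exact solvers.

    This reports; it never raises.  The report's ``fukumizu_applicable`` and
    ``stable_form_applicable`` properties say which closed forms are valid for
    this (task, initialisation) pair.
    """
    from .inits import balancedness_gap, build_BC  # local to avoid cycle

    corr = compute_correlations(data)
    dev = corr.whitening_deviation
    gap = balancedness_gap(state)
    product = state.W2 @ state.W1
    Nm_min = min(data.Ni, data.No)
    rank_task = int(np.linalg.matrix_rank(corr.Sigma_yx))
    rank_init = int(np.linalg.matrix_rank(product))
    full_rank = rank_task == Nm_min and rank_init == Nm_min

    min_sv_B = 0.0
    b_ok = False
    if full_rank and np.linalg.norm(product) > 0 and np.linalg.norm(corr.Sigma_yx) > 0:
        try:
            bc = build_BC(compact_svd(product), compact_svd(corr.Sigma_yx))
            min_sv_B = bc.min_sv_B
            b_ok = min_sv_B > 1e-10
        except ValueError:
            pass

    return AssumptionReport(
        equal_dims=data.Ni == data.No,
        dims=(data.Ni, data.No),
        whitened=dev <= tol,
        whitening_deviation=dev,
        balanced=gap <= tol,
        balancedness_gap=gap,
        full_rank=full_rank,
        rank_task=rank_task,
        rank_init=rank_init,
        b_nonsingular=b_ok,
        min_sv_B=min_sv_B,
    )


def save_dataset(data: Dataset, directory: str | Path, meta: dict | None = None) -> None:
    """Write a dataset as two CSV tables (rows = dimensions, columns = samples)
    plus a JSON sidecar with the dimensions and any generator metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(data.X).to_csv(directory / "X.csv", header=False, index=False)
    pd.DataFrame(data.Y).to_csv(directory / "Y.csv", header=False, index=False)
    sidecar = {"Ni": data.Ni, "No": data.No, "P": data.P}
    if meta:
        sidecar.update(meta)
    (directory / "dataset.json").write_text(json.dumps(sidecar, indent=2))


def load_dataset(directory: str | Path) -> Dataset:
    """Read a dataset written by :func:`save_dataset`."""
    directory = Path(directory)
    X = pd.read_csv(directory / "X.csv", header=None).to_numpy(dtype=float)
    Y = pd.read_csv(directory / "Y.csv", header=None).to_numpy(dtype=float)
    return Dataset(X=X, Y=Y)
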