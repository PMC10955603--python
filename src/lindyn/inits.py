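"""Network initialisations and alignment diagnostics.

The exact solutions require *zero-balanced* weights, ``W1 W1^T = W2^T W2`` — a
condition conserved by gradient flow in linear networks.  All constructors
here produce exactly zero-balanced states via the symmetric square-root split
of a target network function's SVD: given ``M = U S V^T`` we set
``W1 = O S^{1/2} V^T`` and ``W2 = U S^{1/2} O^T`` with a random
column-orthonormal hidden-gauge ``O``.

The interaction between an initialisation and a task enters the closed-form
dynamics only through the alignment matrices ``B = U^T Utilde + V^T Vtilde``
and ``C = U^T Utilde - V^T Vtilde`` built from the two compact SVDs; the
general solution requires B to be invertible (it is singular exactly in
pathological cases such as reversal learning, where the initial function is
the negated task).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tasks import TaskSVD, compact_svd

__all__ = [
    "NetworkState",
    "AlignmentMatrices",
    "balancedness_gap",
    "random_balanced_init",
    "balanced_init_from_product",
    "aligned_init",
    "build_BC",
    "save_state",
    "load_state",
]

#: Absolute threshold on the smallest singular value of B below which the
#: general solution's bracket inverse is meaningless in double precision.
B_SINGULAR_TOL = 1e-10


@dataclass(frozen=True)
class NetworkState:
    """Weights of a two-layer linear network ``y = W2 W1 x``."""

    W1: np.ndarray  # (Nh, Ni)
    W2: np.ndarray  # (No, Nh)

    def __post_init__(self) -> None:
        W1 = np.asarray(self.W1, dtype=float)
        W2 = np.asarray(self.W2, dtype=float)
        if W1.ndim != 2 or W2.ndim != 2:
            raise ValueError("weights must be 2-D matrices")
        if W2.shape[1] != W1.shape[0]:
            raise ValueError(
                f"hidden dimensions disagree: W1 has {W1.shape[0]} rows, "
                f"W2 has {W2.shape[1]} columns"
            )
        object.__setattr__(self, "W1", W1)
        object.__setattr__(self, "W2", W2)

    @property
    def Ni(self) -> int:
        return self.W1.shape[1]

    @property
    def No(self) -> int:
        return self.W2.shape[0]

    @property
    def Nh(self) -> int:
        return self.W1.shape[0]

    @property
    def product(self) -> np.ndarray:
        """The network function W2 W1."""
        return self.W2 @ self.W1

    def qq_matrix(self) -> np.ndarray:
        """The (Ni+No) x (Ni+No) statistics matrix Q Q^T, Q = [W1^T; W2]."""
        Q = np.vstack([self.W1.T, self.W2])
        return Q @ Q.T


@dataclass(frozen=True)
class AlignmentMatrices:
    """B and C of an (initialisation, task) SVD pair, plus min singular value of B."""

    B: np.ndarray
    C: np.ndarray
    min_sv_B: float

    @property
    def b_nonsingular(self) -> bool:
        return self.min_sv_B > B_SINGULAR_TOL


def balancedness_gap(state: NetworkState) -> float:
    """Frobenius norm of the balancedness defect ``W1 W1^T - W2^T W2``."""
    return float(np.linalg.norm(state.W1 @ state.W1.T - state.W2.T @ state.W2))


def _balanced_from_svd(
    U: np.ndarray, s: np.ndarray, V: np.ndarray, Nh: int, rng: np.random.Generator
) -> NetworkState:
    """Zero-balanced factorisation W2 W1 = U diag(s) V^T with random hidden gauge."""
    Nm = s.size
    O = np.linalg.qr(rng.standard_normal((Nh, Nm)))[0]
    sqrt_s = np.sqrt(s)
    W1 = (O * sqrt_s) @ V.T
    W2 = (U * sqrt_s) @ O.T
    return NetworkState(W1=W1, W2=W2)


def random_balanced_init(
    Ni: int, No: int, Nh: int, scale: float, seed: int
) -> NetworkState:
    """Task-agnostic zero-balanced random initialisation of a given scale.

    Draws a random No x Ni Gaussian matrix with entry standard deviation
    ``scale``, and balanced-factorises it through the hidden layer.  The
    resulting state is exactly zero-balanced, and ``W2 W1`` is full rank with
    probability 1.  "Large" versus "small" initialisation is expressed solely
    through ``scale``; there are no separate code paths.
    """
    if Nh < min(Ni, No):
        raise ValueError(
            f"Nh={Nh} < min(Ni, No)={min(Ni, No)}: a bottlenecked network "
            "cannot reach a full-rank function (full-rank assumption)"
        )
    rng = np.random.default_rng(seed)
    G = scale * rng.standard_normal((No, Ni))
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    return _balanced_from_svd(U, s, Vt.T, Nh, rng)


def balanced_init_from_product(M: np.ndarray, Nh: int, seed: int = 0) -> NetworkState:
    """Zero-balanced state realising a prescribed network function ``W2 W1 = M``.

    Used to start a solver from a given function, e.g. a previously learned
    task's solution.
    """
    M = np.asarray(M, dtype=float)
    svd = compact_svd(M)
    if Nh < svd.rank:
        raise ValueError(f"Nh={Nh} < rank(M)={svd.rank}: cannot factor through hidden layer")
    rng = np.random.default_rng(seed)
    return _balanced_from_svd(svd.Utilde, svd.Stilde, svd.Vtilde, Nh, rng)


def aligned_init(A0: np.ndarray, task_svd: TaskSVD) -> NetworkState:
    """Initialisation sharing the task's singular vectors: W1 = A0 Vtilde^T, W2 = Utilde A0^T.

    Requires the square full-rank case (task rank equal to both Ni and No).
    The state is exactly zero-balanced (W1 W1^T = A0 A0^T = W2^T W2) and its
    function is ``Utilde (A0^T A0) Vtilde^T``, so the whole trajectory lives
    in the task's singular basis and reduces to the aligned closed form.
    """
    A0 = np.asarray(A0, dtype=float)
    Ni = task_svd.Vtilde.shape[0]
    No = task_svd.Utilde.shape[0]
    if task_svd.rank != Ni or task_svd.rank != No:
        raise ValueError(
            f"aligned form needs the square full-rank case: rank={task_svd.rank}, "
            f"Ni={Ni}, No={No}"
        )
    if A0.shape[1] != Ni:
        raise ValueError(f"A0 must have {Ni} columns, got {A0.shape[1]}")
    return NetworkState(W1=A0 @ task_svd.Vtilde.T, W2=task_svd.Utilde @ A0.T)


def build_BC(init_svd: TaskSVD, task_svd: TaskSVD) -> AlignmentMatrices:
    """Alignment matrices B = U^T Utilde + V^T Vtilde, C = U^T Utilde - V^T Vtilde.

    ``init_svd`` is the compact SVD of the initial network function, ``task_svd``
    that of Sigma_yx.  Both must retain the same rank.  The smallest singular
    value of B decides whether the stable general solution applies.
    """
    if init_svd.rank != task_svd.rank:
        raise ValueError(
            f"rank mismatch between initial function ({init_svd.rank}) and "
            f"task ({task_svd.rank})"
        )
    UtU = init_svd.Utilde.T @ task_svd.Utilde
    VtV = init_svd.Vtilde.T @ task_svd.Vtilde
    B = UtU + VtV
    C = UtU - VtV
    return AlignmentMatrices(B=B, C=C, min_sv_B=float(np.linalg.svd(B, compute_uv=False)[-1]))


def save_state(state: NetworkState, directory: str | Path, meta: dict | None = None) -> None:
    """Serialise a state as two CSV matrices plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(state.W1).to_csv(directory / "W1.csv", header=False, index=False)
    pd.DataFrame(state.W2).to_csv(directory / "W2.csv", header=False, index=False)
    sidecar = {"Ni": state.Ni, "No": state.No, "Nh": state.Nh}
    if meta:
        sidecar.update(meta)
    (directory / "state.json").write_text(json.dumps(sidecar, indent=2))


def load_state(directory: str | Path) -> NetworkState:
    directory = Path(directory)
    W1 = pd.read_csv(directory / "W1.csv", header=None).to_numpy(dtype=float)
    W2 = pd.read_csv(directory / "W2.csv", header=None).to_numpy(dtype=float)
    return NetworkState(W1=W1, W2=W2)
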