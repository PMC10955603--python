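"""Derived observables: loss, representational similarity, finite-width NTK,
and the catastrophic-forgetting loss formula.

All observables are functions of the statistics matrix QQ^T alone, so they can
be evaluated along analytic and simulated trajectories alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .riccati import QQBlock, Trajectory
from .tasks import TaskCorrelations

__all__ = [
    "RSM",
    "NTKMatrix",
    "network_function",
    "loss_from_function",
    "loss_curve",
    "hidden_rsm",
    "ntk",
    "forgetting_loss",
    "forgetting_matrix",
]

#: Whitening deviation above which the closed-form loss expansion is refused.
_WHITENED_TOL = 1e-8


@dataclass(frozen=True)
class RSM:
    """P x P representational similarity (kernel) matrix of hidden representations.

    ``side`` records which weights produced it: "input-weights" uses
    ``W1^T W1``, "output-weights" reads the same kernel back through the
    output weights.  For zero-balanced states the two coincide.
    """

    K: np.ndarray
    side: str


@dataclass(frozen=True)
class NTKMatrix:
    """(P*No) x (P*No) finite-width neural tangent kernel, sample-major order.

    Entry block (n, m) is ``(x_n^T x_m) W2 W2^T + (x_n^T W1^T W1 x_m) I``.
    """

    Theta: np.ndarray


def network_function(qq: QQBlock) -> np.ndarray:
    """Extract the network function W2 W1 (the bottom-left block of QQ^T)."""
    return qq.function


def loss_from_function(Wtot: np.ndarray, corr: TaskCorrelations) -> float:
    """Mean squared error of a total map under whitened inputs.

    ``L = 1/2 ||Wtot - Sigma_yx||_F^2 + c`` with the irreducible constant
    ``c = 1/2 (<||y||^2> - ||Sigma_yx||_F^2)``; this equals the sample
    average ``1/2 <||Wtot x - y||^2>`` exactly when ``Sigma_xx = I``.
    """
    if corr.whitening_deviation > _WHITENED_TOL:
        raise ValueError(
            "inputs are not whitened (||Sigma_xx - I||_F = "
            f"{corr.whitening_deviation:.3g}); use the simulator's "
            "sample-based loss instead"
        )
    c = 0.5 * (corr.mean_sq_target - np.sum(corr.Sigma_yx**2))
    return float(0.5 * np.sum((Wtot - corr.Sigma_yx) ** 2) + c)


def global_minimum(corr: TaskCorrelations) -> float:
    """The irreducible loss c attained at Wtot = Sigma_yx (whitened inputs)."""
    return loss_from_function(corr.Sigma_yx, corr)


def loss_curve(traj: Trajectory, corr: TaskCorrelations) -> np.ndarray:
    """Loss at every time of a trajectory (whitened inputs)."""
    return np.array([loss_from_function(qq.function, corr) for qq in traj.qq_blocks])


def hidden_rsm(qq: QQBlock, X: np.ndarray, side: str = "input-weights") -> RSM:
    """Kernel matrix of the hidden-layer representations over the inputs X.

    input-weights: ``K = X^T (W1^T W1) X`` from the top-left block.
    output-weights: ``K = X^T (W2 W1)^T (W2 W2^T)^+ (W2 W1) X`` from the
    bottom blocks, with a pseudoinverse.  Zero-balanced states make both
    sides equal, since the hidden representation then reads out identically
    through either layer.
    """
    X = np.asarray(X, dtype=float)
    if side == "input-weights":
        K = X.T @ qq.w1t_w1 @ X
    elif side == "output-weights":
        F = qq.function @ X
        K = F.T @ np.linalg.pinv(qq.w2_w2t) @ F
    else:
        raise ValueError(f"unknown side {side!r}")
    return RSM(K=0.5 * (K + K.T), side=side)


def ntk(qq: QQBlock, X: np.ndarray) -> NTKMatrix:
    """Finite-width neural tangent kernel of the network over inputs X.

    ``Theta = (X^T X) kron (W2 W2^T) + (X^T W1^T W1 X) kron I`` in
    sample-major order (row index = sample * No + output).  The first term is
    the output-weight Jacobian Gram matrix, the second the input-weight one.
    """
    X = np.asarray(X, dtype=float)
    No = qq.No
    Theta = np.kron(X.T @ X, qq.w2_w2t) + np.kron(X.T @ qq.w1t_w1 @ X, np.eye(No))
    return NTKMatrix(Theta=0.5 * (Theta + Theta.T))


def ntk_brute_force(W1: np.ndarray, W2: np.ndarray, X: np.ndarray) -> NTKMatrix:
    """NTK by explicit Jacobian contraction over every parameter entry.

    Independent oracle for :func:`ntk`: builds the full Jacobian of each
    output on each sample with respect to (W1, W2) and contracts.  O(P No
    (Nh Ni + No Nh)) memory — for small instances only.
    """
    No, Nh = W2.shape
    P = X.shape[1]
    n_params = W1.size + W2.size
    J = np.zeros((P * No, n_params))
    for n in range(P):
        x = X[:, n]
        h = W1 @ x
        for o in range(No):
            row = n * No + o
            # d yhat_o / d W1[h, i] = W2[o, h] * x[i]
            J[row, : W1.size] = np.outer(W2[o], x).ravel()
            # d yhat_o / d W2[o', h] = delta_{o o'} * h[h]
            dW2 = np.zeros((No, Nh))
            dW2[o] = h
            J[row, W1.size :] = dW2.ravel()
    return NTKMatrix(Theta=J @ J.T)


def forgetting_loss(Sigma_j: np.ndarray, corr_i: TaskCorrelations) -> float:
    """Loss on task i after training to convergence on task j.

    Catastrophic forgetting in this model is exact and pre-computable: any
    zero-balanced network trained to convergence on task j implements
    ``Sigma_j``, so its loss on task i is ``1/2 ||Sigma_j - Sigma_i||_F^2 +
    c_i`` with the constant depending only on task i's data.
    """
    Sigma_j = np.asarray(Sigma_j, dtype=float)
    if Sigma_j.shape != corr_i.Sigma_yx.shape:
        raise ValueError(
            f"shape mismatch: {Sigma_j.shape} vs {corr_i.Sigma_yx.shape}"
        )
    return loss_from_function(Sigma_j, corr_i)


def forgetting_matrix(corrs: list[TaskCorrelations]) -> np.ndarray:
    """T x T table of pre-computed losses: entry (j, i) = loss of task i after
    training to convergence on task j (rows = trained task, columns = evaluated
    task)."""
    T = len(corrs)
    out = np.zeros((T, T))
    for j in range(T):
        for i in range(T):
            out[j, i] = forgetting_loss(corrs[j].Sigma_yx, corrs[i])
    return out
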