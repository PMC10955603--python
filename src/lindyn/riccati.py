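"""Closed-form gradient-flow dynamics of two-layer linear networks.

Gradient flow on the mean squared error of ``y = W2 W1 x`` with whitened
inputs induces a matrix Riccati equation for the statistics matrix
``QQ^T`` with ``Q = [W1^T; W2]``, whose four quadrants hold ``W1^T W1``,
``W2 W2^T`` and the network function ``W2 W1``.  This module implements:

* the original matrix-Riccati solution (matrix exponentials of the coupling
  matrix F; kept for cross-validation — it mixes positive and negative
  exponentials and is numerically unstable at large times),
* the stable general solution built from the compact SVDs of the task and of
  the initial network function, valid for equal and unequal input/output
  dimensions and any zero-balanced full-rank initialisation with invertible
  alignment matrix B; it contains only negative exponentials,
* the aligned special case (initialisations sharing the task's singular
  vectors), its explicit 2x2 consequences (time of the off-diagonal coupling
  peak, the sigmoidal small-initialisation mode), and the exact exponential
  solution for shallow (one-layer) networks,
* the fixed point of the flow and a balanced rank-factorisation that recovers
  weights from a ``QQ^T`` block (up to the unobservable hidden-layer
  orthogonal gauge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .inits import NetworkState, build_BC
from .tasks import TaskSVD, compact_svd

__all__ = [
    "AssumptionViolation",
    "NumericalInstability",
    "QQBlock",
    "Trajectory",
    "TwoByTwoInit",
    "riccati_fukumizu",
    "exact_qqt",
    "fixed_point",
    "aligned_dynamics",
    "lift_aligned",
    "two_by_two_offdiag_peak",
    "sigmoid_mode",
    "shallow_dynamics",
    "factor_qqt",
    "default_time_grid",
]

#: Condition-number ceiling for the bracket solves; beyond this the solution
#: is meaningless in double precision and we refuse rather than return noise.
COND_MAX = 1e12


class AssumptionViolation(ValueError):
    """A standing assumption of the requested closed form does not hold."""


class NumericalInstability(RuntimeError):
    """A linear solve inside a closed form is too ill-conditioned to trust."""


@dataclass(frozen=True)
class QQBlock:
    """The symmetric (Ni+No) x (Ni+No) statistics matrix QQ^T at one time.

    Block layout: top-left Ni x Ni = ``W1^T W1``; bottom-right No x No =
    ``W2 W2^T``; bottom-left No x Ni = the network function ``W2 W1``
    (top-right its transpose).
    """

    M: np.ndarray
    Ni: int
    No: int

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        n = self.Ni + self.No
        if M.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {M.shape}")
        scale = max(np.linalg.norm(M), 1.0)
        if np.linalg.norm(M - M.T) > 1e-8 * scale:
            raise ValueError("QQ^T block is not symmetric")
        object.__setattr__(self, "M", 0.5 * (M + M.T))

    @property
    def w1t_w1(self) -> np.ndarray:
        return self.M[: self.Ni, : self.Ni]

    @property
    def w2_w2t(self) -> np.ndarray:
        return self.M[self.Ni :, self.Ni :]

    @property
    def function(self) -> np.ndarray:
        """The network function W2 W1 (bottom-left block)."""
        return self.M[self.Ni :, : self.Ni]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.M)[0])

    @classmethod
    def from_state(cls, state: NetworkState) -> "QQBlock":
        return cls(M=state.qq_matrix(), Ni=state.Ni, No=state.No)


@dataclass(frozen=True)
class Trajectory:
    """A time grid with one QQBlock per time.

    Times are in units of the gradient-flow time t, related to discrete
    gradient descent by t = (iteration) * eta with time constant tau = 1/eta.
    """

    times: np.ndarray
    qq_blocks: list[QQBlock]
    source: str  # "analytic" | "simulated"
    tau: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def functions(self) -> list[np.ndarray]:
        return [qq.function for qq in self.qq_blocks]


@dataclass(frozen=True)
class TwoByTwoInit:
    """Aligned 2x2 initialisation: A(0)^T A(0) = [[a1, b0], [b0, a2]].

    ``a1``, ``a2`` are the components aligned with the task's two singular
    modes (with singular values ``s1 >= s2``); ``b0`` is the cross-coupling
    between them.
    """

    a1: float
    a2: float
    b0: float
    s1: float
    s2: float

    @property
    def gram(self) -> np.ndarray:
        return np.array([[self.a1, self.b0], [self.b0, self.a2]])

    @property
    def is_positive_definite(self) -> bool:
        return self.a1 > 0 and self.a1 * self.a2 - self.b0**2 > 0


def default_time_grid(Stilde: np.ndarray, tau: float, n: int = 200) -> np.ndarray:
    """Log-spaced grid over [1e-3, 50] * tau / min(Stilde), 200 points by default."""
    t_unit = tau / float(np.min(Stilde))
    return np.geomspace(1e-3 * t_unit, 50.0 * t_unit, n)


def _solve_sym(A: np.ndarray, Bmat: np.ndarray, context: str) -> np.ndarray:
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > COND_MAX:
        raise NumericalInstability(
            f"{context}: bracket condition number {cond:.3g} exceeds {COND_MAX:.0e}"
        )
    return scipy.linalg.solve(A, Bmat, assume_a="sym")


def riccati_fukumizu(
    init: NetworkState, Sigma_yx: np.ndarray, times: np.ndarray, tau: float
) -> Trajectory:
    """Original matrix-Riccati solution for QQ^T (reference form).

    Valid only for equal input/output dimensions with non-singular Sigma_yx
    (so that the coupling matrix ``F = [[0, Sigma_yx^T], [Sigma_yx, 0]]`` is
    invertible), whitened inputs, zero-balanced weights and full rank.  It
    mixes growing and decaying matrix exponentials, so it loses precision and
    eventually fails at large times; use :func:`exact_qqt` for production work
    and this form for cross-validation at moderate times.
    """
    Sigma_yx = np.asarray(Sigma_yx, dtype=float)
    No, Ni = Sigma_yx.shape
    if No != Ni:
        raise AssumptionViolation(
            f"equal-dimensions assumption violated: Sigma_yx is {No}x{Ni}"
        )
    sv = np.linalg.svd(Sigma_yx, compute_uv=False)
    if sv[-1] <= 1e-12 * sv[0]:
        raise AssumptionViolation(
            "full-rank assumption violated: Sigma_yx is singular, F is not invertible"
        )
    F = np.block([[np.zeros((Ni, Ni)), Sigma_yx.T], [Sigma_yx, np.zeros((No, No))]])
    w, W = np.linalg.eigh(F)  # F symmetric; eigenvalues come in +/- pairs
    Q0 = np.vstack([init.W1.T, init.W2])
    blocks = []
    for t in np.asarray(times, dtype=float):
        theta = t / tau
        expF = (W * np.exp(w * theta)) @ W.T
        # exp(F t/tau) F^-1 exp(F t/tau) - F^-1 shares F's eigenbasis.
        mid = (W * ((np.exp(2 * w * theta) - 1.0) / w)) @ W.T
        EQ = expF @ Q0
        bracket = np.eye(Q0.shape[1]) + 0.5 * Q0.T @ mid @ Q0
        bracket = 0.5 * (bracket + bracket.T)
        qq = EQ @ _solve_sym(bracket, EQ.T, "matrix-Riccati reference form")
        blocks.append(QQBlock(M=0.5 * (qq + qq.T), Ni=Ni, No=No))
    return Trajectory(times=times, qq_blocks=blocks, source="analytic", tau=tau)


def exact_qqt(
    init: NetworkState,
    task_svd: TaskSVD,
    times: np.ndarray,
    tau: float,
    perturb_eps: float | None = None,
    perturb_seed: int = 0,
) -> Trajectory:
    """Stable general closed form for QQ^T(t) from a zero-balanced initialisation.

    Requires whitened inputs, zero-balanced weights, full-rank task and
    initial function of equal rank, and an invertible alignment matrix
    ``B = U^T Utilde + V^T Vtilde``.  Supports equal and unequal input/output
    dimensions; only decaying exponentials appear, so the evaluation is stable
    at arbitrarily large times.

    Parameters
    ----------
    perturb_eps : float, optional
        Diagnostic fallback for singular B (e.g. reversal learning, where the
        initial function is the negated task and the flow sits exactly on a
        saddle separatrix): perturb the initial function by ``eps`` times a
        random unit-scale balanced function, then solve.  Never applied
        silently; the eps used is recorded in the trajectory metadata.
    """
    init_product = init.product
    if perturb_eps is not None:
        rng = np.random.default_rng(perturb_seed)
        G = rng.standard_normal(init_product.shape)
        init_product = init_product + perturb_eps * G / np.linalg.norm(G)
    init_svd = compact_svd(init_product)
    bc = build_BC(init_svd, task_svd)
    if not bc.b_nonsingular and perturb_eps is None:
        raise AssumptionViolation(
            f"alignment matrix B is singular (min singular value "
            f"{bc.min_sv_B:.3g} <= 1e-10); the general closed form does not "
            "apply. Pass perturb_eps (e.g. 1e-6) for the diagnostic "
            "perturbation fallback, or use the gradient-descent simulator."
        )
    U, S, V = init_svd.Utilde, init_svd.Stilde, init_svd.Vtilde
    Ut, St, Vt = task_svd.Utilde, task_svd.Stilde, task_svd.Vtilde
    Ni, No, Nm = Vt.shape[0], Ut.shape[0], task_svd.rank

    Binv = np.linalg.inv(bc.B)
    BinvT = Binv.T
    BC = Binv @ bc.C
    K1 = (Binv / S[None, :]) @ BinvT  # B^-1 S^-1 B^-T
    PvV = task_svd.Pv_perp @ V  # Vperp Vperp^T V
    PuU = task_svd.Pu_perp @ U
    proj = V.T @ PvV + U.T @ PuU
    Kp = Binv @ proj @ BinvT
    G = bc.C.T @ BinvT  # C^T B^-T

    blocks = []
    for t in np.asarray(times, dtype=float):
        e = np.exp(-St * t / tau)
        e2 = e**2
        EGE = e[:, None] * G * e[None, :]
        bracket = (
            4.0 * e[:, None] * K1 * e[None, :]
            + np.diag((1.0 - e2) / St)
            - ((e[:, None] * BC) * ((e2 - 1.0) / St)[None, :]) @ (BC.T * e[None, :])
            + 4.0 * (t / tau) * e[:, None] * Kp * e[None, :]
        )
        bracket = 0.5 * (bracket + bracket.T)
        Ztop = Vt @ (np.eye(Nm) - EGE) + 2.0 * PvV @ (BinvT * e[None, :])
        Zbot = Ut @ (np.eye(Nm) + EGE) + 2.0 * PuU @ (BinvT * e[None, :])
        Z = np.vstack([Ztop, Zbot])
        qq = Z @ _solve_sym(bracket, Z.T, f"general solution at t={t:g}")
        blocks.append(QQBlock(M=0.5 * (qq + qq.T), Ni=Ni, No=No))
    meta = {} if perturb_eps is None else {"perturb_eps": perturb_eps, "perturb_seed": perturb_seed}
    return Trajectory(times=times, qq_blocks=blocks, source="analytic", tau=tau, meta=meta)


def fixed_point(task_svd: TaskSVD) -> QQBlock:
    """Steady state of the flow: the global minimum with rich representations.

    ``W1^T W1 = Vtilde Stilde Vtilde^T``, ``W2 W2^T = Utilde Stilde Utilde^T``
    and network function ``Utilde Stilde Vtilde^T`` — the internal similarity
    structure mirrors the task's, for every zero-balanced initialisation.
    """
    Ut, St, Vt = task_svd.Utilde, task_svd.Stilde, task_svd.Vtilde
    Ni, No = Vt.shape[0], Ut.shape[0]
    top = (Vt * St) @ Vt.T
    bot = (Ut * St) @ Ut.T
    fun = (Ut * St) @ Vt.T
    M = np.block([[top, fun.T], [fun, bot]])
    return QQBlock(M=M, Ni=Ni, No=No)


def aligned_dynamics(
    A0tA0: np.ndarray, Stilde: np.ndarray, times: np.ndarray, tau: float
) -> list[np.ndarray]:
    """Dynamics in the task's singular basis for aligned initialisations.

    For ``W1 = A(0) Vtilde^T``, ``W2 = Utilde A(0)^T`` (square full-rank case)
    the whole trajectory is carried by ``A^T A(t) = [E (A0^T A0)^{-1} E +
    (I - E^2) Stilde^{-1}]^{-1}`` with ``E = exp(-Stilde t/tau)``.  Diagonal
    entries are per-mode connection strengths (converging to the task singular
    values); off-diagonals are counterproductive cross-mode couplings
    (converging to zero).
    """
    A0tA0 = np.asarray(A0tA0, dtype=float)
    Stilde = np.asarray(Stilde, dtype=float)
    sv = np.linalg.svd(A0tA0, compute_uv=False)
    if sv[-1] <= 1e-12 * sv[0]:
        raise AssumptionViolation(
            "A(0)^T A(0) is singular; the aligned closed form requires an "
            "invertible A(0)"
        )
    A0inv = np.linalg.inv(A0tA0)
    out = []
    for t in np.asarray(times, dtype=float):
        e = np.exp(-Stilde * t / tau)
        bracket = e[:, None] * A0inv * e[None, :] + np.diag((1.0 - e**2) / Stilde)
        out.append(np.linalg.inv(0.5 * (bracket + bracket.T)))
    return out


def lift_aligned(
    atats: list[np.ndarray], task_svd: TaskSVD, times: np.ndarray, tau: float
) -> Trajectory:
    """Lift aligned-basis dynamics A^T A(t) to full QQ^T blocks via Utilde, Vtilde."""
    Ut, Vt = task_svd.Utilde, task_svd.Vtilde
    Ni, No = Vt.shape[0], Ut.shape[0]
    blocks = []
    for A in atats:
        top = Vt @ A @ Vt.T
        bot = Ut @ A @ Ut.T
        fun = Ut @ A @ Vt.T
        blocks.append(QQBlock(M=np.block([[top, fun.T], [fun, bot]]), Ni=Ni, No=No))
    return Trajectory(times=times, qq_blocks=blocks, source="analytic", tau=tau)


def two_by_two_offdiag_peak(init2: TwoByTwoInit, tau: float) -> float | None:
    """Time of the transient peak of the cross-coupling |b(t)| in the 2x2 case.

    For equal task singular values ``s1 = s2 = s`` the off-diagonal of
    ``A^T A(t)`` peaks at ``t_peak = tau/(4s) * ln[s(s - a1 - a2) /
    (a1 a2 - b(0)^2)]`` provided the log argument exceeds 1 (an interior peak
    exists).  Returns None when the trajectory is monotone — in particular for
    decoupled inits (b0 = 0, the coupling stays identically zero) and for
    large initialisations, where no peak is observed.

    The formula is the small-initialisation form: writing mu_1, mu_2 for the
    eigenvalues of A(0)^T A(0), the exact peak sits at ``tau/(4s) *
    ln[(s - mu1)(s - mu2)/(mu1 mu2)]``; the printed expression replaces
    ``(s - mu1)(s - mu2)`` by ``s(s - mu1 - mu2)``, a relative error of order
    ``(a/s)^2`` in the log argument.
    """
    if init2.s1 != init2.s2:
        raise AssumptionViolation(
            f"the peak-time formula assumes equal singular values; got "
            f"s1={init2.s1}, s2={init2.s2}"
        )
    if init2.b0 == 0.0:
        return None
    s = init2.s1
    denom = init2.a1 * init2.a2 - init2.b0**2
    if denom <= 0.0:
        raise AssumptionViolation(
            "A(0)^T A(0) must be positive definite (a1*a2 - b0^2 > 0)"
        )
    arg = s * (s - init2.a1 - init2.a2) / denom
    if arg <= 1.0:
        return None
    return tau / (4.0 * s) * float(np.log(arg))


def sigmoid_mode(
    a1_0: float, a2_0: float, s: float, times: np.ndarray, tau: float
) -> np.ndarray:
    """Sigmoidal single-mode trajectory of the small-initialisation regime.

    ``a1(t) = s a1(0) / (exp(-2 s t / tau) [s - a1(0) - a2(0)] + a1(0) + a2(0))``
    for equal task singular values s and small aligned components.  The
    formula is evaluated as printed for any arguments; it is an accurate
    description of the (1,1) aligned component only when |a1(0)|, |a2(0)|,
    |b(0)| are all much smaller than s.
    """
    times = np.asarray(times, dtype=float)
    a_sum = a1_0 + a2_0
    denom = np.exp(-2.0 * s * times / tau) * (s - a_sum) + a_sum
    out = np.zeros_like(times)
    nz = denom != 0.0
    out[nz] = s * a1_0 / denom[nz]
    return out


def shallow_dynamics(
    W0: np.ndarray, Sigma_yx: np.ndarray, times: np.ndarray, tau: float
) -> list[np.ndarray]:
    """Exact dynamics of a shallow (one-layer) linear network, whitened inputs.

    Gradient flow of the mean squared error is the linear ODE
    ``tau dW/dt = Sigma_yx - W``, solved by ``W(t) = Sigma_yx +
    (W(0) - Sigma_yx) exp(-t/tau)``: plain exponential convergence with no
    saddles, which is why shallow networks do not slow down catastrophically
    under reversal learning.
    """
    W0 = np.asarray(W0, dtype=float)
    Sigma_yx = np.asarray(Sigma_yx, dtype=float)
    D = W0 - Sigma_yx
    return [Sigma_yx + D * np.exp(-t / tau) for t in np.asarray(times, dtype=float)]


def factor_qqt(qq: QQBlock, Nh: int, seed: int = 0) -> NetworkState:
    """Recover a zero-balanced weight state from a QQ^T block.

    The weights are determined only up to a time-varying orthogonal
    transformation of the hidden layer; this returns one representative with a
    seed-controlled gauge, reconstructed from the balanced factorisation of
    the function block.  Valid for QQ^T matrices of zero-balanced states
    (which all analytic trajectories preserve).
    """
    min_eig = qq.min_eigenvalue()
    if min_eig < -1e-8 * max(np.linalg.norm(qq.M), 1.0):
        raise ValueError(f"QQ^T is not positive semidefinite (min eigenvalue {min_eig:.3g})")
    M = qq.function
    if np.linalg.norm(M) == 0.0:
        return NetworkState(W1=np.zeros((Nh, qq.Ni)), W2=np.zeros((qq.No, Nh)))
    from .inits import balanced_init_from_product

    return balanced_init_from_product(M, Nh, seed=seed)
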