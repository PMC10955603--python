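"""Full-batch gradient-descent simulation, the numerical verification oracle.

Discrete gradient descent with learning rate eta approximates the gradient
flow ``tau dW/dt = -grad L`` with time constant tau = 1/eta, time measured in
iterations: iteration k corresponds to flow time t = k (so t/tau = k*eta).  The linear simulator uses the exact correlation-matrix
gradients; the nonlinear simulator (tanh / ReLU at the hidden layer)
backpropagates per sample.  A continual-learning runner chains tasks, using
either the analytic solver or the simulator per leg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inits import NetworkState, balancedness_gap
from .observables import forgetting_matrix, global_minimum, loss_from_function
from .riccati import (
    AssumptionViolation,
    QQBlock,
    Trajectory,
    exact_qqt,
    factor_qqt,
)
from .tasks import Dataset, compute_correlations, compact_svd

__all__ = [
    "SimConfig",
    "NonlinearRun",
    "ContinualResult",
    "simulate_gd",
    "simulate_nonlinear",
    "continual_run",
]

_MAX_STEPS_GUARD = 10**6
_DIVERGENCE_FACTOR = 1e6


@dataclass(frozen=True)
class SimConfig:
    """Gradient-descent settings.

    eta is the learning rate (flow time constant tau = 1/eta); conv_tol is the
    loss excess above the analytic global minimum at which a run counts as
    converged; start_noise optionally adds a tiny Gaussian perturbation to the
    weights at step 0 (useful to escape exact saddle initialisations — by
    default only float rounding perturbs the dynamics).
    """

    eta: float = 5e-4
    steps: int = 100_000
    record_stride: int = 100
    activation: str = "linear"  # linear | tanh | relu
    conv_tol: float = 1e-8
    seed: int = 0
    start_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.steps > _MAX_STEPS_GUARD:
            raise ValueError(f"steps exceeds the {_MAX_STEPS_GUARD} guard")
        if self.activation not in ("linear", "tanh", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def tau(self) -> float:
        return 1.0 / self.eta


@dataclass(frozen=True)
class NonlinearRun:
    """Recorded loss and balancedness-defect curves of a per-sample GD run."""

    times: np.ndarray
    losses: np.ndarray
    balancedness_gaps: np.ndarray
    final_state: NetworkState


@dataclass(frozen=True)
class ContinualResult:
    """Outcome of sequential training on several tasks.

    ``final_loss_matrix[j, i]`` is the loss on task i after training leg j to
    convergence; ``predicted_matrix`` holds the pre-computable analytic values
    ``1/2 ||Sigma_j - Sigma_i||_F^2 + c_i``.  ``loss_curves[j][i]`` tracks
    task i's loss over leg j's training times.
    """

    final_loss_matrix: np.ndarray
    predicted_matrix: np.ndarray
    leg_times: list[np.ndarray]
    loss_curves: list[np.ndarray]  # leg j -> (n_tasks, n_times)
    engine: str
    minima: np.ndarray


def _maybe_perturb(state: NetworkState, cfg: SimConfig) -> NetworkState:
    if cfg.start_noise == 0.0:
        return state
    rng = np.random.default_rng(cfg.seed)
    return NetworkState(
        W1=state.W1 + cfg.start_noise * rng.standard_normal(state.W1.shape),
        W2=state.W2 + cfg.start_noise * rng.standard_normal(state.W2.shape),
    )


def _sample_loss(W1: np.ndarray, W2: np.ndarray, data: Dataset) -> float:
    R = W2 @ (W1 @ data.X) - data.Y
    return float(0.5 * np.sum(R**2) / data.P)


def simulate_gd(
    init: NetworkState,
    data: Dataset,
    cfg: SimConfig,
    stop_at_loss: float | None = None,
) -> Trajectory:
    """Full-batch gradient descent on the linear network, recording QQ^T.

    Uses the exact correlation-matrix gradients
    ``dW1 = -eta W2^T (W2 W1 Sigma_xx - Sigma_yx)``,
    ``dW2 = -eta (W2 W1 Sigma_xx - Sigma_yx) W1^T``,
    algebraically identical to per-sample full-batch backpropagation.
    Snapshots every ``record_stride`` iterations (plus the initial and final
    states).  ``stop_at_loss`` ends the run early once the sample loss drops
    to that value or below (checked at snapshot times).
    """
    if cfg.activation != "linear":
        raise ValueError("simulate_gd is the linear-network simulator; "
                         "use simulate_nonlinear for tanh/relu")
    corr = compute_correlations(data)
    Sxx, Syx = corr.Sigma_xx, corr.Sigma_yx
    state = _maybe_perturb(init, cfg)
    W1, W2 = state.W1.copy(), state.W2.copy()
    eta = cfg.eta
    loss0 = max(_sample_loss(W1, W2, data), 1e-30)

    times = [0.0]
    blocks = [QQBlock.from_state(NetworkState(W1=W1, W2=W2))]
    for k in range(1, cfg.steps + 1):
        R = W2 @ W1 @ Sxx - Syx
        gW1 = W2.T @ R
        gW2 = R @ W1.T
        W1 -= eta * gW1
        W2 -= eta * gW2
        if k % cfg.record_stride == 0 or k == cfg.steps:
            loss = _sample_loss(W1, W2, data)
            if not np.isfinite(loss) or loss > _DIVERGENCE_FACTOR * loss0:
                raise RuntimeError(
                    f"gradient descent diverged at step {k} (loss {loss:.3g}); "
                    f"reduce eta below the discrete stability threshold"
                )
            times.append(float(k))
            blocks.append(QQBlock.from_state(NetworkState(W1=W1, W2=W2)))
            if stop_at_loss is not None and loss <= stop_at_loss:
                break
    return Trajectory(
        times=np.array(times), qq_blocks=blocks, source="simulated", tau=cfg.tau
    )


def simulate_nonlinear(init: NetworkState, data: Dataset, cfg: SimConfig) -> NonlinearRun:
    """Per-sample full-batch GD with an optional hidden-layer nonlinearity.

    ``yhat = W2 phi(W1 x)`` with phi linear, tanh or ReLU applied at the
    hidden layer only.  Records the loss and the balancedness defect
    ``||W1 W1^T - W2^T W2||_F`` over training: nonlinearities rapidly
    unbalance the weights, which is what breaks the closed-form forgetting
    predictions in nonlinear networks.
    """
    if cfg.activation == "tanh":
        phi, dphi = np.tanh, lambda z: 1.0 - np.tanh(z) ** 2
    elif cfg.activation == "relu":
        phi, dphi = lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)
    else:
        phi, dphi = lambda z: z, lambda z: np.ones_like(z)

    state = _maybe_perturb(init, cfg)
    W1, W2 = state.W1.copy(), state.W2.copy()
    X, Y, P = data.X, data.Y, data.P
    eta = cfg.eta

    def loss_of() -> float:
        return float(0.5 * np.sum((W2 @ phi(W1 @ X) - Y) ** 2) / P)

    loss0 = max(loss_of(), 1e-30)
    times, losses, gaps = [0.0], [loss_of()], [balancedness_gap(NetworkState(W1=W1, W2=W2))]
    for k in range(1, cfg.steps + 1):
        Z = W1 @ X
        H = phi(Z)
        E = (W2 @ H - Y) / P
        gW2 = E @ H.T
        gW1 = ((W2.T @ E) * dphi(Z)) @ X.T
        W1 -= eta * gW1
        W2 -= eta * gW2
        if k % cfg.record_stride == 0 or k == cfg.steps:
            loss = loss_of()
            if not np.isfinite(loss) or loss > _DIVERGENCE_FACTOR * loss0:
                raise RuntimeError(
                    f"gradient descent diverged at step {k} (loss {loss:.3g}); "
                    f"reduce eta below the discrete stability threshold"
                )
            times.append(float(k))
            losses.append(loss)
            gaps.append(balancedness_gap(NetworkState(W1=W1, W2=W2)))
    return NonlinearRun(
        times=np.array(times),
        losses=np.array(losses),
        balancedness_gaps=np.array(gaps),
        final_state=NetworkState(W1=W1, W2=W2),
    )


def _analytic_convergence_time(task_svd, init_loss_excess: float, conv_tol: float, tau: float) -> float:
    """Time at which the slowest mode's excess has decayed below conv_tol."""
    s_min = float(np.min(task_svd.Stilde))
    excess = max(init_loss_excess, conv_tol * 10)
    # loss excess decays at least like exp(-2 s_min t / tau) near the optimum;
    # the factor 2 margin covers the transient.
    return 2.0 * tau / (2.0 * s_min) * np.log(excess / conv_tol)


def continual_run(
    task_seq: list[Dataset],
    init: NetworkState,
    cfg: SimConfig,
    engine: str = "analytic",
    n_times_per_leg: int = 50,
) -> ContinualResult:
    """Train on a sequence of tasks, each to convergence, chaining states.

    The final state after one task becomes the initial state for the next.
    ``engine="analytic"`` solves every leg with the stable closed form
    (each leg must satisfy its assumptions, including invertible B) and chains
    through the balanced rank factorisation; ``engine="simulated"`` runs
    gradient descent and chains weights directly.  Every task's loss is
    evaluated throughout each leg, and the final-loss matrix is compared
    against the pre-computable forgetting predictions.
    """
    if engine not in ("analytic", "simulated"):
        raise ValueError(f"unknown engine {engine!r}")
    corrs = [compute_correlations(d) for d in task_seq]
    for j, corr in enumerate(corrs):
        if corr.whitening_deviation > 1e-8:
            raise AssumptionViolation(f"task {j} is not whitened")
    svds = [compact_svd(c.Sigma_yx) for c in corrs]
    minima = np.array([global_minimum(c) for c in corrs])
    T = len(task_seq)
    tau = cfg.tau

    state = init
    final_losses = np.zeros((T, T))
    leg_times: list[np.ndarray] = []
    loss_curves: list[np.ndarray] = []
    for j in range(T):
        corr, svd = corrs[j], svds[j]
        if engine == "analytic":
            excess = loss_from_function(state.product, corr) - minima[j]
            T_conv = _analytic_convergence_time(svd, excess, cfg.conv_tol, tau)
            times = np.linspace(T_conv / n_times_per_leg, T_conv, n_times_per_leg)
            try:
                traj = exact_qqt(state, svd, times, tau)
            except AssumptionViolation as err:
                raise AssumptionViolation(
                    f"analytic engine failed on leg {j}: {err} "
                    "(use engine='simulated' or the perturbation fallback)"
                ) from err
            state = factor_qqt(traj.qq_blocks[-1], state.Nh, seed=cfg.seed + j)
        else:
            traj = simulate_gd(state, task_seq[j], cfg,
                               stop_at_loss=minima[j] + cfg.conv_tol)
            last = traj.qq_blocks[-1]
            state = factor_qqt(last, state.Nh, seed=cfg.seed + j)
            times = traj.times
        curves = np.array(
            [[loss_from_function(qq.function, corrs[i]) for qq in traj.qq_blocks]
             for i in range(T)]
        )
        leg_times.append(np.asarray(times))
        loss_curves.append(curves)
        final_fun = traj.qq_blocks[-1].function
        for i in range(T):
            final_losses[j, i] = loss_from_function(final_fun, corrs[i])

    return ContinualResult(
        final_loss_matrix=final_losses,
        predicted_matrix=forgetting_matrix(corrs),
        leg_times=leg_times,
        loss_curves=loss_curves,
        engine=engine,
        minima=minima,
    )
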