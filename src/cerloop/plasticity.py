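"""Learning rules for the loop: delta rules, delayed-target cerebellar
plasticity, e-prop gradients for cortical weights, and the optimizer.

Three plasticity regimes constrain which cortical weights learn:

* ``fixed_rnn``     — only the readout W_rdt (and always the parallel fibres);
* ``input_plastic`` — additionally the input and feedback weights W_ih, W_Ch
  (W_zh for the readout-feedback variant);
* ``fully_plastic`` — additionally the recurrent weights W_hh.

Cortical temporal credit assignment avoids backpropagation through time:
each synapse carries a leaky eligibility trace eps^t = alpha * eps^{t-1} +
a_i^t of its presynaptic activity, and the weight gradient is the sum over
time of the instantaneous learning signal L_j^t = dE_t/dh_j^t (one-step
spatial backpropagation through the readout) times the trace.  Because the
trace depends only on alpha and the presynaptic activity, it is stored per
presynaptic unit, O(n) instead of O(n^2) — algebraically identical.

The cerebellum learns with a behavioural timing-specific rule: parallel
fibres pair the cerebellar output tau steps in the past with the current
target, Delta W_PF ∝ (dE/dc_{t-tau}) g_{t-tau}^T, which after training makes
c_t a prediction of y_{t+tau}.  With a temporal basis {tau_i} each window
addresses its own slice of the feedback vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .model import ModelParams, Trajectory, VariantConfig, run_trial, softmax

__all__ = [
    "REGIMES",
    "LearningConfig",
    "EligibilityState",
    "AdamState",
    "task_loss",
    "delta_readout",
    "delta_parallel_fibres",
    "eligibility_update",
    "eprop_gradient",
    "adam_step",
    "trainable_weights",
    "train_session",
]

REGIMES = ("fixed_rnn", "input_plastic", "fully_plastic")

LossKind = Literal["mse", "cross_entropy"]


@dataclass
class LearningConfig:
    """Learning rates, loss, cerebellar time windows and session sizes.

    ``eta`` applies to the readout and parallel fibres; ``eta_rnn`` to the
    e-prop-trained cortical weights (defaults to ``eta``; 0.0025 gives more
    stable learning in the delayed association task).  ``tau_windows`` lists
    the cerebellar windows in timesteps — ``(3,)`` is the single-window
    default (~150 ms for the motor tasks, ~600 ms for the cognitive tasks at
    their respective step sizes); ``(0, 1, 2, 3, 4, 5)`` is the temporal
    basis.  A session covers ``n_train_examples`` examples in batches of
    ``batch_size`` (each batch is one "trial" = one optimizer step)."""

    eta: float = 0.001
    eta_rnn: float | None = None
    loss_kind: LossKind = "mse"
    tau_windows: tuple[int, ...] = (3,)
    regime: str = "fixed_rnn"
    batch_size: int = 10
    n_train_examples: int = 1000
    n_test: int = 1000

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if any(t < 0 for t in self.tau_windows):
            raise ValueError("cerebellar time windows must be non-negative")
        if self.eta_rnn is None:
            self.eta_rnn = self.eta

    @property
    def n_trials(self) -> int:
        return self.n_train_examples // self.batch_size


@dataclass
class EligibilityState:
    """Per-presynaptic-unit traces and the current learning signal."""

    eps: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (batch, n_pre)
    L: np.ndarray | None = None  # (batch, n_rnn)


def task_loss(
    z: np.ndarray, y: np.ndarray, mask: np.ndarray, loss_kind: LossKind
) -> tuple[float, np.ndarray]:
    """Masked task error and its exact per-step output gradient.

    ``z``, ``y`` are (T, batch, n_out); ``mask`` is a boolean (T,) vector of
    supervised timesteps.  MSE averages over masked steps, batch and output
    dimensions; cross-entropy treats ``z`` as logits, requires one-hot (or
    probability) targets on masked steps, and averages over masked steps and
    batch.  The returned gradient is zero off-mask and already carries the
    averaging factors, so downstream rules simply sum over time and batch.
    """
    T, batch, n_out = z.shape
    mask = np.asarray(mask, dtype=bool)
    n_masked = int(mask.sum())
    if n_masked == 0:
        raise ValueError("loss mask selects no timesteps")
    dE_dz = np.zeros_like(z)
    if loss_kind == "mse":
        diff = z[mask] - y[mask]
        denom = n_masked * batch * n_out
        loss = float(np.sum(diff**2) / denom)
        dE_dz[mask] = 2.0 * diff / denom
    elif loss_kind == "cross_entropy":
        ym = y[mask]
        if np.any(ym < 0) or not np.allclose(ym.sum(axis=-1), 1.0, atol=1e-6):
            raise ValueError("cross_entropy targets must be probability vectors (e.g. one-hot)")
        p = softmax(z[mask])
        denom = n_masked * batch
        loss = float(-np.sum(ym * np.log(np.clip(p, 1e-12, None))) / denom)
        dE_dz[mask] = (p - ym) / denom
    else:
        raise ValueError(f"unknown loss kind {loss_kind!r}")
    return loss, dE_dz


def delta_readout(
    dE_dz: np.ndarray, h: np.ndarray, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Delta-rule gradient for the readout: sum_t (dE_t/dz_t) f(h_t)^T.

    ``h`` is the (T+1, batch, n_rnn) state record of the trajectory.
    Returns ``(grad_W_rdt, grad_b_rdt)`` accumulated over timesteps and
    batch (the batch average is already inside ``dE_dz``)."""
    fh = params.f(h[1:])  # (T, batch, n_rnn)
    grad_W = np.einsum("tbo,tbj->oj", dE_dz, fh)
    grad_b = dE_dz.sum(axis=(0, 1))
    return grad_W, grad_b


def delta_parallel_fibres(
    traj: Trajectory,
    y: np.ndarray,
    mask: np.ndarray,
    tau_windows: tuple[int, ...],
    loss_kind: LossKind,
    params: ModelParams,
) -> np.ndarray:
    """Behavioural timing-specific parallel-fibre gradient.

    For every supervised timestep t and every window tau_i, the window's
    slice of the cerebellar output at t - tau_i is compared with the target
    y_t, and the resulting error gradient is paired with the granule
    activity g_{t-tau_i}.  Pairs with t - tau_i < 1 are skipped.  With
    softmax-bounded feedback the rule is applied to the pre-softmax output
    through a cross-entropy loss, which keeps the update local.  Granule
    columns inactive under a context mask carry zero activity and therefore
    receive no update.
    """
    if traj.c is None or traj.g is None:
        raise ValueError("trajectory carries no cerebellar record")
    T, batch, _ = traj.z.shape
    n_out = y.shape[-1]
    mask = np.asarray(mask, dtype=bool)
    grad = np.zeros_like(params.W_PF)
    any_pairs = False
    for i, tau in enumerate(tau_windows):
        rows = slice(i * n_out, (i + 1) * n_out)
        ts = [t for t in range(1, T + 1) if mask[t - 1] and t - tau >= 1]
        if not ts:
            continue
        any_pairs = True
        pred = np.stack([traj.c[t - tau - 1, :, rows] for t in ts])  # (P, batch, n_out)
        targ = np.stack([y[t - 1] for t in ts])
        g = np.stack([traj.g[t - tau - 1] for t in ts])  # (P, batch, n_granule)
        n_pairs = len(ts)
        if loss_kind == "mse":
            d = 2.0 * (pred - targ) / (n_pairs * batch * n_out)
        else:
            d = (softmax(pred) - targ) / (n_pairs * batch)
        grad[rows] += np.einsum("pbo,pbg->og", d, g)
    if not any_pairs:
        warnings.warn("all cerebellar windows exceed the trial length; zero PF update")
    return grad


def eligibility_update(eps_prev: np.ndarray, a: np.ndarray, alpha: float) -> np.ndarray:
    """Leaky accumulation eps^t = alpha * eps^{t-1} + a^t of presynaptic activity."""
    return alpha * eps_prev + a


def _learning_signal(
    dE_dz_t: np.ndarray, h_t: np.ndarray, params: ModelParams, variant: str
) -> np.ndarray:
    """L_j^t = dE_t/dh_j^t by one-step spatial backpropagation.

    Through the linear readout for all variants except cerebellar_readout,
    where the signal is backpropagated one step through the cerebellar
    network instead."""
    if variant == "cerebellar_readout":
        pre_g = params.f(h_t) @ params.W_MF.T
        d_g = (dE_dz_t @ params.W_PF) * (pre_g > 0)
        return (d_g @ params.W_MF) * params.f_prime(h_t)
    return (dE_dz_t @ params.W_rdt) * params.f_prime(h_t)


def eprop_gradient(
    traj: Trajectory,
    dE_dz: np.ndarray,
    params: ModelParams,
    regime: str,
    variant: str = "cerebellar_feedback",
) -> dict[str, np.ndarray]:
    """e-prop gradients for the cortical weights permitted by the regime.

    Delta w_ji = sum_t L_j^t eps_ji^t, with the trace driven by the
    presynaptic activity appropriate to each matrix: x_t for W_ih, the
    injected feedback for W_Ch / W_zh, and f(h_{t-1}) for W_hh.  Returns an
    empty dict under ``fixed_rnn``."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    if regime == "fixed_rnn":
        return {}
    T, batch, _ = traj.z.shape
    names = ["W_ih"]
    if variant == "cerebellar_feedback":
        names.append("W_Ch")
    elif variant == "readout_feedback":
        names.append("W_zh")
    if regime == "fully_plastic":
        names.append("W_hh")

    def presyn(name: str, t: int) -> np.ndarray:
        if name == "W_ih":
            return traj.x[t - 1]
        if name in ("W_Ch", "W_zh"):
            return traj.fb[t - 1]
        return params.f(traj.h[t - 1])

    state = EligibilityState(
        eps={name: np.zeros((batch, presyn(name, 1).shape[-1])) for name in names}
    )
    grads = {name: np.zeros_like(getattr(params, name)) for name in names}
    for t in range(1, T + 1):
        state.L = _learning_signal(dE_dz[t - 1], traj.h[t], params, variant)
        for name in names:
            state.eps[name] = eligibility_update(
                state.eps[name], presyn(name, t), params.alpha
            )
            grads[name] += np.einsum("bj,bi->ji", state.L, state.eps[name])
    return grads


@dataclass
class AdamState:
    """First/second-moment accumulators of the ADAM optimizer."""

    beta1: float = 0.9
    beta2: float = 0.999
    eps_stab: float = 1e-8
    t: int = 0
    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)

    def begin_step(self) -> None:
        self.t += 1


def adam_step(
    state: AdamState, name: str, param: np.ndarray, grad: np.ndarray, eta: float
) -> np.ndarray:
    """In-place bias-corrected adaptive update of one parameter."""
    if name not in state.m:
        state.m[name] = np.zeros_like(param)
        state.v[name] = np.zeros_like(param)
    m = state.m[name] = state.beta1 * state.m[name] + (1 - state.beta1) * grad
    v = state.v[name] = state.beta2 * state.v[name] + (1 - state.beta2) * grad**2
    m_hat = m / (1 - state.beta1**state.t)
    v_hat = v / (1 - state.beta2**state.t)
    param -= eta * m_hat / (np.sqrt(v_hat) + state.eps_stab)
    return param


def trainable_weights(cfg: LearningConfig, variant: VariantConfig) -> list[str]:
    """Names of the parameters updated under the configured regime/variant.

    The parallel fibres always learn; the mossy fibres never do."""
    names: list[str] = []
    if variant.variant != "cerebellar_readout":
        names += ["W_rdt", "b_rdt"]
    if variant.variant in ("cerebellar_feedback", "cerebellar_readout"):
        names.append("W_PF")
    if cfg.regime != "fixed_rnn":
        names.append("W_ih")
        if variant.variant == "cerebellar_feedback":
            names.append("W_Ch")
        elif variant.variant == "readout_feedback":
            names.append("W_zh")
    if cfg.regime == "fully_plastic":
        names.append("W_hh")
    return names


def train_session(
    params: ModelParams,
    variant: VariantConfig,
    task,
    cfg: LearningConfig,
    rng: np.random.Generator,
    opt_state: AdamState | None = None,
    context_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, AdamState]:
    """One training session: ``cfg.n_trials`` batches with one ADAM step each.

    ``params`` is updated in place.  Returns the per-trial training-error
    trace and the optimizer state (for exact resumption across sessions).
    Aborts with a diagnostic on non-finite loss.
    """
    if opt_state is None:
        opt_state = AdamState()
    allowed = set(trainable_weights(cfg, variant))
    errors = np.empty(cfg.n_trials)
    for trial in range(cfg.n_trials):
        batch = task.sample_batch(cfg.batch_size, rng)
        traj = run_trial(params, variant, batch.x, context_mask=context_mask, rng=rng)
        loss, dE_dz = task_loss(traj.z, batch.y, batch.loss_mask, cfg.loss_kind)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged: non-finite loss at trial {trial} "
                f"(regime={cfg.regime}, variant={variant.variant})"
            )
        errors[trial] = loss

        grads: dict[str, np.ndarray] = {}
        if "W_rdt" in allowed:
            grads["W_rdt"], grads["b_rdt"] = delta_readout(dE_dz, traj.h, params)
        if "W_PF" in allowed:
            if variant.variant == "cerebellar_readout":
                # the cerebellum IS the readout here: its error is the task error
                d_out = dE_dz
                grads["W_PF"] = np.einsum("tbo,tbg->og", d_out, traj.g)
            else:
                grads["W_PF"] = delta_parallel_fibres(
                    traj, batch.y, batch.loss_mask, cfg.tau_windows, cfg.loss_kind, params
                )
        grads.update(eprop_gradient(traj, dE_dz, params, cfg.regime, variant.variant))

        opt_state.begin_step()
        for name, grad in grads.items():
            eta = cfg.eta_rnn if name in ("W_ih", "W_Ch", "W_zh", "W_hh") else cfg.eta
            adam_step(opt_state, name, getattr(params, name), grad, eta)
    return errors, opt_state
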