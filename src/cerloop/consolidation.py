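"""Cerebellar-to-cortical systems consolidation.

After a task is learned with cerebellar feedback, further unsupervised
trials transfer the cerebellar drive into the recurrent cortical weights:
W_hh is nudged so that the recurrent input reproduces the cerebellar input,
while the cerebello-cortical weights W_Ch decay geometrically to zero.  Two
update rules are provided:

* optimal — Delta W_hh = eta_rnn * F, with F the (minimum-norm) least-squares
  solution of F f(H) = W_Ch C over the trial's concatenated timesteps;
* biological — the per-synapse ratio rule
  Delta w_ij = eta_rnn * (W_Ch^j c_t) / sum_k f(h_k,t),
  whose induced change in recurrent input to neuron j is exactly
  proportional to the cerebellar input W_Ch^j c_t (the normalising
  population-activity denominator cancels).

No optimizer is used during consolidation and no targets are needed; the
defaults are eta_rnn = eta_Ch = 0.1 for the optimal rule and
eta_rnn = 3 * eta_Ch = 0.3 for the biological rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.linalg import lstsq

from .model import AblationSchedule, ModelParams, Trajectory, VariantConfig, run_trial

__all__ = [
    "ConsolidationConfig",
    "ConsolidationTrace",
    "feedback_decay",
    "consolidation_step_optimal",
    "consolidation_step_bio",
    "run_consolidation",
]


@dataclass
class ConsolidationConfig:
    rule: str = "biological"
    eta_rnn: float = 0.3
    eta_Ch: float = 0.1
    n_trials: int = 50
    batch_size: int = 10
    ridge: float = 0.0  # optional regulariser for the least-squares solve
    denom_guard: float = 1.0  # |sum_k f(h_k)| below this skips the timestep
    n_test: int = 1000

    def __post_init__(self) -> None:
        if self.rule not in ("optimal", "biological"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.eta_rnn < 0 or self.eta_Ch < 0:
            raise ValueError("consolidation rates must be non-negative")

    @classmethod
    def optimal(cls, **kw) -> "ConsolidationConfig":
        kw.setdefault("eta_rnn", 0.1)
        kw.setdefault("eta_Ch", 0.1)
        return cls(rule="optimal", **kw)


def feedback_decay(W_Ch: np.ndarray, eta_Ch: float) -> np.ndarray:
    """Geometric decay W_Ch <- (1 - eta_Ch) W_Ch of the feedback weights."""
    if not 0.0 <= eta_Ch <= 1.0:
        raise ValueError("eta_Ch must lie in [0, 1]")
    return (1.0 - eta_Ch) * W_Ch


def _flatten_states(traj: Trajectory, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """f(H) (n_rnn, T*batch) and cerebellar drive W_Ch C (n_rnn, T*batch).

    ``C`` uses the feedback signal as it actually entered the cortex
    (post-softmax where the task bounds feedback)."""
    if traj.fb is None:
        raise ValueError("trajectory carries no cerebellar feedback record")
    T, batch, _ = traj.z.shape
    fH = params.f(traj.h[1:]).reshape(T * batch, -1).T
    drive = (traj.fb @ params.W_Ch.T).reshape(T * batch, -1).T
    return fH, drive


def consolidation_step_optimal(
    traj: Trajectory, params: ModelParams, cfg: ConsolidationConfig
) -> np.ndarray:
    """Delta W_hh = eta_rnn * F with F the least-squares fit of the drive.

    F minimises ||F f(H) - W_Ch C||_F; the minimum-norm solution is used on
    rank deficiency, optionally ridge-stabilised."""
    if traj.T == 0:
        raise ValueError("empty trajectory")
    fH, drive = _flatten_states(traj, params)
    if cfg.ridge > 0:
        A = fH @ fH.T + cfg.ridge * np.eye(fH.shape[0])
        F = np.linalg.solve(A, fH @ drive.T).T
    else:
        F = lstsq(fH.T, drive.T, rcond=None)[0].T
    return cfg.eta_rnn * F


def consolidation_step_bio(
    traj: Trajectory, params: ModelParams, cfg: ConsolidationConfig
) -> np.ndarray:
    """Per-synapse ratio rule, accumulated over the sequence.

    Delta w_ij = eta_rnn * (W_Ch^j c_t) / sum_k f(h_k,t) for every
    presynaptic i — the update is rank-one (constant across i) — accumulated
    as the mean over the trial's timesteps and batch examples, so one
    application stays on the scale of a single-timestep update and the
    decaying feedback is transferred at the intended eta_rnn / eta_Ch rate.
    Timesteps whose population activity falls below the guard are skipped
    with a warning."""
    if traj.T == 0:
        raise ValueError("empty trajectory")
    fH, drive = _flatten_states(traj, params)  # (n_rnn, M)
    denom = fH.sum(axis=0)  # (M,)
    ok = np.abs(denom) > cfg.denom_guard
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} timesteps skipped in biological consolidation "
            "(near-zero population activity)"
        )
    if not ok.any():
        return np.zeros_like(params.W_hh)
    per_t = np.where(ok, 1.0 / np.where(ok, denom, 1.0), 0.0)
    col = (drive * per_t)[:, ok].sum(axis=1) / ok.sum()  # (n_rnn,)
    return cfg.eta_rnn * np.tile(col[:, None], (1, params.n_rnn))


@dataclass
class ConsolidationTrace:
    """Per-trial record of the consolidation phase."""

    error: list[float] = field(default_factory=list)
    error_ablated: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    accuracy_ablated: list[float] = field(default_factory=list)
    W_Ch_norm: list[float] = field(default_factory=list)
    W_hh_norm: list[float] = field(default_factory=list)
    dW_hh_norm: list[float] = field(default_factory=list)
    activity_similarity: list[float] = field(default_factory=list)
    activity_similarity_shuffled: list[float] = field(default_factory=list)
    input_similarity: list[float] = field(default_factory=list)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def run_consolidation(
    params: ModelParams,
    variant: VariantConfig,
    task,
    cfg: ConsolidationConfig,
    rng: np.random.Generator,
    eval_every: int = 1,
    n_shuffles: int = 100,
) -> ConsolidationTrace:
    """Consolidate a trained model in place and log the transfer.

    Per trial: forward rollout on unlabelled task inputs, Delta W_hh by the
    configured rule, then feedback decay.  Evaluation (on a fixed test set)
    records the task error with and without full cerebellar ablation, the
    cosine similarity of concatenated RNN + granule activity to its
    pre-consolidation value (with a shuffled-activity baseline), and the
    similarity between the current recurrent input and the pre-consolidation
    total (recurrent + cerebellar) input.
    """
    from .plasticity import task_loss  # local import to avoid a cycle

    if variant.variant != "cerebellar_feedback":
        raise ValueError("consolidation requires the cerebellar_feedback variant")
    step_fn = consolidation_step_optimal if cfg.rule == "optimal" else consolidation_step_bio
    full_ablation = AblationSchedule(target="cerebellum", windows=[(1, task.T)])

    eval_rng = np.random.default_rng(rng.integers(2**31))
    eval_batch = task.sample_batch(cfg.n_test, eval_rng)
    W_hh_pre = params.W_hh.copy()
    W_Ch_pre = params.W_Ch.copy()

    def eval_traj() -> Trajectory:
        return run_trial(params, variant, eval_batch.x)

    pre = eval_traj()
    act_pre = np.concatenate(
        [params.f(pre.h[1:]).ravel(), pre.g.ravel()]
    )
    shuf_rng = np.random.default_rng(eval_rng.integers(2**31))
    shuffled_sim = float(
        np.mean(
            [_cosine(act_pre, shuf_rng.permutation(act_pre)) for _ in range(n_shuffles)]
        )
    )

    trace = ConsolidationTrace()
    for trial in range(cfg.n_trials):
        batch = task.sample_batch(cfg.batch_size, rng)
        traj = run_trial(params, variant, batch.x)
        dW = step_fn(traj, params, cfg)
        if not np.all(np.isfinite(dW)):
            raise FloatingPointError(f"consolidation diverged at trial {trial}")
        params.W_hh += dW
        params.W_Ch = feedback_decay(params.W_Ch, cfg.eta_Ch)

        if (trial + 1) % eval_every == 0 or trial == cfg.n_trials - 1:
            cur = eval_traj()
            abl = run_trial(params, variant, eval_batch.x, ablation=full_ablation)
            loss, _ = task_loss(cur.z, eval_batch.y, eval_batch.loss_mask, task.loss_kind)
            loss_a, _ = task_loss(abl.z, eval_batch.y, eval_batch.loss_mask, task.loss_kind)
            trace.error.append(loss)
            trace.error_ablated.append(loss_a)
            if eval_batch.labels is not None and task.loss_kind == "cross_entropy":
                pred = cur.z[-1].argmax(axis=-1)
                pred_a = abl.z[-1].argmax(axis=-1)
                trace.accuracy.append(float(np.mean(pred == eval_batch.labels)))
                trace.accuracy_ablated.append(float(np.mean(pred_a == eval_batch.labels)))
            act = np.concatenate([params.f(cur.h[1:]).ravel(), cur.g.ravel()])
            trace.activity_similarity.append(_cosine(act, act_pre))
            trace.activity_similarity_shuffled.append(shuffled_sim)
            rec_in = (params.f(cur.h[1:]) @ params.W_hh.T).ravel()
            tot_pre = (
                params.f(cur.h[1:]) @ W_hh_pre.T + cur.fb @ W_Ch_pre.T
            ).ravel()
            trace.input_similarity.append(_cosine(rec_in, tot_pre))
            trace.W_Ch_norm.append(float(np.linalg.norm(params.W_Ch)))
            trace.W_hh_norm.append(float(np.linalg.norm(params.W_hh)))
            trace.dW_hh_norm.append(float(np.linalg.norm(dW)))
    return trace
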