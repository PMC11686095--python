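"""Experiment drivers: weight initialisation, multi-session training,
evaluation, and the study pipelines (variant comparison with ablations, task
switching, delayed association, evidence accumulation, consolidation).

Seed policy: every driver takes a master seed; per-replicate RNG streams are
spawned from it through ``numpy.random.SeedSequence``, so a (config, seed)
pair reproduces a run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .analysis import (
    covariance_change,
    evidence_by_window,
    fit_choice_regression,
    prediction_delay_error,
    selectivity,
)
from .model import (
    AblationSchedule,
    ModelParams,
    ThalamusParams,
    VariantConfig,
    run_trial,
)
from .plasticity import AdamState, LearningConfig, task_loss, train_session
from .tasks import ablation_presets, get_task, make_context_masks

__all__ = [
    "init_weights",
    "seed_streams",
    "train_model",
    "evaluate",
    "line_comparison_experiment",
    "switching_experiment",
    "delayed_association_experiment",
    "evidence_experiment",
    "consolidation_experiment",
]


def seed_streams(master_seed: int, n: int) -> list[np.random.Generator]:
    """n independent per-replicate RNG streams spawned from the master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


def init_weights(
    n_input: int,
    n_out: int,
    n_rnn: int = 50,
    n_granule: int = 1000,
    n_windows: int = 1,
    alpha: float = 0.1,
    variant: str = "cerebellar_feedback",
    thalamus: bool = False,
    n_thal: int = 4,
    rng: np.random.Generator | int | None = None,
) -> tuple[ModelParams, VariantConfig]:
    """Initialise all loop weights for a task geometry.

    Cortical weights W_ih, W_hh, W_Ch ~ U(-a, a) with a = 1/sqrt(n_rnn);
    readout and cerebellar weights W_rdt, W_MF, W_PF ~ U(-b, b) with the
    fan-in "kaiming" bound b = sqrt(6 / ((1 + s^2) fan_in)) = 1/sqrt(fan_in)
    at slope s = sqrt(5); readout biases ~ U(-1/sqrt(n_in), 1/sqrt(n_in)).
    The feedback dimensionality is n_out * n_windows (temporal basis).
    """
    rng = np.random.default_rng(rng)
    a = 1.0 / np.sqrt(n_rnn)
    n_feedback = n_out * n_windows

    def uniform(shape, bound):
        return rng.uniform(-bound, bound, size=shape)

    params = ModelParams(
        alpha=alpha,
        W_hh=uniform((n_rnn, n_rnn), a),
        W_ih=uniform((n_rnn, n_input), a),
        W_Ch=uniform((n_rnn, n_feedback), a),
        W_rdt=uniform((n_out, n_rnn), 1.0 / np.sqrt(n_rnn)),
        b_rdt=uniform((n_out,), 1.0 / np.sqrt(n_rnn)),
        W_MF=uniform((n_granule, n_rnn), 1.0 / np.sqrt(n_rnn)),
        W_PF=uniform((n_feedback, n_granule), 1.0 / np.sqrt(n_granule)),
        W_zh=uniform((n_rnn, n_out), a) if variant == "readout_feedback" else None,
    )
    thal = None
    if thalamus:
        thal = ThalamusParams(
            W_in=uniform((n_thal, n_rnn + n_feedback), 1.0 / np.sqrt(n_rnn + n_feedback)),
            W_th=uniform((n_feedback, n_thal), 1.0 / np.sqrt(n_thal)),
        )
    return params, VariantConfig(variant=variant, thalamus=thal)


_WEIGHT_NAMES = ("W_hh", "W_ih", "W_Ch", "W_rdt", "b_rdt", "W_PF", "W_zh")


def train_model(
    params: ModelParams,
    variant: VariantConfig,
    task,
    cfg: LearningConfig,
    n_sessions: int,
    rng: np.random.Generator,
    context_mask: np.ndarray | None = None,
    opt_state: AdamState | None = None,
    select_best: bool = False,
    n_validation: int = 100,
) -> tuple[np.ndarray, AdamState]:
    """Train for ``n_sessions`` sessions in place; returns the concatenated
    per-trial training-error trace and the optimizer state.

    With ``select_best`` a fixed held-out validation set of ``n_validation``
    examples is scored after every session and the best-scoring weights are
    restored into ``params`` at the end — the snapshot used for post-hoc
    analyses of the learned dynamics."""
    val_seed = int(rng.integers(2**31)) if select_best else 0
    best_loss, best_weights = np.inf, None
    traces = []
    for _ in range(n_sessions):
        errs, opt_state = train_session(
            params, variant, task, cfg, rng, opt_state, context_mask
        )
        traces.append(errs)
        if select_best:
            val = evaluate(
                params, variant, task, n_validation,
                np.random.default_rng(val_seed), context_mask=context_mask,
            )
            if val["loss"] < best_loss:
                best_loss = val["loss"]
                best_weights = {
                    n: getattr(params, n).copy()
                    for n in _WEIGHT_NAMES
                    if getattr(params, n) is not None
                }
    if select_best and best_weights is not None:
        for n, w in best_weights.items():
            getattr(params, n)[...] = w
    return np.concatenate(traces), opt_state


def evaluate(
    params: ModelParams,
    variant: VariantConfig,
    task,
    n_examples: int,
    rng: np.random.Generator,
    ablation: AblationSchedule | None = None,
    context_mask: np.ndarray | None = None,
    return_traj: bool = False,
):
    """Test error (and end-of-trial accuracy for classification tasks)."""
    batch = task.sample_batch(n_examples, rng)
    traj = run_trial(
        params, variant, batch.x, ablation=ablation, context_mask=context_mask, rng=rng
    )
    loss, _ = task_loss(traj.z, batch.y, batch.loss_mask, task.loss_kind)
    out = {"loss": loss}
    if task.loss_kind == "cross_entropy":
        out["accuracy"] = float(np.mean(traj.z[-1].argmax(axis=-1) == batch.labels))
    if return_traj:
        return out, traj, batch
    return out


@dataclass
class ExperimentResult:
    """Per-seed metric arrays plus shared metadata."""

    metrics: dict[str, np.ndarray] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def mean(self, key: str) -> float:
        return float(np.mean(self.metrics[key]))

    def sem(self, key: str) -> float:
        vals = np.asarray(self.metrics[key], float)
        return float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0


def line_comparison_experiment(
    seed: int = 0,
    n_seeds: int = 5,
    n_sessions: int = 25,
    n_rnn: int = 50,
    n_granule: int = 1000,
    alpha: float = 0.1,
    regime: str = "fixed_rnn",
    n_test: int = 500,
    variants: Sequence[str] = ("cerebellar_feedback", "no_feedback", "readout_feedback"),
    tau: int = 3,
) -> ExperimentResult:
    """Line drawing with a fixed cortical RNN across feedback variants.

    Trains each variant per seed, then for the cerebellar model measures
    start/mid/end cerebellar-ablation errors and the cerebellar
    prediction-lead curve across delays 0..5.
    """
    task = get_task("line")
    presets = ablation_presets("line")
    res = ExperimentResult(extras={"n_sessions": n_sessions, "variants": list(variants)})
    final = {v: [] for v in variants}
    abl_err = {k: [] for k in ("control", "start", "mid", "end")}
    delay_curves = []
    for rng in seed_streams(seed, n_seeds):
        eval_seed = rng.integers(2**31)
        for v in variants:
            params, vcfg = init_weights(
                task.n_input, task.n_out, n_rnn=n_rnn, n_granule=n_granule,
                alpha=alpha, variant=v, rng=rng,
            )
            cfg = LearningConfig(regime=regime, loss_kind="mse", tau_windows=(tau,))
            train_model(params, vcfg, task, cfg, n_sessions, rng, select_best=True)
            ev_rng = np.random.default_rng(eval_seed)
            final[v].append(evaluate(params, vcfg, task, n_test, ev_rng)["loss"])
            if v == "cerebellar_feedback":
                for name in ("start", "mid", "end"):
                    ev_rng = np.random.default_rng(eval_seed)
                    abl_err[name].append(
                        evaluate(params, vcfg, task, n_test, ev_rng, ablation=presets[name])[
                            "loss"
                        ]
                    )
                abl_err["control"].append(final[v][-1])
                ev_rng = np.random.default_rng(eval_seed)
                _, traj, _ = evaluate(params, vcfg, task, n_test, ev_rng, return_traj=True)
                delay_curves.append(prediction_delay_error(traj)["cerebellar"])
    for v in variants:
        res.metrics[f"mse_{v}"] = np.array(final[v])
    for k, vals in abl_err.items():
        res.metrics[f"mse_ablate_{k}"] = np.array(vals)
    res.metrics["prediction_delay_curve"] = np.array(delay_curves)  # (seeds, 6)
    return res


def switching_experiment(
    seed: int = 0,
    n_seeds: int = 5,
    regimes: Sequence[str] = ("fixed_rnn", "fully_plastic"),
    overlap: float = 0.0,
    alpha: float = 0.5,
    n_rnn: int = 50,
    n_granule: int = 1000,
    n_sessions_base: int = 20,
    n_sessions_baseline_period: int = 2,
    n_sessions_task2: int = 10,
    n_eval: int = 300,
    tau: int = 3,
) -> ExperimentResult:
    """Line -> curl-field -> line task switching with context-specific
    parallel fibres.

    Per regime and seed: train the line task under the context-0 mask, then
    run a short baseline period of continued task-1 training bracketed by
    activity recordings (B1, B2) on the trained model; freshly initialise
    the private parallel fibres of context 1 and train the curl-field task
    (T2 recording at its end); then switch back and measure the zero-shot
    task-1 error.  Reports the retention score (baseline error / first error
    after switching back) and the baseline-normalised covariance change of
    the cortical population, cov_change(B1, T2) - cov_change(B1, B2).
    """
    line = get_task("line")
    curl = get_task("curl")
    res = ExperimentResult(extras={"overlap": overlap, "regimes": list(regimes)})
    retention = {r: [] for r in regimes}
    cov_change = {r: [] for r in regimes}
    for rng in seed_streams(seed, n_seeds):
        eval_seed = int(rng.integers(2**31))
        masks = make_context_masks(n_granule, 2, overlap)
        for regime in regimes:
            params, vcfg = init_weights(
                line.n_input, line.n_out, n_rnn=n_rnn, n_granule=n_granule,
                alpha=alpha, rng=np.random.default_rng(eval_seed),
            )
            cfg = LearningConfig(regime=regime, loss_kind="mse", tau_windows=(tau,))
            train_rng = np.random.default_rng(eval_seed + 1)

            def acts(ctx_task, mask):
                ev = np.random.default_rng(eval_seed + 2)
                _, traj, _ = evaluate(
                    params, vcfg, ctx_task, n_eval, ev, context_mask=mask, return_traj=True
                )
                fh = params.f(traj.h[1:])
                return fh.reshape(-1, params.n_rnn)

            _, opt = train_model(
                params, vcfg, line, cfg, n_sessions_base, train_rng, context_mask=masks[0]
            )
            act_B1 = acts(line, masks[0])  # baseline period start (trained model)
            _, opt = train_model(
                params, vcfg, line, cfg, n_sessions_baseline_period, train_rng,
                context_mask=masks[0], opt_state=opt,
            )
            act_B2 = acts(line, masks[0])  # baseline period end
            ev = np.random.default_rng(eval_seed + 3)
            base_err = evaluate(params, vcfg, line, n_eval, ev, context_mask=masks[0])["loss"]

            # entering the new context: private PFs freshly initialised
            private1 = masks[1] & ~masks[0]
            params.W_PF[:, private1] = np.random.default_rng(eval_seed + 4).uniform(
                -1.0 / np.sqrt(n_granule), 1.0 / np.sqrt(n_granule),
                size=(params.n_feedback, int(private1.sum())),
            )
            train_model(
                params, vcfg, curl, cfg, n_sessions_task2, train_rng,
                context_mask=masks[1], opt_state=AdamState(),
            )
            act_T2 = acts(curl, masks[1])

            # zero-shot switch back to task 1
            ev = np.random.default_rng(eval_seed + 3)
            switch_err = evaluate(params, vcfg, line, n_eval, ev, context_mask=masks[0])["loss"]
            retention[regime].append(base_err / switch_err)
            d_cov = covariance_change(act_B1, act_T2) - covariance_change(act_B1, act_B2)
            cov_change[regime].append(d_cov)
    for r in regimes:
        res.metrics[f"retention_{r}"] = np.array(retention[r])
        res.metrics[f"cov_change_{r}"] = np.array(cov_change[r])
    return res


def delayed_association_experiment(
    seed: int = 0,
    n_seeds: int = 5,
    n_sessions: int = 30,
    regime: str = "input_plastic",
    n_rnn: int = 50,
    n_granule: int = 1000,
    alpha: float = 0.1,
    T: int = 15,
    n_test: int = 500,
    tau: int = 3,
    keep_models: bool = False,
) -> ExperimentResult:
    """Delayed association with cerebellar feedback: end-of-trial accuracy
    plus the per-timestep cue selectivity with and without mid-delay
    cerebellar ablation (steps 8-12)."""
    task = get_task("delayed_association", T=T)
    abl = ablation_presets("delayed_association")["main"]
    win = slice(abl.windows[0][0] - 1, abl.windows[0][1])
    res = ExperimentResult(extras={"ablation_window": abl.windows[0], "T": T})
    acc, acc_abl, sel_ctrl, sel_abl = [], [], [], []
    models = []
    for rng in seed_streams(seed, n_seeds):
        params, vcfg = init_weights(
            task.n_input, task.n_out, n_rnn=n_rnn, n_granule=n_granule,
            alpha=alpha, rng=rng,
        )
        vcfg.feedback_softmax = True
        cfg = LearningConfig(
            regime=regime, loss_kind="cross_entropy", tau_windows=(tau,), eta_rnn=0.0025
        )
        train_model(params, vcfg, task, cfg, n_sessions, rng, select_best=True)
        ev_seed = int(rng.integers(2**31))
        out, traj, batch = evaluate(
            params, vcfg, task, n_test, np.random.default_rng(ev_seed), return_traj=True
        )
        out_a, traj_a, _ = evaluate(
            params, vcfg, task, n_test, np.random.default_rng(ev_seed),
            ablation=abl, return_traj=True,
        )
        acc.append(out["accuracy"])
        acc_abl.append(out_a["accuracy"])
        sel_ctrl.append(selectivity(traj.z, batch.labels))
        sel_abl.append(selectivity(traj_a.z, batch.labels))
        if keep_models:
            models.append((params, vcfg))
    res.metrics["accuracy"] = np.array(acc)
    res.metrics["accuracy_ablated"] = np.array(acc_abl)
    res.metrics["selectivity_control"] = np.array(sel_ctrl)  # (seeds, T)
    res.metrics["selectivity_ablated"] = np.array(sel_abl)
    res.metrics["selectivity_window_control"] = np.array(sel_ctrl)[:, win].mean(axis=1)
    res.metrics["selectivity_window_ablated"] = np.array(sel_abl)[:, win].mean(axis=1)
    if keep_models:
        res.extras["models"] = models
    return res


def evidence_experiment(
    seed: int = 0,
    n_seeds: int = 5,
    n_sessions: int = 20,
    T_pres: int = 15,
    T_del: int = 5,
    rho: float = 0.7,
    regime: str = "input_plastic",
    n_rnn: int = 50,
    n_granule: int = 400,
    alpha: float = 0.1,
    n_test: int = 600,
    tau: int = 3,
) -> ExperimentResult:
    """Evidence accumulation: accuracy under control and windowed cerebellar
    ablation, plus the temporal choice regression under control and
    late-window ablation.

    The presentation period is split into three equal windows; ablation
    windows coincide with them.  Tie ("equal") trials are excluded from the
    choice regression, which uses binary left/right model choices.
    """
    task = get_task("evidence", T_pres=T_pres, T_del=T_del, rho=rho)
    w = T_pres // 3
    windows = [(1, w), (w + 1, 2 * w), (2 * w + 1, T_pres)]
    res = ExperimentResult(extras={"windows": windows, "T_pres": T_pres})
    acc = {k: [] for k in ("control", "early", "mid", "late")}
    beta_ctrl, beta_late = [], []
    for rng in seed_streams(seed, n_seeds):
        params, vcfg = init_weights(
            task.n_input, task.n_out, n_rnn=n_rnn, n_granule=n_granule,
            alpha=alpha, rng=rng,
        )
        vcfg.feedback_softmax = True
        cfg = LearningConfig(regime=regime, loss_kind="cross_entropy", tau_windows=(tau,))
        train_model(params, vcfg, task, cfg, n_sessions, rng, select_best=True)
        ev_seed = int(rng.integers(2**31))

        def run(ablation=None):
            ev = np.random.default_rng(ev_seed)
            return evaluate(params, vcfg, task, n_test, ev, ablation=ablation, return_traj=True)

        out, traj, batch = run()
        acc["control"].append(out["accuracy"])
        abls = {
            name: AblationSchedule(target="cerebellum", windows=[win])
            for name, win in zip(("early", "mid", "late"), windows)
        }
        trajs = {"control": traj}
        for name, ab in abls.items():
            out_a, traj_a, _ = run(ab)
            acc[name].append(out_a["accuracy"])
            trajs[name] = traj_a

        pulses = (batch.x > 0.5).astype(float)  # de-noised pulse trains
        E = evidence_by_window(pulses, windows)
        for name, store in (("control", beta_ctrl), ("late", beta_late)):
            choice = trajs[name].z[-1, :, :2].argmax(axis=-1)
            keep = trajs[name].z[-1].argmax(axis=-1) != 2
            fit = fit_choice_regression(E[keep], choice[keep])
            store.append(fit.normalized)
    for k, v in acc.items():
        res.metrics[f"accuracy_{k}"] = np.array(v)
    res.metrics["beta_control"] = np.array(beta_ctrl)  # (seeds, 3)
    res.metrics["beta_late_ablation"] = np.array(beta_late)
    return res


def consolidation_experiment(
    seed: int = 0,
    n_seeds: int = 3,
    rule: str = "biological",
    n_consolidation_trials: int = 40,
    n_sessions: int = 30,
    n_rnn: int = 50,
    n_granule: int = 1000,
    T: int = 15,
    n_test: int = 400,
) -> ExperimentResult:
    """Train delayed association (input plastic), then consolidate.

    Reports the end-of-consolidation test error with and without full
    cerebellar ablation, the feedback-weight norm trace, and the activity /
    recurrent-input similarity traces."""
    from .consolidation import ConsolidationConfig, run_consolidation

    task = get_task("delayed_association", T=T)
    res = ExperimentResult(extras={"rule": rule})
    err_end, err_abl_end, wch, acc_abl = [], [], [], []
    act_sim, in_sim = [], []
    for rng in seed_streams(seed, n_seeds):
        params, vcfg = init_weights(
            task.n_input, task.n_out, n_rnn=n_rnn, n_granule=n_granule, rng=rng
        )
        vcfg.feedback_softmax = True
        cfg = LearningConfig(
            regime="input_plastic", loss_kind="cross_entropy", eta_rnn=0.0025
        )
        train_model(params, vcfg, task, cfg, n_sessions, rng, select_best=True)
        ccfg = (
            ConsolidationConfig.optimal(n_trials=n_consolidation_trials, n_test=n_test)
            if rule == "optimal"
            else ConsolidationConfig(n_trials=n_consolidation_trials, n_test=n_test)
        )
        trace = run_consolidation(params, vcfg, task, ccfg, rng)
        err_end.append(trace.error[-1])
        err_abl_end.append(trace.error_ablated[-1])
        acc_abl.append(trace.accuracy_ablated[-1] if trace.accuracy_ablated else np.nan)
        wch.append(trace.W_Ch_norm)
        act_sim.append(trace.activity_similarity[-1])
        in_sim.append(trace.input_similarity[-1])
    res.metrics["error_end"] = np.array(err_end)
    res.metrics["error_ablated_end"] = np.array(err_abl_end)
    res.metrics["accuracy_ablated_end"] = np.array(acc_abl)
    res.metrics["W_Ch_norm_trace"] = np.array(wch)
    res.metrics["activity_similarity_end"] = np.array(act_sim)
    res.metrics["input_similarity_end"] = np.array(in_sim)
    return res
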