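"""Quantitative readouts on simulated trajectories.

Includes per-timestep task selectivity, the temporal choice regression of
evidence-accumulation decisions, activity- and covariance-change statistics
for task switching, a noise-driven controllability-energy estimate (the
state covariance standing in for the controllability Gramian, to which it is
equal for linear dynamics), the signal-to-noise decomposition of cortical
activity with the minimum-granule-cell decoding criterion, and the
cerebellar prediction-lead curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import savgol_filter

from .model import ModelParams, Trajectory, VariantConfig, relu, softmax

__all__ = [
    "smooth_error_trace",
    "selectivity",
    "belief",
    "ChoiceRegression",
    "fit_choice_regression",
    "evidence_by_window",
    "activity_change",
    "covariance_change",
    "EnergyEstimate",
    "controllability_energy",
    "SNRReport",
    "snr_decomposition",
    "train_granule_decoder",
    "snr_and_min_granules",
    "min_granules_to_decode",
    "prediction_delay_error",
]


def smooth_error_trace(errors: np.ndarray, window: int = 25, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing of a per-trial error trace (cognitive tasks)."""
    errors = np.asarray(errors, float)
    if errors.size < window:
        return errors.copy()
    return savgol_filter(errors, window_length=window, polyorder=polyorder)


def selectivity(z: np.ndarray, labels: np.ndarray, by_condition: bool = False):
    """Per-timestep task selectivity: the pre-softmax readout logit at the
    correct-class dimension, averaged over trials.

    ``z`` is (T, batch, n_classes); ``labels`` (batch,).  With
    ``by_condition`` returns an (n_classes, T) array of per-condition
    traces, else the (T,) batch average."""
    T, batch, _ = z.shape
    sel = z[:, np.arange(batch), labels]  # (T, batch)
    if not by_condition:
        return sel.mean(axis=1)
    classes = np.unique(labels)
    return np.stack([sel[:, labels == k].mean(axis=1) for k in classes])


def belief(z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-timestep softmax probability of the correct class, batch-averaged."""
    p = softmax(z)
    return p[:, np.arange(z.shape[1]), labels].mean(axis=1)


@dataclass
class ChoiceRegression:
    """Logistic fit of binary choices on per-window evidence differences.

    choice_prob = sigmoid(beta_1 E_1 + beta_2 E_2 + beta_3 E_3) with
    E_i = (#right - #left) pulses in window i."""

    beta: np.ndarray
    ridge: float = 0.0

    @property
    def normalized(self) -> np.ndarray:
        return self.beta / self.beta.sum()


def fit_choice_regression(
    E: np.ndarray, choices: np.ndarray, ridge: float = 0.0
) -> ChoiceRegression:
    """Maximum-likelihood window weights for observed binary model choices.

    ``E`` is (n, n_windows) evidence differences, ``choices`` in {0, 1}
    (1 = "right"; tie trials are excluded upstream).  The negative
    log-likelihood is minimised with L-BFGS; on (near-)perfect separation
    the coefficients diverge, in which case the fit is retried with a ridge
    penalty and a warning."""
    E = np.asarray(E, float)
    choices = np.asarray(choices, float)

    def nll(beta: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
        u = E @ beta
        # log(1 + e^u) - y*u, stably
        val = np.sum(np.logaddexp(0.0, u) - choices * u) + 0.5 * lam * beta @ beta
        p = 1.0 / (1.0 + np.exp(-u))
        grad = E.T @ (p - choices) + lam * beta
        return val, grad

    def solve(lam: float) -> np.ndarray:
        res = minimize(
            nll, np.zeros(E.shape[1]), args=(lam,), jac=True, method="L-BFGS-B",
            options={"maxiter": 500},
        )
        return res.x

    beta = solve(ridge)
    if ridge == 0.0 and np.max(np.abs(beta)) > 10.0:
        warnings.warn("choice regression is (near) separable; refitting with ridge penalty")
        ridge = 1.0
        beta = solve(ridge)
    return ChoiceRegression(beta=beta, ridge=ridge)


def evidence_by_window(x_clean: np.ndarray, windows: list[tuple[int, int]]) -> np.ndarray:
    """E_i = #right - #left pulses per 1-based window from noise-free pulses.

    ``x_clean`` is (T, batch, 2) with channel 0 = left, 1 = right."""
    out = np.empty((x_clean.shape[1], len(windows)))
    for i, (a, b) in enumerate(windows):
        seg = x_clean[a - 1 : b]
        out[:, i] = seg[:, :, 1].sum(axis=0) - seg[:, :, 0].sum(axis=0)
    return out


def activity_change(
    act_P1: np.ndarray, act_P2: np.ndarray, baseline_std: np.ndarray
) -> np.ndarray:
    """Per-neuron activity change |h^P2 - h^P1| / std_i between two periods.

    ``act_P1``/``act_P2`` are (samples, n_neurons) with matched samples
    (timesteps x examples); ``baseline_std`` is the per-neuron std from the
    start of the baseline period.  Neurons with zero baseline std are
    excluded (NaN) with a warning; the population summary is the nanmean."""
    diff = np.abs(act_P2 - act_P1).mean(axis=0)
    ok = baseline_std > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} neurons excluded from activity change (zero baseline std)")
    return np.where(ok, diff / np.where(ok, baseline_std, 1.0), np.nan)


def covariance_matrix_change(cov1: np.ndarray, cov2: np.ndarray) -> float:
    """1 - Pearson correlation between two flattened covariance matrices."""
    c1, c2 = cov1.ravel(), cov2.ravel()
    if c1.std() == 0 or c2.std() == 0:
        raise ValueError("constant activity: covariance correlation undefined")
    return 1.0 - float(np.corrcoef(c1, c2)[0, 1])


def covariance_change(act_P1: np.ndarray, act_P2: np.ndarray) -> float:
    """1 - Pearson correlation between the two periods' neuron covariance
    matrices; 0 for identical (or rescaled) dynamics, approaching 2 for
    anti-correlated ones."""
    return covariance_matrix_change(
        np.cov(act_P1, rowvar=False), np.cov(act_P2, rowvar=False)
    )


@dataclass
class EnergyEstimate:
    """Noise-driven state covariance and direction-energy summaries.

    ``Sigma`` stands in for the controllability Gramian; ``energy(v)`` is
    v^T Sigma v and ``max_energy`` its top eigenvalue, so normalized
    energies lie in [0, 1]."""

    Sigma: np.ndarray
    energy_feedback: float
    energies_random: np.ndarray
    n_samples: int
    burn_in: int
    meta: dict = field(default_factory=dict)

    @property
    def max_energy(self) -> float:
        return float(np.linalg.eigvalsh(self.Sigma)[-1])

    def energy(self, v: np.ndarray) -> float:
        v = v / np.linalg.norm(v)
        return float(v @ self.Sigma @ v)

    @property
    def normalized_feedback(self) -> float:
        return self.energy_feedback / self.max_energy

    @property
    def normalized_random(self) -> np.ndarray:
        return self.energies_random / self.max_energy


def controllability_energy(
    params: ModelParams,
    variant: VariantConfig,
    n_samples: int = 500,
    T: int = 30,
    burn_in: int = 5,
    probe_step: int = 10,
    n_random_dirs: int = 100,
    noise_std: float = 1.0,
    rng: np.random.Generator | None = None,
) -> EnergyEstimate:
    """Energy of the cerebellar feedback direction under noise-driven dynamics.

    Simulates input-free rollouts h_t = alpha h_{t-1} + W_hh f(h_{t-1}) +
    W_Ch c_t + xi_t with Wiener-process noise (i.i.d. Gaussian increments of
    std ``noise_std`` per step), estimates Sigma as the time-averaged state
    covariance over ``n_samples`` rollouts after ``burn_in`` steps, and
    returns the energy along the normalised cerebellar drive direction
    h_C = W_Ch c / ||W_Ch c|| probed at ``probe_step``, together with the
    energies of ``n_random_dirs`` standard-normal random unit directions.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = params.n_rnn
    h = np.zeros((n_samples, n))
    Sigma = np.zeros((n, n))
    count = 0
    drive_dir = None
    for t in range(1, T + 1):
        c = relu(params.f(h) @ params.W_MF.T) @ params.W_PF.T
        fb = softmax(c) if variant.feedback_softmax else c
        xi = rng.normal(0.0, noise_std, size=(n_samples, n))
        h = params.alpha * h + params.f(h) @ params.W_hh.T + fb @ params.W_Ch.T + xi
        if not np.all(np.isfinite(h)):
            raise FloatingPointError(f"noise-driven dynamics diverged at step {t}")
        if t == probe_step:
            drive = (fb @ params.W_Ch.T).mean(axis=0)
            nrm = np.linalg.norm(drive)
            # zero drive (e.g. silent cerebellum): feedback energy undefined
            drive_dir = drive / nrm if nrm > 0 else None
        if t > burn_in:
            Sigma += np.cov(h, rowvar=False)
            count += 1
    Sigma /= count
    if probe_step > T:
        raise ValueError("probe_step exceeds simulation length")
    e_fb = float(drive_dir @ Sigma @ drive_dir) if drive_dir is not None else float("nan")
    dirs = rng.normal(size=(n_random_dirs, n))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    e_rand = np.einsum("kn,nm,km->k", dirs, Sigma, dirs)
    return EnergyEstimate(
        Sigma=Sigma,
        energy_feedback=e_fb,
        energies_random=e_rand,
        n_samples=n_samples,
        burn_in=burn_in,
        meta={"probe_step": probe_step, "noise_std": noise_std, "T": T},
    )


@dataclass
class SNRReport:
    """Variance split of population activity into task-dependent and
    task-agnostic components; snr = var_task / var_noise."""

    var_task: float
    var_noise: float
    var_total: float

    @property
    def snr(self) -> float:
        return self.var_task / self.var_noise


def snr_decomposition(activity: np.ndarray, conditions: np.ndarray) -> SNRReport:
    """SNR of population activity at one time point.

    ``activity`` is (trials, n_neurons) (already through the cortical
    non-linearity); ``conditions`` the per-trial stimulus condition.  The
    task-agnostic variance is the condition-average of the within-condition
    variance (averaged over neurons); the task variance is the difference to
    the total variance."""
    conds = np.unique(conditions)
    if conds.size < 2:
        raise ValueError("SNR decomposition needs at least two stimulus conditions")
    var_total = float(activity.var(axis=0).mean())
    var_noise = float(
        np.mean([activity[conditions == s].var(axis=0).mean() for s in conds])
    )
    return SNRReport(
        var_task=var_total - var_noise, var_noise=var_noise, var_total=var_total
    )


def train_granule_decoder(
    states: np.ndarray,
    labels: np.ndarray,
    n_granule: int,
    n_sessions: int,
    rng: np.random.Generator,
    n_classes: int | None = None,
    examples_per_session: int = 1000,
    batch_size: int = 10,
    eta: float = 0.001,
) -> np.ndarray:
    """Train a standalone cerebellar classifier on cortical states.

    A fresh expansion network (fixed random mossy fibres, plastic parallel
    fibres trained by the delta rule through a softmax cross-entropy) learns
    to report the stimulus condition from ``states`` (examples, n_rnn; the
    cortical activity at the decision point, pre-nonlinearity).  Returns the
    per-session misclassification rate, the decoding curve behind the
    minimum-granule-cell criterion."""
    from .plasticity import AdamState, adam_step  # local import to avoid a cycle

    n, n_rnn = states.shape
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    W_MF = rng.uniform(-1 / np.sqrt(n_rnn), 1 / np.sqrt(n_rnn), size=(n_granule, n_rnn))
    W_PF = rng.uniform(-1 / np.sqrt(n_granule), 1 / np.sqrt(n_granule),
                       size=(n_classes, n_granule))
    fh = np.tanh(states)
    opt = AdamState()
    errors = np.empty(n_sessions)
    n_trials = examples_per_session // batch_size
    for s in range(n_sessions):
        wrong = 0
        for _ in range(n_trials):
            idx = rng.integers(0, n, size=batch_size)
            g = relu(fh[idx] @ W_MF.T)
            logits = g @ W_PF.T
            p = softmax(logits)
            onehot = np.eye(n_classes)[labels[idx]]
            grad = (p - onehot).T @ g / batch_size
            opt.begin_step()
            adam_step(opt, "W_PF", W_PF, grad, eta)
            wrong += int((logits.argmax(axis=-1) != labels[idx]).sum())
        errors[s] = wrong / (n_trials * batch_size)
    return errors


def snr_and_min_granules(
    states: np.ndarray,
    labels: np.ndarray,
    granule_grid,
    n_seeds: int = 5,
    n_sessions: int = 40,
    threshold: float = 0.05,
    rng: np.random.Generator | None = None,
    **decoder_kwargs,
) -> tuple[SNRReport, int | None, dict[int, np.ndarray]]:
    """SNR of cortical states plus the smallest granule count that decodes
    the stimulus.

    For each count in ``granule_grid`` a cerebellar decoder is trained for
    ``n_sessions`` sessions per seed; a count succeeds when the mean error
    over the last 4 sessions is below ``threshold`` for at least 4 of the
    seeds.  Returns (SNRReport, minimum count or None, per-count error
    curves)."""
    if rng is None:
        rng = np.random.default_rng()
    report = snr_decomposition(np.tanh(states), labels)
    curves: dict[int, np.ndarray] = {}
    for n_gc in sorted(granule_grid):
        curves[n_gc] = np.stack(
            [
                train_granule_decoder(
                    states, labels, n_gc, n_sessions,
                    np.random.default_rng(rng.integers(2**31)), **decoder_kwargs,
                )
                for _ in range(n_seeds)
            ]
        )
    n_min = min_granules_to_decode(
        curves, threshold=threshold, min_seeds=min(4, n_seeds)
    )
    return report, n_min, curves


def min_granules_to_decode(
    session_errors: dict[int, np.ndarray],
    threshold: float = 0.05,
    last_k: int = 4,
    min_seeds: int = 4,
) -> int | None:
    """Smallest granule count whose decoder reaches criterion.

    ``session_errors`` maps granule count -> (n_seeds, n_sessions) per-session
    classification error of a cerebellar decoder.  A count succeeds when the
    mean error over the last ``last_k`` sessions is below ``threshold`` for
    at least ``min_seeds`` seeds.  Returns None if no count succeeds."""
    for n_gc in sorted(session_errors):
        errs = np.asarray(session_errors[n_gc])
        ok = (errs[:, -last_k:].mean(axis=1) < threshold).sum()
        if ok >= min_seeds:
            return n_gc
    return None


def prediction_delay_error(
    traj: Trajectory, delays=range(0, 6), feedback_slice: slice | None = None
) -> dict[str, np.ndarray]:
    """Prediction error between cerebellar output and readout across delays.

    For each delay t0, the cue/time-averaged Euclidean distance
    ||c_t - z_{t+t0}|| (the readout lagging the cerebellar output by t0
    steps), plus the self-prediction baseline ||z_t - z_{t+t0}||.  A trained
    cerebellum with time window tau predicts y_{t+tau}, so the curve is
    minimised at t0 = tau."""
    if traj.c is None:
        raise ValueError("trajectory carries no cerebellar record")
    c = traj.c if feedback_slice is None else traj.c[:, :, feedback_slice]
    z = traj.z
    T = z.shape[0]
    delays = list(delays)
    err = np.empty(len(delays))
    base = np.empty(len(delays))
    for k, t0 in enumerate(delays):
        n = T - t0
        err[k] = np.mean(np.linalg.norm(c[:n] - z[t0 : t0 + n], axis=-1))
        base[k] = np.mean(np.linalg.norm(z[:n] - z[t0 : t0 + n], axis=-1))
    return {"delays": np.array(delays), "cerebellar": err, "self": base}
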