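"""Forward dynamics of the cortico-cerebellar loop.

The cortical network is a leaky discrete-time RNN,

    h_t = alpha * h_{t-1} + W_hh f(h_{t-1}) + W_ih x_t + W_Ch c_t
    z_t = W_rdt f(h_t) + b_rdt,

with f = tanh and leak factor alpha in [0, 1).  The cerebellum is a
feedforward expansion network driven by a copy of the cortical state,

    c_t = W_PF relu(W_MF f(h_{t-1})),

whose hidden layer models the granule cells (a divergent 1:20 expansion at
the defaults of 50 cortical units and 1000 granule cells) and whose output
layer models Purkinje cells.  Four loop variants are supported: no feedback,
readout feedback (the previous readout re-entered through W_zh), cerebellar
feedback, and a cerebellar-readout control in which the model output is
produced directly by the cerebellum.  An optional thalamic relay of four
hidden units can be interposed between cerebellum and cortex.

Timestep conventions: configs, ablation windows and logs are 1-based
inclusive (so "steps 8-12" means five steps); internal arrays are 0-based
with ``x[t-1]`` holding the input of timestep ``t`` and ``h`` carrying one
extra leading row for the initial state ``h_0 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "VariantConfig",
    "ThalamusParams",
    "AblationSchedule",
    "Trajectory",
    "VARIANTS",
    "compute_alpha",
    "softmax",
    "relu",
    "window_to_slice",
    "cerebellar_forward",
    "thalamic_forward",
    "rnn_step",
    "readout",
    "run_trial",
]

VARIANTS = ("no_feedback", "readout_feedback", "cerebellar_feedback", "cerebellar_readout")

Variant = Literal["no_feedback", "readout_feedback", "cerebellar_feedback", "cerebellar_readout"]


def compute_alpha(tau_M: float, dt: float) -> float:
    """Leak factor alpha = exp(-dt / tau_M) of the discretised rate equation.

    ``tau_M`` is the membrane time constant and ``dt`` the discretisation
    step, both in ms.  ``dt = 0`` returns 1.0 (no decay).  Callers may
    override the result with a directly configured alpha; the stated
    constants (tau_M ~ 20 ms, dt = 50 ms for motor tasks; tau_M ~ 90 ms,
    dt = 200 ms for cognitive tasks) are conventionally rounded to 0.1.
    """
    if tau_M <= 0:
        raise ValueError(f"tau_M must be positive, got {tau_M}")
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    return float(np.exp(-dt / tau_M))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(x)
    return e / np.sum(e, axis=axis, keepdims=True)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def window_to_slice(window: tuple[int, int]) -> slice:
    """Convert a 1-based inclusive timestep window to a 0-based slice."""
    a, b = window
    if a < 1 or b < a:
        raise ValueError(f"invalid 1-based window {window}")
    return slice(a - 1, b)


@dataclass
class ThalamusParams:
    """Feedforward thalamic relay between cerebellum and cortex.

    ``W_in`` (fixed random) projects the concatenated cortical activity and
    cerebellar output onto ``n_thal`` hidden units; ``W_th`` maps the hidden
    units to the feedback dimensionality, and the result replaces c_t in the
    cortical update.  ``gain`` scales the output (1.0 normal; 0.25 models a
    weakened thalamus)."""

    W_in: np.ndarray  # (n_thal, n_rnn + n_feedback), never updated
    W_th: np.ndarray  # (n_feedback, n_thal)
    gain: float = 1.0

    @property
    def n_thal(self) -> int:
        return self.W_in.shape[0]


@dataclass
class VariantConfig:
    variant: Variant = "cerebellar_feedback"
    feedback_softmax: bool = False
    thalamus: ThalamusParams | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.thalamus is not None and self.variant != "cerebellar_feedback":
            raise ValueError("thalamic relay requires the cerebellar_feedback variant")


@dataclass
class ModelParams:
    """All synaptic weights and structural constants of the loop.

    ``n_feedback`` equals ``n_out`` for a single cerebellar time window and
    ``n_out * n_windows`` for a temporal basis.  The continuous-time
    constants ``tau_M``/``dt``/``R_m`` are documentation metadata: alpha is
    the configured parameter and the (1 - alpha) R_m input scaling of the
    continuous form is dropped (absorbed into the weight scale)."""

    alpha: float
    W_hh: np.ndarray  # (n_rnn, n_rnn)
    W_ih: np.ndarray  # (n_rnn, n_input)
    W_Ch: np.ndarray  # (n_rnn, n_feedback)
    W_rdt: np.ndarray  # (n_out, n_rnn)
    b_rdt: np.ndarray  # (n_out,)
    W_MF: np.ndarray  # (n_granule, n_rnn), fixed
    W_PF: np.ndarray  # (n_feedback, n_granule), plastic
    W_zh: np.ndarray | None = None  # (n_rnn, n_out), readout-feedback variant only
    activation: str = "tanh"  # cortical non-linearity; "linear" for analysis limits
    tau_M: float | None = None
    dt: float | None = None
    R_m: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.activation not in ("tanh", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        n_rnn = self.W_hh.shape[0]
        if self.W_hh.shape != (n_rnn, n_rnn):
            raise ValueError("W_hh must be square")
        for name, mat, shape in [
            ("W_ih", self.W_ih, (n_rnn, self.W_ih.shape[1])),
            ("W_Ch", self.W_Ch, (n_rnn, self.W_Ch.shape[1])),
            ("W_rdt", self.W_rdt, (self.W_rdt.shape[0], n_rnn)),
            ("W_MF", self.W_MF, (self.W_MF.shape[0], n_rnn)),
        ]:
            if mat.shape != shape:
                raise ValueError(f"{name} has shape {mat.shape}, inconsistent with n_rnn={n_rnn}")
        if self.W_PF.shape != (self.n_feedback, self.n_granule):
            raise ValueError(
                f"W_PF has shape {self.W_PF.shape}, expected {(self.n_feedback, self.n_granule)}"
            )
        if self.b_rdt.shape != (self.n_out,):
            raise ValueError("b_rdt must match the readout dimensionality")

    # the cortical non-linearity defaults to tanh, the granule one to ReLU;
    # the linear cortical option exists for closed-form analysis limits
    def f(self, x: np.ndarray) -> np.ndarray:
        return x if self.activation == "linear" else np.tanh(x)

    def f_prime(self, x: np.ndarray) -> np.ndarray:
        if self.activation == "linear":
            return np.ones_like(x)
        return 1.0 - np.tanh(x) ** 2

    f_C = staticmethod(relu)

    @property
    def n_rnn(self) -> int:
        return self.W_hh.shape[0]

    @property
    def n_input(self) -> int:
        return self.W_ih.shape[1]

    @property
    def n_out(self) -> int:
        return self.W_rdt.shape[0]

    @property
    def n_granule(self) -> int:
        return self.W_MF.shape[0]

    @property
    def n_feedback(self) -> int:
        return self.W_Ch.shape[1]

    def copy(self) -> "ModelParams":
        return replace(
            self,
            **{
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()
            },
        )


@dataclass
class AblationSchedule:
    """Transient silencing of one loop component.

    ``windows`` are 1-based inclusive timestep intervals; ``fraction`` is the
    proportion of units silenced (1.0 = full).  Silencing the cerebellum sets
    the injected cerebellar drive to exactly zero inside the windows; partial
    cortical ablation zeroes a random fixed subset of cortical units (chosen
    once per trial from the trial RNG) after each state update."""

    target: Literal["cerebellum", "cortex_partial", "thalamus"]
    windows: Sequence[tuple[int, int]] = field(default_factory=lambda: [(1, 10**9)])
    fraction: float = 1.0

    def active(self, t: int) -> bool:
        """Whether timestep ``t`` (1-based) falls in any ablation window."""
        return any(a <= t <= b for a, b in self.windows)

    def validate(self, T: int) -> None:
        for a, b in self.windows:
            if a < 1 or b < a:
                raise ValueError(f"invalid window {(a, b)}")
            if b > T:
                raise ValueError(f"ablation window {(a, b)} exceeds trial length {T}")


@dataclass
class Trajectory:
    """Time-indexed record of one forward rollout.

    ``h`` has shape (T+1, batch, n_rnn) with ``h[0]`` the initial state;
    ``z``, ``c``, ``g``, ``x`` have shape (T, batch, .) with row ``t-1``
    holding timestep ``t``.  ``fb`` is the signal that actually entered the
    feedback weights (post-softmax, post-ablation) and is the presynaptic
    activity for feedback-weight plasticity."""

    h: np.ndarray
    z: np.ndarray
    x: np.ndarray
    c: np.ndarray | None = None
    g: np.ndarray | None = None
    fb: np.ndarray | None = None

    @property
    def T(self) -> int:
        return self.x.shape[0]

    @property
    def batch(self) -> int:
        return self.x.shape[1]


def cerebellar_forward(
    h_prev: np.ndarray,
    params: ModelParams,
    context_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One cerebellar pass c = W_PF relu(W_MF f(h_prev)).

    ``h_prev`` is (..., n_rnn).  ``context_mask`` is an optional boolean
    vector over granule (parallel-fibre) columns; masked-out columns
    contribute zero and their cached granule activity is zeroed so that
    downstream plasticity cannot touch them.  Returns ``(c, g)``.
    """
    if h_prev.shape[-1] != params.n_rnn:
        raise ValueError(f"h_prev last dim {h_prev.shape[-1]} != n_rnn {params.n_rnn}")
    g = relu(params.f(h_prev) @ params.W_MF.T)
    if context_mask is not None:
        if context_mask.shape != (params.n_granule,):
            raise ValueError("context_mask must have one entry per granule cell")
        g = np.where(context_mask, g, 0.0)
    c = g @ params.W_PF.T
    return c, g


def thalamic_forward(
    h: np.ndarray, c: np.ndarray, thalamus: ThalamusParams, params: ModelParams
) -> np.ndarray:
    """Thalamic relay theta = gain * W_th relu(W_in [f(h); c])."""
    u = np.concatenate([params.f(h), c], axis=-1)
    return thalamus.gain * (relu(u @ thalamus.W_in.T) @ thalamus.W_th.T)


def rnn_step(
    h_prev: np.ndarray,
    x_t: np.ndarray,
    feedback: np.ndarray | None,
    params: ModelParams,
    variant: Variant = "cerebellar_feedback",
    feedback_softmax: bool = False,
) -> np.ndarray:
    """One cortical update h_t = alpha h_{t-1} + W_hh f(h_{t-1}) + W_ih x_t + feedback term.

    ``feedback`` is the raw feedback vector appropriate to the variant
    (cerebellar/thalamic output for cerebellar_feedback, the previous
    readout for readout_feedback); the matching weight matrix is applied
    here.  With ``feedback_softmax`` the vector is normalised to a
    probability simplex before injection (used by the cognitive tasks to
    bound feedback values)."""
    h = params.alpha * h_prev + params.f(h_prev) @ params.W_hh.T + x_t @ params.W_ih.T
    if variant in ("no_feedback", "cerebellar_readout"):
        if feedback is not None:
            raise ValueError(f"variant {variant!r} accepts no feedback signal")
        return h
    if feedback is None:
        return h
    if feedback_softmax:
        feedback = softmax(feedback)
    if variant == "readout_feedback":
        if params.W_zh is None:
            raise ValueError("readout_feedback variant requires W_zh")
        return h + feedback @ params.W_zh.T
    return h + feedback @ params.W_Ch.T


def readout(
    h_t: np.ndarray, params: ModelParams, mode: Literal["linear", "softmax"] = "linear"
) -> np.ndarray:
    """Linear readout z = W_rdt f(h) + b, optionally softmax-normalised."""
    z = params.f(h_t) @ params.W_rdt.T + params.b_rdt
    if mode == "softmax":
        z = softmax(z)
    return z


def run_trial(
    params: ModelParams,
    variant: VariantConfig,
    x: np.ndarray,
    ablation: AblationSchedule | None = None,
    context_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Roll the loop forward over a batch of input sequences.

    ``x`` has shape (T, batch, n_input) with any input noise already
    included; the initial state is h_0 = 0.  Within ablation windows the
    targeted signal is silenced: cerebellar (or thalamic) drive set exactly
    to zero, or a fixed random subset of cortical units zeroed after each
    update.  The cerebellar_readout variant produces the model output from
    the cerebellum, z_t = C(f(h_t)).
    """
    T, batch, n_in = x.shape
    if n_in != params.n_input:
        raise ValueError(f"input dim {n_in} != n_input {params.n_input}")
    if ablation is not None:
        ablation.validate(T)

    uses_cereb = variant.variant in ("cerebellar_feedback", "cerebellar_readout")
    h = np.zeros((T + 1, batch, params.n_rnn))
    z = np.zeros((T, batch, params.n_out))
    c = np.zeros((T, batch, params.n_feedback)) if uses_cereb else None
    g = np.zeros((T, batch, params.n_granule)) if uses_cereb else None
    fb = None
    if variant.variant == "cerebellar_feedback":
        fb = np.zeros((T, batch, params.n_feedback))
    elif variant.variant == "readout_feedback":
        fb = np.zeros((T, batch, params.n_out))

    cortex_mask = None
    if ablation is not None and ablation.target == "cortex_partial":
        if rng is None:
            raise ValueError("cortex_partial ablation requires a trial rng")
        n_off = int(round(ablation.fraction * params.n_rnn))
        cortex_mask = rng.choice(params.n_rnn, size=n_off, replace=False)

    z_prev = np.zeros((batch, params.n_out))
    for t in range(1, T + 1):
        h_prev = h[t - 1]
        feedback = None
        if variant.variant == "cerebellar_feedback":
            c_t, g_t = cerebellar_forward(h_prev, params, context_mask)
            cereb_off = (
                ablation is not None and ablation.target == "cerebellum" and ablation.active(t)
            )
            if cereb_off:
                c_t = np.zeros_like(c_t)
            c[t - 1] = c_t
            g[t - 1] = g_t
            if variant.thalamus is not None:
                feedback = thalamic_forward(h_prev, c_t, variant.thalamus, params)
                if ablation is not None and ablation.target == "thalamus" and ablation.active(t):
                    feedback = np.zeros_like(feedback)
                if variant.feedback_softmax:
                    feedback = softmax(feedback)
            elif cereb_off:
                # injected cerebellar drive is exactly zero during ablation
                # (softmax deliberately skipped: c_t = 0 means no drive)
                feedback = np.zeros_like(c_t)
            else:
                feedback = softmax(c_t) if variant.feedback_softmax else c_t
            fb[t - 1] = feedback
            h_t = rnn_step(h_prev, x[t - 1], None, params, "no_feedback")
            h_t = h_t + feedback @ params.W_Ch.T
        elif variant.variant == "readout_feedback":
            inj = softmax(z_prev) if variant.feedback_softmax else z_prev
            fb[t - 1] = inj
            h_t = rnn_step(h_prev, x[t - 1], None, params, "no_feedback") + inj @ params.W_zh.T
        else:
            h_t = rnn_step(h_prev, x[t - 1], None, params, variant.variant)
            if variant.variant == "cerebellar_readout":
                # cerebellar state driven by h_{t-1}, cached for PF plasticity
                c_t, g_t = cerebellar_forward(h_prev, params, context_mask)

        if cortex_mask is not None and ablation.active(t):
            h_t[:, cortex_mask] = 0.0
        h[t] = h_t

        if variant.variant == "cerebellar_readout":
            z_t, g_out = cerebellar_forward(h_t, params, context_mask)
            c[t - 1] = z_t
            g[t - 1] = g_out
            if ablation is not None and ablation.target == "cerebellum" and ablation.active(t):
                z_t = np.zeros_like(z_t)
            z[t - 1] = z_t
        else:
            z[t - 1] = readout(h_t, params)
        z_prev = z[t - 1]

    return Trajectory(h=h, z=z, x=x, c=c, g=g, fb=fb)
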