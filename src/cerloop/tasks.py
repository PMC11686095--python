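"""Synthetic task generators.

Five task families exercise the loop:

* line drawing — one of six binary cues at timestep 1 maps to one of five
  straight lines from the origin to evenly spaced points on the unit circle
  (or a no-go "stay at the origin"), drawn over 20 steps;
* curl-field drawing — the same cues, but the target path is a semi-ellipse
  between the origin and the same endpoint (a curl-field perturbation of the
  line task);
* digit drawing — the same input scheme with six fixed 20-point digit
  templates in [0,1]^2 as targets, shipped as a versioned fixture table;
* evidence accumulation — stochastic binary "air-puff" pulses on two
  channels over a 45-step presentation period (zero input with probability
  rho = 0.7) followed by a 5-step delay; the model must report which channel
  pulsed more (left / right / equal), supervised at the final step only;
* delayed association — one of two fixed binary cues at timestep 1, then
  silence; a binary response is supervised over the last six steps.

All generators are pure functions of their configuration and the supplied
RNG, and add zero-mean Gaussian input noise (sigma = 0.1) at every timestep
including the cue step.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .model import AblationSchedule

__all__ = [
    "TrialBatch",
    "ContextMask",
    "LineDrawingTask",
    "DigitDrawingTask",
    "EvidenceAccumulationTask",
    "DelayedAssociationTask",
    "make_line_targets",
    "make_curl_targets",
    "digit_templates",
    "make_context_masks",
    "ablation_presets",
    "get_task",
]

INPUT_NOISE_SIGMA = 0.1


@dataclass
class TrialBatch:
    """A batch of task inputs, targets, loss mask and metadata.

    ``x`` (T, batch, n_input) includes the input noise; ``y`` (T, batch,
    n_out) holds regression targets or one-hot class labels broadcast over
    the supervised steps; ``loss_mask`` (T,) flags supervised timesteps.
    ``labels`` are integer cue/class identities; ``history_centric`` flags
    evidence-accumulation examples whose final-third evidence alone points
    strictly to the wrong answer."""

    x: np.ndarray
    y: np.ndarray
    loss_mask: np.ndarray
    labels: np.ndarray | None = None
    history_centric: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def T(self) -> int:
        return self.x.shape[0]


def _cue_inputs(labels: np.ndarray, T: int, n_input: int, n_cues: int, rng) -> np.ndarray:
    """One-hot cue over the first ``n_cues`` channels at timestep 1, noise throughout."""
    batch = labels.shape[0]
    x = rng.normal(0.0, INPUT_NOISE_SIGMA, size=(T, batch, n_input))
    x[0, np.arange(batch), labels] += 1.0
    return x


def make_line_targets(n_go: int = 5, T: int = 20) -> np.ndarray:
    """(n_go+1, T, 2) line targets: cue k in 0..n_go-1 draws to endpoint
    exp(i(pi/2 + 2 pi k / n_go)); the last cue is no-go (origin)."""
    angles = np.pi / 2 + 2 * np.pi * np.arange(n_go) / n_go
    ends = np.column_stack([np.cos(angles), np.sin(angles)])
    frac = (np.arange(T) / (T - 1))[None, :, None]
    targets = np.concatenate([ends[:, None, :] * frac, np.zeros((1, T, 2))], axis=0)
    return targets


def make_curl_targets(y_end: np.ndarray, T: int = 20) -> np.ndarray:
    """Semi-elliptical path between the origin and ``y_end`` on the unit circle.

    Parameterised by s in [pi, 2pi] sampled at T even points:
        y(s) = y_end / 2 + (1/2) R(theta) (cos s, sin s)^T,
    with theta the angle of ``y_end``; the path leaves the origin at s = pi,
    deviates laterally by 1/2 from the chord at s = 3pi/2, and terminates at
    ``y_end``.  A zero endpoint (no-go) stays at the origin."""
    y_end = np.asarray(y_end, float)
    if np.allclose(y_end, 0.0):
        return np.zeros((T, 2))
    theta = np.arctan2(y_end[1], y_end[0])
    s = np.linspace(np.pi, 2 * np.pi, T)
    out = np.empty((T, 2))
    out[:, 0] = y_end[0] / 2 + 0.5 * np.cos(theta) * np.cos(s) - 0.5 * np.sin(theta) * np.sin(s)
    out[:, 1] = y_end[1] / 2 + 0.5 * np.sin(theta) * np.cos(s) + 0.5 * np.cos(theta) * np.sin(s)
    return out


@lru_cache(maxsize=1)
def digit_templates() -> np.ndarray:
    """(6, 20, 2) fixed digit templates (digits 0-5) from the versioned fixture."""
    ref = importlib.resources.files("cerloop").joinpath("data/digit_templates_v1.csv")
    raw = np.genfromtxt(ref.open("r"), delimiter=",", names=True)
    out = np.zeros((6, 20, 2))
    out[raw["digit"].astype(int), raw["step"].astype(int) - 1, 0] = raw["x"]
    out[raw["digit"].astype(int), raw["step"].astype(int) - 1, 1] = raw["y"]
    return out


@dataclass
class _DrawingTask:
    """Shared input scheme of the drawing tasks: 10-d binary cue at step 1."""

    T: int = 20
    n_input: int = 10
    n_out: int = 2
    n_cues: int = 6
    loss_kind: str = "mse"
    feedback_softmax: bool = False

    def _targets(self) -> np.ndarray:  # (n_cues, T, 2)
        raise NotImplementedError

    def sample_batch(self, batch: int, rng: np.random.Generator) -> TrialBatch:
        labels = rng.integers(0, self.n_cues, size=batch)
        x = _cue_inputs(labels, self.T, self.n_input, self.n_cues, rng)
        y = self._targets()[labels].transpose(1, 0, 2)  # (T, batch, 2)
        return TrialBatch(
            x=x, y=y, loss_mask=np.ones(self.T, dtype=bool), labels=labels,
            meta={"task": self.name},
        )


@dataclass
class LineDrawingTask(_DrawingTask):
    """Line drawing (``curl=True`` gives the curl-field context of the same cues)."""

    curl: bool = False

    @property
    def name(self) -> str:
        return "curl" if self.curl else "line"

    def _targets(self) -> np.ndarray:
        lines = make_line_targets(self.n_cues - 1, self.T)
        if not self.curl:
            return lines
        return np.stack([make_curl_targets(t[-1], self.T) for t in lines])


@dataclass
class DigitDrawingTask(_DrawingTask):
    name: str = "digit"

    def _targets(self) -> np.ndarray:
        return digit_templates()


@dataclass
class EvidenceAccumulationTask:
    """Pulsed evidence accumulation with a left/right/equal report.

    Per presentation timestep the input is (0,0) with probability ``rho``,
    otherwise a one-hot pulse on channel 0 ("left") or 1 ("right") with equal
    probability.  The class label compares pulse counts (ties are the third
    class) and is supervised at the final step only.  ``history_window``
    (default: the final third of the presentation period) defines the
    history-centric flag: an example is history-centric when the same
    count-comparison restricted to that window is strictly wrong."""

    T_pres: int = 45
    T_del: int = 5
    rho: float = 0.7
    n_input: int = 2
    n_out: int = 3
    loss_kind: str = "cross_entropy"
    feedback_softmax: bool = True
    history_window: tuple[int, int] | None = None
    name: str = "evidence"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.history_window is None:
            w = self.T_pres // 3
            self.history_window = (self.T_pres - w + 1, self.T_pres)

    @property
    def T(self) -> int:
        return self.T_pres + self.T_del

    @staticmethod
    def classify(left: np.ndarray, right: np.ndarray) -> np.ndarray:
        """0 = left more, 1 = right more, 2 = equal (exact ties only)."""
        return np.where(left > right, 0, np.where(right > left, 1, 2))

    def sample_batch(self, batch: int, rng: np.random.Generator) -> TrialBatch:
        u = rng.random(size=(self.T_pres, batch))
        pulses = np.zeros((self.T, batch, 2))
        pulses[: self.T_pres, :, 0] = (u >= self.rho) & (u < self.rho + (1 - self.rho) / 2)
        pulses[: self.T_pres, :, 1] = u >= self.rho + (1 - self.rho) / 2
        counts = pulses[: self.T_pres].sum(axis=0)  # (batch, 2)
        labels = self.classify(counts[:, 0], counts[:, 1])
        a, b = self.history_window
        wcounts = pulses[a - 1 : b].sum(axis=0)
        final_third = self.classify(wcounts[:, 0], wcounts[:, 1])
        history_centric = final_third != labels

        x = pulses + rng.normal(0.0, INPUT_NOISE_SIGMA, size=pulses.shape)
        y = np.zeros((self.T, batch, self.n_out))
        y[-1, np.arange(batch), labels] = 1.0
        loss_mask = np.zeros(self.T, dtype=bool)
        loss_mask[-1] = True
        return TrialBatch(
            x=x, y=y, loss_mask=loss_mask, labels=labels,
            history_centric=history_centric,
            meta={"task": self.name, "pulse_counts": counts},
        )


@dataclass
class DelayedAssociationTask:
    """Binary cue at timestep 1, response supervised over the last six steps.

    The two cue vectors are fixed, disjoint 5-hot binary patterns over the
    10 input channels."""

    T: int = 15
    n_input: int = 10
    n_out: int = 2
    loss_kind: str = "cross_entropy"
    feedback_softmax: bool = True
    name: str = "delayed_association"

    def __post_init__(self) -> None:
        if self.T < 6:
            raise ValueError("delayed association requires T >= 6")

    @property
    def cues(self) -> np.ndarray:
        cues = np.zeros((2, self.n_input))
        cues[0, : self.n_input // 2] = 1.0
        cues[1, self.n_input // 2 :] = 1.0
        return cues

    def sample_batch(self, batch: int, rng: np.random.Generator) -> TrialBatch:
        labels = rng.integers(0, 2, size=batch)
        x = rng.normal(0.0, INPUT_NOISE_SIGMA, size=(self.T, batch, self.n_input))
        x[0] += self.cues[labels]
        y = np.zeros((self.T, batch, 2))
        loss_mask = np.zeros(self.T, dtype=bool)
        loss_mask[self.T - 6 :] = True  # steps T-5..T, six steps (10..15 at T=15)
        y[self.T - 6 :, np.arange(batch), labels] = 1.0
        return TrialBatch(
            x=x, y=y, loss_mask=loss_mask, labels=labels, meta={"task": self.name}
        )


@dataclass
class ContextMask:
    """Per-context parallel-fibre column masks with a shared overlap block."""

    masks: list[np.ndarray]
    overlap: float

    def __getitem__(self, ctx: int) -> np.ndarray:
        return self.masks[ctx]


def make_context_masks(
    n_granule: int,
    n_contexts: int,
    overlap: float,
    n_columns_per_context: int | None = None,
) -> ContextMask:
    """Boolean granule-column masks per task context.

    Each context's active set is a shared block (fraction = ``overlap`` of
    its columns) plus a private block disjoint from every other context's.
    By default the per-context column count is the largest that fits into
    ``n_granule``."""
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    if n_columns_per_context is None:
        n_columns_per_context = int(n_granule / (overlap + n_contexts * (1 - overlap)))
    n_shared = int(round(overlap * n_columns_per_context))
    n_private = n_columns_per_context - n_shared
    needed = n_shared + n_contexts * n_private
    if needed > n_granule:
        raise ValueError(
            f"need {needed} granule columns for {n_contexts} contexts of "
            f"{n_columns_per_context} at overlap {overlap}, have {n_granule}"
        )
    masks = []
    for ctx in range(n_contexts):
        m = np.zeros(n_granule, dtype=bool)
        m[:n_shared] = True
        start = n_shared + ctx * n_private
        m[start : start + n_private] = True
        masks.append(m)
    return ContextMask(masks=masks, overlap=overlap)


def ablation_presets(task: str) -> dict[str, AblationSchedule]:
    """Start/mid/end cerebellar-ablation windows per task (1-based inclusive)."""
    if task in ("line", "curl", "digit"):
        windows = {"start": (1, 6), "mid": (8, 13), "end": (15, 20)}
    elif task == "evidence":
        windows = {"start": (1, 15), "mid": (15, 30), "end": (30, 45)}
    elif task == "delayed_association":
        windows = {"start": (1, 5), "mid": (6, 10), "end": (11, 15), "main": (8, 12)}
    else:
        raise ValueError(f"unknown task {task!r}")
    return {k: AblationSchedule(target="cerebellum", windows=[w]) for k, w in windows.items()}


def get_task(name: str, **kwargs):
    """Task factory by name."""
    factories = {
        "line": lambda: LineDrawingTask(**kwargs),
        "curl": lambda: LineDrawingTask(curl=True, **kwargs),
        "digit": lambda: DigitDrawingTask(**kwargs),
        "evidence": lambda: EvidenceAccumulationTask(**kwargs),
        "delayed_association": lambda: DelayedAssociationTask(**kwargs),
    }
    if name not in factories:
        raise ValueError(f"unknown task {name!r}; expected one of {sorted(factories)}")
    return factories[name]()
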