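"""Experiment configuration: a serialisable record of everything needed to
reproduce a run bit-identically (task, variant, regime, sizes, rates, seeds),
with YAML round-tripping and a content hash for manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    task: str = "line"
    variant: str = "cerebellar_feedback"
    regime: str = "fixed_rnn"
    alpha: float = 0.1
    n_rnn: int = 50
    n_granule: int = 1000
    tau_windows: list[int] = field(default_factory=lambda: [3])
    eta: float = 0.001
    eta_rnn: float | None = None
    batch_size: int = 10
    n_train_examples: int = 1000
    n_test: int = 1000
    n_sessions: int = 25
    n_seeds: int = 5
    master_seed: int = 0
    feedback_softmax: bool | None = None  # None: decided by the task
    ablation_preset: str | None = None
    consolidation_rule: str = "biological"
    output_dir: str = "runs"
    task_kwargs: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]
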