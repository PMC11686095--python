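"""Serialisation: HDF5 checkpoints (weights + optimizer + RNG state),
delimited-text trial logs and tidy analysis tables, plus a run manifest
with per-file checksums."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import ModelParams
from .plasticity import AdamState

__all__ = [
    "save_checkpoint",
    "load_checkpoint",
    "append_trial_log",
    "write_tidy_table",
    "save_trajectory",
    "write_manifest",
]

_ARRAY_FIELDS = ("W_hh", "W_ih", "W_Ch", "W_rdt", "b_rdt", "W_MF", "W_PF", "W_zh")


def save_checkpoint(
    path: str | Path,
    params: ModelParams,
    opt_state: AdamState | None = None,
    rng: np.random.Generator | None = None,
    attrs: dict | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("params")
        g.attrs["alpha"] = params.alpha
        g.attrs["activation"] = params.activation
        for name in _ARRAY_FIELDS:
            val = getattr(params, name)
            if val is not None:
                g.create_dataset(name, data=val)
        if opt_state is not None:
            og = f.create_group("optimizer")
            og.attrs.update(
                t=opt_state.t, beta1=opt_state.beta1, beta2=opt_state.beta2,
                eps_stab=opt_state.eps_stab,
            )
            for kind in ("m", "v"):
                kg = og.create_group(kind)
                for name, arr in getattr(opt_state, kind).items():
                    kg.create_dataset(name, data=arr)
        if rng is not None:
            f.attrs["rng_state"] = json.dumps(rng.bit_generator.state)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_checkpoint(path: str | Path):
    """Returns (ModelParams, AdamState | None, Generator | None)."""
    with h5py.File(path, "r") as f:
        g = f["params"]
        kw = {name: g[name][...] for name in _ARRAY_FIELDS if name in g}
        params = ModelParams(
            alpha=float(g.attrs["alpha"]),
            activation=str(g.attrs.get("activation", "tanh")),
            **kw,
        )
        opt = None
        if "optimizer" in f:
            og = f["optimizer"]
            opt = AdamState(
                beta1=float(og.attrs["beta1"]), beta2=float(og.attrs["beta2"]),
                eps_stab=float(og.attrs["eps_stab"]), t=int(og.attrs["t"]),
                m={k: v[...] for k, v in og["m"].items()},
                v={k: v[...] for k, v in og["v"].items()},
            )
        rng = None
        if "rng_state" in f.attrs:
            rng = np.random.default_rng()
            rng.bit_generator.state = json.loads(f.attrs["rng_state"])
    return params, opt, rng


def append_trial_log(path: str | Path, rows: list[dict]) -> None:
    """Append per-trial scalars to a TSV log (columns: trial, seed,
    train_error, test_error; test_error may be empty)."""
    path = Path(path)
    header = "trial\tseed\ttrain_error\ttest_error\n"
    new = not path.exists()
    with path.open("a") as f:
        if new:
            f.write(header)
        for r in rows:
            f.write(
                f"{r['trial']}\t{r['seed']}\t{r['train_error']:.8g}\t"
                f"{r.get('test_error', '')}\n"
            )


def write_tidy_table(path: str | Path, metrics: dict[str, np.ndarray]) -> "pd.DataFrame":
    """Long-format TSV of per-seed metrics for external plotting.

    ``metrics`` maps metric name -> array of shape (n_seeds,) or
    (n_seeds, n_steps); rows are (metric, seed, step, value) with step empty
    for scalars."""
    rows = []
    for name, arr in metrics.items():
        arr = np.atleast_1d(np.asarray(arr))
        if arr.ndim == 1:
            rows += [
                {"metric": name, "seed": s, "step": pd.NA, "value": v}
                for s, v in enumerate(arr)
            ]
        else:
            rows += [
                {"metric": name, "seed": s, "step": t + 1, "value": arr[s, t]}
                for s in range(arr.shape[0])
                for t in range(arr.shape[1])
            ]
    df = pd.DataFrame(rows, columns=["metric", "seed", "step", "value"])
    df.to_csv(path, sep="\t", index=False)
    return df


def save_trajectory(path: str | Path, traj, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        for name in ("h", "z", "x", "c", "g", "fb"):
            val = getattr(traj, name)
            if val is not None:
                f.create_dataset(name, data=val)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def write_manifest(run_dir: str | Path, config_hash: str) -> Path:
    """Manifest of every output file with a sha256 checksum."""
    run_dir = Path(run_dir)
    files = {}
    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(run_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"config_hash": config_hash, "files": files}
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2))
    return out
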