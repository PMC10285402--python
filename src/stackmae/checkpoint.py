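"""Single-file checkpoints: weights + config + seed + training state.

A checkpoint is an ``.npz`` archive holding every parameter array under its
dotted name, optimizer moment arrays, and a JSON metadata blob (config,
seed, iteration count, loss history, RNG state) so an interrupted run can
resume and reproduce the exact next-step loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_META_KEY = "__meta__"
_OPT_PREFIX = "__opt__/"


@dataclass
class Checkpoint:
    weights: dict[str, np.ndarray]
    config: dict
    seed: int
    iteration: int = 0
    loss_history: list[float] = field(default_factory=list)
    rng_state: dict | None = None
    opt_state: dict | None = None
    kind: str = "mae"

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {k: v for k, v in self.weights.items()}
        opt_meta = None
        if self.opt_state is not None:
            opt_meta = {}
            for key, val in self.opt_state.items():
                if isinstance(val, list):
                    opt_meta[key] = {"n": len(val)}
                    for i, arr in enumerate(val):
                        arrays[f"{_OPT_PREFIX}{key}/{i}"] = arr
                else:
                    opt_meta[key] = {"value": val}
        meta = {
            "config": self.config,
            "seed": self.seed,
            "iteration": self.iteration,
            "loss_history": self.loss_history,
            "rng_state": self.rng_state,
            "opt_meta": opt_meta,
            "kind": self.kind,
            "weight_names": sorted(self.weights),
        }
        arrays[_META_KEY] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data[_META_KEY]).decode("utf-8"))
            weights = {name: data[name] for name in meta["weight_names"]}
            opt_state = None
            if meta["opt_meta"] is not None:
                opt_state = {}
                for key, spec in meta["opt_meta"].items():
                    if "n" in spec:
                        opt_state[key] = [
                            data[f"{_OPT_PREFIX}{key}/{i}"] for i in range(spec["n"])
                        ]
                    else:
                        opt_state[key] = spec["value"]
        return cls(
            weights=weights,
            config=meta["config"],
            seed=meta["seed"],
            iteration=meta["iteration"],
            loss_history=meta["loss_history"],
            rng_state=meta["rng_state"],
            opt_state=opt_state,
            kind=meta.get("kind", "mae"),
        )


def rng_state(rng: np.random.Generator) -> dict:
    return json.loads(json.dumps(rng.bit_generator.state))


def restore_rng(state: dict) -> np.random.Generator:
    rng = np.random.default_rng()
    rng.bit_generator.state = state
    return rng
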