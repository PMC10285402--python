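"""YAML run configuration: schema validation, defaults, normalization.

Missing keys are filled from documented defaults (the published
pre-training / fine-tuning schedule values); unknown keys are rejected,
and all schema violations are reported at once.  The resolved config is
embedded in every checkpoint for provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .mae import MAEConfig, OptimizerConfig, ENCODER_PRESETS, DECODER_PRESETS
from .synthetic import SynthConfig
from .unetr import AugmentConfig, FinetuneConfig

# Section defaults.  pretrain/finetune mirror the published schedule tables;
# model defaults to ViT-Base with the 4-block / 512-dim decoder.
DEFAULTS: dict = {
    "seed": 0,
    "model": {
        "preset": "vit-base",
        "encoder_depth": None,
        "encoder_dim": None,
        "encoder_heads": None,
        "decoder_depth": None,
        "decoder_dim": None,
        "decoder_heads": None,
        "patch_size": [1, 16, 16],
    },
    "mask": {
        "strategy": "random",
        "ratio": 0.9,
        "keep_columns": None,
        "keep_sections": None,
    },
    "pretrain": {
        "optimizer": "adamw",
        "base_lr": 1e-4,
        "betas": [0.9, 0.95],
        "weight_decay": 0.005,
        "warmup_iters": 50_000,
        "total_iters": 400_000,
        "batch_size": 128,
        "input_size": [6, 96, 96],
    },
    "finetune": {
        "optimizer": "adamw",
        "base_lr": 1e-4,
        "betas": [0.9, 0.95],
        "momentum": 0.9,
        "weight_decay": 0.05,
        "warmup_iters": 5_000,
        "total_iters": 200_000,
        "dropout": 0.3,
        "drop_path": 0.1,
        "batch_size": 8,
        "input_size": [6, 96, 96],
        "scales": [1.0, 1.0, 1.0],
        "target": "affinity",
        "contour_width": 1,
        "augment": {
            "xy_flip": True,
            "xy_transpose": True,
            "z_flip": True,
            "intensity_jitter": True,
            "section_jitter": True,
        },
    },
    "synth": {
        "out_dir": "synthetic_data",
        "n_volumes": 2,
        "shape": [20, 128, 128],
        "n_objects": 60,
        "min_radius": 5,
        "max_radius": 12,
        "membrane_width": 2,
        "interior_mean": 0.75,
        "membrane_mean": 0.15,
        "noise_sigma": 0.05,
        "container": "h5",
    },
    "postprocess": {
        "method": "zwatershed",
        "t_high": 0.9,
        "t_low": 0.1,
        "min_size": 128,
        "merge_threshold": 0.3,
        "theta_binary": 0.5,
        "theta_contour": 0.5,
        "bcd_min_size": 64,
    },
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if key not in defaults:
            errors.append(f"unknown key {path + key!r}")
            continue
        if isinstance(defaults[key], dict) and defaults[key]:
            if not isinstance(value, dict):
                errors.append(f"key {path + key!r} must be a mapping")
                continue
            out[key] = _merge(defaults[key], value, f"{path}{key}.", errors)
        else:
            out[key] = value
    return out


class RunConfig:
    """A validated, fully-resolved run configuration."""

    def __init__(self, resolved: dict):
        self.resolved = resolved

    # ---- materialization -------------------------------------------------
    def mae_config(self) -> MAEConfig:
        m = self.resolved["model"]
        p = self.resolved["pretrain"]
        k = self.resolved["mask"]
        preset = m["preset"]
        enc = ENCODER_PRESETS[preset]
        dec = DECODER_PRESETS[preset]
        return MAEConfig(
            encoder_depth=m["encoder_depth"] or enc[0],
            encoder_dim=m["encoder_dim"] or enc[1],
            encoder_heads=m["encoder_heads"] or enc[2],
            decoder_depth=m["decoder_depth"] or dec[0],
            decoder_dim=m["decoder_dim"] or dec[1],
            decoder_heads=m["decoder_heads"] or dec[2],
            patch_size=tuple(m["patch_size"]),
            input_size=tuple(p["input_size"]),
            mask_strategy=k["strategy"],
            mask_ratio=k["ratio"],
            keep_columns=k["keep_columns"],
            keep_sections=k["keep_sections"],
            optimizer=OptimizerConfig(
                base_lr=p["base_lr"],
                betas=tuple(p["betas"]),
                weight_decay=p["weight_decay"],
                warmup_iters=p["warmup_iters"],
                total_iters=p["total_iters"],
                batch_size=p["batch_size"],
            ),
        )

    def finetune_config(self) -> FinetuneConfig:
        f = self.resolved["finetune"]
        return FinetuneConfig(
            optimizer=f["optimizer"],
            base_lr=f["base_lr"],
            betas=tuple(f["betas"]),
            momentum=f["momentum"],
            weight_decay=f["weight_decay"],
            warmup_iters=f["warmup_iters"],
            total_iters=f["total_iters"],
            dropout=f["dropout"],
            drop_path=f["drop_path"],
            batch_size=f["batch_size"],
            input_size=tuple(f["input_size"]),
            scales=tuple(f["scales"]),
            target=f["target"],
            contour_width=f["contour_width"],
            augment=AugmentConfig(**f["augment"]),
        )

    def synth_config(self) -> SynthConfig:
        s = self.resolved["synth"]
        return SynthConfig(
            out_dir=s["out_dir"],
            n_volumes=s["n_volumes"],
            shape=tuple(s["shape"]),
            n_objects=s["n_objects"],
            min_radius=s["min_radius"],
            max_radius=s["max_radius"],
            membrane_width=s["membrane_width"],
            interior_mean=s["interior_mean"],
            membrane_mean=s["membrane_mean"],
            noise_sigma=s["noise_sigma"],
            seed=self.seed,
            container=s["container"],
        )

    @property
    def seed(self) -> int:
        return int(self.resolved["seed"])

    @property
    def postprocess(self) -> dict:
        return self.resolved["postprocess"]

    def dump(self) -> dict:
        return copy.deepcopy(self.resolved)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(source: str | Path | dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (path, dict, or None).

    Unknown keys are rejected; all violations are listed in one error.
    Missing keys are filled from the documented defaults.
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as f:
            user = yaml.safe_load(f) or {}
    if not isinstance(user, dict):
        raise ConfigError("top-level config must be a mapping")
    errors: list[str] = []
    resolved = _merge(DEFAULTS, user, "", errors)
    _validate(resolved, errors)
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(resolved)


def _validate(resolved: dict, errors: list[str]) -> None:
    if resolved["model"]["preset"] not in ENCODER_PRESETS:
        errors.append(
            f"model.preset must be one of {sorted(ENCODER_PRESETS)}, "
            f"got {resolved['model']['preset']!r}"
        )
    strategy = resolved["mask"]["strategy"]
    if strategy not in ("random", "space_only", "section_only"):
        errors.append(f"mask.strategy {strategy!r} unknown")
    ratio = resolved["mask"]["ratio"]
    if not (0.0 <= float(ratio) < 1.0):
        errors.append(f"mask.ratio must be in [0, 1), got {ratio}")
    if resolved["finetune"]["target"] not in ("affinity", "bcd"):
        errors.append(f"finetune.target {resolved['finetune']['target']!r} unknown")
    if resolved["finetune"]["optimizer"] not in ("adamw", "sgd"):
        errors.append(f"finetune.optimizer {resolved['finetune']['optimizer']!r} unknown")
    for sec in ("pretrain", "finetune"):
        for key in ("warmup_iters", "total_iters", "batch_size"):
            if int(resolved[sec][key]) < 0:
                errors.append(f"{sec}.{key} must be non-negative")
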