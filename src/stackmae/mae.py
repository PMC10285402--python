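"""The 3D masked autoencoder: visible-token encoder, lightweight decoder,
per-patch-normalized masked MSE, and the pre-training loop.

The encoder (a vanilla ViT) sees only the visible tokens, so a masking
ratio of r cuts its sequence length to floor((1 − r) · N) — at 90% masking
the encoder runs on one tenth of the tokens.  The decoder receives the
full token set: encoded tokens are scattered back into canonical grid
order and every masked slot is filled with one shared learned mask token,
plus decoder-specific positional embeddings (the same fixed 3D sin-cos
table linearly projected to the decoder width).  A linear head predicts
the full voxel content of every patch; the loss is the mean squared error
against per-patch-normalized targets, averaged over masked patches only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .checkpoint import Checkpoint, restore_rng, rng_state
from .masking import MaskPlan, make_plan
from .patches import PatchGrid, grid_for, normalize_patches, patchify, posembed_3d
from .volumes import Volume, sample_subvolume

ENCODER_PRESETS = {
    # name: (depth, embed_dim, heads)
    "vit-base": (12, 768, 12),
    "vit-large": (24, 1024, 16),
    "vit-micro": (2, 64, 4),  # desk-scale preset for tests and smoke runs
}

DECODER_PRESETS = {
    "vit-base": (4, 512, 16),
    "vit-large": (4, 512, 16),
    "vit-micro": (2, 32, 4),
}


@dataclass
class OptimizerConfig:
    """Pre-training optimizer block (AdamW, warmup + cosine decay)."""

    name: str = "adamw"
    base_lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.95)
    weight_decay: float = 0.005
    warmup_iters: int = 50_000
    total_iters: int = 400_000
    batch_size: int = 128


@dataclass
class MAEConfig:
    encoder_depth: int = 12
    encoder_dim: int = 768
    encoder_heads: int = 12
    decoder_depth: int = 4
    decoder_dim: int = 512
    decoder_heads: int = 16
    patch_size: tuple[int, int, int] = (1, 16, 16)
    input_size: tuple[int, int, int] = (6, 96, 96)
    mask_strategy: str = "random"
    mask_ratio: float = 0.9
    keep_columns: int | None = None
    keep_sections: int | None = None
    mask_token_noise: float = 0.0  # stddev of mask-token init; 0 = zero-init
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def __post_init__(self) -> None:
        if self.decoder_dim > self.encoder_dim:
            raise ValueError(
                f"decoder dim {self.decoder_dim} must not exceed encoder dim "
                f"{self.encoder_dim}"
            )
        if self.encoder_dim % self.encoder_heads or self.decoder_dim % self.decoder_heads:
            raise ValueError("embed dims must be divisible by their head counts")

    @classmethod
    def preset(cls, name: str, **overrides) -> "MAEConfig":
        d, dim, h = ENCODER_PRESETS[name]
        dd, ddim, dh = DECODER_PRESETS[name]
        base = dict(
            encoder_depth=d,
            encoder_dim=dim,
            encoder_heads=h,
            decoder_depth=dd,
            decoder_dim=ddim,
            decoder_heads=dh,
        )
        base.update(overrides)
        return cls(**base)

    def as_dict(self) -> dict:
        return asdict(self)

    @property
    def grid(self) -> PatchGrid:
        return grid_for(tuple(self.input_size), tuple(self.patch_size))


@dataclass
class ReconBatch:
    """One reconstruction pass: predictions, normalized targets, plan, loss."""

    pred_patches: np.ndarray
    target_patches_norm: np.ndarray
    plan: MaskPlan
    loss: float


class MaskedAutoencoder(nn.Module):
    def __init__(self, cfg: MAEConfig, rng: np.random.Generator):
        self.cfg = cfg
        grid = cfg.grid
        self.grid = grid
        self.patch_embed = nn.Linear(grid.patch_dim, cfg.encoder_dim, rng)
        self.pos_table = posembed_3d(grid, cfg.encoder_dim)  # fixed, not a parameter
        self.encoder = nn.ViTEncoder(cfg.encoder_depth, cfg.encoder_dim, cfg.encoder_heads, rng)
        self.decoder_embed = nn.Linear(cfg.encoder_dim, cfg.decoder_dim, rng)
        mt = np.zeros((1, 1, cfg.decoder_dim))
        if cfg.mask_token_noise > 0:
            mt = rng.normal(0.0, cfg.mask_token_noise, size=mt.shape)
        self.mask_token = nn.Tensor(mt, requires_grad=True)
        self.decoder_pos_proj = nn.Linear(cfg.encoder_dim, cfg.decoder_dim, rng, bias=False)
        self.decoder = nn.ViTEncoder(cfg.decoder_depth, cfg.decoder_dim, cfg.decoder_heads, rng)
        self.head = nn.Linear(cfg.decoder_dim, grid.patch_dim, rng)

    # ---- stages ---------------------------------------------------------
    def embed(self, patches: np.ndarray) -> nn.Tensor:
        """Linear patch embedding plus fixed positional table."""
        x = nn.Tensor(patches)
        return self.patch_embed(x) + nn.Tensor(self.pos_table[None])

    def encode(self, patches: np.ndarray, plan: MaskPlan | np.ndarray) -> nn.Tensor:
        """Run the encoder on visible tokens only.

        ``plan`` may be a single MaskPlan (shared across the batch) or a
        (B, n_visible) index array with one plan per sample.
        """
        idx = plan.visible_idx if isinstance(plan, MaskPlan) else np.asarray(plan)
        if patches.ndim == 2:
            patches = patches[None]
        if patches.shape[1] != self.grid.n_tokens:
            raise ValueError(
                f"plan/token mismatch: {patches.shape[1]} tokens vs grid "
                f"{self.grid.n_tokens}"
            )
        tokens = self.embed(patches)
        visible = tokens.gather_rows(idx)
        return self.encoder(visible)

    def decode(self, latents: nn.Tensor, plan: MaskPlan | np.ndarray) -> nn.Tensor:
        """Fill masked slots with the mask token, decode, predict patches."""
        idx = plan.visible_idx if isinstance(plan, MaskPlan) else np.asarray(plan)
        B = latents.shape[0]
        n = self.grid.n_tokens
        z = self.decoder_embed(latents)
        base = self.mask_token + nn.Tensor(np.zeros((B, n, self.cfg.decoder_dim), dtype=np.float32))
        full = base.scatter_rows(idx, z)  # canonical grid order restored here
        full = full + self.decoder_pos_proj(nn.Tensor(self.pos_table[None]))
        return self.head(self.decoder(full))

    def forward_batch(self, vols: np.ndarray, plans: list[MaskPlan]) -> tuple[nn.Tensor, ReconBatch]:
        patches, _ = patchify(vols, tuple(self.cfg.patch_size))
        vis_idx = np.stack([p.visible_idx for p in plans])
        mask_idx = np.stack([p.masked_idx for p in plans])
        latents = self.encode(patches, vis_idx)
        pred = self.decode(latents, vis_idx)
        target = normalize_patches(patches)
        loss = masked_mse(pred, target, mask_idx)
        batch = ReconBatch(pred.data, target, plans[0], float(loss.data))
        return loss, batch

    def reconstruct(self, vol: Volume, plan: MaskPlan) -> tuple[np.ndarray, np.ndarray]:
        """Inference helper: (masked input, prediction) as volumes.

        Masked voxels of the input rendering are set to 0.
        """
        from .patches import unpatchify

        patches, grid = patchify(vol, tuple(self.cfg.patch_size))
        latents = self.encode(patches[None], plan)
        pred = self.decode(latents, plan).data[0]
        masked_vis = patches.copy()
        masked_vis[plan.masked_idx] = 0.0
        return unpatchify(masked_vis, grid), unpatchify(pred, grid)


def masked_mse(
    pred: nn.Tensor, target_norm: np.ndarray, masked_idx: np.ndarray
) -> nn.Tensor:
    """Mean squared error over masked patch rows only.

    Visible rows contribute exactly zero — they are never gathered, so the
    loss gradient with respect to their predictions is identically zero.
    """
    masked_idx = np.asarray(masked_idx)
    if masked_idx.size == 0:
        raise ValueError("masked index set is empty; nothing to reconstruct")
    if target_norm.ndim == 2:
        target_norm = target_norm[None]
    bidx = np.arange(target_norm.shape[0])[:, None]
    midx = masked_idx if masked_idx.ndim == 2 else masked_idx[None]
    tgt = target_norm[bidx, midx]
    diff = pred.gather_rows(masked_idx) - nn.Tensor(tgt)
    return (diff * diff).mean()


def recon_loss(batch: ReconBatch) -> float:
    """Recompute the masked-MSE loss of a ReconBatch (numpy, no graph)."""
    pred = batch.pred_patches
    tgt = batch.target_patches_norm
    if pred.ndim == 2:
        pred, tgt = pred[None], tgt[None]
    midx = batch.plan.masked_idx
    d = pred[:, midx] - tgt[:, midx]
    return float((d * d).mean())


def _sample_batch(
    volumes: list[Volume],
    size: tuple[int, int, int],
    batch_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    crops = []
    for _ in range(batch_size):
        vol = volumes[int(rng.integers(len(volumes)))]
        crop, _ = sample_subvolume(vol, None, size, rng)
        crops.append(crop.data)
    return np.stack(crops)


def pretrain(
    dataset: list[Volume],
    cfg: MAEConfig,
    seed: int = 0,
    iterations: int | None = None,
    resume: Checkpoint | None = None,
    log_every: int = 10,
    log_fn=None,
) -> Checkpoint:
    """Self-supervised pre-training on raw volumes; returns a checkpoint.

    All schedule defaults come from the pre-training configuration block
    (AdamW, β = (0.9, 0.95), weight decay 0.005, base lr 1e-4, linear
    warmup then cosine decay, batch 128, input 6×96×96); every value is
    overridable for desk-scale runs.  Raises on NaN loss, reporting the
    iteration.
    """
    opt_cfg = cfg.optimizer
    total = opt_cfg.total_iters if iterations is None else iterations
    init_rng = np.random.default_rng(seed)
    model = MaskedAutoencoder(cfg, init_rng)
    optimizer = nn.AdamW(
        model.parameters(),
        lr=opt_cfg.base_lr,
        betas=tuple(opt_cfg.betas),
        weight_decay=opt_cfg.weight_decay,
    )
    rng = np.random.default_rng(seed + 1)
    start_it = 0
    history: list[float] = []
    if resume is not None:
        model.load_state_dict(resume.weights)
        if resume.opt_state is not None:
            optimizer.load_state_dict(resume.opt_state)
        rng = restore_rng(resume.rng_state)
        start_it = resume.iteration
        history = list(resume.loss_history)

    grid = cfg.grid
    for it in range(start_it, total):
        optimizer.lr = nn.warmup_cosine_lr(
            it, opt_cfg.base_lr, opt_cfg.warmup_iters, min(total, opt_cfg.total_iters)
        )
        vols = _sample_batch(dataset, tuple(cfg.input_size), opt_cfg.batch_size, rng)
        plans = [
            make_plan(
                grid,
                cfg.mask_strategy,
                rng,
                ratio=cfg.mask_ratio,
                keep_columns=cfg.keep_columns,
                keep_sections=cfg.keep_sections,
            )
            for _ in range(opt_cfg.batch_size)
        ]
        loss, _ = model.forward_batch(vols, plans)
        if not math.isfinite(float(loss.data)):
            raise RuntimeError(f"non-finite loss at iteration {it}")
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        history.append(float(loss.data))
        if log_fn is not None and (it % log_every == 0 or it == total - 1):
            log_fn(it, float(loss.data), optimizer.lr)

    return Checkpoint(
        weights=model.state_dict(),
        config=cfg.as_dict(),
        seed=seed,
        iteration=total,
        loss_history=history,
        rng_state=rng_state(rng),
        opt_state=optimizer.state_dict(),
        kind="mae",
    )
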