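"""UNETR-style segmentation with the (optionally pre-trained) ViT backbone.

The backbone is the MAE encoder run without masking.  Skip connections tap
intermediate transformer blocks at depths proportional to {1/4, 1/2, 3/4, 1}
of the stack (blocks {3, 6, 9, 12} for depth 12).  Because the tokenization
never downsampled z (patch z-extent 1) and strides 16 in-plane, the
convolutional decoder upsamples only in y/x — four learned 2x sub-pixel
stages from the token grid back to voxel resolution — while z stays at
full resolution throughout.  A convolutional stem on the raw input feeds
the final full-resolution stage.  The head emits 3 channels for either
target family: (z, y, x) affinities, or (binary, contour, distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .checkpoint import Checkpoint, rng_state
from .mae import MAEConfig
from .patches import patchify, posembed_3d
from .targets import affinity_from_labels, bcd_from_labels
from .volumes import LabelVolume, Volume, sample_subvolume

TARGET_KINDS = ("affinity", "bcd")

BACKBONE_PREFIXES = ("patch_embed.", "encoder.")


@dataclass
class AugmentConfig:
    xy_flip: bool = True
    xy_transpose: bool = True
    z_flip: bool = True
    intensity_jitter: bool = True
    section_jitter: bool = True


@dataclass
class FinetuneConfig:
    """Fine-tuning block; defaults follow the AdamW schedule
    (weight decay 0.05, base lr 1e-4, warmup 5k, dropout 0.3, drop-path 0.1,
    200k iterations, batch 8, input 6×96×96).  :meth:`mitoem` gives the SGD
    variant (lr 4e-3, weight decay 1e-4, warmup 10k, 300k iterations,
    scales [1, 0.5, 0.5])."""

    optimizer: str = "adamw"
    base_lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.95)
    momentum: float = 0.9
    weight_decay: float = 0.05
    warmup_iters: int = 5_000
    total_iters: int = 200_000
    dropout: float = 0.3
    drop_path: float = 0.1
    batch_size: int = 8
    input_size: tuple[int, int, int] = (6, 96, 96)
    scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    target: str = "affinity"
    contour_width: int = 1
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    @classmethod
    def mitoem(cls, **overrides) -> "FinetuneConfig":
        base = dict(
            optimizer="sgd",
            base_lr=4e-3,
            weight_decay=1e-4,
            warmup_iters=10_000,
            total_iters=300_000,
            scales=(1.0, 0.5, 0.5),
            target="bcd",
        )
        base.update(overrides)
        return cls(**base)

    def as_dict(self) -> dict:
        return asdict(self)


def tap_indices(depth: int) -> list[int]:
    """1-based encoder block indices feeding the decoder (proportional to
    the {3, 6, 9, 12}-of-12 design)."""
    idx = sorted({max(1, round(depth * k / 4)) for k in (1, 2, 3, 4)})
    return idx


class SegModel(nn.Module):
    def __init__(
        self,
        cfg: MAEConfig,
        target_kind: str,
        rng: np.random.Generator,
        decoder_channels: tuple[int, int, int, int] = (32, 16, 8, 8),
    ):
        if target_kind not in TARGET_KINDS:
            raise ValueError(f"target_kind must be one of {TARGET_KINDS}")
        if cfg.patch_size[0] != 1:
            raise ValueError("segmentation decoder assumes patch z-extent 1")
        n_up = int(math.log2(cfg.patch_size[1]))
        if 2**n_up != cfg.patch_size[1] or cfg.patch_size[1] != cfg.patch_size[2]:
            raise ValueError("in-plane patch extents must be equal powers of two")
        self.cfg = cfg
        self.target_kind = target_kind
        self.grid = cfg.grid
        self.taps = tap_indices(cfg.encoder_depth)
        self.patch_embed = nn.Linear(self.grid.patch_dim, cfg.encoder_dim, rng)
        self.pos_table = posembed_3d(self.grid, cfg.encoder_dim)
        self.encoder = nn.ViTEncoder(cfg.encoder_depth, cfg.encoder_dim, cfg.encoder_heads, rng)

        ch = list(decoder_channels)
        if len(ch) != n_up:
            # stretch/trim the channel schedule to the number of stages
            ch = [decoder_channels[min(i, len(decoder_channels) - 1)] for i in range(n_up)]
        self.stage_channels = ch
        c0 = ch[0] * 2  # token-grid feature width before the first upsample
        self.proj_final = nn.Linear(cfg.encoder_dim, c0, rng)
        # skips: all taps except the deepest, deepest-first, one per stage
        self.skip_sources = list(reversed(self.taps[:-1]))[: n_up]
        self.skip_projs = [
            nn.Linear(cfg.encoder_dim, ch[s], rng) for s in range(len(self.skip_sources))
        ]
        self.ups = []
        self.convs = []
        prev = c0
        for s in range(n_up):
            self.ups.append(nn.PixelShuffleUp(prev, ch[s], rng))
            self.convs.append(nn.Conv3dLayer(ch[s], ch[s], (3, 3, 3), rng))
            prev = ch[s]
        self.stem = nn.Conv3dLayer(1, prev, (3, 3, 3), rng)
        self.fuse = nn.Conv3dLayer(prev, prev, (3, 3, 3), rng)
        self.head = nn.Conv3dLayer(prev, 3, (1, 1, 1), rng)
        self.train_rng: np.random.Generator | None = None
        self.dropout = 0.0
        self.drop_path = 0.0

    # ---- helpers --------------------------------------------------------
    def _tokens_to_map(self, tokens: nn.Tensor, proj: nn.Linear) -> nn.Tensor:
        B = tokens.shape[0]
        gz, gy, gx = self.grid.grid_shape
        t = proj(tokens)
        c = t.shape[-1]
        return t.reshape(B, gz, gy, gx, c).transpose(0, 4, 1, 2, 3)

    def forward(self, vols: np.ndarray, training: bool = False) -> nn.Tensor:
        """Logit volume (B, 3, Z, Y, X) for a batch of raw volumes."""
        if vols.ndim == 3:
            vols = vols[None]
        patches, _ = patchify(vols, tuple(self.cfg.patch_size))
        x = self.patch_embed(nn.Tensor(patches)) + nn.Tensor(self.pos_table[None])
        kw = dict(
            rng=self.train_rng,
            dropout=self.dropout if training else 0.0,
            drop_path=self.drop_path if training else 0.0,
            training=training,
        )
        final, taps = self.encoder.forward_with_taps(x, **kw)
        f = self._tokens_to_map(final, self.proj_final)
        for s in range(len(self.ups)):
            f = self.ups[s](f)
            if s < len(self.skip_sources):
                skip_tokens = taps[self.skip_sources[s] - 1]
                skip = self._tokens_to_map(skip_tokens, self.skip_projs[s])
                f = f + skip.upsample_yx(2 ** (s + 1))
            f = self.convs[s](f).gelu()
        stem = self.stem(nn.Tensor(vols[:, None])).gelu()
        f = self.fuse(f + stem).gelu()
        return self.head(f)

    def backbone_state(self) -> dict[str, np.ndarray]:
        return {
            k: v
            for k, v in self.state_dict().items()
            if k.startswith(BACKBONE_PREFIXES)
        }


def build_seg_model(
    cfg: MAEConfig,
    target_kind: str = "affinity",
    init: Checkpoint | str | None = None,
    seed: int = 0,
    decoder_channels: tuple[int, int, int, int] = (32, 16, 8, 8),
) -> SegModel:
    """Construct a segmentation model, optionally warm-starting the backbone.

    With a checkpoint, every backbone parameter (patch embedding + encoder)
    is copied from the MAE encoder; the decoder and head stay freshly
    initialized.  Incompatible shapes raise with a full list of mismatches.
    """
    rng = np.random.default_rng(seed)
    model = SegModel(cfg, target_kind, rng, decoder_channels=decoder_channels)
    if init is not None:
        ckpt = Checkpoint.load(init) if isinstance(init, (str,)) else init
        wanted = model.backbone_state()
        source = {k: v for k, v in ckpt.weights.items() if k in wanted}
        missing = sorted(set(wanted) - set(source))
        mismatched = [
            f"{k}: backbone {wanted[k].shape} vs checkpoint {source[k].shape}"
            for k in source
            if source[k].shape != wanted[k].shape
        ]
        if missing or mismatched:
            raise ValueError(
                "checkpoint incompatible with backbone: "
                f"missing={missing}; mismatched={mismatched}"
            )
        own = dict(model.named_parameters())
        for k, arr in source.items():
            own[k].data = np.asarray(arr, dtype=np.float32).copy()
    return model


# ---- augmentation -------------------------------------------------------

def augment_pair(
    img: np.ndarray, lab: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig
) -> tuple[np.ndarray, np.ndarray]:
    if cfg.xy_flip:
        if rng.random() < 0.5:
            img, lab = img[:, ::-1], lab[:, ::-1]
        if rng.random() < 0.5:
            img, lab = img[:, :, ::-1], lab[:, :, ::-1]
    if cfg.xy_transpose and img.shape[1] == img.shape[2] and rng.random() < 0.5:
        img, lab = img.transpose(0, 2, 1), lab.transpose(0, 2, 1)
    if cfg.z_flip and rng.random() < 0.5:
        img, lab = img[::-1], lab[::-1]
    img = np.ascontiguousarray(img).astype(np.float32)
    lab = np.ascontiguousarray(lab)
    if cfg.intensity_jitter:
        a = 1.0 + rng.uniform(-0.1, 0.1)
        b = rng.uniform(-0.05, 0.05)
        img = a * img + b
    if cfg.section_jitter:
        img *= (1.0 + rng.uniform(-0.05, 0.05, size=(img.shape[0], 1, 1))).astype(np.float32)
    return np.clip(img, 0.0, 1.0), lab


def _apply_scales(
    vol: Volume, lab: LabelVolume, scales: tuple[float, float, float]
) -> tuple[Volume, LabelVolume]:
    """Integer-stride downsampling per axis (e.g. [1, 0.5, 0.5] halves y/x)."""
    steps = []
    for s in scales:
        if s <= 0 or s > 1 or (1.0 / s) % 1 != 0:
            raise ValueError(f"scales must be reciprocals of integers in (0, 1], got {scales}")
        steps.append(int(round(1.0 / s)))
    sl = tuple(slice(None, None, st) for st in steps)
    return Volume(vol.data[sl].copy()), LabelVolume(lab.data[sl].copy())


def _rebalance_weights(tgt: np.ndarray) -> np.ndarray:
    """Class-rebalancing weights for sparse binary targets.

    Positives and negatives each receive half the total weight, so thin
    boundary classes are not drowned out; matches the rebalanced BCE used
    by the reference affinity-training configurations this loss follows.
    """
    n = tgt.size
    n_pos = float(tgt.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.ones_like(tgt, dtype=np.float32)
    w = np.where(tgt > 0.5, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w.astype(np.float32)


def _weighted_bce(logits: nn.Tensor, tgt: np.ndarray) -> nn.Tensor:
    w = _rebalance_weights(tgt)
    t = nn.Tensor(tgt)
    return (nn.Tensor(w) * (logits.softplus() - logits * t)).mean()


def _seg_loss(model: SegModel, logits: nn.Tensor, lab: np.ndarray, cfg: FinetuneConfig) -> nn.Tensor:
    if model.target_kind == "affinity":
        tgt = np.stack([affinity_from_labels(LabelVolume(l)).data for l in lab])
        return _weighted_bce(logits, tgt)
    bcd = [bcd_from_labels(LabelVolume(l), cfg.contour_width) for l in lab]
    tgt = np.stack([b.stacked() for b in bcd])
    binary = logits.index_axis1(0)
    contour = logits.index_axis1(1)
    distance = logits.index_axis1(2)
    loss_b = _weighted_bce(binary, tgt[:, 0])
    loss_c = _weighted_bce(contour, tgt[:, 1])
    d = distance.sigmoid() - nn.Tensor(tgt[:, 2])
    loss_d = (d * d).mean()
    return loss_b + loss_c + loss_d


def finetune(
    model: SegModel,
    dataset: list[tuple[Volume, LabelVolume]],
    cfg: FinetuneConfig,
    seed: int = 0,
    iterations: int | None = None,
    log_every: int = 10,
    log_fn=None,
) -> Checkpoint:
    """Supervised fine-tuning on paired (volume, labels); returns a checkpoint.

    Targets (affinity or BCD) are generated on the fly from the augmented
    label crop.  Affinity loss is voxelwise BCE over the three channels;
    BCD loss is BCE (binary) + BCE (contour) + MSE (distance), equally
    weighted.  Raises on NaN loss with the iteration index.
    """
    if not dataset:
        raise ValueError("finetune requires at least one (volume, labels) pair")
    total = cfg.total_iters if iterations is None else iterations
    scaled = [
        _apply_scales(v, l, tuple(cfg.scales)) if tuple(cfg.scales) != (1.0, 1.0, 1.0) else (v, l)
        for v, l in dataset
    ]
    rng = np.random.default_rng(seed + 17)
    model.train_rng = np.random.default_rng(seed + 29)
    model.dropout = cfg.dropout
    model.drop_path = cfg.drop_path
    if cfg.optimizer == "adamw":
        optimizer = nn.AdamW(
            model.parameters(),
            lr=cfg.base_lr,
            betas=tuple(cfg.betas),
            weight_decay=cfg.weight_decay,
        )
    elif cfg.optimizer == "sgd":
        optimizer = nn.SGD(
            model.parameters(),
            lr=cfg.base_lr,
            momentum=cfg.momentum,
            weight_decay=cfg.weight_decay,
        )
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    history: list[float] = []
    for it in range(total):
        optimizer.lr = nn.warmup_cosine_lr(
            it, cfg.base_lr, cfg.warmup_iters, min(total, cfg.total_iters)
        )
        imgs, labs = [], []
        for _ in range(cfg.batch_size):
            vol, lab = scaled[int(rng.integers(len(scaled)))]
            cvol, clab = sample_subvolume(vol, lab, tuple(cfg.input_size), rng)
            img, l = augment_pair(cvol.data, clab.data, rng, cfg.augment)
            imgs.append(img)
            labs.append(l)
        batch = np.stack(imgs)
        logits = model.forward(batch, training=True)
        loss = _seg_loss(model, logits, np.stack(labs), cfg)
        if not math.isfinite(float(loss.data)):
            raise RuntimeError(f"non-finite loss at iteration {it}")
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        history.append(float(loss.data))
        if log_fn is not None and (it % log_every == 0 or it == total - 1):
            log_fn(it, float(loss.data), optimizer.lr)

    model.dropout = 0.0
    model.drop_path = 0.0
    return Checkpoint(
        weights=model.state_dict(),
        config={
            "backbone": model.cfg.as_dict(),
            "finetune": cfg.as_dict(),
            "target_kind": model.target_kind,
        },
        seed=seed,
        iteration=total,
        loss_history=history,
        rng_state=rng_state(rng),
        opt_state=None,
        kind="seg",
    )


def _axis_starts(extent: int, tile: int, step: int) -> list[int]:
    starts = list(range(0, max(extent - tile, 0) + 1, step))
    if starts[-1] != extent - tile and extent > tile:
        starts.append(extent - tile)
    return starts


def _blend_window(tile: tuple[int, int, int]) -> np.ndarray:
    wins = []
    for n in tile:
        if n == 1:
            wins.append(np.ones(1))
        else:
            i = np.arange(n)
            wins.append(0.1 + 0.9 * np.sin(np.pi * (i + 0.5) / n) ** 2)
    return (
        wins[0][:, None, None] * wins[1][None, :, None] * wins[2][None, None, :]
    ).astype(np.float32)


def predict(
    model: SegModel,
    vol: Volume,
    tile: tuple[int, int, int] | None = None,
    overlap: float = 0.25,
) -> np.ndarray:
    """Sliding-window inference; returns per-channel probabilities (3, Z, Y, X).

    Tiles are blended by weighted averaging (raised-sine window) in
    overlaps.  Volumes smaller than one tile are reflect-padded and the
    output cropped back.  All channels pass through a logistic squashing,
    so every value lies in [0, 1]; the distance channel is interpreted on
    that same normalized scale.
    """
    tile = tuple(model.cfg.input_size) if tile is None else tuple(tile)
    data = vol.data
    pads = [(0, max(0, t - s)) for t, s in zip(tile, data.shape)]
    if any(p[1] for p in pads):
        data = np.pad(data, pads, mode="reflect")
    shape = data.shape
    steps = [max(1, int(round(t * (1.0 - overlap)))) for t in tile]
    win = _blend_window(tile)
    num = np.zeros((3,) + shape, dtype=np.float32)
    den = np.zeros(shape, dtype=np.float32)
    from scipy import special

    for z0 in _axis_starts(shape[0], tile[0], steps[0]):
        for y0 in _axis_starts(shape[1], tile[1], steps[1]):
            for x0 in _axis_starts(shape[2], tile[2], steps[2]):
                sl = (
                    slice(z0, z0 + tile[0]),
                    slice(y0, y0 + tile[1]),
                    slice(x0, x0 + tile[2]),
                )
                logits = model.forward(data[sl][None], training=False).data[0]
                probs = special.expit(logits)
                num[(slice(None),) + sl] += probs * win[None]
                den[sl] += win
    out = num / den[None]
    crop = tuple(slice(0, s) for s in vol.data.shape)
    return out[(slice(None),) + crop]
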