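"""UNETR-style segmentation: transfer contract, training, inference."""

import numpy as np
import pytest

from stackmae.mae import MAEConfig, OptimizerConfig, pretrain
from stackmae.synthetic import make_volume_pair
from stackmae.unetr import (
    FinetuneConfig,
    AugmentConfig,
    build_seg_model,
    finetune,
    predict,
    tap_indices,
    _apply_scales,
)
from stackmae.volumes import Volume


def micro_cfg(**over):
    defaults = dict(
        input_size=(6, 32, 32),
        optimizer=OptimizerConfig(base_lr=1e-3, warmup_iters=5, total_iters=100, batch_size=2),
    )
    defaults.update(over)
    return MAEConfig.preset("vit-micro", **defaults)


def desk_ft(**over):
    defaults = dict(
        base_lr=1e-3,
        warmup_iters=10,
        total_iters=100,
        batch_size=2,
        input_size=(6, 32, 32),
        dropout=0.0,
        drop_path=0.0,
        target="affinity",
    )
    defaults.update(over)
    return FinetuneConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_pair():
    rng = np.random.default_rng(31)
    return make_volume_pair(
        (10, 48, 48), rng, n_objects=6, min_radius=6, max_radius=10,
        membrane_width=2, gap=2,
    )


def test_tap_indices_proportional():
    assert tap_indices(12) == [3, 6, 9, 12]
    assert tap_indices(2) == [1, 2]
    assert tap_indices(24) == [6, 12, 18, 24]


def test_checkpoint_transfer_copies_backbone_exactly(tiny_pair):
    vol, _ = tiny_pair
    cfg = micro_cfg()
    ckpt = pretrain([vol], cfg, seed=0, iterations=2)
    model = build_seg_model(cfg, "affinity", init=ckpt, seed=5)
    for name, arr in model.backbone_state().items():
        np.testing.assert_array_equal(arr, ckpt.weights[name])
    # decoder/head parameters are not taken from the checkpoint
    seg_names = {n for n, _ in model.named_parameters()}
    assert any(not n.startswith(("patch_embed.", "encoder.")) for n in seg_names)


def test_incompatible_checkpoint_lists_mismatches(tiny_pair):
    vol, _ = tiny_pair
    small = micro_cfg()
    other = micro_cfg(encoder_dim=32, decoder_dim=32, encoder_heads=4)
    ckpt = pretrain([vol], other, seed=0, iterations=1)
    with pytest.raises(ValueError, match="incompatible"):
        build_seg_model(small, "affinity", init=ckpt, seed=0)


def test_output_channels_and_shape(tiny_pair):
    vol, _ = tiny_pair
    for kind in ("affinity", "bcd"):
        model = build_seg_model(micro_cfg(), kind, seed=1)
        out = model.forward(vol.data[None, :6, :32, :32])
        assert out.shape == (1, 3, 6, 32, 32)


def test_scratch_builds_seed_determinism():
    cfg = micro_cfg()
    m1 = build_seg_model(cfg, "affinity", seed=7)
    m2 = build_seg_model(cfg, "affinity", seed=7)
    m3 = build_seg_model(cfg, "affinity", seed=8)
    s1, s2, s3 = m1.state_dict(), m2.state_dict(), m3.state_dict()
    for k in s1:
        np.testing.assert_array_equal(s1[k], s2[k])
    assert any(not np.array_equal(s1[k], s3[k]) for k in s1)


def test_finetune_reduces_loss(tiny_pair):
    model = build_seg_model(micro_cfg(), "affinity", seed=2)
    ckpt = finetune(model, [tiny_pair], desk_ft(), seed=3, iterations=120)
    hist = np.array(ckpt.loss_history)
    assert hist[-20:].mean() < hist[:10].mean()


def test_finetune_bcd_targets(tiny_pair):
    model = build_seg_model(micro_cfg(), "bcd", seed=2)
    ckpt = finetune(model, [tiny_pair], desk_ft(target="bcd"), seed=3, iterations=15)
    assert np.all(np.isfinite(ckpt.loss_history))


def test_bce_loss_floor_on_perfect_logits():
    """Feeding saturated logits matching the targets drives the BCE terms
    to their floor (closed form on a toy)."""
    from stackmae import nn
    from stackmae.unetr import _weighted_bce

    t = np.array([[0.0, 1.0]], dtype=np.float32)
    logits = nn.Tensor(np.array([[-30.0, 30.0]], dtype=np.float32))
    assert float(_weighted_bce(logits, t).data) < 1e-8


def test_scales_downsample_yx_only(tiny_pair):
    vol, lab = tiny_pair
    v2, l2 = _apply_scales(vol, lab, (1.0, 0.5, 0.5))
    assert v2.shape == (vol.shape[0], vol.shape[1] // 2, vol.shape[2] // 2)
    assert l2.shape == v2.shape
    np.testing.assert_array_equal(v2.data, vol.data[:, ::2, ::2])
    with pytest.raises(ValueError, match="scales"):
        _apply_scales(vol, lab, (1.0, 0.4, 0.4))


def test_finetune_requires_dataset(tiny_pair):
    model = build_seg_model(micro_cfg(), "affinity", seed=2)
    with pytest.raises(ValueError, match="at least one"):
        finetune(model, [], desk_ft(), seed=0, iterations=1)


def test_predict_single_tile_shape_and_range(tiny_pair):
    vol, _ = tiny_pair
    model = build_seg_model(micro_cfg(), "affinity", seed=4)
    sub = Volume(vol.data[:6, :32, :32].copy())
    probs = predict(model, sub)
    assert probs.shape == (3, 6, 32, 32)
    assert probs.min() >= 0.0 and probs.max() <= 1.0


def test_predict_constant_input_near_constant_output():
    model = build_seg_model(micro_cfg(), "affinity", seed=4)
    vol = Volume(np.full((6, 64, 64), 0.5, dtype=np.float32))
    probs = predict(model, vol, overlap=0.5)
    # positional embeddings make even an untrained model mildly
    # position-sensitive; away from seams the spread must still be far
    # below that of uninformative uniform probabilities (std ~0.29)
    inner = probs[:, 1:-1, 8:-8, 8:-8]
    assert inner.std(axis=(1, 2, 3)).max() < 0.2


def test_predict_pads_small_volumes(tiny_pair):
    vol, _ = tiny_pair
    model = build_seg_model(micro_cfg(), "affinity", seed=4)
    small = Volume(vol.data[:4, :20, :20].copy())
    probs = predict(model, small)
    assert probs.shape == (3, 4, 20, 20)
    assert np.all(np.isfinite(probs))


def test_predict_overlap_variants_finite(tiny_pair):
    vol, _ = tiny_pair
    model = build_seg_model(micro_cfg(), "affinity", seed=4)
    sub = Volume(vol.data[:6, :48, :48].copy())
    p0 = predict(model, sub, overlap=0.0)
    p5 = predict(model, sub, overlap=0.5)
    assert p0.shape == p5.shape == (3, 6, 48, 48)
    assert np.all(np.isfinite(p0)) and np.all(np.isfinite(p5))


def test_augment_pair_preserves_pairing():
    from stackmae.unetr import augment_pair

    rng = np.random.default_rng(0)
    img = rng.random((4, 8, 8)).astype(np.float32)
    lab = (img > 0.5).astype(np.int64)
    for _ in range(20):
        a_img, a_lab = augment_pair(img, lab, rng, AugmentConfig())
        assert a_img.shape == img.shape
        assert a_lab.shape == lab.shape
        # geometry applied identically: thresholding commutes approximately
        # only when intensity jitter is off
    a_img, a_lab = augment_pair(
        img, lab, np.random.default_rng(5),
        AugmentConfig(intensity_jitter=False, section_jitter=False),
    )
    np.testing.assert_array_equal((a_img > 0.5).astype(np.int64), a_lab)
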