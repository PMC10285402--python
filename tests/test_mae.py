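"""Masked autoencoder: encoder/decoder contracts, masked loss, pre-training."""

import numpy as np
import pytest

from stackmae.mae import MAEConfig, MaskedAutoencoder, masked_mse, pretrain, recon_loss, ReconBatch
from stackmae.masking import plan_random
from stackmae.patches import normalize_patches, patchify
from stackmae.synthetic import make_volume_pair
from stackmae import nn


def micro_cfg(**over):
    from stackmae.mae import OptimizerConfig

    defaults = dict(
        input_size=(6, 48, 48),
        mask_ratio=0.9,
        optimizer=OptimizerConfig(
            base_lr=1e-3, warmup_iters=10, total_iters=300, batch_size=2
        ),
    )
    defaults.update(over)
    return MAEConfig.preset("vit-micro", **defaults)


@pytest.fixture(scope="module")
def model():
    return MaskedAutoencoder(micro_cfg(input_size=(6, 96, 96)), np.random.default_rng(0))


@pytest.fixture(scope="module")
def volumes():
    rng = np.random.default_rng(42)
    vol, _ = make_volume_pair((10, 64, 64), rng, n_objects=12)
    return [vol]


def test_encoder_sees_only_visible_tokens(model, rng):
    patches = rng.random((1, 216, 256)).astype(np.float32)
    plan = plan_random(216, 0.9, rng)
    latents = model.encode(patches, plan)
    assert latents.shape == (1, 21, model.cfg.encoder_dim)


def test_ratio_zero_keeps_all_tokens(model, rng):
    patches = rng.random((1, 216, 256)).astype(np.float32)
    plan = plan_random(216, 0.0, rng)
    assert model.encode(patches, plan).shape[1] == 216


def test_masked_content_does_not_affect_latents(model, rng):
    patches = rng.random((1, 216, 256)).astype(np.float32)
    plan = plan_random(216, 0.9, rng)
    l1 = model.encode(patches, plan).data
    scrambled = patches.copy()
    scrambled[0, plan.masked_idx] = rng.random((195, 256)).astype(np.float32)
    l2 = model.encode(scrambled, plan).data
    np.testing.assert_array_equal(l1, l2)


def test_decoder_outputs_full_token_set_any_ratio(model, rng):
    patches = rng.random((1, 216, 256)).astype(np.float32)
    for ratio in (0.5, 0.9, 0.95):
        plan = plan_random(216, ratio, rng)
        pred = model.decode(model.encode(patches, plan), plan)
        assert pred.shape == (1, 216, 256)


def test_paper_scale_decoder_config_instantiates():
    cfg = MAEConfig.preset("vit-micro")
    assert MAEConfig(encoder_depth=2, encoder_dim=768, encoder_heads=12).decoder_depth == 4
    # the published best decoder: depth 4, dim 512
    big = MAEConfig(
        encoder_depth=1, encoder_dim=768, encoder_heads=12,
        decoder_depth=4, decoder_dim=512, decoder_heads=16,
        input_size=(6, 96, 96),
    )
    m = MaskedAutoencoder(big, np.random.default_rng(0))
    patches = np.random.default_rng(1).random((1, 216, 256)).astype(np.float32)
    plan = plan_random(216, 0.9, np.random.default_rng(2))
    pred = m.decode(m.encode(patches, plan), plan)
    assert pred.shape == (1, 216, 256)
    assert cfg.decoder_dim <= cfg.encoder_dim


def test_decode_deterministic_in_inference(model, rng):
    patches = rng.random((1, 216, 256)).astype(np.float32)
    plan = plan_random(216, 0.9, rng)
    p1 = model.decode(model.encode(patches, plan), plan).data
    p2 = model.decode(model.encode(patches, plan), plan).data
    np.testing.assert_array_equal(p1, p2)


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="decoder dim"):
        MAEConfig(encoder_dim=64, encoder_heads=4, decoder_dim=128, decoder_heads=4)
    with pytest.raises(ValueError, match="head"):
        MAEConfig(encoder_dim=66, encoder_heads=4, decoder_dim=64, decoder_heads=4)


def test_loss_zero_when_masked_rows_match(rng):
    pred = nn.Tensor(rng.random((1, 10, 8)).astype(np.float32), requires_grad=True)
    target = pred.data.copy()
    masked = np.array([[1, 3, 5]])
    loss = masked_mse(pred, target, masked)
    assert float(loss.data) == 0.0


def test_loss_one_for_unit_error_on_masked_rows(rng):
    target = rng.random((1, 10, 8)).astype(np.float32)
    pred_data = target.copy()
    masked = np.array([[0, 4, 9]])
    pred_data[0, masked[0]] += 1.0
    # visible rows get arbitrary junk: must not contribute
    pred_data[0, 2] += 100.0
    pred = nn.Tensor(pred_data)
    loss = masked_mse(pred, target, masked)
    assert float(loss.data) == pytest.approx(1.0, rel=1e-5)


def test_loss_gradient_zero_on_visible_rows(rng):
    pred = nn.Tensor(rng.random((2, 12, 8)).astype(np.float32), requires_grad=True)
    target = rng.random((2, 12, 8)).astype(np.float32)
    masked = np.stack([np.arange(6), np.arange(6, 12)])
    loss = masked_mse(pred, target, masked)
    loss.backward()
    for b in range(2):
        visible = np.setdiff1d(np.arange(12), masked[b])
        assert np.all(pred.grad[b, visible] == 0.0)
        assert np.any(pred.grad[b, masked[b]] != 0.0)


def test_loss_empty_masked_set_rejected(rng):
    pred = nn.Tensor(rng.random((1, 4, 2)).astype(np.float32))
    with pytest.raises(ValueError, match="empty"):
        masked_mse(pred, pred.data, np.zeros((1, 0), dtype=int))


def test_recon_batch_loss_matches_graph_loss(volumes, rng):
    cfg = micro_cfg()
    m = MaskedAutoencoder(cfg, np.random.default_rng(0))
    patches, _ = patchify(volumes[0].data[:6, :48, :48], (1, 16, 16))
    plan = plan_random(cfg.grid.n_tokens, 0.9, rng)
    latents = m.encode(patches[None], plan)
    pred = m.decode(latents, plan)
    target = normalize_patches(patches)
    loss = masked_mse(pred, target[None], plan.masked_idx[None])
    batch = ReconBatch(pred.data, target[None], plan, float(loss.data))
    assert recon_loss(batch) == pytest.approx(float(loss.data), rel=1e-6)


def test_pretrain_loss_decreases(volumes):
    ckpt = pretrain(volumes, micro_cfg(), seed=0, iterations=120)
    hist = np.array(ckpt.loss_history)
    assert len(hist) == 120
    assert hist[-20:].mean() < hist[:20].mean()


def test_pretrain_resume_reproduces_next_loss(volumes, tmp_path):
    from stackmae.checkpoint import Checkpoint

    full = pretrain(volumes, micro_cfg(), seed=3, iterations=12)
    part = pretrain(volumes, micro_cfg(), seed=3, iterations=8)
    path = part.save(tmp_path / "part.npz")
    resumed = pretrain(
        volumes, micro_cfg(), seed=3, iterations=12, resume=Checkpoint.load(path)
    )
    np.testing.assert_allclose(resumed.loss_history, full.loss_history, rtol=1e-5)
    for k in full.weights:
        np.testing.assert_allclose(resumed.weights[k], full.weights[k], atol=1e-6)


def test_pretrain_high_ratio_with_few_visible_tokens(volumes):
    ckpt = pretrain(volumes, micro_cfg(mask_ratio=0.95), seed=1, iterations=3)
    assert len(ckpt.loss_history) == 3
    assert np.all(np.isfinite(ckpt.loss_history))


def test_reconstruct_masks_voxels_to_zero(volumes, rng):
    cfg = micro_cfg()
    m = MaskedAutoencoder(cfg, np.random.default_rng(0))
    from stackmae.volumes import Volume

    sub = Volume(volumes[0].data[:6, :48, :48].copy())
    plan = plan_random(cfg.grid.n_tokens, 0.9, rng)
    masked_vis, pred = m.reconstruct(sub, plan)
    assert masked_vis.shape == sub.data.shape
    assert pred.shape == sub.data.shape
    patches, _ = patchify(masked_vis, (1, 16, 16))
    assert np.all(patches[plan.masked_idx] == 0.0)
    np.testing.assert_array_equal(
        patches[plan.visible_idx],
        patchify(sub, (1, 16, 16))[0][plan.visible_idx],
    )
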