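"""Dual-head decoder: classification detach, two-way transformer, mask decoding."""

from dataclasses import replace

import numpy as np
import pytest

from bronchoseg.autodiff import Tensor
from bronchoseg.decoder import (ClassificationHead, DecoderConfig, MaskDecoder,
                                TwoWayBlock)
from bronchoseg.losses import cls_loss
from bronchoseg.model import ModelConfig, ModelOutput, MultiTaskModel

RNG = np.random.default_rng(0)


# ---------------------------------------------------------------- classifier
def test_zero_logit_gives_half_probability():
    head = ClassificationHead(8, 4, np.random.default_rng(1))
    head.fc.weight.data[:] = 0.0
    head.fc.bias.data[:] = 0.0
    q, p, label = head.predict(Tensor(RNG.random((8, 4, 4))))
    assert q.item() == 0.0 and p == 0.5 and label == 1


def test_hand_set_final_layer_sigmoid():
    """fc weights 0, bias 2 -> p = sigma(2) ~ 0.8808."""
    head = ClassificationHead(8, 4, np.random.default_rng(1))
    head.fc.weight.data[:] = 0.0
    head.fc.bias.data[:] = 2.0
    _, p, _ = head.predict(Tensor(RNG.random((8, 4, 4))))
    assert p == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)


def test_classification_loss_detached_from_encoder(micro_model_config, tiny_dataset):
    """Backward of the classification loss alone: encoder grads exactly zero."""
    model = MultiTaskModel(micro_model_config)
    out = model.forward(tiny_dataset[0].image)
    model.zero_grad()
    cls_loss(out.class_logit, 1).backward()
    for name, p in model.named_parameters():
        if name.startswith("cls_head"):
            continue
        assert p.grad is None or not np.any(p.grad), name
    assert np.abs(model.cls_head.fc.weight.grad).max() > 0


def test_segmentation_loss_reaches_patch_embed(micro_model_config, tiny_dataset):
    model = MultiTaskModel(micro_model_config)
    out = model.forward(tiny_dataset[0].image)
    model.zero_grad()
    out.mask_logits.sum().backward()
    assert np.abs(model.encoder.patch_embed.weight.grad).max() > 0


def test_wrong_input_level_rejected():
    head = ClassificationHead(16, 4, np.random.default_rng(1))
    with pytest.raises(ValueError):
        head(Tensor(np.zeros((8, 4, 4))))


# ---------------------------------------------------------- two-way transformer
def _zeroed_block(dim=8, heads=2):
    blk = TwoWayBlock(dim, heads, np.random.default_rng(2))
    for attn in (blk.self_attn, blk.cross_t2s, blk.cross_s2t):
        attn.out.weight.data[:] = 0.0
        attn.out.bias.data[:] = 0.0
    blk.mlp.fc2.weight.data[:] = 0.0
    blk.mlp.fc2.bias.data[:] = 0.0
    return blk


def test_zero_output_projections_give_identity():
    blk = _zeroed_block()
    s = Tensor(RNG.standard_normal((4, 8)))
    t = Tensor(RNG.standard_normal((2, 8)))
    pe = Tensor(RNG.standard_normal((4, 8)))
    s2, t2 = blk(s, t, pe)
    assert np.array_equal(s2.data, s.data)
    assert np.array_equal(t2.data, t.data)


def test_spatial_permutation_equivariance():
    """Permuting spatial tokens together with their PE permutes S' identically."""
    blk = TwoWayBlock(8, 2, np.random.default_rng(3))
    s = Tensor(RNG.standard_normal((4, 8)))
    t = Tensor(RNG.standard_normal((1, 8)))
    pe = Tensor(RNG.standard_normal((4, 8)))
    perm = np.array([2, 0, 3, 1])
    s_out, t_out = blk(s, t, pe)
    s_perm, t_perm = blk(Tensor(s.data[perm]), t, Tensor(pe.data[perm]))
    assert np.allclose(s_perm.data, s_out.data[perm], atol=1e-12)
    assert np.allclose(t_perm.data, t_out.data, atol=1e-12)


def test_attention_rows_sum_to_one():
    blk = TwoWayBlock(8, 2, np.random.default_rng(4))
    q = Tensor(RNG.standard_normal((3, 8)))
    k = Tensor(RNG.standard_normal((5, 8)))
    w = blk.cross_t2s.attention_weights(q, k)
    assert w.shape == (2, 3, 5)
    assert np.allclose(w.sum(axis=-1), 1.0)


def test_head_count_must_divide_dim():
    with pytest.raises(ValueError):
        TwoWayBlock(8, 3, np.random.default_rng(0))


# -------------------------------------------------------------- mask decoding
def test_multi_token_decoder_emits_one_map_per_token(micro_model_config):
    cfg = replace(micro_model_config,
                  decoder=DecoderConfig(n_tokens=3))
    model = MultiTaskModel(cfg)
    out = model.forward(RNG.random((32, 32, 3)))
    assert out.mask_logits.shape == (3, 32, 32)
    pred = out.to_prediction()
    assert pred.all_prob_masks.shape == (3, 32, 32)


def test_zero_logits_threshold_boundary_pins_to_geq():
    """All-zero logits -> P = 0.5 everywhere -> all ones under the >= rule."""
    out = ModelOutput(mask_logits=Tensor(np.zeros((1, 8, 8))),
                      class_logit=Tensor(0.0), out_size=(8, 8), threshold=0.5)
    pred = out.to_prediction()
    assert np.all(pred.prob_mask == 0.5)
    assert np.all(pred.binary_mask == 1)


def test_threshold_consistency_on_random_logits():
    logits = RNG.standard_normal((1, 16, 16))
    out = ModelOutput(mask_logits=Tensor(logits), class_logit=Tensor(0.3),
                      out_size=(16, 16), threshold=0.5)
    pred = out.to_prediction()
    assert np.array_equal(pred.binary_mask, (pred.prob_mask >= 0.5))


def test_sigmoid_monotonicity_in_logits():
    lo = ModelOutput(Tensor(np.zeros((1, 4, 4))), Tensor(0.0), (4, 4), 0.5)
    hi_logits = np.zeros((1, 4, 4))
    hi_logits[0, 2, 2] = 1.0
    hi = ModelOutput(Tensor(hi_logits), Tensor(0.0), (4, 4), 0.5)
    assert hi.to_prediction().prob_mask[2, 2] > lo.to_prediction().prob_mask[2, 2]


@pytest.mark.parametrize("size", [64, 128])
def test_end_to_end_shape_contract(size):
    """H0 x W0 x 3 in -> H0 x W0 probability mask + one scalar logit."""
    model = MultiTaskModel(ModelConfig(image_size=(size, size)))
    pred = model.predict(RNG.random((size, size, 3)))
    assert pred.prob_mask.shape == (size, size)
    assert pred.binary_mask.shape == (size, size)
    assert np.isscalar(pred.class_logit) and 0.0 < pred.class_prob < 1.0


def test_token_dot_product_selects_channel_plane():
    """Unit token weight e_1 makes the logit map equal channel 1 of the map."""
    u2 = RNG.standard_normal((4, 2, 2))
    w = np.zeros((1, 4))
    w[0, 1] = 1.0
    logits = (Tensor(w) @ Tensor(u2.reshape(4, 4))).reshape(1, 2, 2)
    assert np.array_equal(logits.data[0], u2[1])


def test_decoder_config_validation():
    with pytest.raises(ValueError):
        DecoderConfig(threshold=0.0).validate(16)
    with pytest.raises(ValueError):
        DecoderConfig(n_tokens=0).validate(16)
    with pytest.raises(ValueError):
        DecoderConfig(n_heads=5).validate(16)


def test_skip_shape_mismatch_rejected(micro_model_config):
    model = MultiTaskModel(micro_model_config)
    from bronchoseg.fusion import FusedFeatureSet
    f1 = Tensor(np.zeros((8, 16, 16)))
    f2 = Tensor(np.zeros((16, 9, 9)))  # wrong grid for the stride chain
    f3 = Tensor(np.zeros((32, 4, 4)))
    mk = lambda f: (f, Tensor(np.zeros(f.shape)))
    with pytest.raises(ValueError):
        model.mask_decoder(FusedFeatureSet([mk(f1), mk(f2), mk(f3)]), (32, 32))
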