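"""Dual-headed decoder: image-level malignancy logit + token-conditioned mask.

Classification head.  The deepest fused feature is upsampled (x2 nearest),
passed through conv / batch-norm / GELU, globally average-pooled and mapped
to a single logit ``q``; ``sigmoid(q)`` is the malignancy probability.  The
head reads a *gradient-detached* copy of the feature, so classification
training never perturbs the shared encoder — the encoder is shaped by the
segmentation objective alone.

Mask decoder.  A learnable dense prompt embedding is added to the deepest
fused feature, and the sum is refined jointly with a small set of learnable
mask tokens by a two-way transformer (token self-attention, token-to-image
and image-to-token cross-attention, with the Fourier positional grid added
to the image side's queries/keys at every attention call).  Two transposed
convolution stages then recover spatial detail, each halving channels and
doubling resolution while adding the skip feature of the matching pyramid
level (layer norm only in the first stage).  Each refined token is mapped
by an MLP to a weight vector whose dot product with the (row-major)
flattened final feature map yields a mask logit map, bilinearly upsampled
to the input resolution, squashed by a sigmoid and thresholded (``>=``) at
``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, resize_bilinear, upsample_nearest
from .fusion import FusedFeatureSet
from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, LayerNorm, Linear,
                 Mlp, Module, MultiheadAttention, Parameter)
from .nn import ChannelLayerNorm

__all__ = ["DecoderConfig", "PredictionPair", "TwoWayBlock", "TwoWayTransformer",
           "ClassificationHead", "MaskDecoder"]


@dataclass(frozen=True)
class DecoderConfig:
    n_tokens: int = 1          # number of output masks M
    depth: int = 2             # two-way transformer blocks
    n_heads: int = 4
    threshold: float = 0.5     # tau, with >= at the boundary
    cls_hidden: int = 32
    seed: int = 0

    def validate(self, token_dim: int):
        if self.n_tokens < 1:
            raise ValueError("need at least one mask token")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if token_dim % self.n_heads:
            raise ValueError(f"heads {self.n_heads} must divide dim {token_dim}")


@dataclass
class PredictionPair:
    """Final per-image outputs on the original pixel grid."""

    prob_mask: np.ndarray      # (H0, W0) in (0, 1)
    binary_mask: np.ndarray    # (H0, W0) in {0, 1}; 1 iff prob >= threshold
    class_logit: float
    class_prob: float
    threshold: float
    all_prob_masks: np.ndarray = field(default=None, repr=False)  # (M, H0, W0)

    @property
    def predicted_label(self) -> int:
        return int(self.class_prob >= 0.5)


class TwoWayBlock(Module):
    """One bidirectional conditioning block (pre-norm, residual).

    Order: token self-attention -> token-to-image cross-attention -> token
    MLP -> image-to-token cross-attention.  The positional encoding is added
    to the image tokens wherever they act as queries or keys.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.norm_t1 = LayerNorm(dim)
        self.self_attn = MultiheadAttention(dim, n_heads, rng)
        self.norm_t2 = LayerNorm(dim)
        self.cross_t2s = MultiheadAttention(dim, n_heads, rng)
        self.norm_t3 = LayerNorm(dim)
        self.mlp = Mlp(dim, 2 * dim, rng)
        self.norm_s1 = LayerNorm(dim)
        self.cross_s2t = MultiheadAttention(dim, n_heads, rng)

    def __call__(self, s: Tensor, t: Tensor, pe: Tensor):
        """s: (N, C) image tokens; t: (M, C) mask tokens; pe: (N, C)."""
        tn = self.norm_t1(t)
        t = t + self.self_attn(tn, tn, tn)
        tn, sn = self.norm_t2(t), s + pe
        t = t + self.cross_t2s(tn, sn, sn)
        t = t + self.mlp(self.norm_t3(t))
        sq = self.norm_s1(s) + pe
        s = s + self.cross_s2t(sq, t, t)
        return s, t


class TwoWayTransformer(Module):
    def __init__(self, dim: int, depth: int, n_heads: int,
                 rng: np.random.Generator):
        self.blocks = [TwoWayBlock(dim, n_heads, rng) for _ in range(depth)]

    def __call__(self, s: Tensor, t: Tensor, pe: Tensor):
        for block in self.blocks:
            s, t = block(s, t, pe)
        return s, t


class ClassificationHead(Module):
    """Upsample -> conv -> BN -> GELU -> GAP -> linear scalar logit."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        self.conv = Conv2d(c_in, hidden, 3, rng, pad=1)
        self.bn = BatchNorm2d(hidden)
        self.fc = Linear(hidden, 1, rng)
        self.c_in = c_in

    def __call__(self, f_cls: Tensor) -> Tensor:
        """Scalar logit q.  Input is detached: no gradient reaches the encoder."""
        if f_cls.shape[0] != self.c_in:
            raise ValueError(
                f"classification head expects {self.c_in} channels, "
                f"got {f_cls.shape[0]}")
        x = f_cls.detach()
        x = self.bn(self.conv(upsample_nearest(x, 2))).gelu()
        pooled = x.mean(axis=(1, 2))          # (hidden,)
        return self.fc(pooled).reshape(())

    def predict(self, f_cls: Tensor):
        q = self(f_cls)
        p = 1.0 / (1.0 + np.exp(-q.item()))
        return q, p, int(p >= 0.5)


class MaskDecoder(Module):
    """Token-conditioned mask decoding with two-stage upsampling."""

    def __init__(self, channels: tuple, grid_hw: tuple, config: DecoderConfig):
        c1, c2, c3 = channels[:3]
        config.validate(c3)
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.dense_prompt = Parameter(0.02 * rng.standard_normal((c3, *grid_hw)))
        self.mask_tokens = Parameter(0.02 * rng.standard_normal((config.n_tokens, c3)))
        self.transformer = TwoWayTransformer(c3, config.depth, config.n_heads, rng)
        self.up1 = ConvTranspose2d(c3, c2, 2, rng, stride=2)
        self.ln1 = ChannelLayerNorm(c2)
        self.up2 = ConvTranspose2d(c2, c1, 2, rng, stride=2)
        self.token_mlp = Mlp(c3, c3, rng, d_out=c1)

    def _dense(self, hw: tuple) -> Tensor:
        """Dense prompt, bilinearly resized if the feature grid differs."""
        if self.dense_prompt.shape[1:] == tuple(hw):
            return self.dense_prompt
        return resize_bilinear(self.dense_prompt, hw)

    def decode_logits(self, fused: FusedFeatureSet) -> Tensor:
        f1, f2, f3 = fused.features
        pe3 = fused.positions[2]
        c3, h3, w3 = f3.shape
        s_map = self._dense((h3, w3)) + f3
        s_tok = s_map.transpose(1, 2, 0).reshape(h3 * w3, c3)
        pe_tok = pe3.transpose(1, 2, 0).reshape(h3 * w3, c3)
        s_out, t_out = self.transformer(s_tok, self.mask_tokens, pe_tok)
        s_map = s_out.reshape(h3, w3, c3).transpose(2, 0, 1)

        u1 = self.ln1(self.up1(s_map) + f2).gelu()
        u2 = (self.up2(u1) + f1).gelu()               # no LN in stage 2

        c1 = u2.shape[0]
        w_tokens = self.token_mlp(t_out)               # (M, c1)
        flat = u2.reshape(c1, u2.shape[1] * u2.shape[2])   # row-major over (H, W)
        logits = (w_tokens @ flat).reshape(-1, u2.shape[1], u2.shape[2])
        return logits                                   # (M, H1, W1)

    def __call__(self, fused: FusedFeatureSet, out_size: tuple) -> Tensor:
        """Full-resolution mask logits (M, H0, W0)."""
        return resize_bilinear(self.decode_logits(fused), out_size)

    def predict(self, fused: FusedFeatureSet, out_size: tuple,
                class_logit: float = 0.0) -> PredictionPair:
        logits = self(fused, out_size).data
        probs = 1.0 / (1.0 + np.exp(-logits))
        tau = self.config.threshold
        return PredictionPair(
            prob_mask=probs[0],
            binary_mask=(probs[0] >= tau).astype(np.uint8),
            class_logit=float(class_logit),
            class_prob=float(1.0 / (1.0 + np.exp(-class_logit))),
            threshold=tau,
            all_prob_masks=probs,
        )
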