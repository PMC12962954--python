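"""Hierarchical windowed-attention encoder producing a 4-level feature pyramid.

The backbone embeds the image into overlapping patches (a strided convolution
whose kernel exceeds its stride, so neighbouring patches share pixels and
local mucosal structure is preserved across patch borders), then alternates
stages of pre-norm windowed self-attention blocks with 2x spatial pooling
and channel doubling.  Spatial resolution strictly decreases and channel
capacity strictly increases with depth: early levels carry fine texture and
lesion boundaries, deep levels carry global airway context.

The model is trained from scratch at desk scale; the stage/width/depth
layout is fully configurable, with a "tiny" default (base 16 channels,
depths 1-1-2-1) sized for CPU experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, resize_bilinear
from .nn import (Conv2d, LayerNorm, Linear, Mlp, Module, MultiheadAttention,
                 Parameter)

__all__ = ["EncoderConfig", "HierarchicalEncoder", "forward_pyramid"]


@dataclass(frozen=True)
class EncoderConfig:
    stages: int = 4
    base_channels: int = 16
    channel_multiplier: int = 2
    depths: tuple = (1, 1, 2, 1)
    n_heads: tuple = (1, 2, 4, 4)
    window: int = 4
    patch_kernel: int = 7
    patch_stride: int = 4
    patch_pad: int = 3
    mlp_ratio: float = 2.0
    pos_grid: int = 16      # reference grid of the stage-1 positional embedding
    seed: int = 0

    @property
    def channels(self) -> tuple:
        return tuple(self.base_channels * self.channel_multiplier ** s
                     for s in range(self.stages))

    @property
    def total_stride(self) -> int:
        # patch embed stride, then one 2x pooling between consecutive stages
        return self.patch_stride * 2 ** (self.stages - 1)

    def validate(self):
        if self.stages != 4:
            raise ValueError("the pyramid contract requires exactly 4 stages")
        if self.patch_kernel <= self.patch_stride:
            raise ValueError(
                "patch kernel must exceed its stride (overlapping embedding)")
        if self.channel_multiplier < 2:
            raise ValueError("channels must strictly increase with depth")
        if len(self.depths) != self.stages or len(self.n_heads) != self.stages:
            raise ValueError("depths/n_heads must have one entry per stage")
        for s, (c, h) in enumerate(zip(self.channels, self.n_heads)):
            if c % h:
                raise ValueError(f"stage {s}: heads {h} must divide channels {c}")


class WindowBlock(Module):
    """Pre-norm transformer block with non-overlapping window self-attention.

    Windows are zero-history: they tile the grid exactly (the effective
    window shrinks to the grid size on coarse stages) and never span stage
    boundaries.
    """

    def __init__(self, dim: int, n_heads: int, window: int, mlp_ratio: float,
                 rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        self.window = window

    def _windowed_attention(self, x: Tensor) -> Tensor:
        h, w, c = x.shape
        win = min(self.window, h, w)
        if h % win or w % win:
            raise ValueError(f"window {win} must tile the {h}x{w} grid")
        rows = []
        for wy in range(h // win):
            cells = []
            for wx in range(w // win):
                blk = x[wy * win:(wy + 1) * win, wx * win:(wx + 1) * win, :]
                tokens = blk.reshape(win * win, c)
                cells.append(self.attn(tokens, tokens, tokens).reshape(win, win, c))
            rows.append(cells[0] if len(cells) == 1 else concat(cells, axis=1))
        return rows[0] if len(rows) == 1 else concat(rows, axis=0)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (H, W, C) token grid."""
        x = x + self._windowed_attention(self.norm1(x))
        return x + self.mlp(self.norm2(x))


class HierarchicalEncoder(Module):
    """Four-stage pyramid backbone; features are (C_s, H_s, W_s) tensors."""

    def __init__(self, config: EncoderConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channels
        self.patch_embed = Conv2d(3, ch[0], config.patch_kernel, rng,
                                  stride=config.patch_stride, pad=config.patch_pad)
        self.stages = []
        self.downsamples = []
        self.pos_embeds = []
        grid = config.pos_grid
        for s in range(config.stages):
            self.stages.append([
                WindowBlock(ch[s], config.n_heads[s], config.window,
                            config.mlp_ratio, rng)
                for _ in range(config.depths[s])])
            # learnable absolute positional embedding per stage: windowed
            # attention alone is permutation-invariant inside a window
            self.pos_embeds.append(Parameter(
                0.02 * rng.standard_normal((ch[s], max(grid >> s, 1),
                                            max(grid >> s, 1)))))
            if s + 1 < config.stages:
                self.downsamples.append(Conv2d(ch[s], ch[s + 1], 2, rng, stride=2))

    # -------------------------------------------------------------- forward
    def embed_patches(self, image: Tensor) -> Tensor:
        """Overlapping patch embedding: (3,H0,W0) -> (C1, H0/ps, W0/ps)."""
        _, h, w = image.shape
        ps = self.config.patch_stride
        if h % self.config.total_stride or w % self.config.total_stride:
            raise ValueError(
                f"image dims {h}x{w} must divide the total stride "
                f"{self.config.total_stride}")
        del ps
        return self.patch_embed(image)

    def forward_pyramid(self, image: Tensor, prompt_fn=None) -> list:
        """Run all stages; ``prompt_fn(s, F_s) -> F_s`` may rewrite each level
        before the next stage consumes it (residual prompt injection point).
        """
        x = self.embed_patches(image)
        pyramid = []
        for s, blocks in enumerate(self.stages):
            pe = self.pos_embeds[s]
            if pe.shape[1:] != x.shape[1:]:
                pe = resize_bilinear(pe, x.shape[1:])
            x = x + pe
            grid = x.transpose(1, 2, 0)          # (H, W, C)
            for block in blocks:
                grid = block(grid)
            feat = grid.transpose(2, 0, 1)       # (C, H, W)
            if prompt_fn is not None:
                feat = prompt_fn(s, feat)
            pyramid.append(feat)
            if s + 1 < len(self.stages):
                x = self.downsamples[s](feat)
        return pyramid

    def __call__(self, image: Tensor) -> list:
        return self.forward_pyramid(image)


def forward_pyramid(image: Tensor, encoder: HierarchicalEncoder) -> list:
    """Functional wrapper over :meth:`HierarchicalEncoder.forward_pyramid`."""
    return encoder.forward_pyramid(image)
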