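"""Selective top-down fusion and Gaussian-Fourier positional encoding.

Rather than a full feature-pyramid network, fusion is deliberately minimal:
only the deepest level's semantics are propagated one step down,

    F_fused^3 = F^3 + U(lateral(F^4)),     F_fused^{1,2} = F^{1,2},

with ``U`` nearest-neighbour interpolation and ``lateral`` a 1x1 projection
reconciling the channel widths (the deepest level has more channels than
its neighbour, which the additive form alone cannot absorb).  The deepest
level is then discarded, leaving exactly three feature maps.

Each retained level is paired with a positional grid built from a learnable
Gaussian frequency matrix ``G`` (d rows of 2-D frequencies):

    PE(u, v) = [sin(2*pi*G [u,v]^T), cos(2*pi*G [u,v]^T)],

with pixel centers normalized affinely so the first row/column maps to -1
and the last to +1.  ``d`` is chosen as half the level's channel count, so
the 2d-channel positional grid matches its feature map exactly and can be
consumed additively downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, upsample_nearest
from .nn import Conv2d, Module, Parameter

__all__ = ["PositionalEncoder", "TopDownFusion", "FusedFeatureSet"]


@dataclass
class FusedFeatureSet:
    """Exactly three (feature, position) pairs; level 4 is consumed, not kept."""

    pairs: list  # [(F_i, P_i)] for i = 1, 2, 3; each a (C,H,W) Tensor pair

    def __post_init__(self):
        if len(self.pairs) != 3:
            raise ValueError(f"expected exactly 3 fused pairs, got {len(self.pairs)}")
        for f, p in self.pairs:
            if f.shape[1:] != p.shape[1:]:
                raise ValueError(
                    f"positional grid {p.shape} does not align with feature {f.shape}")

    @property
    def features(self):
        return [f for f, _ in self.pairs]

    @property
    def positions(self):
        return [p for _, p in self.pairs]


def _normalized_grid(h: int, w: int) -> np.ndarray:
    """(H*W, 2) array of (u, v): row -> u, col -> v, each spanning [-1, 1]."""
    u = np.linspace(-1.0, 1.0, h) if h > 1 else np.zeros(1)
    v = np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(1)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    return np.stack([uu.ravel(), vv.ravel()], axis=1)


class PositionalEncoder(Module):
    """Learnable Gaussian-Fourier features; encoding dimension is 2d."""

    def __init__(self, d: int, rng: np.random.Generator, scale: float = 1.0):
        if d <= 0:
            raise ValueError("d must be positive")
        self.G = Parameter(scale * rng.standard_normal((d, 2)))
        self.d = d

    def encode_points(self, uv: np.ndarray) -> Tensor:
        """(N,2) normalized coordinates -> (N, 2d) encoding in [-1, 1]."""
        proj = (Tensor(np.asarray(uv, dtype=np.float64)) @ self.G.transpose(1, 0)) \
            * (2.0 * np.pi)
        return concat([proj.sin(), proj.cos()], axis=-1)

    def __call__(self, h: int, w: int) -> Tensor:
        """Dense positional grid (2d, H, W)."""
        enc = self.encode_points(_normalized_grid(h, w))
        return enc.reshape(h, w, 2 * self.d).transpose(2, 0, 1)


def encode_position(h: int, w: int, encoder: PositionalEncoder) -> Tensor:
    """Functional wrapper over :class:`PositionalEncoder`."""
    return encoder(h, w)


class TopDownFusion(Module):
    """Fuse a 4-level pyramid into three (feature, position) pairs."""

    def __init__(self, channels: tuple, seed: int = 0, pe_scale: float = 1.0):
        if len(channels) != 4:
            raise ValueError("fusion expects 4 pyramid channel widths")
        rng = np.random.default_rng(seed)
        self.lateral = Conv2d(channels[3], channels[2], 1, rng)
        self.pos_encoders = [
            PositionalEncoder(c // 2, rng, scale=pe_scale) for c in channels[:3]]

    def fuse_top_down(self, pyramid: list) -> list:
        if len(pyramid) != 4:
            raise ValueError(f"expected a 4-level pyramid, got {len(pyramid)}")
        f1, f2, f3, f4 = pyramid
        factor = f3.shape[1] // f4.shape[1]
        fused3 = f3 + upsample_nearest(self.lateral(f4), factor)
        return [f1, f2, fused3]

    def __call__(self, pyramid: list) -> FusedFeatureSet:
        feats = self.fuse_top_down(pyramid)
        pairs = [(f, pe(f.shape[1], f.shape[2]))
                 for f, pe in zip(feats, self.pos_encoders)]
        return FusedFeatureSet(pairs=pairs)
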