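"""Frequency-aware residual prompt adapters.

At every pyramid level ``s`` a lightweight adapter builds a residual prompt

    R^s = rho(GELU(phi(E_PE^s + E_HFC^s))),    F^s <- F^s + R^s

from two cues: a *patch-embedding cue* ``E_PE^s`` (the level's own feature,
linearly compressed by a factor ``r``) and a *frequency cue* ``E_HFC^s``
(the same compression applied to the feature the shared backbone produces
for the high-pass-filtered image at that level).  ``phi`` is a linear map
inside the compressed dimension and ``rho`` the up-projection back to
``C_s`` channels — the down/GELU/up adapter pattern.  ``rho`` is
zero-initialized, so an adapted network starts bit-identical to the plain
backbone and training grows the prompts from zero.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import Linear, Module

__all__ = ["StageAdapter", "FrequencyPromptAdapters"]

DEFAULT_COMPRESSION = 4


class StageAdapter(Module):
    """Adapter for one pyramid level: C_s -> C_s/r -> C_s with zero-init up-proj."""

    def __init__(self, channels: int, r: int, rng: np.random.Generator):
        if r < 1 or channels % r:
            raise ValueError(f"compression r={r} must be a divisor of C={channels}")
        inner = channels // r
        self.down = Linear(channels, inner, rng)      # L_PE^s, shared by both cues
        self.phi = Linear(inner, inner, rng)
        self.rho = Linear(inner, channels, rng, zero_init=True)
        self.channels, self.r = channels, r

    def _project(self, feat: Tensor) -> Tensor:
        """(C,H,W) -> compressed (H,W,C/r) cue via the shared down-projection."""
        if feat.shape[0] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {feat.shape[0]}")
        return self.down(feat.transpose(1, 2, 0))

    def patch_embedding_cue(self, feat: Tensor) -> Tensor:
        return self._project(feat)

    def frequency_cue(self, hfc_feat: Tensor) -> Tensor:
        return self._project(hfc_feat)

    def inject(self, feat: Tensor, e_pe: Tensor, e_hfc: Tensor) -> Tensor:
        """F^s + rho(GELU(phi(E_PE + E_HFC))); shapes must align."""
        if e_pe.shape != e_hfc.shape:
            raise ValueError(f"cue shapes differ: {e_pe.shape} vs {e_hfc.shape}")
        prompt = self.rho(self.phi(e_pe + e_hfc).gelu())
        return feat + prompt.transpose(2, 0, 1)

    def __call__(self, feat: Tensor, hfc_feat: Tensor) -> Tensor:
        return self.inject(feat, self.patch_embedding_cue(feat),
                           self.frequency_cue(hfc_feat))


class FrequencyPromptAdapters(Module):
    """One :class:`StageAdapter` per pyramid level."""

    def __init__(self, channels: tuple, r: int = DEFAULT_COMPRESSION, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.stages = [StageAdapter(c, r, rng) for c in channels]
        self.r = r

    def __call__(self, s: int, feat: Tensor, hfc_feat: Tensor) -> Tensor:
        return self.stages[s](feat, hfc_feat)

    def parameter_share(self, backbone: Module) -> float:
        """Adapter parameter count as a fraction of backbone parameters."""
        return self.n_parameters() / max(backbone.n_parameters(), 1)
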