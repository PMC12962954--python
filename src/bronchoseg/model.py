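"""Full multi-task network: encoder + prompts + fusion + dual-head decoder.

One forward pass runs the shared hierarchical backbone twice — once on the
input frame and once on its high-pass-filtered companion (computed once per
sample and cached by callers) — injects the frequency-aware residual
prompts at every pyramid level, fuses the pyramid top-down, and decodes a
full-resolution probability mask plus a scalar malignancy logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .adapters import DEFAULT_COMPRESSION, FrequencyPromptAdapters
from .autodiff import Tensor
from .decoder import ClassificationHead, DecoderConfig, MaskDecoder, PredictionPair
from .encoder import EncoderConfig, HierarchicalEncoder
from .frequency import DEFAULT_MASK_RATIO, extract_high_frequency
from .fusion import TopDownFusion
from .nn import Module

__all__ = ["ModelConfig", "ModelOutput", "MultiTaskModel"]


@dataclass(frozen=True)
class ModelConfig:
    image_size: tuple = (64, 64)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    adapter_compression: int = DEFAULT_COMPRESSION
    adapters_enabled: bool = True           # ablation switch
    freeze_frequency_branch: bool = False   # stop prompt gradients into backbone
    mask_ratio: float = DEFAULT_MASK_RATIO
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    seed: int = 0

    def validate(self):
        h, w = self.image_size
        ts = self.encoder.total_stride
        if h % ts or w % ts:
            raise ValueError(f"image size {self.image_size} must divide the "
                             f"encoder stride {ts}")


@dataclass
class ModelOutput:
    """Differentiable per-image outputs (training-time view)."""

    mask_logits: Tensor     # (M, H0, W0)
    class_logit: Tensor     # scalar
    out_size: tuple
    threshold: float

    def to_prediction(self) -> PredictionPair:
        probs = 1.0 / (1.0 + np.exp(-self.mask_logits.data))
        q = self.class_logit.item()
        return PredictionPair(
            prob_mask=probs[0],
            binary_mask=(probs[0] >= self.threshold).astype(np.uint8),
            class_logit=q, class_prob=float(1.0 / (1.0 + np.exp(-q))),
            threshold=self.threshold, all_prob_masks=probs)


class MultiTaskModel(Module):
    def __init__(self, config: ModelConfig = ModelConfig()):
        config.validate()
        # seed fan-out: sub-modules get distinct deterministic streams
        enc_cfg = replace(config.encoder, seed=config.seed)
        self.config = replace(config, encoder=enc_cfg)
        ch = enc_cfg.channels
        self.encoder = HierarchicalEncoder(enc_cfg)
        self.adapters = FrequencyPromptAdapters(
            ch, r=config.adapter_compression, seed=config.seed + 1)
        self.fusion = TopDownFusion(ch, seed=config.seed + 2)
        grid = (config.image_size[0] // enc_cfg.total_stride * 2,
                config.image_size[1] // enc_cfg.total_stride * 2)
        dec_cfg = replace(config.decoder, seed=config.seed + 3)
        self.mask_decoder = MaskDecoder(ch, grid, dec_cfg)
        self.cls_head = ClassificationHead(ch[2], dec_cfg.cls_hidden,
                                           np.random.default_rng(config.seed + 4))

    # ------------------------------------------------------------- plumbing
    def high_frequency_image(self, image: np.ndarray) -> np.ndarray:
        """(H,W,3) -> high-pass companion at the configured mask ratio."""
        return extract_high_frequency(image, self.config.mask_ratio).values

    def _prompted_pyramid(self, img_t: Tensor, hfc_t: Tensor) -> list:
        if not self.config.adapters_enabled:
            return self.encoder.forward_pyramid(img_t)
        hfc_pyramid = self.encoder.forward_pyramid(hfc_t)
        if self.config.freeze_frequency_branch:
            hfc_pyramid = [f.detach() for f in hfc_pyramid]

        def prompt(s, feat):
            return self.adapters(s, feat, hfc_pyramid[s])

        return self.encoder.forward_pyramid(img_t, prompt_fn=prompt)

    # -------------------------------------------------------------- forward
    def forward(self, image: np.ndarray, hfc: np.ndarray | None = None) -> ModelOutput:
        """image: (H, W, 3) in [0, 1]; hfc: optional cached high-pass companion."""
        image = np.asarray(image, dtype=np.float64)
        h0, w0 = image.shape[:2]
        if hfc is None:
            hfc = self.high_frequency_image(image)
        img_t = Tensor(image.transpose(2, 0, 1))
        hfc_t = Tensor(np.asarray(hfc).transpose(2, 0, 1))
        pyramid = self._prompted_pyramid(img_t, hfc_t)
        fused = self.fusion(pyramid)
        q = self.cls_head(fused.features[2])
        mask_logits = self.mask_decoder(fused, (h0, w0))
        return ModelOutput(mask_logits=mask_logits, class_logit=q,
                           out_size=(h0, w0),
                           threshold=self.mask_decoder.config.threshold)

    __call__ = forward

    def predict(self, image: np.ndarray, hfc: np.ndarray | None = None) -> PredictionPair:
        from .autodiff import no_grad
        self.cls_head.bn.training = False
        try:
            with no_grad():
                return self.forward(image, hfc).to_prediction()
        finally:
            self.cls_head.bn.training = True
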