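"""Disk formats: PNG images/masks, CSV manifests, YAML configs, checkpoints.

Masks are stored as single-channel PNGs with values {0, 255} on disk and
{0, 1} in memory.  A dataset directory holds ``images/``, ``masks/`` and a
``manifest.csv`` with columns (sample_id, image_path, mask_path, label).
Checkpoints are NumPy ``.npz`` archives of named parameters plus a YAML
snapshot of the model configuration.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .decoder import DecoderConfig
from .encoder import EncoderConfig
from .model import ModelConfig, MultiTaskModel
from .synthetic import GeneratorConfig, ImageSample

__all__ = [
    "save_dataset", "load_dataset", "save_mask_png", "load_mask_png",
    "save_checkpoint", "load_checkpoint", "load_generator_config",
]


def save_mask_png(mask: np.ndarray, path):
    Image.fromarray((np.asarray(mask, dtype=np.uint8) * 255)).save(path)


def load_mask_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)


def save_dataset(samples: list, outdir):
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "image_path", "mask_path", "label"])
        for s in samples:
            ip = f"images/{s.sample_id}.png"
            mp = f"masks/{s.sample_id}.png"
            Image.fromarray((s.image * 255).round().astype(np.uint8)).save(outdir / ip)
            save_mask_png(s.mask, outdir / mp)
            writer.writerow([s.sample_id, ip, mp, s.label])


def load_dataset(path) -> list:
    path = Path(path)
    samples = []
    with open(path / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            img = np.asarray(Image.open(path / row["image_path"]).convert("RGB"),
                             dtype=np.float64) / 255.0
            samples.append(ImageSample(
                image=img, mask=load_mask_png(path / row["mask_path"]),
                label=int(row["label"]), sample_id=row["sample_id"], seed=0))
    return samples


def _config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return [clean(v) for v in x]
        return x

    return clean(d)


def _model_config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    enc = EncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in d.pop("encoder").items()})
    dec = DecoderConfig(**d.pop("decoder"))
    d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return ModelConfig(encoder=enc, decoder=dec, **d)


def save_checkpoint(model: MultiTaskModel, path):
    """Write parameters (.npz) and the config snapshot (.yaml) side by side."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(_config_to_dict(model.config), fh)


def load_checkpoint(path) -> MultiTaskModel:
    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        cfg = _model_config_from_dict(yaml.safe_load(fh))
    model = MultiTaskModel(cfg)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def load_generator_config(path) -> GeneratorConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    return GeneratorConfig(**raw)
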