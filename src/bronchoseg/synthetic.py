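"""Seeded generator of bronchoscopy-like image / mask / label triplets.

Real white-light bronchoscopy frames share a handful of structural traits:
a circular field of view (FOV) on a black canvas, pinkish moist mucosa with
smooth low-contrast texture, a dark lumen where the airway recedes, bright
specular highlights where the light source reflects off wet tissue, and
occasional motion blur.  Lesions appear as irregular, low-contrast blobs.
The generator emulates exactly these traits with seeded random fields; it
is a structural stand-in for clinical data, not a photorealistic simulator.

Malignant and benign lesions are distinguished by *generator parameters*
only — malignant lesions draw from a family with rougher boundaries (more,
larger radial harmonics) and higher texture contrast, benign lesions from a
smoother, flatter family.  This is a documented proxy: no pixel-level
definition of malignancy exists, so the label is grounded in the appearance
family recorded in each sample's metadata.

Every generated image contains at least one lesion, and lesion support is
confined to the FOV disc by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import transform as sktf

__all__ = [
    "ImageSample", "GeneratorConfig", "generate_dataset", "augment",
    "draw_transform", "apply_transform", "split_dataset",
]

#: class ratio observed in the clinical cohort the generator stands in for
DEFAULT_MALIGNANT_FRACTION = 627.0 / 729.0

# appearance families (the malignant/benign proxy, recorded in metadata)
_FAMILIES = {
    "malignant": dict(harmonics=(3, 7), rough=(0.15, 0.32), contrast=(0.22, 0.40),
                      texture=0.14),
    "benign": dict(harmonics=(2, 4), rough=(0.03, 0.10), contrast=(0.08, 0.18),
                   texture=0.05),
}


@dataclass
class ImageSample:
    """One synthetic frame: RGB image in [0,1], binary lesion mask, label."""

    image: np.ndarray          # (H, W, 3) float64 in [0, 1]
    mask: np.ndarray           # (H, W) uint8 in {0, 1}
    label: int                 # 0 benign, 1 malignant
    sample_id: str
    seed: int
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GeneratorConfig:
    n_samples: int = 32
    image_size: tuple = (64, 64)
    malignant_fraction: float = DEFAULT_MALIGNANT_FRACTION
    lesion_count_range: tuple = (1, 2)
    specular_highlights: bool = True
    motion_blur: bool = True
    illumination_gradient: bool = True
    seed: int = 0
    total_stride: int = 32  # encoder stride the image dims must divide by

    def validate(self):
        h, w = self.image_size
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 < self.malignant_fraction < 1.0:
            raise ValueError("malignant_fraction must lie strictly in (0, 1)")
        if h < 32 or w < 32 or h % self.total_stride or w % self.total_stride:
            raise ValueError(
                f"image_size {self.image_size} must be >= 32 and divisible by "
                f"the encoder stride {self.total_stride}")
        lo, hi = self.lesion_count_range
        if lo < 1 or hi < lo:
            raise ValueError("lesion_count_range must satisfy 1 <= lo <= hi")


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean unit-ish smooth random field."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    s = field_.std()
    return field_ / s if s > 0 else field_


def _lesion_mask(rng: np.random.Generator, h: int, w: int, fov_r: float,
                 fam: dict) -> tuple[np.ndarray, dict]:
    """Rasterize one radially-perturbed ellipse blob fully inside the FOV."""
    size = min(h, w)
    r0 = rng.uniform(0.10, 0.24) * size
    rough = rng.uniform(*fam["rough"])
    n_harm = rng.integers(fam["harmonics"][0], fam["harmonics"][1] + 1)
    amps = rough * rng.uniform(0.3, 1.0, n_harm) / np.arange(1, n_harm + 1) ** 0.5
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    ecc = rng.uniform(0.7, 1.0)          # ellipse axis ratio
    tilt = rng.uniform(0, np.pi)
    r_max = r0 * (1 + amps.sum())
    # keep the whole blob inside the FOV disc
    max_off = max(fov_r - r_max - 2.0, 0.0)
    off_r = rng.uniform(0, max_off)
    off_t = rng.uniform(0, 2 * np.pi)
    cy = h / 2.0 + off_r * np.sin(off_t)
    cx = w / 2.0 + off_r * np.cos(off_t)

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    # elliptical distortion in a tilted frame
    ca, sa = np.cos(tilt), np.sin(tilt)
    ex = (dx * ca + dy * sa)
    ey = (-dx * sa + dy * ca) / ecc
    dist = np.hypot(ex, ey)
    theta = np.arctan2(ey, ex)
    radius = r0 * (1 + sum(a * np.cos((k + 2) * theta + p)
                           for k, (a, p) in enumerate(zip(amps, phases))))
    blob = (dist <= radius).astype(np.uint8)
    params = dict(center=(cy, cx), r0=float(r0), rough=float(rough),
                  n_harmonics=int(n_harm), ecc=float(ecc))
    return blob, params


def _render(rng: np.random.Generator, cfg: GeneratorConfig, idx: int,
            seed: int) -> ImageSample:
    h, w = cfg.image_size
    label = int(rng.random() < cfg.malignant_fraction)
    family = "malignant" if label else "benign"
    fam = _FAMILIES[family]

    yy, xx = np.mgrid[0:h, 0:w]
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    fov_r = 0.48 * min(h, w)
    fov = (np.hypot(yy - cy0, xx - cx0) <= fov_r)

    # mucosa base color with smooth texture
    base = np.array([0.72, 0.42, 0.40])
    img = np.empty((h, w, 3))
    tex = _smooth_noise(rng, (h, w), sigma=2.5)
    for c in range(3):
        img[:, :, c] = base[c] * (1 + 0.10 * tex + 0.05 * _smooth_noise(rng, (h, w), 4.0))

    # dark lumen: airway receding into shadow, off-center
    lum_cy = cy0 + rng.uniform(-0.2, 0.2) * h
    lum_cx = cx0 + rng.uniform(-0.2, 0.2) * w
    d_lum = np.hypot(yy - lum_cy, xx - lum_cx)
    illum = 1.0 - 0.65 * np.exp(-(d_lum ** 2) / (2 * (0.16 * min(h, w)) ** 2))
    if cfg.illumination_gradient:
        ang = rng.uniform(0, 2 * np.pi)
        ramp = ((xx - cx0) * np.cos(ang) + (yy - cy0) * np.sin(ang)) / min(h, w)
        illum *= 1.0 - 0.25 * ramp
    img *= illum[:, :, None]

    # lesions
    n_lesions = int(rng.integers(cfg.lesion_count_range[0],
                                 cfg.lesion_count_range[1] + 1))
    mask = np.zeros((h, w), dtype=np.uint8)
    lesion_params = []
    for _ in range(n_lesions):
        blob, params = _lesion_mask(rng, h, w, fov_r, fam)
        contrast = rng.uniform(*fam["contrast"])
        sign = 1.0 if rng.random() < 0.7 else -1.0   # mostly pale, sometimes dusky
        tint = np.array([1.0, 0.85, 0.75])           # lesions shift toward pale yellow
        ltex = 1 + fam["texture"] * _smooth_noise(rng, (h, w), 1.5)
        soft = ndimage.gaussian_filter(blob.astype(float), 0.8)
        delta = sign * contrast * soft * ltex
        img += delta[:, :, None] * tint[None, None, :]
        params.update(contrast=float(contrast), family=family)
        lesion_params.append(params)
        mask |= blob

    # specular highlights: small saturated reflections off wet mucosa
    if cfg.specular_highlights:
        for _ in range(int(rng.integers(1, 4))):
            sy = cy0 + rng.uniform(-0.35, 0.35) * h
            sx = cx0 + rng.uniform(-0.35, 0.35) * w
            sr = rng.uniform(0.01, 0.03) * min(h, w) + 0.8
            spot = np.exp(-((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * sr ** 2))
            img += 1.5 * spot[:, :, None]

    if cfg.motion_blur and rng.random() < 0.5:
        length = int(rng.integers(3, 6))
        ang = rng.uniform(0, np.pi)
        kern = np.zeros((length, length))
        cc = (length - 1) / 2.0
        for t in np.linspace(-cc, cc, 4 * length):
            r_ = int(round(cc + t * np.sin(ang)))
            c_ = int(round(cc + t * np.cos(ang)))
            kern[r_, c_] = 1.0
        kern /= kern.sum()
        for c in range(3):
            img[:, :, c] = ndimage.convolve(img[:, :, c], kern, mode="nearest")

    img *= fov[:, :, None]
    mask &= fov.astype(np.uint8)
    np.clip(img, 0.0, 1.0, out=img)
    return ImageSample(
        image=img, mask=mask, label=label, sample_id=f"sample_{idx:05d}",
        seed=seed, metadata=dict(family=family, lesions=lesion_params))


def generate_dataset(config: GeneratorConfig) -> list[ImageSample]:
    """Generate ``config.n_samples`` seeded triplets (pure function of config)."""
    config.validate()
    samples = []
    for idx in range(config.n_samples):
        ss = np.random.SeedSequence([config.seed, idx])
        sample_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(ss)
        samples.append(_render(rng, config, idx, sample_seed))
    return samples


# ----------------------------------------------------------- augmentation
_TRANSFORM_FAMILIES = ("rotate", "hflip", "vflip", "scale", "translate", "shear")


def draw_transform(rng: np.random.Generator) -> dict:
    """Draw one spatial transform from the configured families.

    Parameter ranges: rotation <= 30 degrees, scale 0.8–1.2, translation
    <= 10% of each dim, shear <= 10 degrees.
    """
    kind = _TRANSFORM_FAMILIES[int(rng.integers(len(_TRANSFORM_FAMILIES)))]
    tf = {"kind": kind}
    if kind == "rotate":
        tf["angle"] = float(rng.uniform(-30, 30))
    elif kind == "scale":
        tf["factor"] = float(rng.uniform(0.8, 1.2))
    elif kind == "translate":
        tf["shift"] = (float(rng.uniform(-0.1, 0.1)), float(rng.uniform(-0.1, 0.1)))
    elif kind == "shear":
        tf["angle"] = float(rng.uniform(-10, 10))
    return tf


def _affine_about_center(tf: dict, h: int, w: int) -> sktf.AffineTransform:
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    kind = tf["kind"]
    if kind == "rotate":
        inner = sktf.AffineTransform(rotation=np.deg2rad(tf["angle"]))
    elif kind == "scale":
        inner = sktf.AffineTransform(scale=(tf["factor"], tf["factor"]))
    elif kind == "translate":
        dy, dx = tf["shift"]
        inner = sktf.AffineTransform(translation=(dx * w, dy * h))
    elif kind == "shear":
        inner = sktf.AffineTransform(shear=np.deg2rad(tf["angle"]))
    else:
        raise ValueError(f"unknown transform kind {kind!r}")
    shift = sktf.AffineTransform(translation=(-cx, -cy))
    unshift = sktf.AffineTransform(translation=(cx, cy))
    return shift + inner + unshift


def apply_transform(sample: ImageSample, tf: dict) -> ImageSample:
    """Apply one transform identically to image and mask; re-binarize the mask."""
    kind = tf["kind"]
    if kind == "identity":
        return replace(sample, image=sample.image.copy(), mask=sample.mask.copy())
    if kind == "hflip":
        return replace(sample, image=sample.image[:, ::-1].copy(),
                       mask=sample.mask[:, ::-1].copy())
    if kind == "vflip":
        return replace(sample, image=sample.image[::-1].copy(),
                       mask=sample.mask[::-1].copy())
    h, w = sample.mask.shape
    aff = _affine_about_center(tf, h, w)
    img = sktf.warp(sample.image, aff.inverse, order=1, mode="constant",
                    cval=0.0, preserve_range=True)
    msk = sktf.warp(sample.mask.astype(float), aff.inverse, order=1,
                    mode="constant", cval=0.0, preserve_range=True)
    return replace(sample, image=np.clip(img, 0.0, 1.0),
                   mask=(msk >= 0.5).astype(np.uint8))


def augment(sample: ImageSample, seed: int, transform: dict | None = None) -> ImageSample:
    """Randomly draw (or take) one spatial transform and apply it; label unchanged."""
    if transform is None:
        transform = draw_transform(np.random.default_rng(seed))
    return apply_transform(sample, transform)


# ------------------------------------------------------------------ splits
def split_dataset(samples: list[ImageSample], fractions=(0.8, 0.1, 0.1),
                  seed: int = 0):
    """Label-stratified, seeded, disjoint and exhaustive 3-way partition.

    Within each class, counts are allocated by largest-remainder rounding of
    ``fraction * class_size``, so every stratum lands within one sample of
    its exact proportional share.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three nonnegative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_nonzero = sum(f > 0 for f in fractions)
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[int]] = {}
    for i, s in enumerate(samples):
        by_label.setdefault(s.label, []).append(i)
    splits: tuple[list, list, list] = ([], [], [])
    for label in sorted(by_label):
        idxs = np.array(by_label[label])
        if len(idxs) < n_nonzero:
            raise ValueError(
                f"class {label} has {len(idxs)} samples; cannot stratify into "
                f"{n_nonzero} nonempty splits")
        idxs = idxs[rng.permutation(len(idxs))]
        exact = np.array(fractions) * len(idxs)
        base = np.floor(exact).astype(int)
        rem = len(idxs) - base.sum()
        order = np.argsort(-(exact - base), kind="stable")
        for j in order[:rem]:
            base[j] += 1
        cuts = np.cumsum(base)[:-1]
        for part, chunk in zip(splits, np.split(idxs, cuts)):
            part.extend(int(i) for i in chunk)
    return tuple([samples[i] for i in sorted(part)] for part in splits)
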