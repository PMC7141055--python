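"""Seed-deterministic stochastic image augmentation.

The operator set mirrors what is commonly applied to camera-trap
training images: mirroring, color-channel shifts, blurring, grayscale
conversion, rotation, pixel dropout, local contrast normalization, and
small localized affine warps.  Each operator has an application
probability and a magnitude range; all are label-preserving by
construction.  ``augment(image, config, seed)`` is a pure function —
the same inputs always give the same output — which makes both
on-the-fly training augmentation and fixed supplementation copies
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

__all__ = ["AugmentationConfig", "augment", "OPS"]

#: Operator application order (fixed so seed streams are stable).
OPS = ("mirror", "channel_shift", "blur", "grayscale", "rotate",
       "pixel_dropout", "contrast_normalize", "local_affine")

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class AugmentationConfig:
    """Per-operator probabilities and magnitude ranges.

    Defaults are deliberately mild — label-preserving for small sprites:
    rotation up to ±25°, blur radius up to 2 px, dropout up to 5% of
    pixels, channel shifts up to ±20 intensity levels, affine
    displacements up to 8% of the image size.  Set a probability to 0 to
    disable an operator; ``AugmentationConfig.none()`` disables all.
    """

    mirror_p: float = 0.5
    channel_shift_p: float = 0.3
    channel_shift_max: float = 20.0
    blur_p: float = 0.2
    blur_sigma: tuple[float, float] = (0.3, 2.0)
    grayscale_p: float = 0.1
    rotate_p: float = 0.3
    rotate_deg: tuple[float, float] = (-25.0, 25.0)
    pixel_dropout_p: float = 0.2
    pixel_dropout_frac: tuple[float, float] = (0.0, 0.05)
    contrast_normalize_p: float = 0.1
    contrast_sigma: float = 3.0
    local_affine_p: float = 0.2
    affine_max_frac: float = 0.08

    @classmethod
    def none(cls) -> "AugmentationConfig":
        """All operators disabled: ``augment`` becomes the identity."""
        return cls(mirror_p=0, channel_shift_p=0, blur_p=0, grayscale_p=0,
                   rotate_p=0, pixel_dropout_p=0, contrast_normalize_p=0,
                   local_affine_p=0)

    @classmethod
    def only(cls, op: str, p: float = 1.0, **magnitudes) -> "AugmentationConfig":
        """Config with a single operator enabled (handy in tests and for
        cheap training-time augmentation)."""
        if op not in OPS:
            raise ValueError(f"unknown op {op!r}; choose from {OPS}")
        return replace(cls.none(), **{f"{op}_p": p}, **magnitudes)

    def probability(self, op: str) -> float:
        return getattr(self, f"{op}_p")


def _as_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def augment(image: np.ndarray, config: AugmentationConfig, seed: int = 0) -> np.ndarray:
    """Apply the enabled operators (each with its probability) to an
    8-bit RGB image; output has the same shape and dtype.

    Deterministic per ``(image, config, seed)``; with all operators
    disabled the input is returned bit-identically.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("augment expects an 8-bit RGB array of shape (H, W, 3)")
    rng = np.random.default_rng(seed)
    out = image.astype(float)
    h, w = image.shape[:2]

    for op in OPS:
        p = config.probability(op)
        if p <= 0 or rng.random() >= p:
            continue
        if op == "mirror":
            out = out[:, ::-1]
        elif op == "channel_shift":
            out = out + rng.uniform(-config.channel_shift_max,
                                    config.channel_shift_max, 3)[None, None, :]
        elif op == "blur":
            sigma = rng.uniform(*config.blur_sigma)
            out = ndimage.gaussian_filter(out, sigma=(sigma, sigma, 0))
        elif op == "grayscale":
            out = np.repeat((out @ _LUMA)[..., None], 3, axis=2)
        elif op == "rotate":
            angle = rng.uniform(*config.rotate_deg)
            out = sktransform.rotate(out, angle, order=1, mode="edge",
                                     preserve_range=True)
        elif op == "pixel_dropout":
            frac = rng.uniform(*config.pixel_dropout_frac)
            drop = rng.random((h, w)) < frac
            out = out.copy()
            out[drop] = 0.0
        elif op == "contrast_normalize":
            # local contrast normalization over pixel neighborhoods
            local_mean = ndimage.gaussian_filter(
                out, sigma=(config.contrast_sigma, config.contrast_sigma, 0))
            out = np.clip(128.0 + 1.5 * (out - local_mean), 0, 255)
        elif op == "local_affine":
            d = config.affine_max_frac
            tform = sktransform.AffineTransform(
                scale=(1 + rng.uniform(-d, d), 1 + rng.uniform(-d, d)),
                shear=rng.uniform(-d, d),
                translation=(rng.uniform(-d, d) * w, rng.uniform(-d, d) * h))
            out = sktransform.warp(out, tform.inverse, order=1, mode="edge",
                                   preserve_range=True)
    return _as_uint8(out)
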