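"""Randomized crop augmentation: one of 12 transforms per sample.

Transform types and magnitude ranges follow the AutoAugment operation set:
geometric (rotate, shear, translate), photometric enhancements (color,
brightness, contrast, sharpness), posterize, solarize and autocontrast.
Every transform preserves the crop shape and the class label.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from PIL import Image, ImageEnhance, ImageOps

from .errors import ConfigError

# (name, (magnitude_lo, magnitude_hi), signed)
_DEFAULT_OPS: tuple[tuple[str, tuple[float, float], bool], ...] = (
    ("rotate", (0.0, 30.0), True),        # degrees
    ("shear_x", (0.0, 0.3), True),        # shear factor
    ("shear_y", (0.0, 0.3), True),
    ("translate_x", (0.0, 10.0), True),   # pixels
    ("translate_y", (0.0, 10.0), True),
    ("color", (0.0, 0.9), True),          # enhancement delta around 1.0
    ("brightness", (0.0, 0.9), True),
    ("contrast", (0.0, 0.9), True),
    ("sharpness", (0.0, 0.9), True),
    ("posterize", (4.0, 8.0), False),     # bits kept
    ("solarize", (0.0, 256.0), False),    # inversion threshold
    ("autocontrast", (0.0, 0.0), False),  # magnitude-free
)

_ENHANCERS = {
    "color": ImageEnhance.Color,
    "brightness": ImageEnhance.Brightness,
    "contrast": ImageEnhance.Contrast,
    "sharpness": ImageEnhance.Sharpness,
}


@dataclasses.dataclass(frozen=True)
class AugmentationSpec:
    """The transform pool and per-transform magnitude ranges."""

    ops: tuple[tuple[str, tuple[float, float], bool], ...] = _DEFAULT_OPS

    def __post_init__(self) -> None:
        known = {name for name, _, _ in _DEFAULT_OPS}
        for name, _, _ in self.ops:
            if name not in known:
                raise ConfigError(f"unknown transform id {name!r}")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.ops]


def _apply_op(img: Image.Image, name: str, magnitude: float) -> Image.Image:
    w, h = img.size
    if name == "rotate":
        return img.rotate(magnitude, resample=Image.BILINEAR, fillcolor=None)
    if name == "shear_x":
        return img.transform((w, h), Image.AFFINE, (1, magnitude, 0, 0, 1, 0),
                             resample=Image.BILINEAR)
    if name == "shear_y":
        return img.transform((w, h), Image.AFFINE, (1, 0, 0, magnitude, 1, 0),
                             resample=Image.BILINEAR)
    if name == "translate_x":
        return img.transform((w, h), Image.AFFINE, (1, 0, magnitude, 0, 1, 0),
                             resample=Image.BILINEAR)
    if name == "translate_y":
        return img.transform((w, h), Image.AFFINE, (1, 0, 0, 0, 1, magnitude),
                             resample=Image.BILINEAR)
    if name in _ENHANCERS:
        return _ENHANCERS[name](img).enhance(1.0 + magnitude)
    if name == "posterize":
        return ImageOps.posterize(img, int(round(magnitude)))
    if name == "solarize":
        t = int(round(magnitude))
        lut = [i if i < t else 255 - i for i in range(256)]
        return img.point(lut * 3)
    if name == "autocontrast":
        return ImageOps.autocontrast(img)
    raise ConfigError(f"unknown transform id {name!r}")


def apply_augmentation(
    crop: np.ndarray,
    spec: AugmentationSpec | None = None,
    rng: np.random.Generator | None = None,
    op_name: str | None = None,
    magnitude: float | None = None,
) -> np.ndarray:
    """Apply one randomly chosen transform (uniform type, uniform magnitude).

    ``op_name``/``magnitude`` pin the choice for testing. Deterministic for a
    fixed rng state; the output is always the same shape, uint8.
    """
    spec = spec or AugmentationSpec()
    rng = rng or np.random.default_rng(0)
    ops = {name: (rng_range, signed) for name, rng_range, signed in spec.ops}
    if op_name is None:
        op_name = spec.names[int(rng.integers(len(spec.names)))]
    if op_name not in ops:
        raise ConfigError(f"unknown transform id {op_name!r}")
    (lo, hi), signed = ops[op_name]
    if magnitude is None:
        magnitude = float(rng.uniform(lo, hi))
        if signed and rng.integers(2):
            magnitude = -magnitude
    img = Image.fromarray(np.asarray(crop, dtype=np.uint8))
    out = _apply_op(img, op_name, magnitude)
    return np.asarray(out, dtype=np.uint8)
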