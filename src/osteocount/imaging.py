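"""Image and annotation I/O plus physical-unit conversions.

Conventions: images are 8-bit RGB, top-left origin, row-major; annotation
coordinates are 0-based with x = column and y = row, matching ImageJ
"Multi-point" pixel indexing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Nominal acquisition scale of the brightfield images (pixels per micron).
DEFAULT_PIXEL_SCALE = 1.32

#: Minimum image side so that a 50x50 crop always fits.
MIN_IMAGE_SIDE = 50

VALID_LABELS = ("osteoclast", "non_osteoclast", "unlabeled")


@dataclasses.dataclass
class MicroscopyImage:
    """An RGB brightfield field of view with its physical pixel scale."""

    pixels: np.ndarray  # H x W x 3 uint8
    pixel_scale: float = DEFAULT_PIXEL_SCALE  # pixels per micron
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(
                f"expected an HxWx3 pixel grid, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValidationError(f"expected uint8 pixels, got {self.pixels.dtype}")
        h, w = self.pixels.shape[:2]
        if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image {w}x{h} is smaller than the minimum {MIN_IMAGE_SIDE} px side"
            )
        if not self.pixel_scale > 0:
            raise ValidationError(f"pixel_scale must be > 0, got {self.pixel_scale}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def area_mm2(self) -> float:
        """Physical area of the field of view in mm^2."""
        return pixels_to_area_mm2(self.width, self.height, self.pixel_scale)


@dataclasses.dataclass(frozen=True)
class CellAnnotation:
    """A manually clicked cell center (ImageJ Multi-point style)."""

    x: int
    y: int
    label: str = "unlabeled"
    image: str = ""

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValidationError(
                f"label {self.label!r} not in {VALID_LABELS}"
            )

    def validate_against(self, height: int, width: int) -> None:
        if not (0 <= self.x < width and 0 <= self.y < height):
            raise ValidationError(
                f"annotation ({self.x}, {self.y}) outside image {width}x{height}"
            )


@dataclasses.dataclass(frozen=True)
class WellGeometry:
    """Culture-well geometry used to scale per-image counts to per-well counts."""

    image_area_mm2: float = 1.587
    well_area_mm2: float = 95.0
    images_per_well: int = 9

    def __post_init__(self) -> None:
        if min(self.image_area_mm2, self.well_area_mm2, self.images_per_well) <= 0:
            raise ValidationError("all WellGeometry fields must be strictly positive")


def pixels_to_area_mm2(width_px: float, height_px: float, pixel_scale: float) -> float:
    """Physical area in mm^2 of a width_px x height_px field at ``pixel_scale`` px/um.

    At the nominal 1.32 px/um scale a 1920x1440 field covers 1.587 mm^2, the
    constant used for per-well normalization.
    """
    if width_px <= 0 or height_px <= 0 or pixel_scale <= 0:
        raise ValidationError("width, height and pixel_scale must be positive")
    return (width_px / pixel_scale) * (height_px / pixel_scale) * 1e-6


def read_image(
    path: str | Path,
    pixel_scale: float = DEFAULT_PIXEL_SCALE,
    source_id: str | None = None,
) -> MicroscopyImage:
    """Read a PNG or TIFF into a :class:`MicroscopyImage`.

    Grayscale inputs are replicated to three channels; an alpha channel is
    dropped; 16-bit data are linearly rescaled to 8-bit (dtype max -> 255).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by backend
        raise IOError(f"could not decode image file {path}") from exc
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        arr = np.floor(arr.astype(np.float64) * (255.0 / 65535.0) + 0.5).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"unsupported image layout {arr.shape} in {path}")
    return MicroscopyImage(
        pixels=np.ascontiguousarray(arr),
        pixel_scale=pixel_scale,
        source_id=source_id if source_id is not None else path.stem,
    )


def write_image(image: MicroscopyImage | np.ndarray, path: str | Path) -> None:
    pixels = image.pixels if isinstance(image, MicroscopyImage) else np.asarray(image)
    iio.imwrite(Path(path), pixels)


def read_centers_csv(
    path: str | Path,
    image_shape: tuple[int, int] | None = None,
) -> list[CellAnnotation]:
    """Read cell-center annotations from a CSV with header image,x,y[,label].

    ``image_shape`` (height, width), when given, validates every coordinate
    against the image bounds.
    """
    df = pd.read_csv(path, dtype={"image": str, "label": str})
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"centers CSV {path} lacks required column(s) {sorted(missing)}")
    annotations: list[CellAnnotation] = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label", None)
        if label is None or (isinstance(label, float) and np.isnan(label)):
            label = "unlabeled"
        ann = CellAnnotation(
            x=int(row.x),
            y=int(row.y),
            label=str(label),
            image=str(getattr(row, "image", "")),
        )
        if image_shape is not None:
            ann.validate_against(*image_shape)
        annotations.append(ann)
    return annotations


def write_centers_csv(annotations: Iterable[CellAnnotation], path: str | Path) -> None:
    records = [
        {"image": a.image, "x": a.x, "y": a.y, "label": a.label} for a in annotations
    ]
    df = pd.DataFrame.from_records(records, columns=["image", "x", "y", "label"])
    df.to_csv(path, index=False)


# Overlay colors follow the published figure convention: osteoclasts red,
# non-osteoclasts blue, segment boundaries thin red lines.
_CLASS_COLORS: Mapping[str, tuple[int, int, int]] = {
    "osteoclast": (220, 20, 20),
    "non_osteoclast": (30, 60, 220),
    "unlabeled": (90, 90, 90),
}
_BOUNDARY_COLOR = (200, 0, 0)


def render_overlay(
    image: MicroscopyImage,
    segments,
    labels: Mapping[int, str] | None = None,
) -> np.ndarray:
    """Return a copy of the image with segment boundaries and class boxes drawn.

    ``segments`` is a :class:`~osteocount.segmentation.SegmentLabelMap`;
    ``labels`` maps retained segment ids to class names. The input pixel grid
    is never mutated.
    """
    from skimage.segmentation import find_boundaries

    labels = dict(labels or {})
    label_map = segments.labels
    ids = set(segments.segment_ids())
    unknown = set(labels) - ids
    if unknown:
        raise ValidationError(f"labels given for unknown segment id(s) {sorted(unknown)}")

    out = image.pixels.copy()
    if not ids:
        return out
    fg = label_map > 0
    boundaries = find_boundaries(np.where(fg, label_map, 0), mode="inner")
    out[boundaries] = _BOUNDARY_COLOR
    for seg_id, cls in labels.items():
        color = _CLASS_COLORS.get(cls, _CLASS_COLORS["unlabeled"])
        rows, cols = np.nonzero(label_map == seg_id)
        if rows.size == 0:
            continue
        r0, r1 = rows.min(), rows.max()
        c0, c1 = cols.min(), cols.max()
        out[r0, c0 : c1 + 1] = color
        out[r1, c0 : c1 + 1] = color
        out[r0 : r1 + 1, c0] = color
        out[r0 : r1 + 1, c1] = color
    return out


def write_overlay(
    image: MicroscopyImage,
    segments,
    labels: Mapping[int, str] | None,
    path: str | Path,
) -> np.ndarray:
    """Render and write the annotated overlay PNG; returns the rendered array."""
    out = render_overlay(image, segments, labels)
    iio.imwrite(Path(path), out)
    return out
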