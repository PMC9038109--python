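"""Marker-controlled watershed segmentation of stained-cell brightfield images.

The stage order is: grayscale conversion, Otsu binarization, morphological
opening/closing with a 3x3 structuring element, Euclidean distance transform,
marker selection at 0.7x the maximum distance, watershed flooding, removal of
segments below 500 px, centroid extraction, and 50x50 crop extraction around
each retained centroid.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import sobel
from skimage.segmentation import watershed as _sk_watershed

from .errors import DegenerateImageError, ValidationError
from .imaging import MicroscopyImage

logger = logging.getLogger(__name__)

LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclasses.dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation stage.

    The kernel size, the 0.7 marker fraction, the 500-px minimum segment
    area and the 50-px crop size are the published pipeline constants;
    iteration counts follow the canonical marker-watershed recipe.
    ``marker_scope`` selects whether the 0.7 fraction is taken of the
    whole-image distance maximum ("image") or of each mask component's own
    maximum ("component", the default — robust when cell sizes vary widely).
    """

    kernel_size: int = 3
    opening_iterations: int = 2
    closing_iterations: int = 1
    sure_background_iterations: int = 3
    marker_fraction: float = 0.7
    marker_scope: Literal["component", "image"] = "component"
    min_segment_area: int = 500
    crop_size: int = 50
    polarity: Literal["dark_cells", "bright_cells"] = "dark_cells"

    def __post_init__(self) -> None:
        if not 0 < self.marker_fraction <= 1:
            raise ValidationError("marker_fraction must be in (0, 1]")
        if self.min_segment_area < 1:
            raise ValidationError("min_segment_area must be >= 1")
        if self.crop_size < 2 or self.crop_size % 2:
            raise ValidationError("crop_size must be an even integer >= 2")
        if self.marker_scope not in ("component", "image"):
            raise ValidationError(f"unknown marker_scope {self.marker_scope!r}")
        if self.polarity not in ("dark_cells", "bright_cells"):
            raise ValidationError(f"unknown polarity {self.polarity!r}")


@dataclasses.dataclass
class SegmentLabelMap:
    """Per-pixel segment identities: 0 background, -1 watershed boundary, k>=1 segments."""

    labels: np.ndarray  # H x W int32

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValidationError("label map must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def segment_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    def areas(self) -> dict[int, int]:
        """Pixel area of every positive segment id."""
        flat = self.labels[self.labels > 0]
        if flat.size == 0:
            return {}
        counts = np.bincount(flat)
        return {int(i): int(counts[i]) for i in np.nonzero(counts)[0]}

    def centroids(self) -> dict[int, tuple[int, int]]:
        """Integer centroid (x, y) per segment: per-axis pixel mean, half-up rounding."""
        out: dict[int, tuple[int, int]] = {}
        for seg_id in self.segment_ids():
            rows, cols = np.nonzero(self.labels == seg_id)
            out[seg_id] = (
                int(np.floor(cols.mean() + 0.5)),
                int(np.floor(rows.mean() + 0.5)),
            )
        return out


@dataclasses.dataclass
class CellCrop:
    """A fixed-size RGB window centered on a detected cell."""

    pixels: np.ndarray  # crop_size x crop_size x 3 uint8
    center: tuple[int, int]  # (x, y) in the source image
    segment_id: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("crop must be HxWx3")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValidationError("crop must be square")


def to_grayscale(image: MicroscopyImage | np.ndarray) -> np.ndarray:
    """Luma grayscale 0.299 R + 0.587 G + 0.114 B, half-up rounded to uint8."""
    pixels = image.pixels if isinstance(image, MicroscopyImage) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValidationError("expected an HxWx3 image")
    w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
    gray = pixels.astype(np.float64) @ w
    return np.floor(gray + 0.5).astype(np.uint8)


def otsu_threshold(
    gray: np.ndarray, polarity: str = "dark_cells"
) -> tuple[int, np.ndarray]:
    """Otsu's histogram threshold and the resulting binary foreground mask.

    Returns the smallest threshold t* maximizing the between-class variance of
    the {<= t} / {> t} split of the 8-bit histogram. Under ``dark_cells``
    polarity the mask marks intensities <= t* as foreground; ``bright_cells``
    inverts.
    """
    gray = np.asarray(gray)
    if gray.dtype != np.uint8:
        raise ValidationError("otsu_threshold expects a uint8 grid")
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image: Otsu threshold is undefined")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # pixels with value <= t
    w1 = total - w0
    sum0 = np.cumsum(hist * levels)
    total_sum = sum0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (total_sum - sum0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    t_star = int(np.argmax(between))  # argmax returns the smallest maximizer
    fg = gray <= t_star
    if polarity == "bright_cells":
        fg = ~fg
    return t_star, fg.astype(np.uint8)


def _structuring_element(size: int) -> np.ndarray:
    return np.ones((size, size), dtype=bool)


def morphological_clean(mask: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Opening (erode-dilate) then closing (dilate-erode) with a square element."""
    config = config or SegmentationConfig()
    selem = _structuring_element(config.kernel_size)
    out = np.asarray(mask, dtype=bool)
    if config.opening_iterations > 0:
        out = ndi.binary_opening(
            out, structure=selem, iterations=config.opening_iterations
        )
    if config.closing_iterations > 0:
        out = ndi.binary_closing(
            out, structure=selem, iterations=config.closing_iterations
        )
    return out.astype(np.uint8)


def distance_transform(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance of each foreground pixel to the nearest background pixel.

    The image border is treated as adjacent to (virtual) background, so the
    transform is well defined even on an all-foreground mask.
    """
    mask = np.asarray(mask).astype(bool)
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dist = ndi.distance_transform_edt(padded)
    return dist[1:-1, 1:-1]


def select_markers(
    dist: np.ndarray,
    fraction: float | None = None,
    cleaned_mask: np.ndarray | None = None,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Build the watershed marker grid from the distance map.

    Sure foreground is thresholded at ``fraction`` x the maximum distance
    (whole-image or per mask component, per ``config.marker_scope``); sure
    background is the complement of the dilated cleaned mask. Output labels:
    1 = background marker, 0 = unknown band, 2.. = cell markers
    (8-connected components of sure foreground).
    """
    config = config or SegmentationConfig()
    fraction = config.marker_fraction if fraction is None else fraction
    dist = np.asarray(dist, dtype=np.float64)
    if cleaned_mask is None:
        cleaned_mask = dist > 0
    cleaned_mask = np.asarray(cleaned_mask).astype(bool)

    eight = np.ones((3, 3), dtype=bool)
    if config.marker_scope == "image":
        max_dist = dist.max() if dist.size else 0.0
        sure_fg = dist >= fraction * max_dist if max_dist > 0 else np.zeros_like(cleaned_mask)
        sure_fg &= cleaned_mask
    else:
        sure_fg = np.zeros_like(cleaned_mask)
        comp_labels, n_comp = ndi.label(cleaned_mask, structure=eight)
        if n_comp:
            comp_max = ndi.maximum(dist, labels=comp_labels, index=np.arange(1, n_comp + 1))
            comp_max = np.atleast_1d(comp_max)
            thr = np.zeros(n_comp + 1)
            thr[1:] = fraction * comp_max
            sure_fg = (comp_labels > 0) & (dist >= thr[comp_labels])

    selem = _structuring_element(config.kernel_size)
    dilated = (
        ndi.binary_dilation(
            cleaned_mask, structure=selem, iterations=config.sure_background_iterations
        )
        if config.sure_background_iterations > 0
        else cleaned_mask
    )
    markers = np.zeros(dist.shape, dtype=np.int32)
    markers[~dilated] = 1
    fg_labels, n_fg = ndi.label(sure_fg, structure=eight)
    markers[fg_labels > 0] = fg_labels[fg_labels > 0] + 1
    return markers


def watershed_segment(
    image: MicroscopyImage,
    markers: np.ndarray,
    dist: np.ndarray | None = None,
) -> SegmentLabelMap:
    """Flood from the marker grid; boundary pixels are labeled -1.

    The flooding surface is the negative distance transform when ``dist`` is
    supplied (splits touching cells at their neck) and otherwise the Sobel
    gradient of the grayscale image.
    """
    markers = np.asarray(markers, dtype=np.int32)
    if markers.shape != image.pixels.shape[:2]:
        raise ValidationError("marker grid shape does not match the image")
    if not (markers > 1).any():
        return SegmentLabelMap(np.zeros(markers.shape, dtype=np.int32))
    elevation = -np.asarray(dist, dtype=np.float64) if dist is not None else sobel(
        to_grayscale(image).astype(np.float64)
    )
    ws = _sk_watershed(elevation, markers=markers, watershed_line=True)
    out = np.where(ws >= 2, ws - 1, 0).astype(np.int32)
    out[ws == 0] = -1  # watershed lines
    # A boundary between two background-flooded basins is not a cell boundary.
    out[(ws == 0) & (markers == 1)] = 0
    return SegmentLabelMap(out)


def filter_small_segments(
    segments: SegmentLabelMap, min_area: int | None = None
) -> tuple[SegmentLabelMap, list[tuple[int, int]]]:
    """Drop segments with area < min_area (strictly less; 500-px rule).

    Returns the retained map (dropped segments relabeled to background,
    original ids kept) and the removed (id, area) list.
    """
    min_area = 500 if min_area is None else min_area
    areas = segments.areas()
    removed = [(i, a) for i, a in sorted(areas.items()) if a < min_area]
    labels = segments.labels.copy()
    if removed:
        removed_ids = np.array([i for i, _ in removed])
        labels[np.isin(labels, removed_ids)] = 0
    return SegmentLabelMap(labels), removed


def segment_centers(segments: SegmentLabelMap) -> list[tuple[int, int, int]]:
    """(segment id, center x, center y) for every retained segment."""
    return [(i, x, y) for i, (x, y) in sorted(segments.centroids().items())]


def extract_crops(
    image: MicroscopyImage,
    centers: Sequence[tuple[int, int, int]] | Sequence[tuple[int, int]],
    crop_size: int = 50,
) -> list[CellCrop]:
    """Fixed-size crops centered on each (x, y); borders filled by reflection.

    ``centers`` items are either (segment id, x, y) or (x, y). The window is
    rows [y-h, y+h) and columns [x-h, x+h) with h = crop_size // 2.
    """
    half = crop_size // 2
    h, w = image.pixels.shape[:2]
    padded = np.pad(image.pixels, ((half, half), (half, half), (0, 0)), mode="symmetric")
    crops: list[CellCrop] = []
    for item in centers:
        if len(item) == 3:
            seg_id, x, y = item
        else:
            seg_id, (x, y) = 0, item
        if not (0 <= x < w and 0 <= y < h):
            raise ValidationError(f"crop center ({x}, {y}) outside image {w}x{h}")
        window = padded[y : y + crop_size, x : x + crop_size]
        crops.append(
            CellCrop(
                pixels=window.copy(),
                center=(int(x), int(y)),
                segment_id=int(seg_id),
                source_id=image.source_id,
            )
        )
    return crops


def segment_image(
    image: MicroscopyImage, config: SegmentationConfig | None = None
) -> tuple[SegmentLabelMap, list[CellCrop]]:
    """Full segmentation stage: image -> retained segments + centered crops."""
    config = config or SegmentationConfig()
    gray = to_grayscale(image)
    try:
        _, mask = otsu_threshold(gray, polarity=config.polarity)
    except DegenerateImageError:
        logger.info("%s: constant grayscale, no cells found", image.source_id)
        empty = SegmentLabelMap(np.zeros(gray.shape, dtype=np.int32))
        return empty, []
    cleaned = morphological_clean(mask, config)
    dist = distance_transform(cleaned)
    markers = select_markers(dist, config.marker_fraction, cleaned, config)
    segments = watershed_segment(image, markers, dist)
    n_pre = len(segments.segment_ids())
    retained, removed = filter_small_segments(segments, config.min_segment_area)
    centers = segment_centers(retained)
    crops = extract_crops(image, centers, config.crop_size)
    logger.info(
        "%s: %d segments, %d removed (<%d px), %d crops extracted",
        image.source_id, n_pre, len(removed), config.min_segment_area, len(crops),
    )
    return retained, crops
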