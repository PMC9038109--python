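"""Synthetic TRAP-stain-like scene generator with exact ground truth.

Scenes emulate brightfield fields of osteoclast cultures: a light background,
large pink/purple multinucleated osteoclasts (>= 3 darker nuclei), small pale
mononuclear non-osteoclasts, and sub-500-px debris. Cells are rendered as
jittered ellipses so the downstream watershed, size filter and classifier see
realistic object-size and color structure with known per-object truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon

from .errors import CapacityError, ValidationError
from .imaging import CellAnnotation, MicroscopyImage, write_centers_csv, write_image

# Body colors, 8-bit. Red and blue are sampled per channel; green is sampled
# as R minus a class-specific red-green gap so the stain saturation that
# defines TRAP positivity separates the classes by construction (the gap
# ranges are disjoint with a 15-level margin). Every body stays darker than
# the background by several noise SDs so Otsu keeps it in the foreground.
OC_RED_RANGE = (190, 225)
OC_RED_GREEN_GAP = (75, 105)
OC_BLUE_RANGE = (170, 210)
NON_OC_RED_RANGE = (195, 220)
NON_OC_RED_GREEN_GAP = (40, 60)
NON_OC_BLUE_RANGE = (180, 205)
DEBRIS_COLOR_RANGE = ((135, 165), (125, 155), (115, 145))


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic field of view."""

    height: int = 512
    width: int = 512
    n_osteoclasts: int = 5
    n_non_osteoclasts: int = 20
    n_debris: int = 3
    oc_radius: tuple[float, float] = (20.0, 45.0)
    non_radius: tuple[float, float] = (6.0, 14.0)
    debris_radius: tuple[float, float] = (2.5, 9.0)
    nuclei_per_oc: tuple[int, int] = (3, 8)
    nuclei_per_non: tuple[int, int] = (0, 2)
    background_level: int = 240
    noise_sd: float = 5.0
    nucleus_darkening: tuple[float, float] = (0.55, 0.75)
    # Bodies stay near-convex: the distance transform of a convex body is
    # concave, so the 0.7-of-max marker superlevel set is a single component.
    eccentricity: float = 0.25
    boundary_jitter: float = 0.04
    spacing_margin: float = 8.0
    touching_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.oc_radius[0] < 13.0:
            # pi * 13^2 > 500: every osteoclast body must survive the size filter
            raise ValidationError("osteoclast minimum radius must keep body area >= 500 px")
        if np.pi * self.debris_radius[1] ** 2 * (1 + self.boundary_jitter) ** 2 >= 500:
            raise ValidationError("debris maximum radius must keep area < 500 px")
        if self.nuclei_per_oc[0] < 3:
            raise ValidationError("osteoclasts must have at least 3 nuclei")
        if self.nuclei_per_non[1] > 2:
            raise ValidationError("non-osteoclasts must have at most 2 nuclei")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneConfig":
        raw = json.loads(text)
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


@dataclasses.dataclass(frozen=True)
class CellTruth:
    center: tuple[int, int]  # (x, y)
    label: str  # osteoclast | non_osteoclast
    area: int  # rendered body pixel count
    n_nuclei: int


@dataclasses.dataclass(frozen=True)
class DebrisTruth:
    center: tuple[int, int]
    area: int


@dataclasses.dataclass
class GroundTruth:
    cells: list[CellTruth]
    debris: list[DebrisTruth]

    @property
    def osteoclasts(self) -> list[CellTruth]:
        return [c for c in self.cells if c.label == "osteoclast"]

    @property
    def non_osteoclasts(self) -> list[CellTruth]:
        return [c for c in self.cells if c.label == "non_osteoclast"]

    def annotations(self, image_name: str = "") -> list[CellAnnotation]:
        return [
            CellAnnotation(x=c.center[0], y=c.center[1], label=c.label, image=image_name)
            for c in self.cells
        ]


@dataclasses.dataclass
class _Body:
    cx: float
    cy: float
    a: float  # semi-axis
    b: float
    theta: float
    jitter_k: int
    jitter_phase: float
    jitter_amp: float

    @property
    def max_radius(self) -> float:
        return max(self.a, self.b) * (1 + self.jitter_amp)

    def mask_indices(self, height: int, width: int, n_vertices: int = 120):
        phi = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        # radius of an ellipse in polar form, modulated by low-frequency jitter
        r_ell = (self.a * self.b) / np.sqrt(
            (self.b * np.cos(phi)) ** 2 + (self.a * np.sin(phi)) ** 2
        )
        r = r_ell * (1 + self.jitter_amp * np.sin(self.jitter_k * phi + self.jitter_phase))
        ang = phi + self.theta
        rows = self.cy + r * np.sin(ang)
        cols = self.cx + r * np.cos(ang)
        return draw_polygon(rows, cols, shape=(height, width))


def _sample_body(
    rng: np.random.Generator,
    radius_range: tuple[float, float],
    jitter: float,
    eccentricity: float = 0.25,
) -> _Body:
    base = rng.uniform(*radius_range)
    ecc = rng.uniform(-eccentricity, eccentricity)
    return _Body(
        cx=0.0,
        cy=0.0,
        a=base * (1 + ecc),
        b=base * (1 - ecc),
        theta=rng.uniform(0, np.pi),
        jitter_k=int(rng.integers(4, 7)),
        jitter_phase=rng.uniform(0, 2 * np.pi),
        jitter_amp=jitter,
    )


def _place(
    rng: np.random.Generator,
    body: _Body,
    placed: list[_Body],
    height: int,
    width: int,
    margin: float,
    max_tries: int = 300,
) -> bool:
    r = body.max_radius
    lo_x, hi_x = r + 2, width - r - 2
    lo_y, hi_y = r + 2, height - r - 2
    if hi_x <= lo_x or hi_y <= lo_y:
        return False
    for _ in range(max_tries):
        cx = rng.uniform(lo_x, hi_x)
        cy = rng.uniform(lo_y, hi_y)
        ok = all(
            np.hypot(cx - p.cx, cy - p.cy) >= r + p.max_radius + margin for p in placed
        )
        if ok:
            body.cx, body.cy = cx, cy
            return True
    return False


def _sample_color(rng: np.random.Generator, ranges) -> np.ndarray:
    return np.array([rng.uniform(lo, hi) for lo, hi in ranges])


def _sample_cell_color(
    rng: np.random.Generator,
    red_range: tuple[float, float],
    red_green_gap: tuple[float, float],
    blue_range: tuple[float, float],
) -> np.ndarray:
    red = rng.uniform(*red_range)
    green = red - rng.uniform(*red_green_gap)
    blue = rng.uniform(*blue_range)
    return np.array([red, green, blue])


def _render_nuclei(
    canvas: np.ndarray,
    rng: np.random.Generator,
    body: _Body,
    body_color: np.ndarray,
    n_nuclei: int,
    radius_range: tuple[float, float],
    darkening: tuple[float, float],
    shape: tuple[int, int],
) -> None:
    placed: list[tuple[float, float, float]] = []
    reach = 0.55 * min(body.a, body.b)
    for _ in range(n_nuclei):
        nr = rng.uniform(*radius_range)
        for _ in range(50):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, max(reach - nr, 0.5))
            nx = body.cx + rad * np.cos(ang)
            ny = body.cy + rad * np.sin(ang)
            if all(np.hypot(nx - px, ny - py) >= nr + pr + 1 for px, py, pr in placed):
                break
        placed.append((nx, ny, nr))
        factor = rng.uniform(*darkening)
        nucleus = _Body(nx, ny, nr, nr * rng.uniform(0.8, 1.0),
                        rng.uniform(0, np.pi), 3, 0.0, 0.0)
        rr, cc = nucleus.mask_indices(*shape)
        canvas[rr, cc] = body_color * factor


def generate_scene(config: SceneConfig) -> tuple[MicroscopyImage, GroundTruth]:
    """Render one scene; deterministic for a fixed config (seed included).

    Placement, shape/color, debris and pixel noise each use an independent
    random substream of the seed, so e.g. changing ``n_debris`` does not
    reshuffle cell placement.
    """
    h, w = config.height, config.width
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_oc, rng_non, rng_debris, rng_noise = (np.random.default_rng(s) for s in streams)

    placed: list[_Body] = []
    oc_bodies: list[tuple[_Body, np.ndarray, int]] = []
    pair_budget = config.touching_pairs

    def place_or_raise(rng, body, margin, kind):
        if not _place(rng, body, placed, h, w, margin):
            raise CapacityError(
                f"could not place {kind} after retries (placed {len(placed)} objects)",
                placed=len(placed),
            )
        placed.append(body)

    for i in range(config.n_osteoclasts):
        body = _sample_body(rng_oc, config.oc_radius, config.boundary_jitter, config.eccentricity)
        if pair_budget > 0 and i > 0:
            # attach to the previous osteoclast at sub-threshold spacing
            prev = placed[-1]
            ang = rng_oc.uniform(0, 2 * np.pi)
            d = 0.75 * (prev.max_radius + body.max_radius)
            body.cx = float(np.clip(prev.cx + d * np.cos(ang), body.max_radius + 2,
                                    w - body.max_radius - 2))
            body.cy = float(np.clip(prev.cy + d * np.sin(ang), body.max_radius + 2,
                                    h - body.max_radius - 2))
            placed.append(body)
            pair_budget -= 1
        else:
            place_or_raise(rng_oc, body, config.spacing_margin, "osteoclast")
        color = _sample_cell_color(rng_oc, OC_RED_RANGE, OC_RED_GREEN_GAP, OC_BLUE_RANGE)
        n_nuc = int(rng_oc.integers(config.nuclei_per_oc[0], config.nuclei_per_oc[1] + 1))
        oc_bodies.append((body, color, n_nuc))

    non_bodies: list[tuple[_Body, np.ndarray, int]] = []
    for _ in range(config.n_non_osteoclasts):
        body = _sample_body(rng_non, config.non_radius, config.boundary_jitter, config.eccentricity)
        place_or_raise(rng_non, body, config.spacing_margin, "non-osteoclast")
        color = _sample_cell_color(
            rng_non, NON_OC_RED_RANGE, NON_OC_RED_GREEN_GAP, NON_OC_BLUE_RANGE
        )
        n_nuc = int(
            rng_non.integers(config.nuclei_per_non[0], config.nuclei_per_non[1] + 1)
        )
        non_bodies.append((body, color, n_nuc))

    debris_bodies: list[tuple[_Body, np.ndarray]] = []
    for _ in range(config.n_debris):
        body = _sample_body(rng_debris, config.debris_radius, config.boundary_jitter, config.eccentricity)
        place_or_raise(rng_debris, body, config.spacing_margin, "debris")
        debris_bodies.append((body, _sample_color(rng_debris, DEBRIS_COLOR_RANGE)))

    canvas = np.full((h, w, 3), float(config.background_level))
    cells: list[CellTruth] = []
    for (body, color, n_nuc), label, nuc_range in (
        [(t, "osteoclast", (3.5, 6.0)) for t in oc_bodies]
        + [(t, "non_osteoclast", (2.0, 3.5)) for t in non_bodies]
    ):
        rr, cc = body.mask_indices(h, w)
        canvas[rr, cc] = color
        rng_for_nuclei = rng_oc if label == "osteoclast" else rng_non
        if n_nuc > 0:
            _render_nuclei(
                canvas, rng_for_nuclei, body, color, n_nuc, nuc_range,
                config.nucleus_darkening, (h, w),
            )
        cells.append(
            CellTruth(
                center=(int(round(body.cx)), int(round(body.cy))),
                label=label,
                area=int(rr.size),
                n_nuclei=n_nuc,
            )
        )

    debris_truth: list[DebrisTruth] = []
    for body, color in debris_bodies:
        rr, cc = body.mask_indices(h, w)
        canvas[rr, cc] = color
        debris_truth.append(
            DebrisTruth(center=(int(round(body.cx)), int(round(body.cy))), area=int(rr.size))
        )

    noise = rng_noise.normal(0.0, config.noise_sd, size=canvas.shape)
    pixels = np.clip(np.round(canvas + noise), 0, 255).astype(np.uint8)
    image = MicroscopyImage(pixels=pixels, source_id=f"synthetic-seed{config.seed}")
    return image, GroundTruth(cells=cells, debris=debris_truth)


def split_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Floor-then-distribute (largest remainder) split of n items.

    Reproduces the published image-level split, e.g. 458 images at
    (0.651, 0.164, 0.185) -> 298 training / 75 validation / 85 testing.
    """
    fractions = list(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"split fractions must sum to 1, got {sum(fractions)}")
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_dataset(
    n_images: int,
    template: SceneConfig,
    fractions: Sequence[float] = (0.651, 0.164, 0.185),
    seed: int = 0,
) -> dict[str, list[tuple[MicroscopyImage, GroundTruth]]]:
    """Generate whole-image train/validation/test splits of synthetic scenes.

    The split is at the image level (never by crop); per-image seeds derive
    from ``seed``.
    """
    counts = split_counts(n_images, fractions)
    rng = np.random.default_rng(seed)
    image_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    scenes = [
        generate_scene(dataclasses.replace(template, seed=int(s))) for s in image_seeds
    ]
    out: dict[str, list[tuple[MicroscopyImage, GroundTruth]]] = {}
    start = 0
    for name, k in zip(("train", "val", "test"), counts):
        out[name] = scenes[start : start + k]
        start += k
    return out


def crops_with_labels(
    pairs: Sequence[tuple[MicroscopyImage, GroundTruth]], crop_size: int = 50
):
    """Extract ground-truth-centered crops and binary labels (1 = osteoclast)."""
    from .segmentation import extract_crops

    crops, labels = [], []
    for image, truth in pairs:
        centers = [(0, c.center[0], c.center[1]) for c in truth.cells]
        crops.extend(extract_crops(image, centers, crop_size))
        labels.extend(1 if c.label == "osteoclast" else 0 for c in truth.cells)
    return crops, np.asarray(labels, dtype=np.int64)


def write_scene(
    out_dir: str | Path,
    name: str,
    image: MicroscopyImage,
    truth: GroundTruth,
    config: SceneConfig,
) -> None:
    """Write a scene as PNG + ground-truth centers CSV + config JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_image(image, out_dir / f"{name}.png")
    write_centers_csv(truth.annotations(f"{name}.png"), out_dir / f"{name}.centers.csv")
    (out_dir / f"{name}.config.json").write_text(config.to_json())
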