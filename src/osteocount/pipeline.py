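"""End-to-end counting: image -> segments -> crops -> predictions -> counts.

Also the per-well normalization (mean per-image osteoclast count scaled by
well area / single-image field area) and the declarative run driver used by
the command-line interface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .classify import (
    TrainedClassifier,
    TrainingConfig,
    load_checkpoint,
    predict_crops,
    save_checkpoint,
    train_classifier,
)
from .errors import ConfigError, ValidationError
from .imaging import MicroscopyImage, WellGeometry, write_overlay
from .segmentation import SegmentationConfig, segment_image
from .synth import SceneConfig, crops_with_labels, generate_dataset, write_scene

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CellRecord:
    segment_id: int
    center: tuple[int, int]
    area: int
    p_oc: float
    label: int


@dataclasses.dataclass
class ImageCountResult:
    source_id: str
    n_segments: int
    n_osteoclasts: int
    n_non_osteoclasts: int
    cells: list[CellRecord]

    def __post_init__(self) -> None:
        if self.n_osteoclasts + self.n_non_osteoclasts != self.n_segments:
            raise ValidationError("per-class counts must sum to the segment count")


@dataclasses.dataclass
class WellCountResult:
    mean_per_image: float
    per_well: float
    geometry: WellGeometry


def count_image(
    image: MicroscopyImage,
    classifier: TrainedClassifier,
    seg_config: SegmentationConfig | None = None,
    overlay_path: str | Path | None = None,
) -> ImageCountResult:
    """Segment, classify and tally osteoclasts in one image."""
    segments, crops = segment_image(image, seg_config)
    predictions = predict_crops(crops, classifier)
    areas = segments.areas()
    cells = [
        CellRecord(
            segment_id=crop.segment_id,
            center=crop.center,
            area=areas.get(crop.segment_id, 0),
            p_oc=pred.p_oc,
            label=pred.label,
        )
        for crop, pred in zip(crops, predictions)
    ]
    n_oc = sum(1 for c in cells if c.label == 1)
    result = ImageCountResult(
        source_id=image.source_id,
        n_segments=len(cells),
        n_osteoclasts=n_oc,
        n_non_osteoclasts=len(cells) - n_oc,
        cells=cells,
    )
    if overlay_path is not None:
        labels = {c.segment_id: ("osteoclast" if c.label == 1 else "non_osteoclast")
                  for c in cells}
        write_overlay(image, segments, labels, overlay_path)
    logger.info(
        "%s: %d cells, %d osteoclasts", image.source_id, len(cells), n_oc
    )
    return result


def count_well(
    image_results: Sequence[ImageCountResult],
    geometry: WellGeometry | None = None,
) -> WellCountResult:
    """Mean per-image osteoclast count scaled to the whole well surface."""
    if not image_results:
        raise ValidationError("count_well requires at least one image result")
    geometry = geometry or WellGeometry()
    mean = float(np.mean([r.n_osteoclasts for r in image_results]))
    per_well = mean * geometry.well_area_mm2 / geometry.image_area_mm2
    return WellCountResult(mean_per_image=mean, per_well=per_well, geometry=geometry)


# ---------------------------------------------------------------------------
# Declarative runs

_KNOWN_STAGES = ("synth", "train", "count", "evaluate")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def run_config(config_path: str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the stages declared in a YAML run config.

    Recognized top-level keys: ``seed``, ``out_dir`` and any of the stages
    ``synth`` (generate a dataset), ``train`` (fit the classifier on the
    synthetic training split), ``count`` (run the counting pipeline on the
    test split), ``evaluate`` (score counts against ground truth). Artifacts
    and a manifest are written under the run directory.
    """
    config_path = Path(config_path)
    raw = yaml.safe_load(config_path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a mapping")
    unknown = set(raw) - set(_KNOWN_STAGES) - {"seed", "out_dir"}
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    seed = int(raw.get("seed", 0))
    run_dir = Path(out_dir or raw.get("out_dir", config_path.parent / "run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_file": str(config_path),
        "config_hash": _config_hash(raw),
        "seed": seed,
        "version": __version__,
        "stages": {},
    }

    splits = None
    classifier: TrainedClassifier | None = None

    if "synth" in raw:
        synth_cfg = dict(raw["synth"] or {})
        n_images = int(synth_cfg.pop("n_images", 12))
        fractions = tuple(synth_cfg.pop("fractions", (0.651, 0.164, 0.185)))
        template = SceneConfig(**synth_cfg)
        splits = generate_dataset(n_images, template, fractions, seed=seed)
        scene_dir = run_dir / "scenes"
        for split, pairs in splits.items():
            for i, (image, truth) in enumerate(pairs):
                write_scene(scene_dir / split, f"scene{i:03d}", image, truth, template)
        manifest["stages"]["synth"] = {
            "n_images": n_images,
            "split_sizes": {k: len(v) for k, v in splits.items()},
        }

    if "train" in raw:
        if splits is None:
            raise ConfigError("train stage requires a synth stage in the same run")
        train_cfg = TrainingConfig(**{"seed": seed, **(raw["train"] or {})})
        train_crops, train_labels = crops_with_labels(splits["train"])
        val_crops, val_labels = crops_with_labels(splits["val"])
        classifier, history = train_classifier(
            train_crops, train_labels, val_crops, val_labels, train_cfg
        )
        save_checkpoint(classifier, run_dir / "model.ckpt.npz")
        manifest["stages"]["train"] = {
            "n_train_crops": len(train_crops),
            "best_val_accuracy": history["best_val_accuracy"],
            "selected_epoch": history["selected_epoch"],
        }

    results: list[ImageCountResult] = []
    if "count" in raw:
        count_cfg = dict(raw["count"] or {})
        model_path = count_cfg.pop("model", None)
        if classifier is None:
            if model_path is None:
                raise ConfigError("count stage needs a trained model or a model path")
            classifier = load_checkpoint(model_path)
        if splits is None:
            raise ConfigError("count stage requires a synth stage in the same run")
        seg_config = SegmentationConfig(**count_cfg.pop("segmentation", {}))
        geometry = WellGeometry(**count_cfg.pop("well", {}))
        for i, (image, _) in enumerate(splits["test"]):
            results.append(
                count_image(
                    image, classifier, seg_config,
                    overlay_path=run_dir / f"overlay{i:03d}.png",
                )
            )
        well = count_well(results, geometry)
        manifest["stages"]["count"] = {
            "per_image": [r.n_osteoclasts for r in results],
            "mean_per_image": well.mean_per_image,
            "per_well": well.per_well,
        }

    if "evaluate" in raw:
        if not results or splits is None:
            raise ConfigError("evaluate stage requires a count stage in the same run")
        truth_counts = [len(t.osteoclasts) for _, t in splits["test"]]
        auto_counts = [r.n_osteoclasts for r in results]
        exact = sum(int(a == b) for a, b in zip(truth_counts, auto_counts))
        manifest["stages"]["evaluate"] = {
            "true_counts": truth_counts,
            "auto_counts": auto_counts,
            "exact_count_images": exact,
        }

    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
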