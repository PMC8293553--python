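"""Batch processing, configuration and the manual-correction workflow.

A :class:`PipelineConfig` bundles the full parameter set of the counting
macro — scale calibration, crop rectangle, one color band per particle
class, and the physical size filter — and is loaded from a single YAML/JSON
file so a whole experiment runs off one declared configuration.  The
reference configuration (the values used throughout the original screen) is

.. code-block:: yaml

    scale: {line_px: 1100, known_mm: 50}      # 22 px/mm
    crop: [400, 426, 2634, 1824]
    bands:
      tubercle: {h: [0, 55], s: [102, 255], b: [95, 255]}
    size_mm2: [0.05, 20]

:func:`process_directory` is the automatic macro: it walks an image
directory in lexicographic filename order, counts tubercles per image,
writes one particle table per image plus a summary table, and skips (and
logs) unreadable files rather than aborting an unattended batch run.

:func:`apply_corrections` is the semiautomatic workflow: point-based
deletion of false particles and addition of missed tubercles, read from a
corrections CSV.  Added particles are count corrections only — they carry a
zero measured area and the class ``manual_added``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .imaging import (
    CropRect,
    HSBRange,
    ImageFormatError,
    Particle,
    ParticleSet,
    ScaleCalibration,
    SizeRange,
    calibrate_scale,
    count_tubercles,
)

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "CorrectionSet",
    "ProcessResult",
    "SUMMARY_COLUMNS",
    "CORRECTIONS_COLUMNS",
    "load_config",
    "read_image",
    "process_directory",
    "apply_corrections",
    "load_corrections",
    "summarize",
]

logger = logging.getLogger("rhizosun")

SUMMARY_COLUMNS = ["image_id", "tubercle_count", "necrotic_count", "corrected"]
CORRECTIONS_COLUMNS = ["image_id", "action", "x_mm", "y_mm"]
IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

#: radius within which a delete point falling outside every bounding box is
#: still snapped to the nearest particle centroid
DELETE_SNAP_MM = 2.0


class ConfigError(ValueError):
    """Raised for a missing or invalid configuration key; names the key."""


@dataclass(frozen=True)
class PipelineConfig:
    """Complete parameter set of the counting pipeline."""

    calibration: ScaleCalibration
    crop: CropRect
    bands: dict[str, HSBRange]
    size: SizeRange
    input_glob: str = "*"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if "tubercle" not in self.bands:
            raise ConfigError("bands.tubercle: a 'tubercle' color band is required")

    def to_dict(self) -> dict:
        return {
            "scale": {"px_per_mm": self.calibration.px_per_mm},
            "crop": list(self.crop.as_tuple()),
            "bands": {
                name: {
                    "h": [b.h_min, b.h_max],
                    "s": [b.s_min, b.s_max],
                    "b": [b.b_min, b.b_max],
                }
                for name, b in self.bands.items()
            },
            "size_mm2": [self.size.min_mm2, self.size.max_mm2],
            "input_glob": self.input_glob,
        }


def _require(mapping: dict, key: str, context: str) -> object:
    if key not in mapping:
        raise ConfigError(f"{context}{key}: required key is missing")
    return mapping[key]


def _parse_config(data: dict) -> PipelineConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root: expected a mapping")
    scale = _require(data, "scale", "")
    if "px_per_mm" in scale:
        calibration = ScaleCalibration(float(scale["px_per_mm"]))
    elif "line_px" in scale and "known_mm" in scale:
        calibration = calibrate_scale(float(scale["line_px"]), float(scale["known_mm"]))
    else:
        raise ConfigError(
            "scale: expected either {px_per_mm} or {line_px, known_mm}"
        )
    crop_vals = _require(data, "crop", "")
    if not (isinstance(crop_vals, (list, tuple)) and len(crop_vals) == 4):
        raise ConfigError("crop: expected [x, y, width, height]")
    crop = CropRect(*(int(v) for v in crop_vals))
    bands_raw = _require(data, "bands", "")
    if not isinstance(bands_raw, dict) or not bands_raw:
        raise ConfigError("bands: expected a mapping of class name to h/s/b ranges")
    bands = {}
    for name, spec in bands_raw.items():
        for ch in ("h", "s", "b"):
            if ch not in spec or len(spec[ch]) != 2:
                raise ConfigError(f"bands.{name}.{ch}: expected a [min, max] pair")
        bands[name] = HSBRange(
            int(spec["h"][0]), int(spec["h"][1]),
            int(spec["s"][0]), int(spec["s"][1]),
            int(spec["b"][0]), int(spec["b"][1]),
        )
    size_vals = _require(data, "size_mm2", "")
    if not (isinstance(size_vals, (list, tuple)) and len(size_vals) == 2):
        raise ConfigError("size_mm2: expected [min, max]")
    size = SizeRange(float(size_vals[0]), float(size_vals[1]))
    try:
        return PipelineConfig(
            calibration=calibration,
            crop=crop,
            bands=bands,
            size=size,
            input_glob=str(data.get("input_glob", "*")),
            output_dir=data.get("output_dir"),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    try:
        return _parse_config(data)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def read_image(path: str | Path, *, drop_alpha: bool = False) -> np.ndarray:
    """Read an 8-bit RGB image; grayscale is rejected, RGBA only with
    ``drop_alpha=True``."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        if drop_alpha:
            arr = arr[..., :3]
        else:
            raise ImageFormatError(
                f"{path}: RGBA input; pass drop_alpha=True to discard the alpha channel"
            )
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise ImageFormatError(
            f"{path}: expected an 8-bit RGB image, got shape {arr.shape} dtype {arr.dtype}"
        )
    return arr


@dataclass
class ProcessResult:
    """Outcome of a batch run: summary table, per-image particles, failures."""

    summary: pd.DataFrame
    particle_sets: dict[str, ParticleSet]
    failures: list[tuple[str, str]] = field(default_factory=list)


def _discover_images(input_dir: Path, pattern: str) -> list[Path]:
    files = [
        p
        for p in sorted(input_dir.glob(pattern), key=lambda p: p.name)
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    ]
    stems: dict[str, Path] = {}
    for p in files:
        if p.stem in stems:
            raise ValueError(
                f"duplicate image id {p.stem!r}: {stems[p.stem]} and {p}"
            )
        stems[p.stem] = p
    return files


def process_directory(
    config: PipelineConfig,
    input_dir: str | Path,
    output_dir: str | Path | None = None,
    *,
    drop_alpha: bool = False,
) -> ProcessResult:
    """Count tubercles in every image of a directory (the automatic macro).

    Images are processed in lexicographic filename order; the image id is
    the filename stem.  When *output_dir* is given, one particle CSV per
    image and a ``summary.csv`` are written there.  Unreadable files are
    logged and reported in ``failures`` without aborting the batch.
    """
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory does not exist: {input_dir}")
    out = Path(output_dir if output_dir is not None else (config.output_dir or "."))
    files = _discover_images(input_dir, config.input_glob)
    if not files:
        logger.warning("no images matched %r in %s", config.input_glob, input_dir)
    particle_sets: dict[str, ParticleSet] = {}
    failures: list[tuple[str, str]] = []
    for path in files:
        try:
            image = read_image(path, drop_alpha=drop_alpha)
            particle_sets[path.stem] = count_tubercles(
                image, config, image_id=path.stem
            )
        except Exception as exc:  # noqa: BLE001 - skip-and-log batch policy
            logger.error("failed to process %s: %s", path, exc)
            failures.append((path.name, str(exc)))
    summary = summarize(list(particle_sets.values()))
    if output_dir is not None or config.output_dir is not None:
        out.mkdir(parents=True, exist_ok=True)
        for image_id, ps in particle_sets.items():
            ps.to_dataframe().to_csv(out / f"{image_id}_particles.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
    return ProcessResult(summary=summary, particle_sets=particle_sets, failures=failures)


def summarize(
    particle_sets: list[ParticleSet], corrected: set[str] | None = None
) -> pd.DataFrame:
    """Build the summary table: one row per image, sorted by image id.

    ``tubercle_count`` counts classes tubercle + manual_added;
    ``necrotic_count`` reports the optional second band separately.
    """
    corrected = corrected or set()
    ids = [ps.image_id for ps in particle_sets]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate image ids in summary: {sorted(dupes)}")
    rows = [
        {
            "image_id": ps.image_id,
            "tubercle_count": ps.tubercle_count,
            "necrotic_count": ps.necrotic_count,
            "corrected": ps.image_id in corrected,
        }
        for ps in sorted(particle_sets, key=lambda ps: ps.image_id)
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


@dataclass
class CorrectionSet:
    """Manual corrections for one image (the semiautomatic workflow)."""

    image_id: str
    add_points: list[tuple[float, float]] = field(default_factory=list)
    delete_points: list[tuple[float, float]] = field(default_factory=list)
    crop_override: CropRect | None = None
    calibration_override: ScaleCalibration | None = None

    def __post_init__(self) -> None:
        for x, y in [*self.add_points, *self.delete_points]:
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"{self.image_id}: non-finite correction point ({x}, {y})")

    def inverse(self) -> "CorrectionSet":
        """Swap adds and deletes; applying a set then its inverse restores
        the original count."""
        return CorrectionSet(
            image_id=self.image_id,
            add_points=list(self.delete_points),
            delete_points=list(self.add_points),
        )


def load_corrections(path: str | Path) -> dict[str, CorrectionSet]:
    """Read a corrections CSV (image_id, action, x_mm, y_mm; action add|delete)."""
    df = pd.read_csv(path)
    missing = [c for c in CORRECTIONS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: corrections CSV missing columns {missing}")
    out: dict[str, CorrectionSet] = {}
    for row in df.to_dict("records"):
        image_id = str(row["image_id"])
        cs = out.setdefault(image_id, CorrectionSet(image_id=image_id))
        action = str(row["action"]).strip().lower()
        point = (float(row["x_mm"]), float(row["y_mm"]))
        if action == "add":
            cs.add_points.append(point)
        elif action == "delete":
            cs.delete_points.append(point)
        else:
            raise ValueError(f"{path}: unknown action {row['action']!r} for {image_id}")
    return out


def apply_corrections(
    particles: ParticleSet,
    corrections: CorrectionSet,
    calibration: ScaleCalibration | None = None,
) -> ParticleSet:
    """Apply point deletions and additions to one image's particle set.

    Each delete point removes at most one particle: the one whose bounding
    box contains the point (nearest centroid wins among several), falling
    back to the nearest centroid within 2 mm; a point matching nothing is a
    logged warning, not an error.  Each add point appends a ``manual_added``
    particle with zero measured area — a count correction, not a
    segmentation edit.  *calibration* converts mm points to pixels for the
    bounding-box test; without it only the centroid rule applies.
    """
    if corrections.image_id != particles.image_id:
        raise ValueError(
            f"corrections are for {corrections.image_id!r}, "
            f"particles are for {particles.image_id!r}"
        )
    remaining = list(particles.particles)
    for x_mm, y_mm in corrections.delete_points:
        target_idx: int | None = None
        if calibration is not None:
            x_px, y_px = calibration.mm_to_px(x_mm), calibration.mm_to_px(y_mm)
            inside = [
                (np.hypot(p.centroid_x_mm - x_mm, p.centroid_y_mm - y_mm), k)
                for k, p in enumerate(remaining)
                if p.bbox.x <= x_px < p.bbox.x + p.bbox.width
                and p.bbox.y <= y_px < p.bbox.y + p.bbox.height
            ]
            if inside:
                target_idx = min(inside)[1]
        if target_idx is None:
            near = [
                (np.hypot(p.centroid_x_mm - x_mm, p.centroid_y_mm - y_mm), k)
                for k, p in enumerate(remaining)
            ]
            near = [t for t in near if t[0] <= DELETE_SNAP_MM]
            if near:
                target_idx = min(near)[1]
        if target_idx is None:
            logger.warning(
                "%s: delete point (%.2f, %.2f) mm matched no particle",
                particles.image_id, x_mm, y_mm,
            )
            continue
        remaining.pop(target_idx)
    next_id = max((p.id for p in remaining), default=0)
    for x_mm, y_mm in corrections.add_points:
        next_id += 1
        if calibration is not None:
            bx, by = int(calibration.mm_to_px(x_mm)), int(calibration.mm_to_px(y_mm))
        else:
            bx = by = 0
        remaining.append(
            Particle(
                id=next_id,
                area_mm2=0.0,
                area_px=0,
                centroid_x_mm=float(x_mm),
                centroid_y_mm=float(y_mm),
                centroid_x_px=float("nan"),
                centroid_y_px=float("nan"),
                bbox=CropRect(max(bx, 0), max(by, 0), 1, 1),
                class_label="manual_added",
            )
        )
    return ParticleSet(image_id=particles.image_id, particles=remaining)
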