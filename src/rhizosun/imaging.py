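"""Core image operations for tubercle counting.

The detection pipeline mirrors the classic particle-analysis recipe used for
rhizotron phenotyping of *Orobanche cumana* tubercles on sunflower roots:

1. calibrate a pixel-to-millimeter scale from a ruler in the image,
2. crop to the region of interest,
3. convert RGB to 8-bit HSB and keep pixels inside a color band that isolates
   the orange tubercles from white roots and paper,
4. fill holes in the binary mask,
5. extract connected components and keep those within a physical size range,
   reporting area (mm²) and center of mass.

All geometry uses 0-based pixel indices with the origin at the top-left
corner, x rightward and y downward.  Millimeter coordinates are pixel
coordinates divided by the calibration factor, relative to the crop origin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as _skcolor
from skimage import measure as _skmeasure

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import PipelineConfig

__all__ = [
    "CalibrationError",
    "CropBoundsError",
    "ImageFormatError",
    "ScaleCalibration",
    "CropRect",
    "HSBRange",
    "SizeRange",
    "Particle",
    "ParticleSet",
    "PARTICLE_TABLE_COLUMNS",
    "calibrate_scale",
    "crop_image",
    "rgb_to_hsb",
    "threshold_hsb",
    "fill_holes",
    "find_particles",
    "count_tubercles",
]


class CalibrationError(ValueError):
    """Raised for a non-positive scale calibration input."""


class CropBoundsError(ValueError):
    """Raised when a crop rectangle does not fit inside the image."""


class ImageFormatError(ValueError):
    """Raised for images that are not 8-bit 3-channel RGB."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-millimeter conversion factor.

    Parameters
    ----------
    px_per_mm:
        Number of pixels per millimeter, strictly positive.  A ruler imaged
        alongside the rhizotron typically gives e.g. 1100 px for 50 mm,
        i.e. 22 px/mm.
    """

    px_per_mm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.px_per_mm) or self.px_per_mm <= 0:
            raise CalibrationError(
                f"px_per_mm must be a positive finite number, got {self.px_per_mm!r}"
            )

    @property
    def pixel_area_mm2(self) -> float:
        """Area of one pixel in mm²."""
        return (1.0 / self.px_per_mm) ** 2

    def px_to_mm(self, value_px: float) -> float:
        return value_px / self.px_per_mm

    def mm_to_px(self, value_mm: float) -> float:
        return value_mm * self.px_per_mm


def calibrate_scale(line_length_px: float, known_length_mm: float) -> ScaleCalibration:
    """Derive the scale from a ruler line of known physical length.

    ``calibrate_scale(1100, 50)`` gives 22 px/mm.
    """
    if line_length_px <= 0 or known_length_mm <= 0:
        raise CalibrationError(
            "line_length_px and known_length_mm must both be > 0, got "
            f"{line_length_px!r} px and {known_length_mm!r} mm"
        )
    return ScaleCalibration(px_per_mm=float(line_length_px) / float(known_length_mm))


@dataclass(frozen=True)
class CropRect:
    """Axis-aligned crop rectangle, 0-based, top-left origin."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"crop width/height must be > 0, got {self.width}x{self.height}")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"crop origin must be non-negative, got ({self.x}, {self.y})")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x, self.y, self.width, self.height)


@dataclass(frozen=True)
class HSBRange:
    """Inclusive 8-bit hue/saturation/brightness band.

    Hue may wrap: ``h_min > h_max`` means the band passes through 255 → 0,
    which keeps red-centered bands expressible.
    """

    h_min: int
    h_max: int
    s_min: int
    s_max: int
    b_min: int
    b_max: int

    def __post_init__(self) -> None:
        for name in ("h_min", "h_max", "s_min", "s_max", "b_min", "b_max"):
            v = getattr(self, name)
            if not (0 <= int(v) <= 255):
                raise ValueError(f"{name} must be in [0, 255], got {v}")
        if self.s_min > self.s_max:
            raise ValueError(f"s_min > s_max ({self.s_min} > {self.s_max})")
        if self.b_min > self.b_max:
            raise ValueError(f"b_min > b_max ({self.b_min} > {self.b_max})")

    def contains(self, h: np.ndarray, s: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Vectorized membership test; returns a boolean array."""
        h = np.asarray(h)
        if self.h_min <= self.h_max:
            h_ok = (h >= self.h_min) & (h <= self.h_max)
        else:  # wraparound band
            h_ok = (h >= self.h_min) | (h <= self.h_max)
        s_ok = (np.asarray(s) >= self.s_min) & (np.asarray(s) <= self.s_max)
        b_ok = (np.asarray(b) >= self.b_min) & (np.asarray(b) <= self.b_max)
        return h_ok & s_ok & b_ok


#: The published macro band isolating orange tubercles.
DEFAULT_TUBERCLE_BAND = HSBRange(0, 55, 102, 255, 95, 255)


@dataclass(frozen=True)
class SizeRange:
    """Inclusive particle-area filter in mm²."""

    min_mm2: float
    max_mm2: float

    def __post_init__(self) -> None:
        if not (0 <= self.min_mm2 < self.max_mm2):
            raise ValueError(
                f"size range requires 0 <= min < max, got [{self.min_mm2}, {self.max_mm2}]"
            )

    def contains(self, area_mm2: float) -> bool:
        return self.min_mm2 <= area_mm2 <= self.max_mm2


#: The published size filter: particles between 0.05 and 20 mm².
DEFAULT_SIZE_RANGE = SizeRange(0.05, 20.0)


@dataclass(frozen=True)
class Particle:
    """One detected particle (putative tubercle).

    Centroids are the binary (unweighted) center of mass, reported both in mm
    relative to the crop origin and in original-image pixel coordinates.
    """

    id: int
    area_mm2: float
    area_px: int
    centroid_x_mm: float
    centroid_y_mm: float
    centroid_x_px: float
    centroid_y_px: float
    bbox: CropRect
    class_label: str = "tubercle"


PARTICLE_TABLE_COLUMNS = [
    "particle_id",
    "class",
    "area_mm2",
    "area_px",
    "centroid_x_mm",
    "centroid_y_mm",
    "bbox_x",
    "bbox_y",
    "bbox_w",
    "bbox_h",
]


@dataclass
class ParticleSet:
    """Per-image collection of detected particles."""

    image_id: str
    particles: list[Particle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    def count(self, *class_labels: str) -> int:
        if not class_labels:
            return len(self.particles)
        return sum(1 for p in self.particles if p.class_label in class_labels)

    @property
    def tubercle_count(self) -> int:
        """Tubercles counted for the summary: detected plus manually added."""
        return self.count("tubercle", "manual_added")

    @property
    def necrotic_count(self) -> int:
        return self.count("necrotic")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "particle_id": p.id,
                "class": p.class_label,
                "area_mm2": round(p.area_mm2, 6),
                "area_px": p.area_px,
                "centroid_x_mm": round(p.centroid_x_mm, 6),
                "centroid_y_mm": round(p.centroid_y_mm, 6),
                "bbox_x": p.bbox.x,
                "bbox_y": p.bbox.y,
                "bbox_w": p.bbox.width,
                "bbox_h": p.bbox.height,
            }
            for p in self.particles
        ]
        return pd.DataFrame(rows, columns=PARTICLE_TABLE_COLUMNS)

    @classmethod
    def from_dataframe(cls, image_id: str, df: pd.DataFrame) -> "ParticleSet":
        # the particle table does not store pixel centroids (mm is canonical);
        # they are reported as nan on round-trip
        particles = []
        for row in df.to_dict("records"):
            particles.append(
                Particle(
                    id=int(row["particle_id"]),
                    area_mm2=float(row["area_mm2"]),
                    area_px=int(row["area_px"]),
                    centroid_x_mm=float(row["centroid_x_mm"]),
                    centroid_y_mm=float(row["centroid_y_mm"]),
                    centroid_x_px=float("nan"),
                    centroid_y_px=float("nan"),
                    bbox=CropRect(
                        int(row["bbox_x"]),
                        int(row["bbox_y"]),
                        int(row["bbox_w"]),
                        int(row["bbox_h"]),
                    ),
                    class_label=str(row["class"]),
                )
            )
        return cls(image_id=image_id, particles=particles)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        shape = getattr(image, "shape", None)
        raise ImageFormatError(
            f"expected an 8-bit RGB image with shape (H, W, 3), got shape {shape}; "
            "grayscale and RGBA inputs are rejected (drop the alpha channel explicitly)"
        )
    return image


def crop_image(image: np.ndarray, rect: CropRect) -> np.ndarray:
    """Return the sub-image selected by *rect*.

    Output pixel (0, 0) is input pixel (rect.x, rect.y); output dimensions are
    (rect.width, rect.height).
    """
    image = np.asarray(image)
    h, w = image.shape[0], image.shape[1]
    if rect.x + rect.width > w:
        raise CropBoundsError(
            f"crop right edge {rect.x + rect.width} exceeds image width {w}"
        )
    if rect.y + rect.height > h:
        raise CropBoundsError(
            f"crop bottom edge {rect.y + rect.height} exceeds image height {h}"
        )
    return image[rect.y : rect.y + rect.height, rect.x : rect.x + rect.width]


def rgb_to_hsb(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit HSB channels.

    The standard hexcone conversion gives hue in degrees [0, 360) and
    saturation/brightness in [0, 1]; all three are mapped to [0, 255] bytes
    (hue = round(deg·255/360)).  Achromatic pixels have hue 0.
    """
    image = _check_rgb(image)
    # float32 keeps the conversion well within the ±1-byte rounding contract
    hsv = _skcolor.rgb2hsv(np.ascontiguousarray(image, dtype=np.float32) / np.float32(255.0))
    return np.rint(hsv * 255.0).astype(np.uint8)


def threshold_hsb(hsb_image: np.ndarray, band: HSBRange) -> np.ndarray:
    """Boolean foreground mask: pixels whose H, S and B all fall in *band*."""
    hsb_image = _check_rgb(hsb_image)
    return band.contains(hsb_image[..., 0], hsb_image[..., 1], hsb_image[..., 2])


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not connected (4-connectivity) to the border."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def _label_raster_order(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected labeling with labels renumbered 1..n in raster order of
    each component's first pixel."""
    labels, n = _skmeasure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return labels, 0
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier raster indices win
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable") + 1
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[order] = np.arange(1, n + 1)
    return remap[labels], n


def find_particles(
    mask: np.ndarray,
    cal: ScaleCalibration,
    size: SizeRange,
    *,
    class_label: str = "tubercle",
    crop_origin: tuple[int, int] = (0, 0),
) -> list[Particle]:
    """Extract 8-connected components within the physical size range.

    Components are measured (area, binary center of mass) and kept when their
    area in mm² lies inclusively within *size*.  Ids are assigned in raster
    order of each component's first (topmost, then leftmost) pixel; ids count
    only the particles that pass the size filter.

    *crop_origin* = (x, y) offset of the mask inside the original image; it
    shifts the reported pixel centroids (mm centroids stay crop-relative).
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = _label_raster_order(mask)
    particles: list[Particle] = []
    if n == 0:
        return particles
    ox, oy = crop_origin
    next_id = 1
    for region in sorted(_skmeasure.regionprops(labels), key=lambda r: r.label):
        area_px = int(region.area)
        area_mm2 = area_px * cal.pixel_area_mm2
        if not size.contains(area_mm2):
            continue
        cy, cx = region.centroid  # (row, col) = (y, x)
        minr, minc, maxr, maxc = region.bbox
        particles.append(
            Particle(
                id=next_id,
                area_mm2=area_mm2,
                area_px=area_px,
                centroid_x_mm=cal.px_to_mm(cx),
                centroid_y_mm=cal.px_to_mm(cy),
                centroid_x_px=cx + ox,
                centroid_y_px=cy + oy,
                bbox=CropRect(minc, minr, maxc - minc, maxr - minr),
                class_label=class_label,
            )
        )
        next_id += 1
    return particles


def count_tubercles(
    image: np.ndarray,
    config: "PipelineConfig",
    *,
    image_id: str = "image",
) -> ParticleSet:
    """Run the full per-image pipeline: crop → HSB → threshold → fill → measure.

    One pass is made per configured color band (the default configuration has
    a single "tubercle" band; an optional "necrotic" band catches browned
    tubercles that fall below the brightness cut of the main band).  Particle
    ids are unique across bands.
    """
    try:
        cropped = crop_image(_check_rgb(image), config.crop)
    except (CropBoundsError, ImageFormatError) as exc:
        raise type(exc)(f"{image_id}: {exc}") from exc
    hsb = rgb_to_hsb(cropped)
    particles: list[Particle] = []
    for label in sorted(config.bands, key=lambda k: (k != "tubercle", k)):
        band = config.bands[label]
        mask = fill_holes(threshold_hsb(hsb, band))
        found = find_particles(
            mask,
            config.calibration,
            config.size,
            class_label=label,
            crop_origin=(config.crop.x, config.crop.y),
        )
        offset = len(particles)
        particles.extend(dataclasses.replace(p, id=p.id + offset) for p in found)
    return ParticleSet(image_id=image_id, particles=particles)
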