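"""Seeded generator of rhizotron-like root-system images with ground truth.

The generator emulates the imaging conditions of a rhizotron screen for
*Orobanche cumana* tubercles on sunflower roots: a near-white glass-fiber
paper background, white low-saturation roots, orange tubercles whose color
sits inside the standard detection band, and the documented confounds —

* **pale** tubercles whose saturation falls below the band (missed),
* **necrotic** (browned) tubercles whose brightness falls below the band
  (missed),
* **touching clusters** of tubercles that merge into one particle,
* **rockwool speckles and a stem-base blob** at the top of the image whose
  color passes the band (false positives; never part of the ground truth).

Every tubercle of every class is recorded in the ground truth with its
center (mm), equivalent radius (mm) and class, so detection recall and
precision can be measured exactly.

Color model (8-bit HSB).  Tubercles draw hue ~ U(5, 40), saturation
~ U(150, 255), brightness ~ U(110, 240) — inside the band 0–55 / 102–255 /
95–255 with margin on every channel.  Pale tubercles keep the tubercle hue
and brightness but draw saturation ~ U(30, 95), below the 102 cut.  Necrotic
tubercles draw hue ~ U(8, 30) and brightness ~ U(30, 90), below the 95 cut;
they are rendered with a dark rim (brightness ≤ 45) so that the anti-aliased
blend from tubercle to background never passes through an in-band color —
without the rim, a dark saturated core blended toward white crosses a thin
ring of moderate saturation and brightness that the band would accept.

Determinism: one `numpy` generator seeded from ``SceneParams.seed``; batch
generation derives one child seed per image from (master seed, image index),
so adding images to a design never perturbs earlier ones.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .evaluation import GroundTruth, TRUTH_COLUMNS

__all__ = [
    "SceneParams",
    "Scenario",
    "ExperimentDesign",
    "PlacementError",
    "generate_rhizotron_image",
    "generate_experiment",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["image_id", "scenario", "true_count", "seed"]

#: y extent (px) of the rockwool / stem-base strip at the top of the canvas;
#: tubercles are kept below it so distractors never overlap real objects.
_TOP_STRIP_PX = 110
_TUBERCLE_MARGIN_PX = 40


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without overlap."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic rhizotron image.

    ``canvas_px`` defaults to (2634, 1824) — the crop size of the reference
    acquisition setup — at 22 px/mm, so pipeline configurations transfer
    unchanged.  ``cluster_frac`` is the expected fraction of tubercles that
    are members of a touching pair (both members count), ``pale_frac`` /
    ``necrotic_frac`` the per-tubercle probabilities of those classes.
    """

    canvas_px: tuple[int, int] = (2634, 1824)  # (width, height)
    px_per_mm: float = 22.0
    n_tubercles: int = 30
    radius_mm: tuple[float, float] = (0.15, 2.5)
    pale_frac: float = 0.0
    necrotic_frac: float = 0.0
    cluster_frac: float = 0.0
    rockwool_speckles: int = 0
    stem_base_blob: bool = False
    background_noise_sd: float = 2.5
    n_roots: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.canvas_px
        if w <= 0 or h <= 0:
            raise ValueError(f"canvas must be positive, got {self.canvas_px}")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        if self.n_tubercles < 0:
            raise ValueError("n_tubercles must be >= 0")
        if not (0 < self.radius_mm[0] < self.radius_mm[1]):
            raise ValueError(f"radius range invalid: {self.radius_mm}")
        for name in ("pale_frac", "necrotic_frac", "cluster_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pale_frac + self.necrotic_frac > 1.0:
            raise ValueError("pale_frac + necrotic_frac must be <= 1")


# ---------------------------------------------------------------------------
# Low-level rendering
# ---------------------------------------------------------------------------

_BG_RGB = (249.0, 247.0, 243.0)
_ROOT_RGB = (243.0, 240.0, 232.0)


def _hsb_bytes_to_rgb(h: float, s: float, b: float) -> tuple[float, float, float]:
    """8-bit HSB channel values to float RGB in [0, 255]."""
    r, g, bl = colorsys.hsv_to_rgb(h / 255.0, s / 255.0, b / 255.0)
    return (r * 255.0, g * 255.0, bl * 255.0)


def _paint_ellipse(
    img: np.ndarray,
    cx: float,
    cy: float,
    r_px: float,
    aspect: float,
    angle: float,
    rgb: tuple[float, float, float],
    *,
    feather_px: float = 1.2,
) -> None:
    """Alpha-composite a soft-edged ellipse of equivalent radius *r_px*.

    Semi-axes are r/sqrt(aspect) and r*sqrt(aspect) (area preserved at
    pi r^2).  The edge transition is centered on the nominal boundary, so the
    thresholded footprint tracks the nominal disc to sub-pixel accuracy —
    this keeps rendered areas inside the physical size filter whenever the
    nominal area is.
    """
    h, w = img.shape[:2]
    a = r_px / np.sqrt(aspect)
    b = r_px * np.sqrt(aspect)
    pad = a + feather_px + 1.5
    x0, x1 = int(max(0, np.floor(cx - pad))), int(min(w, np.ceil(cx + pad) + 1))
    y0, y1 = int(max(0, np.floor(cy - pad))), int(min(h, np.ceil(cy + pad) + 1))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    u = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    v = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    alpha = np.clip(0.5 + (1.0 - q) * r_px / feather_px, 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    patch += alpha[..., None] * (np.asarray(rgb, dtype=np.float32) - patch)


def _paint_disk_chain(
    img: np.ndarray, points: np.ndarray, half_width: float, rgb: tuple[float, float, float]
) -> None:
    """Draw a polyline as a chain of overlapping soft disks (a root)."""
    for x, y in points:
        _paint_ellipse(img, x, y, half_width, 1.0, 0.0, rgb, feather_px=1.5)


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------


def _draw_roots(img: np.ndarray, rng: np.random.Generator, params: SceneParams) -> np.ndarray:
    """Random-walk root polylines from the stem region downward.

    Returns the dense (x, y) points of all polylines; tubercles anchor on
    them.
    """
    w, h = params.canvas_px
    all_points = []
    for _ in range(max(1, params.n_roots)):
        x = rng.uniform(0.12 * w, 0.88 * w)
        y = float(_TOP_STRIP_PX)
        half_width = rng.uniform(4.0, 8.0)
        pts = []
        while y < h - 10:
            pts.append((x, y))
            y += 12.0
            x = float(np.clip(x + rng.normal(0.0, 6.0), 20, w - 20))
        pts = np.asarray(pts)
        _paint_disk_chain(img, pts, half_width, _ROOT_RGB)
        all_points.append(pts)
    return np.concatenate(all_points, axis=0)


def _sample_color(rng: np.random.Generator, cls: str) -> tuple[float, float, float]:
    if cls == "tubercle":
        hsb = (rng.uniform(5, 40), rng.uniform(150, 255), rng.uniform(110, 240))
    elif cls == "pale":
        hsb = (rng.uniform(5, 40), rng.uniform(30, 95), rng.uniform(110, 240))
    elif cls == "necrotic":
        hsb = (rng.uniform(8, 30), rng.uniform(130, 230), rng.uniform(30, 90))
    else:  # distractor: in-band, rockwool/stem tone
        hsb = (rng.uniform(10, 50), rng.uniform(120, 240), rng.uniform(100, 250))
    return _hsb_bytes_to_rgb(*hsb)


def _paint_tubercle(
    img: np.ndarray,
    rng: np.random.Generator,
    cx: float,
    cy: float,
    r_px: float,
    cls: str,
) -> None:
    aspect = rng.uniform(0.78, 1.0)
    angle = rng.uniform(0.0, np.pi)
    rgb = _sample_color(rng, cls)
    if cls == "necrotic":
        # dark rim: the edge blend runs rim <-> background, which stays out
        # of band at any mixing ratio; the core sits strictly inside
        rim = _sample_color(rng, "necrotic")
        rim = tuple(c * (rng.uniform(25, 45) / max(rim)) for c in rim)
        _paint_ellipse(img, cx, cy, r_px, aspect, angle, rim)
        core_r = max(r_px - 2.0, r_px * 0.5)
        _paint_ellipse(img, cx, cy, core_r, aspect, angle, rgb)
    else:
        _paint_ellipse(img, cx, cy, r_px, aspect, angle, rgb)


def _place_tubercles(
    rng: np.random.Generator,
    params: SceneParams,
    root_points: np.ndarray,
) -> list[dict]:
    """Choose positions, radii and classes for all tubercles.

    Non-cluster tubercles keep a clearance of 4 px between discs; cluster
    partners are placed at 0.75 × (r1 + r2) so their masks touch and merge
    into a single particle.
    """
    w, h = params.canvas_px
    lo_px = params.radius_mm[0] * params.px_per_mm
    hi_px = params.radius_mm[1] * params.px_per_mm
    placed: list[dict] = []
    classes = ["tubercle", "pale", "necrotic"]
    probs = [
        1.0 - params.pale_frac - params.necrotic_frac,
        params.pale_frac,
        params.necrotic_frac,
    ]

    def _clear(cx: float, cy: float, r: float, ignore: int | None = None) -> bool:
        # 1.14 covers the worst-case semi-major axis r/sqrt(aspect_min):
        # non-cluster ellipses must stay disjoint whatever their orientation
        for k, t in enumerate(placed):
            if k == ignore:
                continue
            if np.hypot(cx - t["cx"], cy - t["cy"]) < 1.14 * (r + t["r_px"]) + 4.0:
                return False
        return True

    for i in range(params.n_tubercles):
        r_px = rng.uniform(lo_px, hi_px)
        cls = classes[rng.choice(3, p=probs)]
        as_partner = placed and rng.random() < params.cluster_frac / 2.0
        ok = False
        for _ in range(300):
            if as_partner:
                anchor_idx = int(rng.integers(len(placed)))
                anchor = placed[anchor_idx]
                theta = rng.uniform(0, 2 * np.pi)
                d = 0.75 * (r_px + anchor["r_px"])
                cx = anchor["cx"] + d * np.cos(theta)
                cy = anchor["cy"] + d * np.sin(theta)
                if not (
                    _TOP_STRIP_PX + _TUBERCLE_MARGIN_PX + r_px < cy < h - r_px - 8
                    and r_px + 8 < cx < w - r_px - 8
                ):
                    continue
                # partner may touch its anchor but nothing else
                if _clear(cx, cy, r_px, ignore=anchor_idx):
                    ok = True
                    break
            else:
                j = rng.integers(len(root_points))
                cx = float(root_points[j, 0] + rng.normal(0.0, 5.0))
                cy = float(root_points[j, 1] + rng.normal(0.0, 5.0))
                if not (
                    _TOP_STRIP_PX + _TUBERCLE_MARGIN_PX + r_px < cy < h - r_px - 8
                    and r_px + 8 < cx < w - r_px - 8
                ):
                    continue
                if _clear(cx, cy, r_px):
                    ok = True
                    break
        if not ok and not as_partner:
            # dense scenes: root-anchored placement exhausted, fall back to
            # anywhere in the allowed region before declaring infeasibility
            y_lo = _TOP_STRIP_PX + _TUBERCLE_MARGIN_PX + r_px
            y_hi, x_hi = h - r_px - 8, w - r_px - 8
            if y_lo < y_hi and r_px + 8 < x_hi:
                for _ in range(200):
                    cx = float(rng.uniform(r_px + 8, x_hi))
                    cy = float(rng.uniform(y_lo, y_hi))
                    if _clear(cx, cy, r_px):
                        ok = True
                        break
        if not ok:
            raise PlacementError(
                f"could not place tubercle {i + 1}/{params.n_tubercles} "
                f"after bounded retries (canvas {params.canvas_px})"
            )
        placed.append({"cx": cx, "cy": cy, "r_px": r_px, "class": cls})
    return placed


def _draw_distractors(
    img: np.ndarray, rng: np.random.Generator, params: SceneParams
) -> None:
    """Rockwool speckles and stem-base blob in the top strip.

    All are inside the color band and the size filter, so each yields one
    false-positive particle; none is recorded in the ground truth.
    """
    w, _ = params.canvas_px
    lo = 0.2 * params.px_per_mm
    hi = 0.5 * params.px_per_mm
    for _ in range(params.rockwool_speckles):
        cx = rng.uniform(20, w - 20)
        cy = rng.uniform(15, _TOP_STRIP_PX - 15)
        _paint_ellipse(
            img, cx, cy, rng.uniform(lo, hi), rng.uniform(0.6, 1.0),
            rng.uniform(0, np.pi), _sample_color(rng, "distractor"),
        )
    if params.stem_base_blob:
        cx = rng.uniform(0.35 * w, 0.65 * w)
        cy = rng.uniform(30, _TOP_STRIP_PX - 25)
        _paint_ellipse(
            img, cx, cy, 1.2 * params.px_per_mm, 0.55,
            rng.uniform(0, np.pi), _sample_color(rng, "distractor"),
        )


def generate_rhizotron_image(
    params: SceneParams, *, image_id: str = "synthetic"
) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic rhizotron image and its exact ground truth.

    Returns an (H, W, 3) uint8 RGB array and a :class:`GroundTruth` whose
    rows record every tubercle (all classes) with center and equivalent
    radius in mm; distractor blobs are deliberately absent from the truth.
    Deterministic for a given ``params`` (including its seed).
    """
    rng = np.random.default_rng(params.seed)
    w, h = params.canvas_px
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = np.asarray(_BG_RGB, dtype=np.float32)
    if params.background_noise_sd > 0:
        img += rng.normal(0.0, params.background_noise_sd, size=img.shape).astype(
            np.float32
        )
    root_points = _draw_roots(img, rng, params)
    _draw_distractors(img, rng, params)
    tubercles = _place_tubercles(rng, params, root_points)
    for t in tubercles:
        _paint_tubercle(img, rng, t["cx"], t["cy"], t["r_px"], t["class"])
    rows = [
        {
            "image_id": image_id,
            "truth_id": i + 1,
            "x_mm": round(t["cx"] / params.px_per_mm, 6),
            "y_mm": round(t["cy"] / params.px_per_mm, 6),
            "radius_mm": round(t["r_px"] / params.px_per_mm, 6),
            "class": t["class"],
        }
        for i, t in enumerate(tubercles)
    ]
    truth = GroundTruth(
        image_id=image_id, table=pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    )
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), truth


# ---------------------------------------------------------------------------
# Experiment designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """One genotype-like scenario: a label, a number of rhizotron images and
    a per-image true-count distribution.

    ``counts`` kinds:

    * ``{"kind": "constant", "value": v}``
    * ``{"kind": "uniform_int", "low": a, "high": b}`` (inclusive)
    * ``{"kind": "truncnorm", "mean": m, "sd": s}`` — normal draw truncated
      at 0 and rounded to int, matching the mean ± sd phrasing of infection
      scores (e.g. susceptible ≈ 45 ± 6, tolerant < 5, resistant exactly 0).
    """

    label: str
    n_images: int
    counts: dict

    def sample(self, rng: np.random.Generator) -> int:
        kind = self.counts.get("kind")
        if kind == "constant":
            value = int(self.counts["value"])
        elif kind == "uniform_int":
            value = int(rng.integers(int(self.counts["low"]), int(self.counts["high"]) + 1))
        elif kind == "truncnorm":
            value = -1
            while value < 0:
                value = int(round(rng.normal(self.counts["mean"], self.counts["sd"])))
        else:
            raise ValueError(f"unknown count distribution kind: {kind!r}")
        if value < 0:
            raise ValueError(f"count distribution produced {value} < 0")
        return value


@dataclass(frozen=True)
class ExperimentDesign:
    scenarios: tuple[Scenario, ...]

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("design needs at least one scenario")
        for s in self.scenarios:
            if s.n_images < 1:
                raise ValueError(f"scenario {s.label!r}: n_images must be >= 1")


def _child_seed(master_seed: int, index: int) -> int:
    """Per-image seed derived from (master, index); stable under appends."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def generate_experiment(
    design: ExperimentDesign,
    base_params: SceneParams,
    out_dir: str | Path,
    *,
    seed: int | None = None,
    image_format: str = "png",
) -> pd.DataFrame:
    """Generate all images of a design into *out_dir*.

    Writes ``<image_id>.<fmt>`` per image, a pooled ``ground_truth.csv`` and
    a ``manifest.csv`` (image_id, scenario, true_count, seed).  Per-image
    counts are drawn from each scenario's distribution using the master
    seed; each image then renders from its own derived child seed.  Returns
    the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = base_params.seed if seed is None else int(seed)
    count_rng = np.random.default_rng(np.random.SeedSequence([master, 987654321]))
    manifest_rows = []
    truth_frames = []
    index = 0
    for scenario in design.scenarios:
        for i in range(scenario.n_images):
            image_id = f"{scenario.label}_{i:03d}"
            n = scenario.sample(count_rng)
            child = _child_seed(master, index)
            params = replace(base_params, n_tubercles=n, seed=child)
            img, truth = generate_rhizotron_image(params, image_id=image_id)
            iio.imwrite(out_dir / f"{image_id}.{image_format}", img)
            truth_frames.append(truth.table)
            manifest_rows.append(
                {"image_id": image_id, "scenario": scenario.label, "true_count": n, "seed": child}
            )
            index += 1
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    nonempty = [t for t in truth_frames if len(t)]
    pooled = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=TRUTH_COLUMNS)
    )
    pooled[TRUTH_COLUMNS].to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest
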