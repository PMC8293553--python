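"""Agreement between automatic detections and reference annotations.

Two levels of comparison are supported, mirroring how automatic tubercle
counts are validated against manual counts:

* **object level** — one-to-one matching of detected particles to reference
  tubercle positions by centroid distance, giving per-image true positives,
  false positives, false negatives, recall and precision;
* **count level** — Pearson correlation of per-image automatic vs reference
  counts, plus the least-squares trend line through the origin
  (slope b = Σxy / Σx²), the conventional way such counts are reported.

The visual criterion by which a human judges that a manual mark and an
automatic particle are "the same tubercle" has no published definition; the
distance-threshold rule used here (default 2 mm, about one tubercle radius)
is a stand-in and is labeled as such in every report it writes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import ParticleSet

__all__ = [
    "TRUTH_COLUMNS",
    "GroundTruth",
    "MatchResult",
    "AgreementStats",
    "match_particles",
    "agreement_stats",
    "evaluate_experiment",
    "load_ground_truth",
    "write_report",
]

TRUTH_COLUMNS = ["image_id", "truth_id", "x_mm", "y_mm", "radius_mm", "class"]

#: description embedded in reports: the matching rule is a convention
MATCH_RULE = (
    "greedy one-to-one nearest-centroid matching within tolerance_mm "
    "(stand-in for the undefined visual match criterion)"
)

DEFAULT_TOLERANCE_MM = 2.0


@dataclass
class GroundTruth:
    """Reference annotations for one image.

    ``table`` columns: image_id, truth_id, x_mm, y_mm, radius_mm, class with
    class in {tubercle, pale, necrotic}.  Coordinates share the mm frame of
    the detection pipeline (crop origin).
    """

    image_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"ground-truth table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def count(self) -> int:
        """Number of annotated tubercles (all classes)."""
        return len(self.table)


def load_ground_truth(path: str | Path) -> dict[str, GroundTruth]:
    """Read a pooled ground-truth CSV into per-image GroundTruth objects."""
    df = pd.read_csv(path)
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: ground-truth CSV missing columns {missing}")
    return {
        str(image_id): GroundTruth(image_id=str(image_id), table=sub.reset_index(drop=True))
        for image_id, sub in df.groupby("image_id", sort=True)
    }


@dataclass(frozen=True)
class MatchResult:
    """Object-level matching outcome for one image.

    recall = tp / (tp + fn) and precision = tp / (tp + fp); an undefined
    ratio (empty denominator) is reported as nan, never as a zero-division.
    """

    image_id: str
    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int, float], ...] = field(default=())

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else math.nan


def match_particles(
    auto: ParticleSet,
    truth: GroundTruth,
    tolerance_mm: float = DEFAULT_TOLERANCE_MM,
    *,
    auto_classes: Sequence[str] = ("tubercle", "manual_added"),
) -> MatchResult:
    """Greedy one-to-one matching of detections to reference positions.

    Candidate pairs within *tolerance_mm* are accepted in ascending distance
    order (ties broken by lower (auto_id, truth_id)); each detection and each
    reference point is used at most once.  Unmatched reference points are
    false negatives; unmatched detections are false positives.
    """
    if auto.image_id != truth.image_id:
        raise ValueError(
            f"image id mismatch: detections are {auto.image_id!r}, "
            f"truth is {truth.image_id!r}"
        )
    if tolerance_mm <= 0:
        raise ValueError(f"tolerance_mm must be > 0, got {tolerance_mm}")
    dets = [p for p in auto if p.class_label in auto_classes]
    n_a, n_t = len(dets), len(truth.table)
    if n_a == 0 or n_t == 0:
        return MatchResult(image_id=auto.image_id, tp=0, fp=n_a, fn=n_t)
    ax = np.array([p.centroid_x_mm for p in dets])
    ay = np.array([p.centroid_y_mm for p in dets])
    tx = truth.table["x_mm"].to_numpy(dtype=float)
    ty = truth.table["y_mm"].to_numpy(dtype=float)
    dist = np.hypot(ax[:, None] - tx[None, :], ay[:, None] - ty[None, :])
    ai, ti = np.nonzero(dist <= tolerance_mm)
    order = sorted(range(len(ai)), key=lambda k: (dist[ai[k], ti[k]], ai[k], ti[k]))
    used_a: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    truth_ids = truth.table["truth_id"].to_numpy()
    for k in order:
        i, j = int(ai[k]), int(ti[k])
        if i in used_a or j in used_t:
            continue
        used_a.add(i)
        used_t.add(j)
        pairs.append((dets[i].id, int(truth_ids[j]), float(dist[i, j])))
    tp = len(pairs)
    return MatchResult(
        image_id=auto.image_id,
        tp=tp,
        fp=n_a - tp,
        fn=n_t - tp,
        pairs=tuple(pairs),
    )


@dataclass(frozen=True)
class AgreementStats:
    """Count-level agreement: Pearson r and the trend line through origin."""

    n_images: int
    pearson_r: float
    slope_origin: float
    paired_counts: tuple[tuple[float, float], ...]


def agreement_stats(paired_counts: Iterable[tuple[float, float]]) -> AgreementStats:
    """Pearson correlation and through-origin slope of (reference, automatic).

    The slope is b = Σxy / Σx², the least-squares fit of y = b·x.  With a
    constant reference vector (zero variance) or fewer than two pairs the
    correlation is reported as nan; with Σx² = 0 the slope is nan.
    """
    pairs = [(float(x), float(y)) for x, y in paired_counts]
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    n = len(pairs)
    if n >= 2 and np.ptp(x) > 0 and np.ptp(y) > 0:
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        r = math.nan
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y) / sxx) if sxx > 0 else math.nan
    return AgreementStats(
        n_images=n, pearson_r=r, slope_origin=slope, paired_counts=tuple(pairs)
    )


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    vals = [v for v in values if not math.isnan(v)]
    if not vals:
        return math.nan, math.nan
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else 0.0
    return mean, sd


def evaluate_experiment(
    particle_sets: Mapping[str, ParticleSet] | Iterable[ParticleSet],
    truths: Mapping[str, GroundTruth] | Iterable[GroundTruth],
    tolerance_mm: float = DEFAULT_TOLERANCE_MM,
) -> dict:
    """Full benchmark report: per-image matching plus pooled count agreement.

    Every image with both detections and a ground truth contributes one
    MatchResult and one (reference count, automatic count) pair; images with
    no matching truth are excluded and listed in the report.  Recall and
    precision are averaged with the sample standard deviation across images
    (nan entries from empty denominators are excluded, with the effective n
    reported alongside).
    """
    if not isinstance(particle_sets, Mapping):
        particle_sets = {ps.image_id: ps for ps in particle_sets}
    if not isinstance(truths, Mapping):
        truths = {t.image_id: t for t in truths}
    excluded = sorted(set(particle_sets) - set(truths))
    common = sorted(set(particle_sets) & set(truths))
    per_image = {}
    paired = []
    recalls, precisions = [], []
    for image_id in common:
        ps, gt = particle_sets[image_id], truths[image_id]
        m = match_particles(ps, gt, tolerance_mm)
        per_image[image_id] = {
            "auto_count": ps.tubercle_count,
            "true_count": gt.count,
            "tp": m.tp,
            "fp": m.fp,
            "fn": m.fn,
            "recall": _round(m.recall),
            "precision": _round(m.precision),
        }
        paired.append((gt.count, ps.tubercle_count))
        recalls.append(m.recall)
        precisions.append(m.precision)
    stats = agreement_stats(paired)
    mean_r, sd_r = _mean_sd(recalls)
    mean_p, sd_p = _mean_sd(precisions)
    return {
        "tolerance_mm": tolerance_mm,
        "match_rule": MATCH_RULE,
        "n_images": len(common),
        "excluded_images": excluded,
        "per_image": per_image,
        "pooled": {
            "pearson_r": _round(stats.pearson_r),
            "slope_origin": _round(stats.slope_origin),
            "mean_recall": _round(mean_r),
            "sd_recall": _round(sd_r),
            "n_recall": sum(1 for v in recalls if not math.isnan(v)),
            "mean_precision": _round(mean_p),
            "sd_precision": _round(sd_p),
            "n_precision": sum(1 for v in precisions if not math.isnan(v)),
        },
    }


def _round(v: float, ndigits: int = 6) -> float | None:
    """Round for stable serialized reports; nan becomes None (JSON null)."""
    v = float(v)
    return None if math.isnan(v) else round(v, ndigits)


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write the evaluation report as JSON plus a paired-counts CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "evaluation_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    rows = [
        {
            "image_id": image_id,
            "reference_count": d["true_count"],
            "automatic_count": d["auto_count"],
        }
        for image_id, d in sorted(report["per_image"].items())
    ]
    pd.DataFrame(rows, columns=["image_id", "reference_count", "automatic_count"]).to_csv(
        out_dir / "paired_counts.csv", index=False
    )
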