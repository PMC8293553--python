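"""Shared fixtures: pipeline configurations and seeded synthetic benchmarks."""

from __future__ import annotations

import numpy as np
import pytest

from rhizosun import (
    DEFAULT_SIZE_RANGE,
    DEFAULT_TUBERCLE_BAND,
    CropRect,
    PipelineConfig,
    ScaleCalibration,
    SceneParams,
    count_tubercles,
    generate_rhizotron_image,
)

#: compact canvas for fast unit tests: 600 x 450 px = 27.3 x 20.5 mm at 22 px/mm
SMALL_CANVAS = (600, 450)


def make_config(canvas: tuple[int, int], px_per_mm: float = 22.0) -> PipelineConfig:
    """Reference pipeline config with a full-canvas crop."""
    return PipelineConfig(
        calibration=ScaleCalibration(px_per_mm),
        crop=CropRect(0, 0, canvas[0], canvas[1]),
        bands={"tubercle": DEFAULT_TUBERCLE_BAND},
        size=DEFAULT_SIZE_RANGE,
    )


def small_params(**kwargs) -> SceneParams:
    defaults = dict(
        canvas_px=SMALL_CANVAS,
        n_tubercles=8,
        radius_mm=(0.2, 1.2),
        n_roots=3,
        seed=0,
    )
    defaults.update(kwargs)
    return SceneParams(**defaults)


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return make_config(SMALL_CANVAS)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return make_config((2634, 1824))


@pytest.fixture(scope="session")
def confound_benchmark(default_config):
    """19 seeded full-size images with the documented confounds enabled:
    5% pale tubercles, 8% cluster members, 2 rockwool distractor blobs per
    image, true counts uniform over 10-80."""
    rng = np.random.default_rng(20201)
    results = []
    for i in range(19):
        n = int(rng.integers(10, 81))
        params = SceneParams(
            n_tubercles=n,
            pale_frac=0.05,
            cluster_frac=0.08,
            rockwool_speckles=2,
            seed=int(rng.integers(0, 2**31)),
        )
        image_id = f"rhizotron_{i:02d}"
        img, truth = generate_rhizotron_image(params, image_id=image_id)
        detections = count_tubercles(img, default_config, image_id=image_id)
        results.append((truth, detections))
    return results
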