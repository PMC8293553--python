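"""Unit and property tests for the core image operations."""

from __future__ import annotations

import colorsys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import fill_holes_by_border_flood, flood_components
from rhizosun import (
    DEFAULT_SIZE_RANGE,
    DEFAULT_TUBERCLE_BAND,
    CalibrationError,
    CropBoundsError,
    CropRect,
    HSBRange,
    ImageFormatError,
    ScaleCalibration,
    SizeRange,
    calibrate_scale,
    count_tubercles,
    crop_image,
    fill_holes,
    find_particles,
    rgb_to_hsb,
    threshold_hsb,
)
from conftest import make_config

CAL22 = ScaleCalibration(22.0)


class TestCalibration:
    @pytest.mark.parametrize(
        "line_px, known_mm, expected",
        [(1100, 50, 22.0), (100, 100, 1.0), (2200, 50, 44.0)],
    )
    def test_px_per_mm(self, line_px, known_mm, expected):
        assert calibrate_scale(line_px, known_mm).px_per_mm == pytest.approx(expected)

    def test_pixel_area(self):
        assert calibrate_scale(2200, 50).pixel_area_mm2 == pytest.approx(1 / 1936)

    @pytest.mark.parametrize("args", [(0, 50), (1100, 0), (-5, 50), (1100, -1)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(CalibrationError):
            calibrate_scale(*args)

    def test_direct_construction_validates(self):
        with pytest.raises(CalibrationError):
            ScaleCalibration(0.0)


class TestCrop:
    def test_reference_crop_dimensions(self):
        img = np.zeros((2464, 3280, 3), dtype=np.uint8)
        out = crop_image(img, CropRect(400, 426, 2634, 1824))
        assert out.shape == (1824, 2634, 3)

    def test_identity_crop(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(40, 60, 3), dtype=np.uint8)
        assert np.array_equal(crop_image(img, CropRect(0, 0, 60, 40)), img)

    def test_origin_correspondence(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(50, 50, 3), dtype=np.uint8)
        out = crop_image(img, CropRect(7, 11, 20, 25))
        assert np.array_equal(out[0, 0], img[11, 7])
        assert np.array_equal(out[-1, -1], img[11 + 24, 7 + 19])

    def test_out_of_bounds_names_edge(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        with pytest.raises(CropBoundsError, match="right edge"):
            crop_image(img, CropRect(90, 10, 20, 20))
        with pytest.raises(CropBoundsError, match="bottom edge"):
            crop_image(img, CropRect(10, 90, 20, 20))

    @pytest.mark.parametrize("rect", [(0, 0, 0, 5), (0, 0, 5, -1), (-1, 0, 5, 5)])
    def test_invalid_rect_rejected(self, rect):
        with pytest.raises(ValueError):
            CropRect(*rect)


class TestRgbToHsb:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 0, 0), (0, 255, 255)),  # pure red
            ((255, 255, 255), (0, 0, 255)),  # achromatic: hue defined 0
            ((255, 128, 0), (21, 255, 255)),  # orange: 30.1 deg -> byte 21
            ((0, 0, 0), (0, 0, 0)),
        ],
    )
    def test_reference_pixels(self, rgb, expected):
        out = rgb_to_hsb(np.array([[rgb]], dtype=np.uint8))
        assert tuple(out[0, 0]) == expected

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ImageFormatError):
            rgb_to_hsb(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ImageFormatError):
            rgb_to_hsb(np.zeros((4, 4, 4), dtype=np.uint8))

    @given(
        st.integers(0, 255), st.integers(0, 255), st.integers(0, 255)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_hexcone_oracle(self, r, g, b):
        """Channel values agree with colorsys within the 1-byte rounding."""
        out = rgb_to_hsb(np.array([[[r, g, b]]], dtype=np.uint8))[0, 0]
        h, s, v = colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)
        expect = np.array([h * 255, s * 255, v * 255])
        diff = np.abs(out.astype(float) - expect)
        diff[0] = min(diff[0], 255 - diff[0])  # hue wraps
        assert np.all(diff <= 1.0)


class TestThreshold:
    def test_band_membership(self):
        hsb = np.array(
            [[[21, 255, 255], [0, 0, 255], [120, 200, 200]]], dtype=np.uint8
        )
        mask = threshold_hsb(hsb, DEFAULT_TUBERCLE_BAND)
        assert mask.tolist() == [[True, False, False]]

    def test_inclusive_endpoints(self):
        band = HSBRange(0, 55, 102, 255, 95, 255)
        hsb = np.array([[[55, 102, 95], [56, 102, 95], [55, 101, 95]]], dtype=np.uint8)
        assert threshold_hsb(hsb, band).tolist() == [[True, False, False]]

    def test_hue_wraparound(self):
        band = HSBRange(240, 10, 0, 255, 0, 255)  # red band through 255 -> 0
        hsb = np.array([[[250, 100, 100], [5, 100, 100], [100, 100, 100]]], dtype=np.uint8)
        assert threshold_hsb(hsb, band).tolist() == [[True, True, False]]

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_widening_band_grows_mask(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        hsb = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        h0 = data.draw(st.integers(0, 255))
        h1 = data.draw(st.integers(0, 255).filter(lambda v: v >= h0))
        s0, s1 = sorted(data.draw(st.tuples(st.integers(0, 255), st.integers(0, 255))))
        b0, b1 = sorted(data.draw(st.tuples(st.integers(0, 255), st.integers(0, 255))))
        inner = HSBRange(h0, h1, s0, s1, b0, b1)
        outer = HSBRange(
            max(h0 - 10, 0), min(h1 + 10, 255),
            max(s0 - 10, 0), min(s1 + 10, 255),
            max(b0 - 10, 0), min(b1 + 10, 255),
        )
        m_in = threshold_hsb(hsb, inner)
        m_out = threshold_hsb(hsb, outer)
        assert np.all(m_out[m_in])  # superset


def _disc_mask(shape, cy, cx, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


class TestFillHoles:
    def test_annulus_becomes_disc(self):
        outer = _disc_mask((40, 40), 20, 20, 12)
        inner = _disc_mask((40, 40), 20, 20, 6)
        assert np.array_equal(fill_holes(outer & ~inner), outer)

    def test_solid_disc_unchanged(self):
        disc = _disc_mask((30, 30), 15, 15, 9)
        assert np.array_equal(fill_holes(disc), disc)

    def test_c_shape_open_to_border_unchanged(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:18, 2:5] = True  # left bar
        mask[2:5, 2:18] = True  # top bar
        mask[15:18, 2:18] = True  # bottom bar: C open to the right border
        assert np.array_equal(fill_holes(mask), fill_holes_by_border_flood(mask))
        assert np.array_equal(fill_holes(mask), mask)

    def test_output_superset_of_input(self):
        rng = np.random.default_rng(3)
        mask = rng.random((32, 32)) < 0.4
        filled = fill_holes(mask)
        assert np.all(filled[mask])


class TestFindParticles:
    def test_region_area_in_mm2(self):
        # connected 314-px region at 22 px/mm -> 314/484 = 0.6488 mm2
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:25, 10:30] = True  # 300 px
        mask[25, 10:24] = True  # +14 px
        assert int(mask.sum()) == 314
        particles = find_particles(mask, CAL22, DEFAULT_SIZE_RANGE)
        assert len(particles) == 1
        assert particles[0].area_mm2 == pytest.approx(314 / 484, rel=1e-9)

    def test_small_speck_filtered(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 5:10] = True  # 5 px = 0.0103 mm2 < 0.05
        assert find_particles(mask, CAL22, DEFAULT_SIZE_RANGE) == []

    def test_inclusive_size_bounds(self):
        cal = ScaleCalibration(10.0)  # pixel = 0.01 mm2
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0:5] = True  # exactly 0.05 mm2
        size = SizeRange(0.05, 20.0)
        assert len(find_particles(mask, cal, size)) == 1

    def test_diagonal_touch_merges(self):
        mask = np.zeros((40, 80), dtype=bool)
        mask[5:15, 5:15] = True
        mask[15:25, 15:25] = True  # shares only a diagonal adjacency
        particles = find_particles(mask, CAL22, DEFAULT_SIZE_RANGE)
        assert len(particles) == 1
        assert len(flood_components(mask)) == 1

    def test_ids_in_raster_order_and_centroid_in_bbox(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[30:40, 2:12] = True  # later in raster order
        mask[2:12, 30:40] = True  # first pixel earlier (row 2)
        particles = find_particles(mask, CAL22, DEFAULT_SIZE_RANGE)
        assert [p.id for p in particles] == [1, 2]
        assert particles[0].bbox.y == 2 and particles[1].bbox.y == 30
        for p in particles:
            assert p.bbox.x <= p.centroid_x_mm * 22 <= p.bbox.x + p.bbox.width
            assert p.bbox.y <= p.centroid_y_mm * 22 <= p.bbox.y + p.bbox.height

    def test_empty_mask(self):
        assert find_particles(np.zeros((10, 10), bool), CAL22, DEFAULT_SIZE_RANGE) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_component_count_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48)) < 0.35
        wide = SizeRange(1e-9, 1e9)
        particles = find_particles(mask, CAL22, wide)
        comps = flood_components(mask)
        assert len(particles) == len(comps)
        assert sorted(p.area_px for p in particles) == sorted(len(c) for c in comps)

    def test_area_conservation_pre_filter(self):
        rng = np.random.default_rng(9)
        mask = fill_holes(rng.random((64, 64)) < 0.4)
        particles = find_particles(mask, CAL22, SizeRange(1e-9, 1e9))
        assert sum(p.area_px for p in particles) == int(mask.sum())


class TestCountTubercles:
    def test_blank_image_counts_zero(self, small_config):
        img = np.full((450, 600, 3), 250, dtype=np.uint8)
        assert count_tubercles(img, small_config).tubercle_count == 0

    def test_grayscale_rejected_with_image_id(self, small_config):
        with pytest.raises(ImageFormatError, match="plate_7"):
            count_tubercles(
                np.zeros((450, 600), dtype=np.uint8), small_config, image_id="plate_7"
            )

    def test_crop_error_carries_image_id(self, default_config):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        with pytest.raises(CropBoundsError, match="tiny_img"):
            count_tubercles(img, default_config, image_id="tiny_img")

    def test_translation_invariance(self, small_config):
        """Shifting content away from borders shifts centroids by exactly
        (dx, dy)/px_per_mm and preserves counts and areas."""
        img = np.full((450, 600, 3), 250, dtype=np.uint8)
        yy, xx = np.mgrid[:450, :600]
        disc = (yy - 100) ** 2 + (xx - 120) ** 2 <= 15**2
        img[disc] = (230, 120, 30)  # in-band orange
        dx, dy = 37, 52
        shifted = np.full_like(img, 250)
        shifted[dy:, dx:] = img[: 450 - dy, : 600 - dx]
        a = count_tubercles(img, small_config).particles
        b = count_tubercles(shifted, small_config).particles
        assert len(a) == len(b) == 1
        assert b[0].area_px == a[0].area_px
        assert b[0].centroid_x_mm - a[0].centroid_x_mm == pytest.approx(dx / 22)
        assert b[0].centroid_y_mm - a[0].centroid_y_mm == pytest.approx(dy / 22)

    def test_scale_consistency_on_upsampling(self):
        """2x nearest-neighbour upsampling with doubled px_per_mm leaves the
        count unchanged and mm2 areas within 5% for discs of radius >= 5 px."""
        img = np.full((200, 300, 3), 250, dtype=np.uint8)
        yy, xx = np.mgrid[:200, :300]
        for cy, cx, r in [(60, 80, 6), (140, 200, 12)]:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = (235, 130, 40)
        up = np.kron(img, np.ones((2, 2, 1), dtype=np.uint8))
        ps1 = count_tubercles(img, make_config((300, 200), px_per_mm=22.0))
        ps2 = count_tubercles(up, make_config((600, 400), px_per_mm=44.0))
        assert ps1.tubercle_count == ps2.tubercle_count == 2
        for p1, p2 in zip(ps1.particles, ps2.particles):
            assert p2.area_mm2 == pytest.approx(p1.area_mm2, rel=0.05)

    def test_pale_tubercles_excluded(self, small_config):
        """Low-saturation tubercles fall below the saturation cut."""
        img = np.full((450, 600, 3), 250, dtype=np.uint8)
        yy, xx = np.mgrid[:450, :600]
        centers = [(80, 100), (80, 300), (250, 100), (250, 300), (380, 480)]
        for cy, cx in centers:  # clean: saturation ~ 212
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 10**2] = (240, 120, 40)
        for cy, cx in [(160, 480), (330, 300)]:  # pale: saturation ~ 64
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 10**2] = (240, 210, 180)
        assert count_tubercles(img, small_config).tubercle_count == 5

    def test_necrotic_band_counted_separately(self, small_config):
        """A second dark-brown band catches necrotic tubercles as their own
        class without inflating the tubercle count."""
        from dataclasses import replace

        from rhizosun import HSBRange

        img = np.full((450, 600, 3), 250, dtype=np.uint8)
        yy, xx = np.mgrid[:450, :600]
        img[(yy - 100) ** 2 + (xx - 150) ** 2 <= 10**2] = (240, 120, 40)  # orange
        img[(yy - 300) ** 2 + (xx - 400) ** 2 <= 10**2] = (70, 40, 12)  # dark brown
        cfg = replace(
            small_config,
            bands={
                "tubercle": DEFAULT_TUBERCLE_BAND,
                "necrotic": HSBRange(0, 55, 102, 255, 20, 94),
            },
        )
        ps = count_tubercles(img, cfg)
        assert ps.tubercle_count == 1
        assert ps.necrotic_count == 1
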