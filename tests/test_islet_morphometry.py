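import numpy as np
import pytest
from skimage.measure import regionprops

from keystonekit import islet_morphometry as im
from keystonekit import synthetic_data as sd
from keystonekit.io_formats import ChannelImage


def _disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestBackgroundSubtract:
    def test_uniform_image_self_cancels(self):
        img = ChannelImage(np.full((20, 20), 50, dtype=np.int64), 8)
        roi = im.IsletRoi(_disk_mask((20, 20), (10, 10), 5))
        out = im.background_subtract(img, roi)
        assert np.all(out.pixels == 0)

    def test_offset_arithmetic(self):
        arr = np.full((20, 20), 10, dtype=np.int64)
        inner = _disk_mask((20, 20), (10, 10), 4)
        arr[inner] = 100
        roi = im.IsletRoi(_disk_mask((20, 20), (10, 10), 6))
        out = im.background_subtract(ChannelImage(arr, 8), roi)
        assert np.all(out.pixels[inner] == 90)

    def test_planted_offset_removed_within_one_unit(self):
        islet = sd.PlantedIslet(center=(60, 60), semi_axes=(20, 14))
        ins, _, rois, _ = sd.gen_islet_image(
            dims=(120, 120), islets=[islet], background=25, seed=3
        )
        out = im.background_subtract(ins, rois[0])
        residual = out.pixels[~rois[0].mask].mean()
        assert abs(residual) <= 1.0

    def test_explicit_background_region_override(self):
        arr = np.full((20, 20), 10, dtype=np.int64)
        arr[0:5, 0:5] = 30  # bright corner that would bias the default estimate
        roi = im.IsletRoi(_disk_mask((20, 20), (12, 12), 4))
        clean = np.zeros((20, 20), bool)
        clean[15:20, 15:20] = True
        out = im.background_subtract(
            ChannelImage(arr, 8), roi, background_roi=im.IsletRoi(clean)
        )
        assert np.all(out.pixels[15:20, 15:20] == 0)
        assert np.all(out.pixels[0:5, 0:5] == 20)

    def test_roi_covering_image_rejected(self):
        img = ChannelImage(np.zeros((8, 8), dtype=np.int64), 8)
        with pytest.raises(ValueError, match="background"):
            im.background_subtract(img, im.IsletRoi(np.ones((8, 8), bool)))


class TestSegmentIslet:
    def test_all_pixels_above_threshold(self):
        img = ChannelImage(np.full((10, 10), 9, dtype=np.int64), 8)
        _, area = im.segment_islet(img, im.IsletRoi(np.ones((10, 10), bool)))
        assert area == 100

    def test_threshold_strictly_above_eight(self):
        img = ChannelImage(np.full((10, 10), 8, dtype=np.int64), 8)
        _, area = im.segment_islet(img, im.IsletRoi(np.ones((10, 10), bool)))
        assert area == 0

    def test_area_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        img = ChannelImage(rng.integers(0, 60, size=(30, 30)), 8)
        roi = im.IsletRoi(np.ones((30, 30), bool))
        areas = [im.segment_islet(img, roi, t)[1] for t in range(0, 60, 5)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_planted_ellipse_area_within_2pct(self):
        islet = sd.PlantedIslet(center=(60, 60), semi_axes=(25, 15))
        ins, glu, rois, _ = sd.gen_islet_image(
            dims=(120, 120), islets=[islet], noise_sd=0.0, seed=1
        )
        sub = im.background_subtract(ins, rois[0])
        sub2 = im.background_subtract(glu, rois[0])
        union = (
            im.segment_islet(sub, rois[0])[0] | im.segment_islet(sub2, rois[0])[0]
        )
        assert union.sum() == pytest.approx(np.pi * 25 * 15, rel=0.02)


class TestEllipseAxes:
    def test_filled_circle(self):
        mask = _disk_mask((64, 64), (32, 32), 15)
        major, minor, _ = im.ellipse_axes(mask)
        assert major == pytest.approx(30, rel=0.02)
        assert minor == pytest.approx(30, rel=0.02)

    def test_axis_aligned_ellipse_against_dense_grid_moments(self):
        rr, cc = np.mgrid[0:100, 0:100]
        mask = ((rr - 50) / 20.0) ** 2 + ((cc - 50) / 10.0) ** 2 <= 1
        major, minor, orientation = im.ellipse_axes(mask)
        assert major == pytest.approx(40, rel=0.02)
        assert minor == pytest.approx(20, rel=0.02)
        assert abs(orientation) % np.pi == pytest.approx(0, abs=0.05)

    def test_matches_regionprops_equivalent_ellipse(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.uniform(12, 30)
            b = rng.uniform(10, a)
            theta = rng.uniform(0, np.pi)
            rr, cc = np.mgrid[0:120, 0:120]
            dr, dc = rr - 60, cc - 60
            u = dr * np.cos(theta) + dc * np.sin(theta)
            v = -dr * np.sin(theta) + dc * np.cos(theta)
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1
            major, minor, _ = im.ellipse_axes(mask)
            props = regionprops(mask.astype(np.uint8))[0]
            assert major == pytest.approx(props.axis_major_length, rel=1e-6)
            assert minor == pytest.approx(props.axis_minor_length, rel=1e-6)

    def test_rotation_leaves_lengths_invariant(self):
        rr, cc = np.mgrid[0:100, 0:100]
        mask = ((rr - 50) / 20.0) ** 2 + ((cc - 50) / 10.0) ** 2 <= 1
        major1, minor1, o1 = im.ellipse_axes(mask)
        major2, minor2, o2 = im.ellipse_axes(mask.T)
        assert major2 == pytest.approx(major1, rel=1e-9)
        assert minor2 == pytest.approx(minor1, rel=1e-9)

    def test_translation_invariant(self):
        mask = np.zeros((80, 80), bool)
        mask[10:30, 10:20] = True
        shifted = np.roll(np.roll(mask, 25, axis=0), 30, axis=1)
        assert im.ellipse_axes(mask)[:2] == pytest.approx(
            im.ellipse_axes(shifted)[:2]
        )

    def test_collinear_mask_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[5, 2:12] = True
        with pytest.raises(ValueError, match="degenerate"):
            im.ellipse_axes(mask)


class TestCellFractions:
    def _pair(self, beta_fraction):
        islet = sd.PlantedIslet(
            center=(60, 60), semi_axes=(25, 16), beta_fraction=beta_fraction
        )
        ins, glu, rois, _ = sd.gen_islet_image(dims=(120, 120), islets=[islet], seed=2)
        return (
            im.background_subtract(ins, rois[0]),
            im.background_subtract(glu, rois[0]),
            rois[0],
        )

    def test_single_channel_islet(self):
        ins, glu, roi = self._pair(1.0)
        beta_pct, alpha_pct, _, _ = im.cell_fractions(ins, glu, roi)
        assert beta_pct > 97 and alpha_pct < 3

    def test_planted_70_30_split_within_3_points(self):
        ins, glu, roi = self._pair(0.7)
        beta_pct, alpha_pct, _, _ = im.cell_fractions(ins, glu, roi)
        assert beta_pct == pytest.approx(70, abs=3)
        assert alpha_pct == pytest.approx(30, abs=3)

    def test_channel_swap_symmetry(self):
        ins, glu, roi = self._pair(0.7)
        b1, a1, ba1, aa1 = im.cell_fractions(ins, glu, roi)
        b2, a2, ba2, aa2 = im.cell_fractions(glu, ins, roi)
        assert (b1, a1, ba1, aa1) == (a2, b2, aa2, ba2)


class TestSizeDistribution:
    def _m(self, d):
        return im.IsletMorphometry(
            islet_area=100, major_axis=d, minor_axis=d, orientation=0.0,
            beta_pct=70, alpha_pct=30, beta_area=70, alpha_area=30,
        )

    def test_basic_binning(self):
        hist = im.size_distribution(
            [self._m(10), self._m(20), self._m(30)], [0, 15, 25, 40]
        )
        assert hist == [1, 1, 1]

    def test_edge_value_falls_in_upper_bin(self):
        assert im.size_distribution([self._m(15)], [0, 15, 30]) == [0, 1]

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            im.size_distribution([self._m(5)], [0, 20, 10])

    def test_planted_size_mixture_recovered_within_5_points(self):
        rng = np.random.default_rng(8)
        small, large = 0, 0
        diameters = []
        for _ in range(200):
            if rng.uniform() < 0.6:
                d = rng.uniform(8, 14)
                small += 1
            else:
                d = rng.uniform(20, 30)
                large += 1
            diameters.append(d)
        hist = im.size_distribution(
            [self._m(d) for d in diameters], [0, 17, 40]
        )
        assert hist[0] / 200 == pytest.approx(small / 200, abs=0.05)


class TestMeasureIslet:
    def test_full_workflow_on_planted_islet(self):
        islet = sd.PlantedIslet(
            center=(90, 100), semi_axes=(40, 25), rotation=0.6, beta_fraction=0.7
        )
        ins, glu, rois, _ = sd.gen_islet_image(dims=(192, 192), islets=[islet], seed=0)
        m = im.measure_islet(ins, glu, rois[0])
        assert m.major_axis == pytest.approx(80, rel=0.02)
        assert m.minor_axis == pytest.approx(50, rel=0.02)
        assert m.beta_pct == pytest.approx(70, abs=3)
        assert m.minor_axis <= m.major_axis
        assert m.islet_area <= rois[0].area
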