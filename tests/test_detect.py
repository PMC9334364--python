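"""Detection-pipeline tests against element-wise and synthetic oracles.

Every algebraic step (gradient volume, max projections, detection image,
weighted axial localization) is checked against an independent brute-force
loop; the image-processing steps are checked on constructed scenes with
known answers.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holotrack import (
    Bead,
    DarkVolume,
    OpticalConfig,
    SimulationConfig,
    TrackerParams,
    binarize,
    compose_edof,
    default_plane_set,
    detect_frame,
    detection_image,
    gradient_volume,
    locate_xy,
    locate_z,
    max_projections,
    remove_background,
    render_dark_volume,
    segment,
    simulate_hologram,
)
from holotrack.detect import MaxMaps, SegmentedObject
from holotrack.errors import ConfigError, DegenerateInputError
from holotrack.simulate import HologramFrame


def _random_dark_volume(rng, shape=(12, 14, 6)):
    plane_z = np.sort(rng.uniform(50, 150, shape[2]))
    return DarkVolume(rng.uniform(0, 1, shape), plane_z)


class TestRemoveBackground:
    def test_constant_hologram_maps_to_zero(self):
        h = HologramFrame(np.full((64, 64), 3.3))
        np.testing.assert_allclose(remove_background(h), 0.0, atol=1e-12)

    def test_multiplicative_background_recovered(self):
        # H = B · (1 + cos θ) with broad Gaussian B: the dark hologram
        # must recover the fringe term cos θ almost perfectly
        y, x = np.mgrid[0:256, 0:256].astype(float)
        b = 1.0 + 0.5 * np.exp(-((x - 128) ** 2 + (y - 128) ** 2) / (2 * 90.0**2))
        theta = 2 * np.pi * (x * 7 + y * 3) / 256.0
        h = HologramFrame(b * (1.0 + 0.3 * np.cos(theta)))
        dark = remove_background(h, sigma_bg=16.0)
        target = 0.3 * np.cos(theta)
        corr = np.corrcoef(dark.ravel(), target.ravel())[0, 1]
        assert corr > 0.99

    def test_temporal_mode_suppresses_static_artifact(self, small_config):
        # an artificial static dust term survives per-frame lowpass
        # normalization but cancels against the temporal median
        sim = SimulationConfig(optical=small_config, z2=60.0, sample_depth=20.0)
        dust = np.zeros((64, 64))
        dust[44:52, 40:48] = 0.8
        clean_frames, dusty_frames = [], []
        for i, x in enumerate((8.0, 11.0, 14.0, 17.0, 20.0)):
            h = simulate_hologram([Bead((x, 12.0, 10.0), 3.0)], sim)
            clean_frames.append(h)
            dusty_frames.append(HologramFrame(h.intensity + dust, i))
        dark_clean = remove_background(clean_frames[0], mode="temporal", stack=clean_frames)
        dark_dusty = remove_background(dusty_frames[0], mode="temporal", stack=dusty_frames)
        fringe_amp = np.abs(dark_clean).max()
        temporal_residual = np.abs(dark_dusty - dark_clean)[44:52, 40:48].mean()
        assert temporal_residual < 0.05 * fringe_amp
        dark_lowpass = remove_background(dusty_frames[0], mode="lowpass")
        lowpass_residual = np.abs(dark_lowpass - dark_clean)[44:52, 40:48].mean()
        assert lowpass_residual > temporal_residual

    def test_all_zero_hologram_rejected(self):
        with pytest.raises(DegenerateInputError):
            remove_background(HologramFrame(np.zeros((32, 32))))

    def test_dark_volume_invariant_to_intensity_scale(self, small_config):
        sim = SimulationConfig(optical=small_config, z2=60.0, sample_depth=20.0)
        h = simulate_hologram([Bead((12.0, 12.0, 10.0), 3.0)], sim)
        planes = default_plane_set(60.0, 20.0, 11)
        dv1 = render_dark_volume(
            remove_background(h), planes, small_config, dtype=np.float64
        )
        h_scaled = HologramFrame(7.5 * h.intensity)
        dv2 = render_dark_volume(
            remove_background(h_scaled), planes, small_config, dtype=np.float64
        )
        np.testing.assert_allclose(dv1.values, dv2.values, atol=1e-10)


class TestRenderDarkVolume:
    def test_zero_dark_hologram_gives_zero_volume(self, small_config):
        dv = render_dark_volume(
            np.zeros((64, 64)), default_plane_set(60.0, 20.0, 5), small_config
        )
        np.testing.assert_array_equal(dv.values, 0.0)

    def test_empty_plane_set_rejected(self, small_config):
        with pytest.raises(ConfigError):
            render_dark_volume(np.zeros((64, 64)), np.array([]), small_config)

    def test_plane_refinement_stable(self):
        # doubling the axial sampling must not move the detection by more
        # than one (coarse) plane spacing
        config = OpticalConfig(grid_shape=(256, 256))
        sim = SimulationConfig(optical=config, z2=100.0, sample_depth=40.0)
        h = simulate_hologram([Bead((51.2, 51.2, 20.0))], sim)
        results = []
        for n_planes in (41, 81):
            params = TrackerParams(plane_z=default_plane_set(100.0, 40.0, n_planes))
            dets = detect_frame(h, params, config).detections
            results.append(max(dets, key=lambda d: d.mask_area).z)
        assert abs(results[1] - results[0]) < 1.0  # coarse spacing


class TestGradientVolume:
    def test_constant_volume_has_zero_gradient(self):
        dv = DarkVolume(np.full((8, 9, 3), 2.0), np.array([10.0, 20.0, 30.0]))
        gv = gradient_volume(dv, pixel_pitch=0.5)
        np.testing.assert_array_equal(gv.values, 0.0)

    def test_linear_ramp_gives_squared_slope(self):
        pitch = 0.5
        slope = 0.3  # DV units per µm
        x_um = np.arange(16) * pitch
        plane = np.tile(slope * x_um, (16, 1))
        dv = DarkVolume(np.repeat(plane[:, :, None], 3, axis=2), np.array([1.0, 2.0, 3.0]))
        gv = gradient_volume(dv, pitch)
        np.testing.assert_allclose(gv.values[:, 1:-1, :], slope**2, rtol=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_loop(self, seed):
        rng = np.random.default_rng(seed)
        dv = _random_dark_volume(rng)
        pitch = 0.7
        gv = gradient_volume(dv, pitch)
        v = dv.values
        rows, cols, planes = v.shape
        for _ in range(20):
            r = rng.integers(0, rows)
            c = rng.integers(0, cols)
            p = rng.integers(0, planes)
            rp, rm = min(r + 1, rows - 1), max(r - 1, 0)
            cp, cm = min(c + 1, cols - 1), max(c - 1, 0)
            dy = (v[rp, c, p] - v[rm, c, p]) / (2 * pitch)
            dx = (v[r, cp, p] - v[r, cm, p]) / (2 * pitch)
            assert gv.values[r, c, p] == pytest.approx(dx**2 + dy**2, abs=1e-12)


class TestMaxProjections:
    def test_single_plane_maps_equal_plane(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, (6, 6, 2))
        vals[:, :, 1] = 0.0
        dv = DarkVolume(vals, np.array([10.0, 20.0]))
        gv = gradient_volume(dv, 1.0)
        maps = max_projections(dv, gv)
        np.testing.assert_array_equal(maps.m_dv, vals[:, :, 0])

    def test_tie_takes_smallest_z(self):
        vals = np.zeros((4, 4, 3))
        vals[2, 2, :] = [1.0, 5.0, 5.0]  # equal maxima in planes 1 and 2
        dv = DarkVolume(np.ones((4, 4, 3)), np.array([10.0, 20.0, 30.0]))
        from holotrack import GradientVolume

        gv = GradientVolume(vals, dv.plane_z)
        maps = max_projections(dv, gv)
        assert maps.z_gv[2, 2] == 20.0

    def test_matches_per_pixel_scan(self):
        rng = np.random.default_rng(5)
        dv = _random_dark_volume(rng)
        gv = gradient_volume(dv, 0.4)
        maps = max_projections(dv, gv)
        for r in range(dv.values.shape[0]):
            for c in range(dv.values.shape[1]):
                assert maps.m_dv[r, c] == dv.values[r, c].max()
                k = int(np.argmax(gv.values[r, c]))
                assert maps.m_gv[r, c] == gv.values[r, c, k]
                assert maps.z_gv[r, c] == dv.plane_z[k]


class TestDetectionImage:
    def test_zero_gradient_annihilates(self):
        maps = MaxMaps(np.ones((5, 5)), np.zeros((5, 5)), np.zeros((5, 5)))
        np.testing.assert_array_equal(detection_image(maps), 0.0)

    def test_unit_dv_is_proportional_to_gv(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0, 2, (5, 5))
        maps = MaxMaps(np.ones((5, 5)), g, np.zeros((5, 5)))
        np.testing.assert_allclose(detection_image(maps), g / g.max(), rtol=1e-12)

    def test_product_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 3, (7, 7))
        b = rng.uniform(0, 3, (7, 7))
        maps = MaxMaps(a, b, np.zeros((7, 7)))
        product = a * b
        np.testing.assert_allclose(
            detection_image(maps), product / product.max(), rtol=1e-12
        )


class TestBinarizeSegment:
    def test_zero_image_all_background(self):
        assert not binarize(np.zeros((32, 32))).any()

    def test_bright_disk_recovered(self):
        y, x = np.mgrid[0:64, 0:64]
        disk = ((x - 30) ** 2 + (y - 34) ** 2 <= 8**2).astype(float)
        bw = binarize(disk, min_area=4)
        area = bw.sum()
        true_area = np.pi * 8**2
        assert abs(area - true_area) / true_area < 0.2

    def test_adaptive_threshold_keeps_faint_object(self):
        rng = np.random.default_rng(3)
        img = 0.05 * rng.uniform(size=(128, 128))
        y, x = np.mgrid[0:128, 0:128]
        img[(x - 30) ** 2 + (y - 30) ** 2 <= 6**2] = 1.0
        img[(x - 90) ** 2 + (y - 90) ** 2 <= 6**2] = 0.3
        objects = segment(binarize(img, sensitivity=1.0))
        assert len(objects) == 2

    def test_oversized_window_rejected(self):
        with pytest.raises(ConfigError):
            binarize(np.zeros((32, 32)), window=65)

    def test_diagonal_pixels_are_one_object(self):
        bw = np.zeros((8, 8), bool)
        bw[2, 2] = bw[3, 3] = True
        assert len(segment(bw)) == 1

    def test_empty_mask_gives_no_objects(self):
        assert segment(np.zeros((8, 8), bool)) == []

    def test_labels_ordered_by_scan_order(self):
        bw = np.zeros((16, 16), bool)
        bw[10:12, 1:3] = True  # lower-left
        bw[1:3, 10:12] = True  # upper-right: first in scan order
        objects = segment(bw)
        assert objects[0].rows[0] < objects[1].rows[0]

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_component_count_matches_flood_fill(self, seed):
        rng = np.random.default_rng(seed)
        bw = rng.uniform(size=(24, 24)) < 0.3
        objects = segment(bw)
        assert len(objects) == _flood_fill_count(bw)

    def test_detection_count_monotone_in_min_area(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(size=(64, 64)) ** 4
        counts = [
            len(segment(binarize(img, min_area=m, sensitivity=1.5)))
            for m in (1, 4, 9, 16)
        ]
        assert counts == sorted(counts, reverse=True)


def _flood_fill_count(bw):
    seen = np.zeros_like(bw, bool)
    count = 0
    rows, cols = bw.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if bw[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < rows
                                and 0 <= cc < cols
                                and bw[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


class TestLocalization:
    def _maps(self, m_gv, z_gv):
        return MaxMaps(np.ones_like(m_gv), np.asarray(m_gv, float), np.asarray(z_gv, float))

    def test_single_pixel_returns_its_z(self):
        obj = SegmentedObject(1, np.array([0]), np.array([0]))
        maps = self._maps([[2.0]], [[1250.0]])
        assert locate_z(obj, maps) == pytest.approx(1250.0)

    def test_equal_weights_give_midpoint(self):
        obj = SegmentedObject(1, np.array([0, 0]), np.array([0, 1]))
        maps = self._maps([[1.0, 1.0]], [[1000.0, 1200.0]])
        assert locate_z(obj, maps) == pytest.approx(1100.0)

    def test_weighted_mean_hand_computed(self):
        obj = SegmentedObject(1, np.array([0, 0]), np.array([0, 1]))
        maps = self._maps([[1.0, 3.0]], [[1000.0, 1200.0]])
        assert locate_z(obj, maps) == pytest.approx(1150.0)

    def test_zero_weights_rejected(self):
        obj = SegmentedObject(1, np.array([0]), np.array([0]))
        maps = self._maps([[0.0]], [[100.0]])
        with pytest.raises(DegenerateInputError):
            locate_z(obj, maps)

    def test_locate_xy_single_pixel(self):
        dv = DarkVolume(np.ones((8, 8, 2)), np.array([10.0, 20.0]))
        obj = SegmentedObject(1, np.array([3]), np.array([5]))
        x, y = locate_xy(obj, dv, 12.0, pixel_pitch=0.5)
        assert (x, y) == (2.5, 1.5)

    def test_locate_xy_blob_peak(self):
        vals = np.zeros((16, 16, 3))
        y, x = np.mgrid[0:16, 0:16]
        vals[:, :, 1] = np.exp(-((x - 7) ** 2 + (y - 9) ** 2) / 4.0)
        dv = DarkVolume(vals, np.array([10.0, 20.0, 30.0]))
        rows, cols = np.nonzero(np.ones((16, 16)))
        obj = SegmentedObject(1, rows, cols)
        assert locate_xy(obj, dv, 19.0, 1.0) == (7.0, 9.0)

    def test_locate_xy_nearest_plane_tie_toward_smaller_z(self):
        vals = np.zeros((4, 4, 2))
        vals[1, 1, 0] = 1.0  # peak only in the first plane
        vals[2, 2, 1] = 1.0
        dv = DarkVolume(vals, np.array([10.0, 20.0]))
        rows, cols = np.nonzero(np.ones((4, 4)))
        obj = SegmentedObject(1, rows, cols)
        assert locate_xy(obj, dv, 15.0, 1.0) == (1.0, 1.0)


class TestComposeEdof:
    def test_no_objects_gives_min_projection(self):
        rng = np.random.default_rng(0)
        dv = _random_dark_volume(rng)
        edof = compose_edof([], dv, [])
        np.testing.assert_allclose(edof, dv.values.min(axis=2))

    def test_each_object_rendered_from_its_own_plane(self):
        from holotrack import Detection

        vals = np.zeros((32, 32, 4))
        rng = np.random.default_rng(1)
        vals += rng.uniform(0, 0.1, vals.shape)
        vals[5:9, 5:9, 1] = 1.0
        vals[20:24, 20:24, 3] = 1.0
        dv = DarkVolume(vals, np.array([10.0, 20.0, 30.0, 40.0]))
        objects = [
            SegmentedObject(1, *np.nonzero(vals[:, :, 1] > 0.5)),
            SegmentedObject(2, *np.nonzero(vals[:, :, 3] > 0.5)),
        ]
        detections = [
            Detection(0, 6.0, 6.0, 20.0),
            Detection(1, 22.0, 22.0, 40.0),
        ]
        edof = compose_edof(detections, dv, objects, dilate_px=0)
        np.testing.assert_array_equal(edof[5:9, 5:9], vals[5:9, 5:9, 1])
        np.testing.assert_array_equal(edof[20:24, 20:24], vals[20:24, 20:24, 3])


class TestDetectFrame:
    def test_blank_hologram_yields_no_detections(self, small_config):
        params = TrackerParams(plane_z=default_plane_set(60.0, 20.0, 5))
        h = HologramFrame(np.full((64, 64), 2.0))
        assert detect_frame(h, params, small_config).detections == []

    def test_multi_bead_frame_detected(self):
        config = OpticalConfig(grid_shape=(256, 256))
        sim = SimulationConfig(optical=config, z2=100.0, sample_depth=40.0)
        beads = [
            Bead((25.0, 25.0, 10.0)),
            Bead((75.0, 30.0, 20.0)),
            Bead((50.0, 80.0, 30.0)),
        ]
        h = simulate_hologram(beads, sim)
        params = TrackerParams(plane_z=default_plane_set(100.0, 40.0, 41))
        dets = detect_frame(h, params, config).detections
        assert len(dets) == 3
        for bead in beads:
            z_true = 100.0 + 40.0 - bead.center[2]
            best = min(dets, key=lambda d: (d.x - bead.center[0]) ** 2 + (d.y - bead.center[1]) ** 2)
            # localization within half a bead diameter on every axis
            assert abs(best.x - bead.center[0]) < 2.5
            assert abs(best.y - bead.center[1]) < 2.5
            assert abs(best.z - z_true) < 2.5

    def test_all_z_within_plane_range(self):
        config = OpticalConfig(grid_shape=(256, 256))
        sim = SimulationConfig(optical=config, z2=100.0, sample_depth=40.0, snr=5.0, seed=1)
        h = simulate_hologram([Bead((40.0, 60.0, 35.0))], sim)
        planes = default_plane_set(100.0, 40.0, 41)
        dets = detect_frame(h, TrackerParams(plane_z=planes), config).detections
        assert dets
        for d in dets:
            assert planes[0] <= d.z <= planes[-1]
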