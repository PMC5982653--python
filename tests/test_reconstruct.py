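import logging
import math

import numpy as np
import pytest

import ringtomo as rt
from ringtomo.errors import ConfigurationError

FS = 12e6
C = 1540.0


class TestAssembleColumns:
    def test_columns_are_ascans_per_angle(self, cylinder_sinogram):
        matrix, angles = rt.assemble_columns(cylinder_sinogram, 1)
        assert matrix.shape == (2048, 8)
        assert list(angles) == sorted(angles)
        np.testing.assert_array_equal(matrix[:, 3], cylinder_sinogram.ascans[3, 0])

    def test_missing_element_rejected(self, cylinder_sinogram):
        with pytest.raises(KeyError):
            rt.assemble_columns(cylinder_sinogram, 99)


class TestBandpass:
    def test_dc_removed(self):
        matrix = np.ones((2048, 3))
        out = rt.bandpass(matrix, FS)
        assert np.abs(out).max() < 1e-6

    def test_center_frequency_preserved_within_1db(self):
        t = np.arange(4096) / FS
        tone = np.sin(2 * np.pi * 3.5e6 * t)[:, None]
        out = rt.bandpass(tone, FS)
        interior = np.abs(out[1000:-1000, 0]).max()
        assert 10 ** (-1 / 20) < interior < 10 ** (1 / 20)

    def test_zero_in_zero_out(self):
        out = rt.bandpass(np.zeros((512, 2)), FS)
        assert np.all(out == 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            rt.bandpass(np.zeros((64, 1)), FS, rt.FilterSpec(band_high_hz=7e6))


class TestEnvelope:
    def test_tone_envelope_is_amplitude(self):
        t = np.arange(4096) / FS
        tone = 2.5 * np.sin(2 * np.pi * 3.5e6 * t)[:, None]
        env = rt.envelope(tone)
        assert env.min() >= 0.0
        np.testing.assert_allclose(env[500:-500, 0], 2.5, rtol=0.01)

    def test_zero_in_zero_out(self):
        assert np.all(rt.envelope(np.zeros((128, 2))) == 0.0)

    def test_burst_envelope_peak_at_window_center(self):
        t = np.arange(2048) / FS
        center = 1000 / FS
        burst = np.exp(-(((t - center) / 2e-6) ** 2)) * np.sin(2 * np.pi * 3.5e6 * t)
        env = rt.envelope(burst[:, None])
        assert abs(int(np.argmax(env[:, 0])) - 1000) <= 1


class TestLogCompress:
    def test_mapping_endpoints_and_midpoint(self):
        dr = 50.0
        x = np.array([[1.0, 10 ** (-dr / 20), 10 ** (-dr / 40), 1e-9]])
        y = rt.log_compress(x, rt.CompressionSpec(dynamic_range_db=dr))
        assert y[0, 0] == pytest.approx(1.0)
        assert y[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert y[0, 2] == pytest.approx(0.5)
        assert y[0, 3] == 0.0  # below the floor clips to 0

    def test_all_zero_guard(self):
        assert np.all(rt.log_compress(np.zeros((4, 4))) == 0.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rt.log_compress(np.array([[-1.0]]))


class TestTruncateHalfDepth:
    def test_samples_beyond_ring_radius_zeroed(self):
        matrix = np.ones((2048, 2))
        out = rt.truncate_half_depth(matrix, FS, C, 180.0)
        # ceil(2 x 90 mm / 1540 m/s x 12 MHz) = 1403 is the last kept sample
        assert np.all(out[1404:] == 0.0)
        assert np.all(out[1403] == 1.0)
        # 2 us transmit dead zone: first 24 samples zeroed
        assert np.all(out[:24] == 0.0)
        assert np.all(out[24:1404] == 1.0)

    def test_infinite_ring_is_identity_outside_dead_zone(self):
        matrix = np.ones((2048, 1))
        out = rt.truncate_half_depth(matrix, FS, C, np.inf)
        assert np.all(out[24:] == 1.0)

    def test_zero_in_zero_out(self):
        out = rt.truncate_half_depth(np.zeros((100, 3)), FS, C, 180.0)
        assert np.all(out == 0.0)


def _single_sample_matrix(sample_index, n_samples=2048):
    m = np.zeros((n_samples, 1))
    m[sample_index, 0] = 1.0
    return m


class TestScanConvert:
    def test_ring_radius_sample_lands_at_center(self, geom):
        i = 1402  # one-way range 89.96 mm, just inside the ring radius
        img = rt.scan_convert(_single_sample_matrix(i), [0.0], geom, FS, C)
        row, col = np.unravel_index(np.argmax(img.pixels), img.shape)
        x, y = img.pixel_to_xy_mm(row, col)
        assert abs(x) <= img.pixel_size_mm / 2 + 1e-9
        assert abs(y) <= img.pixel_size_mm / 2 + 1e-9

    def test_eighty_mm_sample_lands_ten_mm_past_axis_side(self, geom):
        i = 1247  # one-way range 80.02 mm along the 0-degree beam
        r = C * i / (2 * FS) * 1e3
        img = rt.scan_convert(_single_sample_matrix(i), [0.0], geom, FS, C)
        row, col = np.unravel_index(np.argmax(img.pixels), img.shape)
        x, y = img.pixel_to_xy_mm(row, col)
        assert x == pytest.approx(90.0 - r, abs=img.pixel_size_mm / 2 + 1e-9)
        assert abs(x - 10.0) < 0.3
        assert abs(y) <= img.pixel_size_mm / 2 + 1e-9

    def test_zero_matrix_gives_empty_mask(self, geom):
        img = rt.scan_convert(np.zeros((2048, 4)), [0, 90, 180, 270], geom, FS, C)
        assert np.all(img.pixels == 0.0)
        assert not img.mask.any()


class TestMorphProcess:
    def test_fully_covered_identity_configuration(self):
        rng = np.random.default_rng(0)
        pixels = rng.uniform(0, 1, (32, 32))
        image = rt.SliceImage(
            pixels=pixels, pixel_size_mm=1.0, element=1,
            mask=np.ones((32, 32), dtype=bool),
        )
        out = rt.morph_process(image, rt.MorphSpec(dilation_radius_px=0))
        np.testing.assert_array_equal(out.pixels, pixels)

    def test_single_bright_pixel_dilates_to_13_pixel_disk(self):
        pixels = np.zeros((21, 21))
        pixels[10, 10] = 1.0
        image = rt.SliceImage(
            pixels=pixels, pixel_size_mm=1.0, element=1,
            mask=np.ones((21, 21), dtype=bool),
        )
        out = rt.morph_process(image, rt.MorphSpec(dilation_radius_px=2))
        # a radius-2 disk footprint contains 13 pixels
        assert int((out.pixels == 1.0).sum()) == 13
        assert out.dilation_radius_px == 2

    def test_checkerboard_fill_reproduces_constant(self):
        n = 21
        yy, xx = np.mgrid[0:n, 0:n]
        mask = (yy + xx) % 2 == 0
        pixels = np.where(mask, 0.7, 0.0)
        image = rt.SliceImage(
            pixels=pixels, pixel_size_mm=1.0, element=1, mask=mask
        )
        out = rt.morph_process(image, rt.MorphSpec(dilation_radius_px=0))
        np.testing.assert_allclose(out.pixels, 0.7, atol=1e-6)

    def test_empty_mask_warns_and_returns_input(self, caplog):
        image = rt.SliceImage(
            pixels=np.zeros((8, 8)), pixel_size_mm=1.0, element=1,
            mask=np.zeros((8, 8), dtype=bool),
        )
        with caplog.at_level(logging.WARNING):
            out = rt.morph_process(image)
        assert out is image
        assert any("empty" in r.message for r in caplog.records)


class TestReconstructSlice:
    def test_stage_order_is_pinned_and_composition_matches(self, cylinder_sinogram):
        trace = []
        img = rt.reconstruct_slice(
            cylinder_sinogram, 1, grid_spec=rt.GridSpec(pixel_size_mm=2.0),
            stage_trace=trace,
        )
        assert [name for name, _ in trace] == [
            "assemble_columns",
            "bandpass",
            "envelope",
            "log_compress",
            "truncate_half_depth",
            "scan_convert",
            "morph_process",
        ]
        # manual composition in the same order reproduces the pipeline output
        sino = cylinder_sinogram
        m, angles = rt.assemble_columns(sino, 1)
        m = rt.bandpass(m, sino.sampling_rate_hz)
        m = rt.envelope(m)
        m = rt.log_compress(m)
        m = rt.truncate_half_depth(
            m, sino.sampling_rate_hz, sino.medium.sound_speed_m_s,
            sino.geometry.ring_diameter_mm,
        )
        manual = rt.scan_convert(
            m, angles, sino.geometry, sino.sampling_rate_hz,
            sino.medium.sound_speed_m_s, rt.GridSpec(pixel_size_mm=2.0),
        )
        manual = rt.morph_process(manual)
        np.testing.assert_array_equal(img.pixels, manual.pixels)

    def test_all_zero_sinogram_gives_all_zero_image(self, geom, medium, pulse):
        plan = rt.build_full_circle_plan(geom, 90.0, [1])
        sino = rt.simulate_sinogram(
            geom, rt.Phantom(), medium, pulse, plan, noise_sigma=0.0, seed=0
        )
        img = rt.reconstruct_slice(sino, 1, grid_spec=rt.GridSpec(pixel_size_mm=2.0))
        assert np.all(img.pixels == 0.0)

    def test_deterministic_given_inputs(self, cylinder_sinogram):
        grid = rt.GridSpec(pixel_size_mm=2.0)
        a = rt.reconstruct_slice(cylinder_sinogram, 1, grid_spec=grid)
        b = rt.reconstruct_slice(cylinder_sinogram, 1, grid_spec=grid)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestGeometricFidelity:
    def test_brightest_pixel_at_nearest_surface_point(self, geom, medium, pulse):
        """For a noise-free off-axis cylinder, each beam's brightest deposit
        must land within a pixel plus a range sample of the closed-form
        nearest surface point (oracle: brute-force ray marching)."""
        phantom = rt.Phantom(reflectors=(rt.Cylinder((6.0, 4.0, 0.0), 10.0, 60.0),))
        plan = rt.build_full_circle_plan(geom, 15.0, [1])
        sino = rt.simulate_sinogram(
            geom, phantom, medium, pulse, plan, noise_sigma=0.0, seed=0
        )
        grid = rt.GridSpec(pixel_size_mm=0.5)
        checked = 0
        for j, angle in enumerate(sino.angles_deg):
            # brute-force march along the beam to the first surface point
            origin = rt.transducer_position(geom, angle, 1)
            direction = rt.beam_direction(geom, angle)
            ts = np.arange(0.0, 180.0, 0.005)
            pts = origin[None, :2] + ts[:, None] * direction[None, :2]
            inside = np.hypot(pts[:, 0] - 6.0, pts[:, 1] - 4.0) <= 10.0
            if not inside.any():
                continue
            entry = pts[np.argmax(inside)]
            matrix, _ = rt.assemble_columns(sino, 1)
            matrix = rt.envelope(rt.bandpass(matrix, sino.sampling_rate_hz))
            matrix = rt.truncate_half_depth(
                matrix, sino.sampling_rate_hz, medium.sound_speed_m_s,
                geom.ring_diameter_mm,
            )
            single = np.zeros_like(matrix[:, :1])
            single[:, 0] = matrix[:, j]
            if single.max() <= 1e-9:
                # grazing beam beyond the incidence cutoff returns no echo
                continue
            img = rt.scan_convert(
                single, [angle], geom, sino.sampling_rate_hz,
                medium.sound_speed_m_s, grid,
            )
            row, col = np.unravel_index(np.argmax(img.pixels), img.shape)
            x, y = img.pixel_to_xy_mm(row, col)
            one_sample_mm = medium.sound_speed_m_s / (2 * sino.sampling_rate_hz) * 1e3
            tol = math.sqrt(2) * grid.pixel_size_mm / 2 + one_sample_mm + 0.1
            assert math.hypot(x - entry[0], y - entry[1]) <= tol
            checked += 1
        assert checked >= 8
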