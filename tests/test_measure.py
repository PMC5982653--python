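import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ringtomo as rt
from ringtomo.errors import MeasurementError


class TestTofToDistance:
    @pytest.mark.parametrize(
        "t_us, c, expected_mm",
        [
            (93.51, 1540.0, 72.0),  # the 72 mm pulse-echo ranging example
            (0.0, 1540.0, 0.0),
            (100.0, 1500.0, 75.0),
        ],
    )
    def test_known_values(self, t_us, c, expected_mm):
        assert rt.tof_to_distance(t_us * 1e-6, c) == pytest.approx(
            expected_mm, abs=0.01
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rt.tof_to_distance(-1e-6, 1540.0)

    @given(
        t=st.floats(1e-9, 1e-3),
        c=st.floats(100.0, 3000.0),
        k=st.floats(0.1, 10.0),
    )
    def test_linearity_in_both_arguments(self, t, c, k):
        s = rt.tof_to_distance(t, c)
        assert rt.tof_to_distance(k * t, c) == pytest.approx(k * s, rel=1e-9)
        assert rt.tof_to_distance(t, k * c) == pytest.approx(k * s, rel=1e-9)


class TestEstimateTof:
    def test_simulated_reflector_at_72mm(self, geom, medium, pulse):
        phantom = rt.Phantom(reflectors=(rt.Cylinder((0, 0, 0), 18.0, 60.0),))
        ascan = rt.simulate_ascan(geom, phantom, medium, pulse, 0.0, 1, noise_sigma=0.0)
        est = rt.estimate_tof(ascan, medium.sound_speed_m_s)
        one_sample_mm = medium.sound_speed_m_s / (2 * ascan.sampling_rate_hz) * 1e3
        assert est.distance_mm == pytest.approx(72.0, abs=one_sample_mm)

    def test_all_zero_ascan_reports_no_echo(self):
        ascan = rt.AScan(samples=np.zeros(2048))
        est = rt.estimate_tof(ascan, 1540.0)
        assert est.no_echo
        assert est.distance_mm is None

    def test_global_peak_rule_picks_stronger_echo(self):
        # strong echo at 40 mm, weak at 70 mm -> argmax picker returns 40 mm
        fs, c = 12e6, 1540.0
        t = np.arange(2048) / fs
        trace = np.zeros_like(t)
        for dist, amp in ((40.0, 1.0), (70.0, 0.3)):
            delay = 2 * dist * 1e-3 / c
            trace += amp * np.exp(-(((t - delay) / 2e-7) ** 2)) * np.sin(
                2 * np.pi * 3.5e6 * (t - delay)
            )
        est = rt.estimate_tof(rt.AScan(samples=trace), c)
        assert est.distance_mm == pytest.approx(40.0, abs=0.1)
        first = rt.estimate_tof(
            rt.AScan(samples=trace), c, picker="first_crossing", threshold=0.2
        )
        assert first.distance_mm == pytest.approx(40.0, abs=0.5)


class TestOpposingPairSize:
    @pytest.mark.parametrize(
        "d1, d2, expected",
        [(87.5, 87.5, 5.0), (65.0, 65.0, 50.0), (72.0, 57.0, 51.0)],
    )
    def test_size_is_diameter_minus_distances(self, d1, d2, expected):
        est = rt.opposing_pair_size(d1, d2, 180.0)
        assert est.size_mm == pytest.approx(expected)
        assert est.method == "opposing_tof"

    def test_overlapping_distances_rejected(self):
        with pytest.raises(MeasurementError):
            rt.opposing_pair_size(100.0, 100.0, 180.0)

    def test_closure_with_simulated_opposing_echoes(self, geom, medium, pulse):
        """Ranging from opposite sides of a centered cylinder recovers its
        diameter: d1 + size + d2 = D within two range samples."""
        phantom = rt.Phantom(reflectors=(rt.Cylinder((0, 0, 0), 10.0, 60.0),))
        estimates = []
        for angle in (0.0, 180.0):
            a = rt.simulate_ascan(geom, phantom, medium, pulse, angle, 1, noise_sigma=0.0)
            estimates.append(rt.estimate_tof(a, medium.sound_speed_m_s))
        est = rt.opposing_pair_size(
            estimates[0].distance_mm, estimates[1].distance_mm, 180.0
        )
        two_samples_mm = medium.sound_speed_m_s / 12e6 * 1e3
        assert est.size_mm == pytest.approx(20.0, abs=two_samples_mm)


class TestCaliperDiameter:
    def test_perfect_disk_equivalent_diameter(self, flat_disk_image):
        est = rt.caliper_diameter(flat_disk_image)
        # rasterized-disk oracle: area within one pixel ring of the ideal
        assert est.size_mm == pytest.approx(20.0, abs=0.5)
        assert est.method == "caliper"
        assert est.details["centroid_xy_mm"] == pytest.approx((0.0, 0.0), abs=0.5)

    def test_empty_image_reports_no_object(self):
        image = rt.SliceImage(
            pixels=np.zeros((32, 32)), pixel_size_mm=0.5, element=1,
            mask=np.ones((32, 32), dtype=bool),
        )
        assert rt.caliper_diameter(image) is None

    def test_larger_of_two_components_is_measured(self):
        pixels = np.zeros((64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        pixels[np.hypot(yy - 20, xx - 20) <= 10] = 1.0  # large disk
        pixels[np.hypot(yy - 48, xx - 48) <= 4] = 1.0  # small disk
        image = rt.SliceImage(
            pixels=pixels, pixel_size_mm=1.0, element=1,
            mask=np.ones((64, 64), dtype=bool),
        )
        est = rt.caliper_diameter(image)
        assert est.size_mm == pytest.approx(20.0, abs=1.5)

    def test_rotation_invariance_of_equivalent_diameter(self, flat_disk_image):
        rotated = rt.SliceImage(
            pixels=np.rot90(flat_disk_image.pixels).copy(),
            pixel_size_mm=0.5, element=1,
            mask=np.ones_like(flat_disk_image.mask),
        )
        a = rt.caliper_diameter(flat_disk_image).size_mm
        b = rt.caliper_diameter(rotated).size_mm
        assert abs(a - b) <= 0.5  # within one pixel

    def test_chords_of_square_component(self):
        pixels = np.zeros((81, 81))
        pixels[20:61, 20:61] = 1.0  # 41 px square, 20.5 mm at 0.5 mm pixels
        image = rt.SliceImage(
            pixels=pixels, pixel_size_mm=0.5, element=1,
            mask=np.ones((81, 81), dtype=bool),
        )
        est = rt.caliper_diameter(image)
        assert est.details["min_chord_mm"] == pytest.approx(20.5, abs=0.6)
        assert est.details["max_chord_mm"] == pytest.approx(
            20.5 * math.sqrt(2), abs=1.0
        )


class TestRelativeError:
    @pytest.mark.parametrize(
        "measured, nominal, expected",
        [(21.0, 20.0, 5.0), (21.5, 20.0, 7.5), (33.3, 33.3, 0.0)],
    )
    def test_known_values(self, measured, nominal, expected):
        assert rt.relative_error(measured, nominal) == pytest.approx(expected)

    def test_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError):
            rt.relative_error(10.0, 0.0)

    @given(
        m=st.floats(0.0, 1e3),
        n=st.floats(1e-3, 1e3),
        k=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, m, n, k):
        assert rt.relative_error(k * m, k * n) == pytest.approx(
            rt.relative_error(m, n), rel=1e-9, abs=1e-9
        )
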