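"""Ray-based monostatic pulse-echo simulation.

Each element fires a Gaussian-modulated sinusoid toward the rotation axis and
records its own echo. A first-order (single-bounce) model is used: every
interface crossing along the straight ray returns an echo at the round-trip
delay t = 2 d / c, scaled by surface reflectivity, a cos^2 incidence-angle
factor with a hard cutoff, and frequency-linear attenuation (water before the
first interface, tissue after). Additive white Gaussian noise models the
acquisition chain. No refraction, multiple scattering, diffraction or
transmit focusing is simulated; the reconstruction assumes the same
straight-ray constant-c model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import gausspulse

from .errors import ConfigurationError
from .geometry import RingGeometry, ScanPlan, beam_direction, transducer_position
from .phantoms import Crossing, Medium, Phantom, Pulse, interface_crossings

__all__ = [
    "AScan",
    "Sinogram",
    "echo_amplitude",
    "simulate_ascan",
    "simulate_sinogram",
    "min_samples_for_half_depth",
    "DEFAULT_SAMPLING_RATE_HZ",
    "DEFAULT_N_SAMPLES",
    "DEFAULT_NOISE_SIGMA",
    "DEFAULT_MAX_INCIDENCE_DEG",
]

DEFAULT_SAMPLING_RATE_HZ = 12e6
DEFAULT_N_SAMPLES = 2048  # 131 mm of range at defaults, > the 90 mm half depth
DEFAULT_NOISE_SIGMA = 0.01  # 1% of unit pulse amplitude
DEFAULT_MAX_INCIDENCE_DEG = 60.0


@dataclass(frozen=True)
class AScan:
    """One pulse-echo time series (amplitude vs sample index)."""

    samples: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    beam_angle_deg: float = 0.0
    element: int = 1
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class Sinogram:
    """Raw echo dataset: one A-scan per (angle, element).

    ``ascans`` has shape (n_angles, n_elements, n_samples); angles are
    strictly increasing in [0, 360).
    """

    ascans: np.ndarray
    angles_deg: np.ndarray
    elements: tuple[int, ...]
    sampling_rate_hz: float
    geometry: RingGeometry = field(default_factory=RingGeometry)
    medium: Medium = field(default_factory=Medium)
    seed: int | None = None
    interval_deg: float | None = None

    def __post_init__(self) -> None:
        expected = (len(self.angles_deg), len(self.elements))
        if self.ascans.shape[:2] != expected:
            raise ValueError(
                f"ascans shape {self.ascans.shape} does not match "
                f"{expected} (angles, elements)"
            )
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.ascans.shape[2]

    def element_column(self, element: int) -> int:
        try:
            return self.elements.index(element)
        except ValueError:
            raise KeyError(
                f"element {element} not acquired (have {self.elements})"
            ) from None

    def ascan(self, angle_index: int, element: int) -> AScan:
        return AScan(
            samples=self.ascans[angle_index, self.element_column(element)],
            sampling_rate_hz=self.sampling_rate_hz,
            beam_angle_deg=float(self.angles_deg[angle_index]),
            element=element,
        )


def min_samples_for_half_depth(
    geom: RingGeometry,
    medium: Medium,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> int:
    """Fewest samples covering the round trip to the ring radius."""
    return math.ceil(
        2.0 * (geom.ring_radius_mm * 1e-3) / medium.sound_speed_m_s * sampling_rate_hz
    )


def echo_amplitude(
    crossing: Crossing,
    medium: Medium,
    pulse: Pulse,
    max_incidence_deg: float = DEFAULT_MAX_INCIDENCE_DEG,
) -> float:
    """Echo amplitude of one interface crossing.

    amplitude = A0 * reflectivity * cos^2(incidence) * 10^(-att_dB/20), zero
    beyond the incidence cutoff. The round-trip attenuation in dB is
    alpha * (2 * path / 10 cm) * f0_MHz per medium segment: water attenuation
    up to the first interface, tissue attenuation beyond it.
    """
    if crossing.incidence_deg > max_incidence_deg:
        return 0.0
    f_mhz = pulse.center_frequency_hz / 1e6
    tissue_cm = 2.0 * crossing.tissue_path_mm / 10.0
    water_cm = 2.0 * (crossing.distance_mm - crossing.tissue_path_mm) / 10.0
    att_db = (
        medium.water_attenuation_db_cm_mhz * water_cm
        + medium.tissue_attenuation_db_cm_mhz * tissue_cm
    ) * f_mhz
    cos_inc = math.cos(math.radians(crossing.incidence_deg))
    return pulse.amplitude * crossing.reflectivity * cos_inc**2 * 10.0 ** (-att_db / 20.0)


def simulate_ascan(
    geom: RingGeometry,
    phantom: Phantom,
    medium: Medium,
    pulse: Pulse,
    beam_angle_deg: float,
    element: int,
    n_samples: int = DEFAULT_N_SAMPLES,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int | None = None,
    max_incidence_deg: float = DEFAULT_MAX_INCIDENCE_DEG,
) -> AScan:
    """Simulate one monostatic A-scan.

    The trace is the superposition, over all interface crossings of the
    element's ray, of Gaussian-modulated sinusoids at the pulse centre
    frequency delayed by t = 2 d / c and scaled by :func:`echo_amplitude`,
    plus zero-mean Gaussian noise. Deterministic for a fixed seed.
    """
    n_min = min_samples_for_half_depth(geom, medium, sampling_rate_hz)
    if n_samples < n_min:
        raise ConfigurationError(
            f"n_samples={n_samples} cannot cover the half-depth range; "
            f"need at least {n_min} samples at {sampling_rate_hz/1e6:g} MHz"
        )
    origin = transducer_position(geom, beam_angle_deg, element)
    direction = beam_direction(geom, beam_angle_deg)
    t = np.arange(n_samples) / sampling_rate_hz
    trace = np.zeros(n_samples)
    c = medium.sound_speed_m_s
    for crossing in interface_crossings(phantom, origin, direction):
        amp = echo_amplitude(crossing, medium, pulse, max_incidence_deg)
        if amp == 0.0:
            continue
        delay = 2.0 * (crossing.distance_mm * 1e-3) / c
        if delay >= t[-1]:
            continue
        trace += amp * gausspulse(
            t - delay,
            fc=pulse.center_frequency_hz,
            bw=pulse.fractional_bandwidth,
        )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sigma, n_samples)
    return AScan(
        samples=trace,
        sampling_rate_hz=sampling_rate_hz,
        beam_angle_deg=beam_angle_deg,
        element=element,
        seed=seed,
    )


def _sub_seed(master_seed: int | None, counter: int) -> int | None:
    """Counter-based per-acquisition seed so any A-scan is independently
    reproducible from (master seed, acquisition index)."""
    if master_seed is None:
        return None
    ss = np.random.SeedSequence([int(master_seed), int(counter)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_sinogram(
    geom: RingGeometry,
    phantom: Phantom,
    medium: Medium,
    pulse: Pulse,
    plan: ScanPlan,
    n_samples: int = DEFAULT_N_SAMPLES,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int | None = 0,
    max_incidence_deg: float = DEFAULT_MAX_INCIDENCE_DEG,
) -> Sinogram:
    """Simulate a full sinogram: one A-scan per (angle, element) of the plan."""
    phantom.check_fits_in_ring(geom)
    angles = np.asarray(plan.angles_deg, dtype=float)
    data = np.zeros((len(angles), len(plan.element_indices), n_samples))
    counter = 0
    for i, angle in enumerate(angles):
        for j, element in enumerate(plan.element_indices):
            ascan = simulate_ascan(
                geom,
                phantom,
                medium,
                pulse,
                beam_angle_deg=float(angle),
                element=element,
                n_samples=n_samples,
                sampling_rate_hz=sampling_rate_hz,
                noise_sigma=noise_sigma,
                seed=_sub_seed(seed, counter),
                max_incidence_deg=max_incidence_deg,
            )
            data[i, j] = ascan.samples
            counter += 1
    return Sinogram(
        ascans=data,
        angles_deg=angles,
        elements=plan.element_indices,
        sampling_rate_hz=sampling_rate_hz,
        geometry=geom,
        medium=medium,
        seed=seed,
        interval_deg=plan.interval_deg,
    )
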