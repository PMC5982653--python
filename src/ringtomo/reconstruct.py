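"""Six-step horizontal-slice reconstruction from a circular-scan sinogram.

The pipeline follows the acquisition-side processing order exactly:

1. assemble the chosen element's A-scans as columns of a sample x angle matrix;
2. zero-phase Butterworth bandpass around the pulse centre frequency;
3. envelope detection (magnitude of the analytic signal);
4. logarithmic compression to a fixed dynamic range, normalised to [0, 1];
5. half-depth truncation, then polar-to-Cartesian scan conversion about the
   rotation-table centre (each sample deposited at range r = c i / (2 fs)
   along its beam, colliding deposits combined by maximum);
6. morphological post-processing: bicubic filling of uncovered pixels between
   covered ones, then grayscale dilation ("inflation") with a disk.

Because every element sees the nearer half of the field and the opposing
element the other half, each A-scan is only used out to the ring radius
(half depth), yet the assembled slice covers the full diameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import griddata
from scipy.signal import butter, hilbert, sosfiltfilt, sosfilt
from skimage.morphology import dilation, disk

from .errors import ConfigurationError
from .geometry import RingGeometry
from .simulate import Sinogram

__all__ = [
    "FilterSpec",
    "CompressionSpec",
    "GridSpec",
    "MorphSpec",
    "SliceImage",
    "assemble_columns",
    "bandpass",
    "envelope",
    "log_compress",
    "truncate_half_depth",
    "scan_convert",
    "morph_process",
    "reconstruct_slice",
    "DEFAULT_DEAD_ZONE_S",
]

logger = logging.getLogger(__name__)

DEFAULT_DEAD_ZONE_S = 2e-6  # transmit-breakthrough suppression after t = 0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass design: order-4, +/-50% band around 3.5 MHz,
    applied forward-backward (zero phase) so echo delays are not shifted."""

    order: int = 4
    band_low_hz: float = 1.75e6
    band_high_hz: float = 5.25e6
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ConfigurationError("need 0 < band_low_hz < band_high_hz")


@dataclass(frozen=True)
class CompressionSpec:
    """Log-compression dynamic range in dB (values below -DR map to 0)."""

    dynamic_range_db: float = 50.0

    def __post_init__(self) -> None:
        if self.dynamic_range_db <= 0:
            raise ConfigurationError("dynamic_range_db must be > 0")


@dataclass(frozen=True)
class GridSpec:
    """Cartesian output grid, centred on the rotation axis."""

    pixel_size_mm: float = 0.5
    extent_mm: float = 180.0

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0 or self.extent_mm <= 0:
            raise ConfigurationError("pixel_size_mm and extent_mm must be > 0")

    @property
    def n_pixels(self) -> int:
        return int(round(self.extent_mm / self.pixel_size_mm))


@dataclass(frozen=True)
class MorphSpec:
    """Morphological post-processing: bicubic fill + disk dilation radius."""

    fill_method: str = "bicubic"
    dilation_radius_px: int = 2

    def __post_init__(self) -> None:
        if self.fill_method not in ("bicubic",):
            raise ConfigurationError(f"unknown fill_method {self.fill_method!r}")
        if self.dilation_radius_px < 0:
            raise ConfigurationError("dilation_radius_px must be >= 0")


@dataclass(frozen=True)
class SliceImage:
    """Reconstructed Cartesian slice, values in [0, 1].

    Row 0 is +y (top), column 0 is -x (left); the rotation axis sits at the
    array centre. ``mask`` flags pixels that received at least one nonzero
    deposit during scan conversion; ``dilation_radius_px`` records the
    inflation applied by the morphology stage (0 before it) so measurement
    code can compensate for the known extensive bias of dilation;
    ``dynamic_range_db`` records the log-compression range so calipers can
    convert pixel thresholds back to echo-amplitude ratios.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    element: int
    mask: np.ndarray
    ring_radius_mm: float | None = None
    dilation_radius_px: int = 0
    dynamic_range_db: float | None = None

    def __post_init__(self) -> None:
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask shapes differ")
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("slice must be a square 2-D image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def pixel_to_xy_mm(self, row: float, col: float) -> tuple[float, float]:
        c0 = (self.pixels.shape[0] - 1) / 2.0
        return ((col - c0) * self.pixel_size_mm, (c0 - row) * self.pixel_size_mm)


def assemble_columns(
    sinogram: Sinogram, element: int
) -> tuple[np.ndarray, np.ndarray]:
    """Step 1: matrix whose j-th column is the A-scan at the j-th angle.

    Returns (sample x angle matrix, angles in increasing order). Raises
    KeyError if the element was not acquired.
    """
    col = sinogram.element_column(element)
    return sinogram.ascans[:, col, :].T.copy(), np.asarray(
        sinogram.angles_deg, dtype=float
    )


def bandpass(
    matrix: np.ndarray, sampling_rate_hz: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Step 2: column-wise Butterworth bandpass (zero-phase by default)."""
    nyquist = sampling_rate_hz / 2.0
    if spec.band_high_hz >= nyquist:
        raise ConfigurationError(
            f"band_high_hz={spec.band_high_hz:g} is at or above the Nyquist "
            f"frequency {nyquist:g}"
        )
    sos = butter(
        spec.order,
        [spec.band_low_hz, spec.band_high_hz],
        btype="bandpass",
        fs=sampling_rate_hz,
        output="sos",
    )
    if spec.zero_phase:
        return sosfiltfilt(sos, matrix, axis=0)
    return sosfilt(sos, matrix, axis=0)


def envelope(matrix: np.ndarray) -> np.ndarray:
    """Step 3: column-wise magnitude of the analytic signal."""
    return np.abs(hilbert(matrix, axis=0))


def log_compress(
    matrix: np.ndarray, spec: CompressionSpec = CompressionSpec()
) -> np.ndarray:
    """Step 4: y = clip((20 log10(x / x_max) + DR) / DR, 0, 1).

    All-zero input maps to all-zero output; negative input is a domain error.
    """
    if np.any(matrix < 0):
        raise ValueError("log compression requires non-negative input")
    x_max = float(matrix.max(initial=0.0))
    if x_max == 0.0:
        return np.zeros_like(matrix, dtype=float)
    dr = spec.dynamic_range_db
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(matrix / x_max)
    return np.clip((db + dr) / dr, 0.0, 1.0)


def _half_depth_max_index(
    sampling_rate_hz: float, sound_speed_m_s: float, ring_diameter_mm: float
) -> int:
    return math.ceil(
        2.0 * (ring_diameter_mm / 2.0 * 1e-3) / sound_speed_m_s * sampling_rate_hz
    )


def truncate_half_depth(
    matrix: np.ndarray,
    sampling_rate_hz: float,
    sound_speed_m_s: float,
    ring_diameter_mm: float,
    dead_zone_s: float = DEFAULT_DEAD_ZONE_S,
) -> np.ndarray:
    """Step 5a: zero samples whose one-way range exceeds the ring radius.

    Each element only needs the nearer half of the field; the opposing
    element covers the rest. A short dead zone after t = 0 is also zeroed to
    suppress the transmit artifact.
    """
    out = np.array(matrix, dtype=float, copy=True)
    if math.isfinite(ring_diameter_mm):
        i_max = _half_depth_max_index(
            sampling_rate_hz, sound_speed_m_s, ring_diameter_mm
        )
        if i_max + 1 < out.shape[0]:
            out[i_max + 1 :] = 0.0
    n_dead = int(math.floor(dead_zone_s * sampling_rate_hz))
    if n_dead > 0:
        out[: min(n_dead, out.shape[0])] = 0.0
    return out


def scan_convert(
    matrix: np.ndarray,
    angles_deg: np.ndarray,
    geom: RingGeometry,
    sampling_rate_hz: float,
    sound_speed_m_s: float,
    grid: GridSpec = GridSpec(),
    element: int = 1,
    combine: str = "max",
) -> SliceImage:
    """Step 5b: deposit each beam sample on the Cartesian grid.

    The sample at one-way range r = c i / (2 fs) along the beam at angle
    theta lands at T(theta) + r * b(theta), with T the transducer position
    and b the unit vector toward the rotation axis; a sample at r = ring
    radius therefore lands at the image centre. Colliding deposits combine
    by maximum (or mean); pixels receiving a nonzero deposit are flagged in
    the coverage mask.
    """
    if combine not in ("max", "mean"):
        raise ConfigurationError(f"unknown combine rule {combine!r}")
    n = grid.n_pixels
    img = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    sums = np.zeros((n, n)) if combine == "mean" else None
    counts = np.zeros((n, n)) if combine == "mean" else None

    # every sample is offered for deposit (samples past the ring radius land
    # beyond the image centre); the half-depth truncation stage decides what
    # is actually nonzero
    idx = np.arange(matrix.shape[0])
    r_mm = sound_speed_m_s * idx / (2.0 * sampling_rate_hz) * 1e3
    c0 = (n - 1) / 2.0
    ring_r = geom.ring_radius_mm

    for j, theta_deg in enumerate(np.asarray(angles_deg, dtype=float)):
        theta = math.radians(theta_deg)
        # in-plane transducer position and beam direction
        x = ring_r * math.cos(theta) - r_mm * math.cos(theta)
        y = ring_r * math.sin(theta) - r_mm * math.sin(theta)
        cols = np.round(c0 + x / grid.pixel_size_mm).astype(int)
        rows = np.round(c0 - y / grid.pixel_size_mm).astype(int)
        vals = matrix[idx, j]
        ok = (rows >= 0) & (rows < n) & (cols >= 0) & (cols < n) & (vals > 0)
        if not np.any(ok):
            continue
        rr, cc, vv = rows[ok], cols[ok], vals[ok]
        if combine == "max":
            np.maximum.at(img, (rr, cc), vv)
        else:
            np.add.at(sums, (rr, cc), vv)
            np.add.at(counts, (rr, cc), 1.0)
        mask[rr, cc] = True

    if combine == "mean":
        nz = counts > 0
        img[nz] = sums[nz] / counts[nz]
    return SliceImage(
        pixels=img,
        pixel_size_mm=grid.pixel_size_mm,
        element=element,
        mask=mask,
        ring_radius_mm=ring_r,
        dilation_radius_px=0,
    )


def morph_process(image: SliceImage, spec: MorphSpec = MorphSpec()) -> SliceImage:
    """Step 6: bicubic filling of uncovered pixels, then disk dilation.

    Uncovered pixels lying between covered ones (inside the convex hull of
    the coverage, i.e. the scanned ring interior) are filled by bicubic
    interpolation of the covered neighbours; pixels outside the hull are left
    untouched so no halo leaks outside the ring. The subsequent grayscale
    dilation ("inflation") closes residual sampling gaps; its radius is
    recorded on the slice so calipers can compensate. A wholly empty mask is
    returned unchanged with a warning.
    """
    if not image.mask.any():
        logger.warning("morph_process: empty coverage mask, image returned unchanged")
        return image
    pixels = np.array(image.pixels, copy=True)
    uncovered = ~image.mask
    if uncovered.any():
        pts = np.argwhere(image.mask)
        targets = np.argwhere(uncovered)
        filled = griddata(
            pts, pixels[image.mask], targets, method="cubic"
        )
        good = np.isfinite(filled)
        pixels[targets[good, 0], targets[good, 1]] = filled[good]
    if spec.dilation_radius_px > 0:
        pixels = dilation(pixels, disk(spec.dilation_radius_px))
    return replace(
        image,
        pixels=np.clip(pixels, 0.0, 1.0),
        dilation_radius_px=spec.dilation_radius_px,
    )


def reconstruct_slice(
    sinogram: Sinogram,
    element: int,
    filter_spec: FilterSpec = FilterSpec(),
    compression_spec: CompressionSpec = CompressionSpec(),
    grid_spec: GridSpec = GridSpec(),
    morph_spec: MorphSpec = MorphSpec(),
    dead_zone_s: float = DEFAULT_DEAD_ZONE_S,
    combine: str = "max",
    stage_trace: list | None = None,
) -> SliceImage:
    """Run the full six-step reconstruction for one element.

    Steps are applied strictly in order: assemble -> bandpass -> envelope ->
    log-compress -> half-depth truncation -> scan conversion -> morphology.
    If ``stage_trace`` is a list, (stage name, stage output) pairs are
    appended for inspection. Deterministic given its inputs.
    """

    def record(name, value):
        if stage_trace is not None:
            stage_trace.append((name, value))
        return value

    matrix, angles = assemble_columns(sinogram, element)
    record("assemble_columns", matrix)
    matrix = record(
        "bandpass", bandpass(matrix, sinogram.sampling_rate_hz, filter_spec)
    )
    matrix = record("envelope", envelope(matrix))
    matrix = record("log_compress", log_compress(matrix, compression_spec))
    matrix = record(
        "truncate_half_depth",
        truncate_half_depth(
            matrix,
            sinogram.sampling_rate_hz,
            sinogram.medium.sound_speed_m_s,
            sinogram.geometry.ring_diameter_mm,
            dead_zone_s=dead_zone_s,
        ),
    )
    image = record(
        "scan_convert",
        scan_convert(
            matrix,
            angles,
            sinogram.geometry,
            sinogram.sampling_rate_hz,
            sinogram.medium.sound_speed_m_s,
            grid_spec,
            element=element,
            combine=combine,
        ),
    )
    image = replace(image, dynamic_range_db=compression_spec.dynamic_range_db)
    return record("morph_process", morph_process(image, morph_spec))
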