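"""Pulse-echo ranging and image-based size measurement.

Ranging uses the time-of-flight relation s = t c / 2: the round-trip delay to
the envelope peak, times the sound speed, halved. An object spanning the ring
between two opposing transducers has size D - d1 - d2, with D the ring
diameter and d1, d2 the two one-way echo distances. On reconstructed slices a
caliper measurement binarizes at a fraction of the image maximum, compensates
the reconstruction's recorded inflation (grayscale dilation is extensive, so
the same disk is eroded back before measuring), and sizes the selected
connected component by its hole-filled equivalent-circle diameter, with
min/max chords through the centroid reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.signal import hilbert
from skimage.measure import label, regionprops
from skimage.morphology import convex_hull_image, disk

from .errors import MeasurementError
from .reconstruct import DEFAULT_DEAD_ZONE_S, SliceImage
from .simulate import AScan

__all__ = [
    "RangeEstimate",
    "SizeEstimate",
    "tof_to_distance",
    "estimate_tof",
    "opposing_pair_size",
    "caliper_diameter",
    "relative_error",
]


@dataclass(frozen=True)
class RangeEstimate:
    """TOF ranging result; ``distance_mm`` is None when no echo was found."""

    tof_s: float | None
    distance_mm: float | None
    peak_amplitude: float

    @property
    def no_echo(self) -> bool:
        return self.distance_mm is None


@dataclass(frozen=True)
class SizeEstimate:
    """A size measurement with its provenance."""

    size_mm: float
    method: str  # "opposing_tof" or "caliper"
    details: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size_mm < 0:
            raise MeasurementError("size must be >= 0")


def tof_to_distance(t_s: float, c_m_s: float) -> float:
    """One-way distance in mm from a round-trip delay: s = t c / 2."""
    if t_s < 0:
        raise ValueError("time of flight must be >= 0")
    if c_m_s <= 0:
        raise ValueError("sound speed must be > 0")
    return t_s * c_m_s / 2.0 * 1e3


def estimate_tof(
    ascan: AScan,
    sound_speed_m_s: float,
    dead_zone_s: float = DEFAULT_DEAD_ZONE_S,
    picker: str = "argmax",
    threshold: float = 0.5,
) -> RangeEstimate:
    """Locate the echo in an A-scan and convert to distance.

    The default picker takes the global envelope maximum after the dead zone
    (matches single-echo traces); ``picker="first_crossing"`` instead takes
    the first sample whose envelope exceeds ``threshold`` times the maximum,
    for layered targets. An A-scan that is identically zero beyond the dead
    zone yields a no-echo result rather than an error.
    """
    if ascan.n_samples == 0:
        raise ValueError("A-scan is empty")
    env = np.abs(hilbert(ascan.samples))
    start = int(math.floor(dead_zone_s * ascan.sampling_rate_hz))
    if start >= len(env):
        return RangeEstimate(None, None, 0.0)
    env = env.copy()
    env[:start] = 0.0
    peak = float(env.max())
    if peak == 0.0:
        return RangeEstimate(None, None, 0.0)
    if picker == "argmax":
        i = int(np.argmax(env))
    elif picker == "first_crossing":
        above = np.nonzero(env >= threshold * peak)[0]
        i = int(above[0])
    else:
        raise ValueError(f"unknown picker {picker!r}")
    tof = i / ascan.sampling_rate_hz
    return RangeEstimate(tof, tof_to_distance(tof, sound_speed_m_s), peak)


def opposing_pair_size(
    d1_mm: float, d2_mm: float, ring_diameter_mm: float = 180.0
) -> SizeEstimate:
    """Object extent along a diameter from two opposing echo distances.

    size = D - d1 - d2; raises MeasurementError when the distances overlap
    (d1 + d2 > D), which cannot happen for a consistent echo pair.
    """
    if d1_mm + d2_mm > ring_diameter_mm:
        raise MeasurementError(
            f"opposing distances {d1_mm} + {d2_mm} mm exceed the ring "
            f"diameter {ring_diameter_mm} mm"
        )
    return SizeEstimate(
        size_mm=ring_diameter_mm - d1_mm - d2_mm,
        method="opposing_tof",
        details={"d1_mm": d1_mm, "d2_mm": d2_mm, "ring_diameter_mm": ring_diameter_mm},
    )


def _component_chords(
    mask: np.ndarray, centroid_rc: tuple[float, float], pixel_size_mm: float
) -> dict[str, float]:
    """Min/max chord lengths through the centroid over 1-degree directions."""
    r0, c0 = centroid_rc
    n_rows, n_cols = mask.shape
    step = 0.25
    chords = []
    for ang_deg in range(0, 180):
        a = math.radians(ang_deg)
        dr, dc = -math.sin(a), math.cos(a)
        half = []
        for s in (1.0, -1.0):
            t = 0.0
            while True:
                t += step
                rr = int(round(r0 + s * t * dr))
                cc = int(round(c0 + s * t * dc))
                if not (0 <= rr < n_rows and 0 <= cc < n_cols) or not mask[rr, cc]:
                    break
            half.append(t - step)
        chords.append((half[0] + half[1]) * pixel_size_mm)
    chords = np.asarray(chords)
    return {
        "min_chord_mm": float(chords.min()),
        "max_chord_mm": float(chords.max()),
        "min_chord_angle_deg": float(int(np.argmin(chords))),
        "max_chord_angle_deg": float(int(np.argmax(chords))),
    }


def _binarize(image: SliceImage, pixel_threshold: float, correct_dilation: bool):
    mask = image.pixels >= pixel_threshold
    if correct_dilation and image.dilation_radius_px > 0:
        mask = binary_erosion(mask, structure=disk(image.dilation_radius_px))
    return mask


def _select_region(regions, select: str, shape, min_area_px: int):
    big = [r for r in regions if r.area >= min_area_px]
    if not big:
        big = regions
    c0 = (shape[0] - 1) / 2.0
    if select == "largest":
        return max(big, key=lambda r: r.area_filled)
    if select == "innermost":
        def outermost_radius(r):
            d = np.hypot(r.coords[:, 0] - c0, r.coords[:, 1] - c0)
            return float(d.max())
        return min(big, key=outermost_radius)
    raise ValueError(f"unknown select rule {select!r}")


def _inner_component_mask(
    image: SliceImage,
    threshold: float,
    correct_dilation: bool,
    min_area_px: int,
) -> tuple[np.ndarray, int] | None:
    """Filled mask of a central structure inside the outermost bright one.

    Mirrors how a sonographer calipers a lesion inside an organ: first find
    the enclosing boundary at ``threshold`` x the global peak amplitude, then
    cut the enclosed region at ``threshold`` of the way from its background
    level to its own peak (the inner structure is fainter — deeper, more
    attenuated — so a global threshold would either miss it or drown in the
    scan-conversion noise floor near the rotation axis). The search is
    restricted to the central half of the enclosing boundary's radius, which
    assumes a roughly centred inclusion. Because the specular outline of a
    convex inclusion arrives as a dotted ring at finite angular sampling and
    finite echo SNR, the detected fragments are completed by their convex
    hull rather than by hole filling. Returns (filled mask, fragment count)
    or None.
    """
    pixels = image.pixels
    offset = 20.0 * math.log10(threshold) / image.dynamic_range_db
    outer = _binarize(image, float(pixels.max()) + offset, correct_dilation)
    if not outer.any():
        return None
    hull = convex_hull_image(outer)
    hull_centroid = np.argwhere(hull).mean(axis=0)
    hull_radius_px = math.sqrt(hull.sum() / math.pi)
    n_rows, n_cols = pixels.shape
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    central = (
        np.hypot(rr - hull_centroid[0], cc - hull_centroid[1])
        <= 0.5 * hull_radius_px
    )
    central &= ~outer
    if not central.any():
        return None
    # The inclusion is faint relative to the scan-conversion noise floor, so
    # cut at `threshold` of the way from the background level (median of the
    # central region) to the central peak, in display (compressed) units —
    # the half-maximum-above-background rule a reader applies on a B-mode
    # display.
    background = float(np.median(pixels[central]))
    interior_peak = float(pixels[central].max())
    if interior_peak <= background:
        return None
    level = background + threshold * (interior_peak - background)
    mask = _binarize(image, level, correct_dilation) & central
    if not mask.any():
        return None
    # the outline arrives as small dots (one per beam); only discard
    # isolated single-pixel speckle
    regions = [
        r
        for r in regionprops(label(mask, connectivity=2))
        if r.area >= min(2, min_area_px)
    ]
    if not regions:
        return None
    fragments = np.zeros_like(mask)
    for r in regions:
        fragments[tuple(r.coords.T)] = True
    return convex_hull_image(fragments), len(regions)


def caliper_diameter(
    image: SliceImage,
    threshold: float = 0.5,
    select: str = "largest",
    correct_dilation: bool = True,
    min_area_px: int = 5,
) -> SizeEstimate | None:
    """Caliper measurement of a bright component in a reconstructed slice.

    Segmentation binarizes at ``threshold`` times the image maximum and
    erodes back the inflation recorded on the slice (dilation with a flat
    disk commutes with thresholding, so the erosion restores the
    pre-inflation support). One connected component is selected —
    ``select="largest"`` (greatest hole-filled area, the default) or
    ``"innermost"`` (closest to the rotation axis, e.g. the mass inside a
    breast slice); components below ``min_area_px`` pixels are ignored when
    larger ones exist (interpolation-overshoot speckle). On log-compressed
    slices the innermost path instead measures a centred inclusion
    hierarchically, re-thresholding relative to the interior of the
    enclosing structure (see ``_inner_component_mask``).

    On log-compressed slices (``dynamic_range_db`` set) the selected
    component is then re-thresholded at ``threshold`` times its own peak
    *echo amplitude* — the conventional -6 dB caliper at the default 0.5 —
    since a fixed pixel threshold on compressed data would cut far down the
    echo's skirt and inflate every size.

    Because a solid object images as its specular outline, the component is
    hole-filled before sizing; the reported size is the equivalent-circle
    diameter 2 sqrt(area / pi), with min/max chords through the centroid in
    ``details`` (the minimum chord is the face-to-face extent of a square).
    Returns None when no pixel clears the threshold ("no object").
    """
    pixels = image.pixels
    peak = float(pixels.max(initial=0.0))
    if peak <= 0.0:
        return None
    n_components = 1
    if select == "innermost" and image.dynamic_range_db is not None:
        inner = _inner_component_mask(image, threshold, correct_dilation, min_area_px)
        if inner is None:
            return None
        comp, n_components = inner
        area_px = float(comp.sum())
    else:
        mask = _binarize(image, threshold * peak, correct_dilation)
        if not mask.any():
            return None
        regions = regionprops(label(mask, connectivity=2))
        if not regions:
            return None
        n_components = len(regions)
        region = _select_region(regions, select, pixels.shape, min_area_px)

        if image.dynamic_range_db is not None:
            # refine at `threshold` x the component's own peak amplitude:
            # a ratio rho in amplitude is an offset 20 log10(rho) / DR in
            # compressed pixel units
            comp_peak = float(pixels[tuple(region.coords.T)].max())
            offset = 20.0 * math.log10(threshold) / image.dynamic_range_db
            refined_mask = _binarize(image, comp_peak + offset, correct_dilation)
            refined_regions = regionprops(label(refined_mask, connectivity=2))
            seed_coords = set(map(tuple, region.coords))
            overlapping = [
                r
                for r in refined_regions
                if seed_coords.intersection(map(tuple, r.coords))
            ]
            if overlapping:
                region = max(overlapping, key=lambda r: r.area)

        comp = np.zeros_like(mask)
        rmin, cmin, rmax, cmax = region.bbox
        comp[rmin:rmax, cmin:cmax] = region.image_filled
        area_px = float(region.area_filled)
    eq_diam_mm = 2.0 * math.sqrt(area_px / math.pi) * image.pixel_size_mm
    centroid = tuple(np.argwhere(comp).mean(axis=0))
    chords = _component_chords(comp, centroid, image.pixel_size_mm)
    x_mm, y_mm = image.pixel_to_xy_mm(centroid[0], centroid[1])
    return SizeEstimate(
        size_mm=eq_diam_mm,
        method="caliper",
        details={
            "area_mm2": area_px * image.pixel_size_mm**2,
            "centroid_xy_mm": (x_mm, y_mm),
            "equivalent_diameter_mm": eq_diam_mm,
            "threshold": threshold,
            "n_components": n_components,
            "select": select,
            "dilation_corrected_px": (
                image.dilation_radius_px if correct_dilation else 0
            ),
            **chords,
        },
    )


def relative_error(measured_mm: float, nominal_mm: float) -> float:
    """Relative sizing error in percent: 100 |measured - nominal| / nominal."""
    if nominal_mm <= 0:
        raise ValueError("nominal size must be > 0")
    return 100.0 * abs(measured_mm - nominal_mm) / nominal_mm
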