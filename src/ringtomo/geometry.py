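"""Rotating ring acquisition geometry.

Four vertical 128-element linear arrays sit on a 180 mm ring at 0/90/180/270
degrees. A rotary table turns the assembly through 90 degrees in steps of a
chosen interval (table precision 0.05 degrees), so the union of the four
arrays' sectors covers the full circle. Each element fires a pulse toward the
rotation axis and listens for its own echo (monostatic pulse-echo), one A-scan
per (beam angle, element) pair.

Conventions
-----------
* Angles are in degrees, counter-clockwise from the +x axis, stored in
  [0, 360).
* Element indices are 1-based (element 1 .. 128) at every public interface.
* z increases downward from element 1 at z = 0, one element pitch per element.
* Lengths are millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, PrecisionError

__all__ = [
    "RingGeometry",
    "ScanPlan",
    "build_full_circle_plan",
    "transducer_position",
    "beam_direction",
]

_ANGLE_DECIMALS = 6  # deduplication tolerance for angles shared between arrays


@dataclass(frozen=True)
class RingGeometry:
    """Fixed geometry of the rotating ring scanner.

    Parameters
    ----------
    ring_diameter_mm : float
        Distance between opposing transducer faces (default 180 mm).
    n_arrays : int
        Number of linear arrays on the ring (default 4).
    array_base_angles_deg : tuple of float
        Rest angular position of each array, degrees CCW from +x.
    n_elements : int
        Elements per linear array (default 128).
    element_pitch_mm : float
        Vertical spacing between adjacent elements (default 1 mm).
    rotation_span_deg : float
        Angle the table rotates through (default 90, so four arrays tile
        the full circle).
    min_interval_deg : float
        Rotary-table angular precision; the finest usable step (default 0.05).
    """

    ring_diameter_mm: float = 180.0
    n_arrays: int = 4
    array_base_angles_deg: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    n_elements: int = 128
    element_pitch_mm: float = 1.0
    rotation_span_deg: float = 90.0
    min_interval_deg: float = 0.05

    def __post_init__(self) -> None:
        if self.ring_diameter_mm <= 0:
            raise GeometryError("ring_diameter_mm must be > 0")
        if self.element_pitch_mm <= 0:
            raise GeometryError("element_pitch_mm must be > 0")
        if self.n_elements < 1:
            raise GeometryError("n_elements must be >= 1")
        if self.n_arrays < 1:
            raise GeometryError("n_arrays must be >= 1")
        if len(self.array_base_angles_deg) != self.n_arrays:
            raise GeometryError(
                f"expected {self.n_arrays} base angles, got "
                f"{len(self.array_base_angles_deg)}"
            )
        wrapped = sorted(a % 360.0 for a in self.array_base_angles_deg)
        if len(set(round(a, _ANGLE_DECIMALS) for a in wrapped)) != self.n_arrays:
            raise GeometryError("array base angles must be distinct modulo 360")
        if self.n_arrays > 1:
            gaps = np.diff(wrapped + [wrapped[0] + 360.0])
            if not np.allclose(gaps, 360.0 / self.n_arrays, atol=1e-9):
                raise GeometryError("array base angles must be evenly spaced")
            if not math.isclose(
                self.rotation_span_deg * self.n_arrays, 360.0, rel_tol=1e-9
            ):
                raise GeometryError(
                    "rotation_span_deg x n_arrays must cover 360 degrees "
                    "for evenly spaced arrays"
                )

    @property
    def ring_radius_mm(self) -> float:
        return self.ring_diameter_mm / 2.0


@dataclass(frozen=True)
class ScanPlan:
    """An enumerated circular acquisition: which angles, which elements.

    ``angles_deg`` are the absolute beam angles (all arrays merged,
    deduplicated modulo 360, increasing); ``acquisitions`` lists the
    (angle, element) pairs in acquisition order (angle-major).
    """

    interval_deg: float
    angles_deg: tuple[float, ...]
    element_indices: tuple[int, ...]
    acquisitions: tuple[tuple[float, int], ...] = field(repr=False)

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def n_acquisitions(self) -> int:
        return len(self.acquisitions)


def build_full_circle_plan(
    geom: RingGeometry,
    interval_deg: float,
    elements: list[int] | tuple[int, ...] | None = None,
) -> ScanPlan:
    """Enumerate a full-circle scan at the given angular interval.

    Each array sweeps the half-open sector [base, base + rotation_span), so an
    absolute angle shared by adjacent arrays at a sector boundary is acquired
    exactly once; a full-circle plan therefore holds 360/interval angles
    (7200 at the 0.05 degree table precision).

    Raises
    ------
    PrecisionError
        If ``interval_deg`` is below the table precision.
    GeometryError
        If ``interval_deg`` does not divide the rotation span.
    IndexError
        If an element index is out of range.
    """
    if interval_deg < geom.min_interval_deg - 1e-12:
        raise PrecisionError(
            f"interval {interval_deg} deg is below the rotary-table precision "
            f"of {geom.min_interval_deg} deg"
        )
    n_steps_f = geom.rotation_span_deg / interval_deg
    n_steps = round(n_steps_f)
    if n_steps < 1 or not math.isclose(
        n_steps * interval_deg, geom.rotation_span_deg, rel_tol=1e-9
    ):
        raise GeometryError(
            f"interval {interval_deg} deg does not divide the rotation span "
            f"of {geom.rotation_span_deg} deg"
        )

    if elements is None:
        elements = list(range(1, geom.n_elements + 1))
    for e in elements:
        if not 1 <= e <= geom.n_elements:
            raise IndexError(
                f"element {e} out of range 1..{geom.n_elements}"
            )

    offsets = np.arange(n_steps) * interval_deg
    raw = np.concatenate(
        [(base + offsets) % 360.0 for base in geom.array_base_angles_deg]
    )
    angles = np.unique(np.round(raw, _ANGLE_DECIMALS))
    plan = ScanPlan(
        interval_deg=float(interval_deg),
        angles_deg=tuple(float(a) for a in angles),
        element_indices=tuple(int(e) for e in elements),
        acquisitions=tuple(
            (float(a), int(e)) for a in angles for e in elements
        ),
    )
    return plan


def transducer_position(
    geom: RingGeometry, beam_angle_deg: float, element: int
) -> np.ndarray:
    """Face-centre position (x, y, z) in mm of an element at a beam angle.

    x = R cos(theta), y = R sin(theta) with R the ring radius; z = (element-1)
    element pitches below the top element plane.
    """
    if not 1 <= element <= geom.n_elements:
        raise IndexError(f"element {element} out of range 1..{geom.n_elements}")
    theta = math.radians(beam_angle_deg)
    r = geom.ring_radius_mm
    return np.array(
        [
            r * math.cos(theta),
            r * math.sin(theta),
            (element - 1) * geom.element_pitch_mm,
        ]
    )


def beam_direction(geom: RingGeometry, beam_angle_deg: float) -> np.ndarray:
    """In-plane unit vector from the transducer toward the rotation axis."""
    theta = math.radians(beam_angle_deg)
    return np.array([-math.cos(theta), -math.sin(theta), 0.0])
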