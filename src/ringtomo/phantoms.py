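"""Acoustic phantoms: media, pulses, geometric reflectors and ray crossings.

A phantom is an ordered collection of geometric reflectors (cylinders,
cuboids, ellipsoids) immersed in water. A pulse fired along a straight ray
produces an echo at every interface crossing; the simulator only needs, for
each crossing, its one-way distance, the incidence angle against the surface
normal, the surface reflectivity and how much of the path ran through tissue
(everything beyond the first interface) versus water (everything before it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .geometry import RingGeometry

__all__ = [
    "Medium",
    "Pulse",
    "Crossing",
    "Reflector",
    "Cylinder",
    "Cuboid",
    "Ellipsoid",
    "Phantom",
    "interface_crossings",
    "make_breast_phantom",
]

_TOL = 1e-9  # mm-scale tolerance; tangent hits inside this are dropped


@dataclass(frozen=True)
class Medium:
    """Propagation medium: sound speed and frequency-linear attenuation.

    ``sound_speed_m_s`` defaults to 1540 m/s (the tank is held at 32 degrees C
    to push the water speed toward physiologic values). Attenuations are in
    dB/(cm MHz); water is treated as lossless at 3.5 MHz over a 9 cm half
    depth, soft tissue defaults to 0.65, the midpoint of the 0.6-0.7 range
    quoted for soft tissue.
    """

    sound_speed_m_s: float = 1540.0
    water_attenuation_db_cm_mhz: float = 0.0
    tissue_attenuation_db_cm_mhz: float = 0.65

    def __post_init__(self) -> None:
        if self.sound_speed_m_s <= 0:
            raise ValueError("sound_speed_m_s must be > 0")
        if self.water_attenuation_db_cm_mhz < 0 or self.tissue_attenuation_db_cm_mhz < 0:
            raise ValueError("attenuation coefficients must be >= 0")


@dataclass(frozen=True)
class Pulse:
    """Transmit pulse: Gaussian-modulated sinusoid.

    Centre frequency defaults to 3.5 MHz; the -6 dB fractional bandwidth
    (0.6) is a transducer impulse-response surrogate. ``repetition_interval_s``
    is carried as acquisition metadata only.
    """

    center_frequency_hz: float = 3.5e6
    fractional_bandwidth: float = 0.6
    amplitude: float = 1.0
    repetition_interval_s: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional_bandwidth must be in (0, 2)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class Crossing:
    """One ray/interface crossing.

    distance_mm is the one-way path length from the ray origin;
    incidence_deg the angle between the ray and the inward surface normal;
    tissue_path_mm how much of distance_mm lies beyond the first interface
    (attenuated as tissue rather than water).
    """

    distance_mm: float
    incidence_deg: float
    reflectivity: float
    tissue_path_mm: float = 0.0


class Reflector:
    """Base class: a closed surface with a reflectivity in (0, 1]."""

    reflectivity: float

    def _check(self) -> None:
        if not 0 < self.reflectivity <= 1:
            raise ValueError("reflectivity must be in (0, 1]")

    def ray_hits(
        self, origin: np.ndarray, direction: np.ndarray
    ) -> list[tuple[float, np.ndarray]]:
        """All (t, inward unit normal) crossings of the ray with the surface,
        t > 0, unsorted. Tangent grazes are dropped."""
        raise NotImplementedError

    def max_xy_radius(self) -> float:
        """Largest distance of any surface point from the z axis (containment checks)."""
        raise NotImplementedError


@dataclass(frozen=True)
class Cylinder(Reflector):
    """Vertical circular cylinder (axis parallel to z)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    height_mm: float
    reflectivity: float = 0.95

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.height_mm <= 0:
            raise ValueError("cylinder dimensions must be > 0")
        self._check()

    def ray_hits(self, origin, direction):
        c = np.asarray(self.center_mm, dtype=float)
        o = np.asarray(origin, dtype=float) - c
        d = np.asarray(direction, dtype=float)
        hits: list[tuple[float, np.ndarray]] = []
        half_h = self.height_mm / 2.0
        a = d[0] * d[0] + d[1] * d[1]
        if a > _TOL:
            b = 2.0 * (o[0] * d[0] + o[1] * d[1])
            cc = o[0] * o[0] + o[1] * o[1] - self.radius_mm**2
            disc = b * b - 4.0 * a * cc
            if disc > _TOL * self.radius_mm**2:
                sq = math.sqrt(disc)
                for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                    if t > _TOL:
                        p = o + t * d
                        if abs(p[2]) <= half_h:
                            n_out = np.array([p[0], p[1], 0.0])
                            n_out /= np.linalg.norm(n_out)
                            hits.append((t, -n_out))
        if abs(d[2]) > _TOL:
            for sign in (-1.0, 1.0):
                t = (sign * half_h - o[2]) / d[2]
                if t > _TOL:
                    p = o + t * d
                    if p[0] ** 2 + p[1] ** 2 < self.radius_mm**2:
                        hits.append((t, np.array([0.0, 0.0, -sign])))
        return hits

    def max_xy_radius(self) -> float:
        cx, cy, _ = self.center_mm
        return math.hypot(cx, cy) + self.radius_mm


@dataclass(frozen=True)
class Cuboid(Reflector):
    """Axis-aligned box, optionally yawed about its own vertical axis."""

    center_mm: tuple[float, float, float]
    edges_mm: tuple[float, float, float]
    yaw_deg: float = 0.0
    reflectivity: float = 0.95

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.edges_mm):
            raise ValueError("cuboid edges must be > 0")
        self._check()

    def _rot(self) -> np.ndarray:
        a = math.radians(self.yaw_deg)
        ca, sa = math.cos(a), math.sin(a)
        return np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])

    def ray_hits(self, origin, direction):
        rot = self._rot()
        o = rot.T @ (np.asarray(origin, dtype=float) - np.asarray(self.center_mm))
        d = rot.T @ np.asarray(direction, dtype=float)
        half = np.asarray(self.edges_mm, dtype=float) / 2.0
        hits: list[tuple[float, np.ndarray]] = []
        for ax in range(3):
            if abs(d[ax]) <= _TOL:
                continue  # ray parallel to this face pair (tangent dropped)
            for sign in (-1.0, 1.0):
                t = (sign * half[ax] - o[ax]) / d[ax]
                if t <= _TOL:
                    continue
                p = o + t * d
                others = [i for i in range(3) if i != ax]
                if all(abs(p[i]) < half[i] - _TOL for i in others):
                    n_out_local = np.zeros(3)
                    n_out_local[ax] = sign
                    hits.append((t, -(rot @ n_out_local)))
        return hits

    def max_xy_radius(self) -> float:
        cx, cy, _ = self.center_mm
        ex, ey, _ = self.edges_mm
        return math.hypot(cx, cy) + math.hypot(ex, ey) / 2.0


@dataclass(frozen=True)
class Ellipsoid(Reflector):
    """Axis-aligned ellipsoid; equal semi-axes give a sphere."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    reflectivity: float = 0.3

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes_mm):
            raise ValueError("ellipsoid semi-axes must be > 0")
        self._check()

    def ray_hits(self, origin, direction):
        axes = np.asarray(self.semi_axes_mm, dtype=float)
        o = (np.asarray(origin, dtype=float) - np.asarray(self.center_mm)) / axes
        w = np.asarray(direction, dtype=float) / axes
        a = float(w @ w)
        b = 2.0 * float(o @ w)
        c = float(o @ o) - 1.0
        disc = b * b - 4.0 * a * c
        hits: list[tuple[float, np.ndarray]] = []
        if disc > _TOL:
            sq = math.sqrt(disc)
            for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                if t > _TOL:
                    p = np.asarray(origin, dtype=float) + t * np.asarray(
                        direction, dtype=float
                    ) - np.asarray(self.center_mm)
                    n_out = p / axes**2
                    n_out /= np.linalg.norm(n_out)
                    hits.append((t, -n_out))
        return hits

    def max_xy_radius(self) -> float:
        cx, cy, _ = self.center_mm
        return math.hypot(cx, cy) + max(self.semi_axes_mm[0], self.semi_axes_mm[1])


@dataclass(frozen=True)
class Phantom:
    """An ordered set of reflectors in a background medium."""

    reflectors: tuple[Reflector, ...] = ()
    background: Medium = field(default_factory=Medium)

    def check_fits_in_ring(self, geom: RingGeometry) -> None:
        """Raise GeometryError if any reflector pokes outside the ring."""
        for i, r in enumerate(self.reflectors):
            if r.max_xy_radius() >= geom.ring_radius_mm:
                raise GeometryError(
                    f"reflector {i} ({type(r).__name__}) extends to radius "
                    f"{r.max_xy_radius():.1f} mm, outside the "
                    f"{geom.ring_radius_mm:.1f} mm ring"
                )


def interface_crossings(
    phantom: Phantom, origin: np.ndarray, direction: np.ndarray
) -> list[Crossing]:
    """All interface crossings of a ray with the phantom, sorted by distance.

    Distances are one-way path lengths in mm from ``origin`` (which must lie
    outside all reflectors); the incidence angle is measured against the
    inward surface normal at each crossing; ``tissue_path_mm`` is the path
    beyond the first crossing (the first interface marks the water/tissue
    boundary for attenuation purposes). Tangent grazes are dropped.
    """
    direction = np.asarray(direction, dtype=float)
    if not math.isclose(float(np.linalg.norm(direction)), 1.0, rel_tol=1e-6):
        raise ValueError("direction must be a unit vector")
    raw: list[tuple[float, float, float]] = []
    for refl in phantom.reflectors:
        for t, n_in in refl.ray_hits(origin, direction):
            cos_inc = abs(float(direction @ n_in))
            inc = math.degrees(math.acos(min(1.0, max(0.0, cos_inc))))
            raw.append((t, inc, refl.reflectivity))
    raw.sort(key=lambda x: x[0])
    if not raw:
        return []
    t0 = raw[0][0]
    return [
        Crossing(
            distance_mm=t,
            incidence_deg=inc,
            reflectivity=refl,
            tissue_path_mm=max(0.0, t - t0),
        )
        for t, inc, refl in raw
    ]


def make_breast_phantom(
    body_width_mm: float = 155.0,
    body_height_mm: float = 80.0,
    mass_diameter_mm: float = 50.0,
    center_z_mm: float = 63.0,
    body_reflectivity: float = 0.3,
    mass_reflectivity: float = 0.8,
    medium: Medium | None = None,
) -> Phantom:
    """Breast phantom: an ellipsoidal body with a centred spherical mass.

    The body is an ellipsoid with semi-axes (width/2, width/2, height); the
    mass is a centred sphere of the given diameter with higher reflectivity.
    ``center_z_mm`` places the equatorial plane on an element plane (default
    63 mm = element 64 at 1 mm pitch). Tissue attenuation applies along the
    path beyond the body surface.
    """
    body_semi = (body_width_mm / 2.0, body_width_mm / 2.0, body_height_mm)
    mass_r = mass_diameter_mm / 2.0
    if mass_r >= min(body_semi):
        raise GeometryError(
            f"mass diameter {mass_diameter_mm} mm does not fit strictly inside "
            f"the body (min semi-axis {min(body_semi)} mm)"
        )
    center = (0.0, 0.0, center_z_mm)
    return Phantom(
        reflectors=(
            Ellipsoid(center, body_semi, reflectivity=body_reflectivity),
            Ellipsoid(center, (mass_r, mass_r, mass_r), reflectivity=mass_reflectivity),
        ),
        background=medium if medium is not None else Medium(),
    )
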