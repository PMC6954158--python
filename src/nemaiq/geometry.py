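"""NEMA IEC body phantom geometry and activity bookkeeping.

The NEMA IEC body phantom carries six hollow glass/plastic spheres
(nominal diameters 10-37 mm) on a ring inside a torso-shaped tank.  The
spheres are filled with a hot F-18 solution and the tank with a cooler
background solution; image-quality metrics are then defined relative to
the known inner radii, wall thicknesses and activity concentrations
(AC, kBq/ml) of those compartments.

This module holds the measured sphere geometry, activity/decay
arithmetic, and validated phantom definitions used by the synthetic
volume generator and by the metric/fit code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FWHM_PER_SIGMA",
    "F18_HALF_LIFE_MIN",
    "NEMA_SPHERE_TABLE",
    "SphereSpec",
    "ActivityConfig",
    "CylinderBody",
    "PhantomDefinition",
    "radius_from_volume",
    "volume_from_radius",
    "true_sbr",
    "decay_scale",
    "voxel_size_from_fov",
    "nema_iec_phantom",
]

#: FWHM of a Gaussian divided by its standard deviation, 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: F-18 half-life in minutes (configurable everywhere it is used).
F18_HALF_LIFE_MIN = 109.77

#: (label [nominal diameter, mm], inner volume [ml], inner radius [mm]);
#: radii follow from the volumes via ``radius_from_volume``.
NEMA_SPHERE_TABLE = (
    ("37", 25.6, 18.3),
    ("28", 10.7, 13.7),
    ("22", 5.4, 10.9),
    ("17", 2.6, 8.5),
    ("13", 1.2, 6.6),
    ("10", 0.58, 5.2),
)

DEFAULT_RING_RADIUS_MM = 57.2
DEFAULT_WALL_RANGE_MM = (0.9, 1.3)


def radius_from_volume(volume_ml: float) -> float:
    """Radius in mm of a sphere with the given volume in ml."""
    if volume_ml <= 0:
        raise ValueError(f"volume must be positive, got {volume_ml}")
    return (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def volume_from_radius(radius_mm: float) -> float:
    """Volume in ml of a sphere with the given radius in mm."""
    if radius_mm <= 0:
        raise ValueError(f"radius must be positive, got {radius_mm}")
    return 4.0 / 3.0 * math.pi * radius_mm**3 / 1000.0


def true_sbr(sphere_ac: float, background_ac: float) -> float:
    """Sphere-to-background ratio of two activity concentrations."""
    if sphere_ac <= 0 or background_ac <= 0:
        raise ValueError("activity concentrations must be positive")
    return sphere_ac / background_ac


def decay_scale(ac0: float, elapsed_min: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Activity concentration after radioactive decay over ``elapsed_min``."""
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    if elapsed_min < 0:
        raise ValueError("elapsed time must be non-negative")
    return ac0 * 2.0 ** (-elapsed_min / half_life_min)


def voxel_size_from_fov(fov_mm: float, matrix: int) -> float:
    """In-plane voxel size for a square reconstruction matrix over a field of view."""
    if fov_mm <= 0 or matrix < 1:
        raise ValueError("need positive FOV and matrix >= 1")
    return fov_mm / matrix


@dataclass(frozen=True)
class SphereSpec:
    """One fillable sphere insert.

    ``label`` is the nominal outer diameter in mm as used in scanner QC
    reports; ``inner_radius`` is the radius of the hot compartment and
    ``wall_thickness`` the cold glass wall around it.  ``center`` is in
    the phantom (world) frame, mm.
    """

    label: str
    inner_radius: float
    wall_thickness: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.inner_radius <= 0:
            raise ValueError(f"inner_radius must be positive, got {self.inner_radius}")
        if not (0 < self.wall_thickness < self.inner_radius):
            raise ValueError(
                f"wall_thickness must be in (0, inner_radius), got {self.wall_thickness}"
            )

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.wall_thickness

    @property
    def inner_volume_ml(self) -> float:
        return volume_from_radius(self.inner_radius)

    @property
    def center_mm(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class ActivityConfig:
    """Compartment activity concentrations at a reference time.

    sphere_ac and background_ac are in kBq/ml, decay-referenced to
    ``reference_time`` (minutes, study clock).
    """

    sphere_ac: float
    background_ac: float
    reference_time: float = 0.0
    half_life: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if not (self.sphere_ac > self.background_ac > 0):
            raise ValueError("require sphere_ac > background_ac > 0")
        if self.half_life <= 0:
            raise ValueError("half-life must be positive")

    @property
    def sbr(self) -> float:
        return true_sbr(self.sphere_ac, self.background_ac)

    def decayed(self, elapsed_min: float) -> "ActivityConfig":
        """Both compartments decayed by ``elapsed_min`` from the reference time."""
        return replace(
            self,
            sphere_ac=decay_scale(self.sphere_ac, elapsed_min, self.half_life),
            background_ac=decay_scale(self.background_ac, elapsed_min, self.half_life),
            reference_time=self.reference_time + elapsed_min,
        )


@dataclass(frozen=True)
class CylinderBody:
    """Axis-aligned (z) cylindrical approximation of the phantom body.

    The default simulation body is deliberately generous so that no
    VOI or fit window comes near the boundary; the exact torso
    cross-section is irrelevant to the metrics computed here.
    """

    radius: float = 140.0
    length: float = 160.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("body radius and length must be positive")


@dataclass
class PhantomDefinition:
    """Spheres + background body + activities, with placement validation."""

    spheres: list[SphereSpec]
    body: CylinderBody
    activity: ActivityConfig
    background_voi_center: tuple[float, float, float] | None = None
    background_voi_volume_ml: float = 30.0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def background_voi_radius(self) -> float:
        return radius_from_volume(self.background_voi_volume_ml)

    def sphere(self, label: str) -> SphereSpec:
        for s in self.spheres:
            if s.label == label:
                return s
        raise KeyError(f"no sphere labelled {label!r}")

    def validate(self) -> None:
        bc = np.asarray(self.body.center, dtype=float)
        for i, a in enumerate(self.spheres):
            # sphere inside body
            ca = a.center_mm - bc
            if (
                math.hypot(ca[0], ca[1]) + a.outer_radius > self.body.radius
                or abs(ca[2]) + a.outer_radius > self.body.length / 2
            ):
                raise ValueError(f"sphere {a.label} is not fully inside the body")
            for b in self.spheres[i + 1 :]:
                d = float(np.linalg.norm(a.center_mm - b.center_mm))
                if d <= a.outer_radius + b.outer_radius:
                    raise ValueError(f"spheres {a.label} and {b.label} overlap (distance {d:.1f} mm)")
        if self.background_voi_center is not None:
            v = np.asarray(self.background_voi_center, dtype=float)
            r = self.background_voi_radius
            cv = v - bc
            if math.hypot(cv[0], cv[1]) + r > self.body.radius or abs(cv[2]) + r > self.body.length / 2:
                raise ValueError("background VOI is not fully inside the body")
            for s in self.spheres:
                if float(np.linalg.norm(v - s.center_mm)) <= s.outer_radius + r:
                    raise ValueError(f"background VOI clips sphere {s.label}")


def nema_iec_phantom(
    activity: ActivityConfig,
    ring_radius: float = DEFAULT_RING_RADIUS_MM,
    wall_range: tuple[float, float] = DEFAULT_WALL_RANGE_MM,
    body: CylinderBody | None = None,
    background_voi_axial_offset: float = 40.0,
    background_voi_volume_ml: float = 30.0,
) -> PhantomDefinition:
    """Default six-sphere phantom layout.

    The spheres sit on a ring of ``ring_radius`` in the central
    transaxial plane, equally spaced at 60 degrees.  Wall thicknesses
    are linearly interpolated over ``wall_range`` from the smallest to
    the largest sphere (only the range is known from caliper
    measurements).  The 30-ml background VOI sits azimuthally midway
    between two adjacent spheres at an axial offset, validated to clip
    neither the spheres nor the body.
    """
    if body is None:
        body = CylinderBody()
    n = len(NEMA_SPHERE_TABLE)
    # largest first in the table; walls grow with sphere size
    walls = np.linspace(wall_range[1], wall_range[0], n)
    spheres = []
    for k, ((label, _vol, radius), wall) in enumerate(zip(NEMA_SPHERE_TABLE, walls)):
        theta = math.radians(60.0 * k)
        center = (ring_radius * math.cos(theta), ring_radius * math.sin(theta), 0.0)
        spheres.append(
            SphereSpec(label=label, inner_radius=radius, wall_thickness=float(wall), center=center)
        )
    theta = math.radians(30.0)
    voi_center = (
        ring_radius * math.cos(theta),
        ring_radius * math.sin(theta),
        background_voi_axial_offset,
    )
    return PhantomDefinition(
        spheres=spheres,
        body=body,
        activity=activity,
        background_voi_center=voi_center,
        background_voi_volume_ml=background_voi_volume_ml,
    )
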