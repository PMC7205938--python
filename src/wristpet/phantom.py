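"""Forearm phantom geometry and 511-keV attenuation queries.

The phantom is a stack of coaxial-axis (all parallel to Z) circular
cylinders: an 8-cm-diameter, 20-cm-long water arm containing the radius and
ulna bones and the radial/ulnar arteries and veins.  Overlaps are resolved
by an explicit integer priority (vessels > bones > arm > background), and
rays are traced analytically for Beer-Lambert attenuation.

Distances are cm, linear attenuation coefficients 1/cm, densities g/cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Material",
    "CylinderVolume",
    "PhantomModel",
    "InvalidGeometryError",
    "WATER",
    "CORTICAL_BONE",
    "BLOOD",
    "AIR",
    "build_forearm_phantom",
    "trace_path",
    "attenuation_factor",
    "DEFAULT_GEOMETRY",
]


class InvalidGeometryError(ValueError):
    """A phantom override violates a containment/disjointness invariant."""


@dataclass(frozen=True)
class Material:
    """Homogeneous attenuating medium at 511 keV.

    ``compton_fraction`` is the fraction of photon interactions that are
    Compton scatters (the remainder are treated as photoelectric
    absorption); at 511 keV in light media it is close to 1.
    """

    name: str
    density: float  # g/cm^3
    mu_511: float  # linear attenuation coefficient at 511 keV, 1/cm
    compton_fraction: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.mu_511 <= 0:
            raise ValueError(f"mu_511 must be > 0, got {self.mu_511}")
        if not 0.0 <= self.compton_fraction <= 1.0:
            raise ValueError("compton_fraction must lie in [0, 1]")


# Narrow-beam 511-keV constants (NIST-consistent textbook values); the
# study design fixes only the material *kind* (water / bone / blood), so
# the numeric coefficients are package constants, overridable via config.
WATER = Material("water", density=1.000, mu_511=0.0958, compton_fraction=0.99)
CORTICAL_BONE = Material("cortical-bone", density=1.920, mu_511=0.178, compton_fraction=0.99)
BLOOD = Material("blood", density=1.060, mu_511=0.101, compton_fraction=0.99)
AIR = Material("air", density=1.205e-3, mu_511=1.04e-4, compton_fraction=0.99)

MATERIALS = {m.name: m for m in (WATER, CORTICAL_BONE, BLOOD, AIR)}


@dataclass(frozen=True)
class CylinderVolume:
    """Circular cylinder with axis along Z, centered axially on z=0."""

    label: str
    center: tuple[float, float]  # (x, y) cm in the transaxial plane
    radius: float  # cm
    length: float  # cm
    material: Material
    priority: int  # higher wins where volumes overlap

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"{self.label}: radius must be > 0")
        if self.length <= 0:
            raise ValueError(f"{self.label}: length must be > 0")

    @property
    def half_length(self) -> float:
        return 0.5 * self.length

    @property
    def volume_ml(self) -> float:
        return math.pi * self.radius**2 * self.length

    def contains(self, point) -> bool:
        x, y, z = point
        if abs(z) > self.half_length:
            return False
        dx, dy = x - self.center[0], y - self.center[1]
        return dx * dx + dy * dy <= self.radius**2


@dataclass(frozen=True)
class PhantomModel:
    """Ordered collection of prioritized cylinders in a background medium.

    The lowest-priority volume is the container (the arm); every other
    volume must lie strictly inside it, and the inner volumes must be
    pairwise disjoint.
    """

    volumes: tuple[CylinderVolume, ...]
    background: Material = AIR

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        priorities = [v.priority for v in self.volumes]
        if len(set(priorities)) != len(priorities):
            raise InvalidGeometryError("volume priorities must be unique")
        arm = self.container
        for v in self.volumes:
            if v is arm:
                continue
            d = math.hypot(v.center[0] - arm.center[0], v.center[1] - arm.center[1])
            if d + v.radius > arm.radius + 1e-12:
                raise InvalidGeometryError(
                    f"{v.label} extends outside the {arm.label} cylinder"
                )
            if v.half_length > arm.half_length + 1e-12:
                raise InvalidGeometryError(f"{v.label} is longer than the {arm.label}")
        inner = [v for v in self.volumes if v is not arm]
        for i, a in enumerate(inner):
            for b in inner[i + 1 :]:
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius - 1e-12:
                    raise InvalidGeometryError(f"{a.label} intersects {b.label}")

    @property
    def container(self) -> CylinderVolume:
        return min(self.volumes, key=lambda v: v.priority)

    def material_at(self, point) -> Material:
        best = None
        for v in self.volumes:
            if v.contains(point) and (best is None or v.priority > best.priority):
                best = v
        return best.material if best is not None else self.background

    def volume(self, label: str) -> CylinderVolume:
        for v in self.volumes:
            if v.label == label:
                return v
        raise KeyError(label)

    def as_arrays(self) -> dict[str, np.ndarray]:
        """Flat geometry arrays for the vectorized transport engine.

        Volumes are ordered container-first, then ascending priority.
        """
        vols = sorted(self.volumes, key=lambda v: v.priority)
        return {
            "cx": np.array([v.center[0] for v in vols]),
            "cy": np.array([v.center[1] for v in vols]),
            "radius": np.array([v.radius for v in vols]),
            "half_length": np.array([v.half_length for v in vols]),
            "mu": np.array([v.material.mu_511 for v in vols]),
            "compton_fraction": np.array([v.material.compton_fraction for v in vols]),
            "labels": [v.label for v in vols],
        }


# Transaxial layout (cm).  Radii and the 1.1-cm bone gap (read as a
# surface-to-surface gap) are fixed by the modeled design; exact vessel
# coordinates are schematic anatomy, so these defaults place the
# arteries/veins on the volar (negative-Y) aspect.  All entries overridable.
DEFAULT_GEOMETRY: dict = {
    "arm": {"center": (0.0, 0.0), "radius": 4.0, "length": 20.0},
    "radius_bone": {"center": (-1.8, 0.5), "radius": 1.25, "length": 20.0},
    "ulna_bone": {"center": (1.8, 0.5), "radius": 1.25, "length": 20.0},
    "radial_artery": {"center": (-2.0, -2.5), "radius": 0.125, "length": 20.0},
    "ulnar_artery": {"center": (2.0, -2.5), "radius": 0.125, "length": 20.0},
    "radial_vein": {"center": (-2.4, -2.5), "radius": 0.075, "length": 20.0},
    "ulnar_vein": {"center": (2.4, -2.5), "radius": 0.075, "length": 20.0},
    "materials": {"water": {}, "cortical-bone": {}, "blood": {}},
}

_VOLUME_MATERIAL = {
    "arm": "water",
    "radius_bone": "cortical-bone",
    "ulna_bone": "cortical-bone",
    "radial_artery": "blood",
    "ulnar_artery": "blood",
    "radial_vein": "blood",
    "ulnar_vein": "blood",
}

# vessels > bones > arm; unique per volume
_PRIORITY = {
    "arm": 0,
    "radius_bone": 1,
    "ulna_bone": 2,
    "radial_artery": 3,
    "ulnar_artery": 4,
    "radial_vein": 5,
    "ulnar_vein": 6,
}


def _merge(base: dict, overrides: dict | None) -> dict:
    if not overrides:
        return {k: dict(v) for k, v in base.items()}
    out = {}
    for k, v in base.items():
        out[k] = dict(v)
        if k in overrides:
            out[k].update(overrides[k])
    return out


def build_forearm_phantom(config: dict | None = None) -> PhantomModel:
    """Build the seven-volume forearm phantom.

    Default geometry: water arm (r=4 cm, L=20 cm) centered at the origin,
    two cortical-bone cylinders (r=1.25 cm), two blood arteries
    (r=0.125 cm) and two blood veins (r=0.075 cm), all axes along Z.

    ``config`` may override per-volume ``center``/``radius``/``length`` and
    the numeric constants of the named materials; overrides that break
    containment or disjointness raise :class:`InvalidGeometryError`.
    """
    geo = _merge(DEFAULT_GEOMETRY, config)
    mats = {}
    for name, base in (("water", WATER), ("cortical-bone", CORTICAL_BONE), ("blood", BLOOD)):
        over = geo.get("materials", {}).get(name, {})
        mats[name] = replace(base, **over) if over else base
    volumes = []
    for label, mat_name in _VOLUME_MATERIAL.items():
        spec = geo[label]
        volumes.append(
            CylinderVolume(
                label=label,
                center=tuple(spec["center"]),
                radius=float(spec["radius"]),
                length=float(spec["length"]),
                material=mats[mat_name],
                priority=_PRIORITY[label],
            )
        )
    return PhantomModel(volumes=tuple(volumes))


def water_cylinder_phantom(radius: float = 4.0, length: float = 20.0) -> PhantomModel:
    """Uniform water cylinder (the count-rate-experiment phantom)."""
    arm = CylinderVolume("water-cylinder", (0.0, 0.0), radius, length, WATER, 0)
    return PhantomModel(volumes=(arm,))


def _ray_cylinder_interval(origin, direction, vol: CylinderVolume):
    """Parameter interval [t0, t1] of a ray inside a finite Z-cylinder.

    Returns ``None`` when the ray misses.  ``direction`` must be unit.
    """
    ox, oy, oz = origin
    dx, dy, dz = direction
    cx, cy = vol.center
    px, py = ox - cx, oy - cy
    a = dx * dx + dy * dy
    if a < 1e-14:
        # ray parallel to the axis
        if px * px + py * py > vol.radius**2:
            return None
        t_lo, t_hi = -math.inf, math.inf
    else:
        b = px * dx + py * dy
        c = px * px + py * py - vol.radius**2
        disc = b * b - a * c
        if disc <= 0:
            return None
        sq = math.sqrt(disc)
        t_lo, t_hi = (-b - sq) / a, (-b + sq) / a
    # intersect with the axial slab
    if abs(dz) < 1e-14:
        if abs(oz) > vol.half_length:
            return None
    else:
        z0 = (-vol.half_length - oz) / dz
        z1 = (vol.half_length - oz) / dz
        if z0 > z1:
            z0, z1 = z1, z0
        t_lo, t_hi = max(t_lo, z0), min(t_hi, z1)
    if t_hi <= t_lo:
        return None
    return t_lo, t_hi


def trace_path(
    phantom: PhantomModel,
    origin,
    direction,
    max_length: float,
) -> list[tuple[Material, float]]:
    """Ordered (material, pathlength) segments of a ray through the phantom.

    Only segments inside phantom volumes are reported (the background is
    skipped); materials are resolved by highest priority at each point, and
    adjacent same-material segments are merged.
    """
    direction = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(direction))
    if norm == 0.0:
        raise ValueError("direction vector must be nonzero")
    if abs(norm - 1.0) > 1e-9:
        raise ValueError("direction must be normalized")
    if max_length <= 0:
        raise ValueError("max_length must be > 0")
    origin = tuple(float(v) for v in origin)
    d = tuple(float(v) for v in direction)

    boundaries = {0.0, float(max_length)}
    for vol in phantom.volumes:
        iv = _ray_cylinder_interval(origin, d, vol)
        if iv is None:
            continue
        lo, hi = max(iv[0], 0.0), min(iv[1], float(max_length))
        if hi > lo:
            boundaries.update((lo, hi))
    ts = sorted(boundaries)
    segments: list[tuple[Material, float]] = []
    for lo, hi in zip(ts[:-1], ts[1:]):
        if hi - lo < 1e-12:
            continue
        tm = 0.5 * (lo + hi)
        point = (origin[0] + d[0] * tm, origin[1] + d[1] * tm, origin[2] + d[2] * tm)
        mat = phantom.material_at(point)
        if mat is phantom.background:
            continue
        if segments and segments[-1][0] is mat:
            segments[-1] = (mat, segments[-1][1] + (hi - lo))
        else:
            segments.append((mat, hi - lo))
    return segments


def attenuation_factor(segments) -> float:
    """Beer-Lambert survival probability exp(-sum mu_i * l_i) in [0, 1]."""
    tau = 0.0
    for mat, length in segments:
        if length < 0:
            raise ValueError("pathlength must be >= 0")
        tau += mat.mu_511 * length
    return math.exp(-tau)
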