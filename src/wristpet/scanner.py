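"""Detector geometry, crystal physics, and the singles digitizer stages.

Two geometries are built from the same monolithic 2.45 (tangential) x 3.0
(axial) x 2.0 (radial) cm crystal block:

* ``wristPET1`` — a closed ring of 14 blocks (3-cm axial field of view).
  Blocks are numbered 1..14 clockwise viewed from +Z, with blocks 1 and 14
  straddling the +Y axis so that the volar arc (blocks 4-11) is symmetric
  about -Y; blocks 4 and 11 sit on the horizontal equator.
* ``wristPET2`` — the open half-ring keeping only blocks 4-11, optionally
  stacked into 1-4 axial rings at 3.0-cm pitch (axial FoV 3 cm per ring).

Crystal physics (attenuation length, energy resolution, decay time,
coincidence window) for GSO, LSO, BGO, CeBr3 and LaBr3 are package
constants.  The digitizer stages provided here are Gaussian energy
blurring, an energy window, and a per-block non-paralyzable deadtime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CrystalMaterial",
    "DetectorBlock",
    "ScannerConfig",
    "CRYSTALS",
    "BLOCK_TANGENTIAL_CM",
    "BLOCK_AXIAL_CM",
    "BLOCK_RADIAL_CM",
    "build_wristpet1",
    "build_wristpet2",
    "crystal_pathlength",
    "detection_probability",
    "blur_energy",
    "apply_energy_window",
    "apply_deadtime",
]

BLOCK_TANGENTIAL_CM = 2.45
BLOCK_AXIAL_CM = 3.0
BLOCK_RADIAL_CM = 2.0

DEFAULT_INNER_DIAMETER_CM = 11.0  # 14 x 2.45 cm blocks need >= 10.92 cm
DEFAULT_ENERGY_WINDOW_KEV = (350.0, 650.0)
N_RING_BLOCKS = 14
HALF_RING_INDICES = tuple(range(4, 12))  # blocks 4..11 inclusive


@dataclass(frozen=True)
class CrystalMaterial:
    """Scintillator physics used by the simplified detection model.

    ``metadata`` stores catalogue values (Z_eff, emission wavelength,
    light output, refractive index) that the simplified physics does not
    consume.
    """

    name: str
    density: float  # g/cm^3
    decay_time_ns: float
    energy_resolution_511: float  # % FWHM at 511 keV
    attenuation_length_511_mm: float
    coincidence_window_ns: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in (
            self.density,
            self.decay_time_ns,
            self.attenuation_length_511_mm,
            self.coincidence_window_ns,
        ):
            if f <= 0:
                raise ValueError(f"{self.name}: physics fields must be > 0")
        if self.energy_resolution_511 < 0:
            raise ValueError(f"{self.name}: energy resolution must be >= 0")


CRYSTALS: dict[str, CrystalMaterial] = {
    "GSO": CrystalMaterial(
        "GSO", 6.71, 60.0, 8.5, 14.3, 4.5,
        metadata={"Z_eff": 58.6, "wavelength_nm": 430, "light_output_ph_per_keV": "12-15", "refractive_index": 1.85},
    ),
    "LSO": CrystalMaterial(
        "LSO", 7.40, 40.0, 10.0, 11.4, 4.5,
        metadata={"Z_eff": 65.0, "wavelength_nm": 420, "light_output_ph_per_keV": "20-30", "refractive_index": 1.82},
    ),
    "BGO": CrystalMaterial(
        "BGO", 7.13, 300.0, 10.2, 10.4, 10.0,
        metadata={"Z_eff": 74.2, "wavelength_nm": 480, "light_output_ph_per_keV": "8", "refractive_index": 2.15},
    ),
    "CeBr3": CrystalMaterial(
        "CeBr3", 5.20, 17.0, 5.2, 19.6, 4.5,
        metadata={"Z_eff": 45.9, "wavelength_nm": 370, "light_output_ph_per_keV": "60", "refractive_index": 1.88},
    ),
    "LaBr3": CrystalMaterial(
        "LaBr3", 5.30, 26.0, 3.2, 24.0, 4.5,
        metadata={"Z_eff": 46.9, "wavelength_nm": 370, "light_output_ph_per_keV": "70", "refractive_index": 1.88},
    ),
}


@dataclass(frozen=True)
class DetectorBlock:
    """One monolithic crystal block with its inward normal at the axis."""

    id: int  # unique within the scanner
    angular_index: int  # 1..14 position on the wristPET1 ring
    ring_index: int
    center: tuple[float, float, float]  # cm
    azimuth: float  # rad, direction from the scanner axis to the block
    material: CrystalMaterial

    @property
    def inward_normal(self) -> tuple[float, float, float]:
        return (-math.cos(self.azimuth), -math.sin(self.azimuth), 0.0)


@dataclass(frozen=True)
class ScannerConfig:
    """A set of blocks plus the digitizer settings shared by all of them."""

    name: str
    blocks: tuple[DetectorBlock, ...]
    material: CrystalMaterial
    ring_inner_diameter: float  # cm
    n_axial_rings: int
    energy_window_keV: tuple[float, float] = DEFAULT_ENERGY_WINDOW_KEV
    deadtime_ns: float | None = None  # default: 3 x crystal decay time

    def __post_init__(self) -> None:
        if self.energy_window_keV[0] >= self.energy_window_keV[1]:
            raise ValueError("energy window low must be < high")

    @property
    def coincidence_window_ns(self) -> float:
        return self.material.coincidence_window_ns

    @property
    def deadtime_s(self) -> float:
        tau_ns = self.deadtime_ns if self.deadtime_ns is not None else 3.0 * self.material.decay_time_ns
        return tau_ns * 1e-9

    @property
    def axial_fov(self) -> float:
        return BLOCK_AXIAL_CM * self.n_axial_rings

    def as_arrays(self) -> dict[str, np.ndarray]:
        az = np.array([b.azimuth for b in self.blocks])
        centers = np.array([b.center for b in self.blocks])
        return {
            "cos_az": np.cos(az),
            "sin_az": np.sin(az),
            "cx": centers[:, 0],
            "cy": centers[:, 1],
            "cz": centers[:, 2],
            "ids": np.array([b.id for b in self.blocks]),
        }

    def geometry_dict(self) -> dict:
        """JSON-ready geometry dump (block ids, centers, normals)."""
        return {
            "name": self.name,
            "ring_inner_diameter_cm": self.ring_inner_diameter,
            "n_axial_rings": self.n_axial_rings,
            "material": self.material.name,
            "blocks": [
                {
                    "id": b.id,
                    "angular_index": b.angular_index,
                    "ring_index": b.ring_index,
                    "center_cm": list(b.center),
                    "inward_normal": list(b.inward_normal),
                }
                for b in self.blocks
            ],
        }


def _block_azimuth(angular_index: int) -> float:
    """Azimuth (rad) of a wristPET1 block center; indices run clockwise."""
    pitch = 2.0 * math.pi / N_RING_BLOCKS
    return math.radians(90.0) - (angular_index - 0.5) * pitch


def _make_block(block_id, angular_index, ring_index, z, material, inner_radius) -> DetectorBlock:
    az = _block_azimuth(angular_index)
    rc = inner_radius + 0.5 * BLOCK_RADIAL_CM
    return DetectorBlock(
        id=block_id,
        angular_index=angular_index,
        ring_index=ring_index,
        center=(rc * math.cos(az), rc * math.sin(az), z),
        azimuth=az,
        material=material,
    )


def build_wristpet1(
    material: CrystalMaterial,
    *,
    inner_diameter: float = DEFAULT_INNER_DIAMETER_CM,
    energy_window_keV: tuple[float, float] = DEFAULT_ENERGY_WINDOW_KEV,
    deadtime_ns: float | None = None,
) -> ScannerConfig:
    """Closed single ring of 14 blocks, 3-cm axial field of view."""
    r_in = 0.5 * inner_diameter
    blocks = tuple(
        _make_block(i, i, 0, 0.0, material, r_in) for i in range(1, N_RING_BLOCKS + 1)
    )
    return ScannerConfig(
        name="wristPET1",
        blocks=blocks,
        material=material,
        ring_inner_diameter=inner_diameter,
        n_axial_rings=1,
        energy_window_keV=energy_window_keV,
        deadtime_ns=deadtime_ns,
    )


def build_wristpet2(
    material: CrystalMaterial,
    n_rings: int = 1,
    *,
    inner_diameter: float = DEFAULT_INNER_DIAMETER_CM,
    energy_window_keV: tuple[float, float] = DEFAULT_ENERGY_WINDOW_KEV,
    deadtime_ns: float | None = None,
) -> ScannerConfig:
    """Open half-ring (blocks 4-11) stacked into 1-4 axial rings.

    Rings are stacked at 3.0-cm pitch and centered on z=0; coincidences
    between any two blocks (including cross-ring) are allowed downstream.
    """
    if not 1 <= int(n_rings) <= 4:
        raise ValueError("n_rings must be in 1..4")
    n_rings = int(n_rings)
    r_in = 0.5 * inner_diameter
    z_centers = (np.arange(n_rings) - 0.5 * (n_rings - 1)) * BLOCK_AXIAL_CM
    blocks = []
    block_id = 1
    for ring, z in enumerate(z_centers):
        for angular in HALF_RING_INDICES:
            blocks.append(_make_block(block_id, angular, ring, float(z), material, r_in))
            block_id += 1
    return ScannerConfig(
        name=f"wristPET2-{n_rings}ring",
        blocks=tuple(blocks),
        material=material,
        ring_inner_diameter=inner_diameter,
        n_axial_rings=n_rings,
        energy_window_keV=energy_window_keV,
        deadtime_ns=deadtime_ns,
    )


def crystal_pathlength(block: DetectorBlock, origin, direction) -> float:
    """Chord length (cm) of a ray inside the block's oriented box; 0 on miss."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must be normalized")
    ca, sa = math.cos(block.azimuth), math.sin(block.azimuth)
    rel = origin - np.asarray(block.center)
    # local frame: radial (outward), tangential, axial
    p = np.array(
        [rel[0] * ca + rel[1] * sa, -rel[0] * sa + rel[1] * ca, rel[2]]
    )
    d = np.array(
        [direction[0] * ca + direction[1] * sa, -direction[0] * sa + direction[1] * ca, direction[2]]
    )
    half = np.array([0.5 * BLOCK_RADIAL_CM, 0.5 * BLOCK_TANGENTIAL_CM, 0.5 * BLOCK_AXIAL_CM])
    t_lo, t_hi = -math.inf, math.inf
    for k in range(3):
        if abs(d[k]) < 1e-14:
            if abs(p[k]) > half[k]:
                return 0.0
            continue
        a = (-half[k] - p[k]) / d[k]
        b = (half[k] - p[k]) / d[k]
        if a > b:
            a, b = b, a
        t_lo, t_hi = max(t_lo, a), min(t_hi, b)
    if t_hi <= t_lo or t_hi <= 0:
        return 0.0
    return float(t_hi - max(t_lo, 0.0))


def detection_probability(pathlength_cm: float, material: CrystalMaterial):
    """Interaction probability 1 - exp(-l/lambda) over a crystal chord."""
    pathlength_cm = np.asarray(pathlength_cm, dtype=float)
    if np.any(pathlength_cm < 0):
        raise ValueError("pathlength must be >= 0")
    lam_cm = material.attenuation_length_511_mm / 10.0
    out = 1.0 - np.exp(-pathlength_cm / lam_cm)
    return float(out) if out.ndim == 0 else out


def energy_fwhm(E_keV, material: CrystalMaterial):
    """FWHM (keV) at deposit energy E: resolution quoted at 511 keV,
    scaled with 1/sqrt(E)."""
    E_keV = np.asarray(E_keV, dtype=float)
    r0 = material.energy_resolution_511 / 100.0
    out = r0 * 511.0 * np.sqrt(511.0 / E_keV)
    return float(out) if out.ndim == 0 else out


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def blur_energy(E_keV, material: CrystalMaterial, rng: np.random.Generator):
    """Gaussian energy response: mean E, FWHM from :func:`energy_fwhm`;
    negative draws are clamped to 0.  Vectorized over E."""
    E_keV = np.asarray(E_keV, dtype=float)
    if np.any(E_keV <= 0):
        raise ValueError("E must be > 0")
    sigma = energy_fwhm(E_keV, material) * _FWHM_TO_SIGMA
    out = np.maximum(rng.normal(E_keV, sigma), 0.0)
    return float(out) if out.ndim == 0 else out


def apply_energy_window(E_keV, window=DEFAULT_ENERGY_WINDOW_KEV):
    """Closed-interval acceptance low <= E <= high; vectorized."""
    low, high = window
    if not low < high:
        raise ValueError("window low must be < high")
    E_keV = np.asarray(E_keV, dtype=float)
    out = (E_keV >= low) & (E_keV <= high)
    return bool(out) if out.ndim == 0 else out


def apply_deadtime(event_times, tau: float) -> np.ndarray:
    """Non-paralyzable deadtime on one block's sorted event times.

    An accepted event at t blocks every event in (t, t+tau]; returns the
    boolean survivor mask.  Raises on unsorted input.
    """
    times = np.asarray(event_times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("event times must be sorted ascending")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    n = len(times)
    keep = np.zeros(n, dtype=bool)
    if n == 0:
        return keep
    if tau == 0:
        keep[:] = True
        return keep
    i = 0
    while i < n:
        keep[i] = True
        # first event strictly after the dead window
        i = int(np.searchsorted(times, times[i] + tau, side="right"))
    return keep
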