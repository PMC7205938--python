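"""Decay sampling, simplified photon transport, detection and coincidence sorting.

The chain per annihilation: a decay is drawn from the activity timeline
(inhomogeneous Poisson), two 511-keV photons are emitted back-to-back in a
uniformly random direction, each photon is tracked through the phantom
with exponential free paths on the segmented attenuation profile, may
Compton-scatter once (Klein-Nishina angle, Compton energy loss; a second
interaction absorbs), and escaping photons are tested against the first
detector block they intersect.  Detected singles are energy-blurred,
energy-windowed, timestamped (decay time plus Gaussian timing jitter;
photon time of flight is neglected), deadtime-filtered per block, and
sorted into coincidences with the keep-if-all-are-good multiple policy.

All hot paths operate on photon batches (numpy arrays); the public
per-event operations wrap batches of one.  Positron range and annihilation
acollinearity are neglected (sub-millimeter effects at this geometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import PhantomModel
from .scanner import (
    BLOCK_AXIAL_CM,
    BLOCK_RADIAL_CM,
    BLOCK_TANGENTIAL_CM,
    ScannerConfig,
    apply_deadtime,
)
from .flow import ActivityTimeline

__all__ = [
    "DecayEvent",
    "SingleEvent",
    "CoincidenceEvent",
    "DecayBatch",
    "SinglesBatch",
    "CoincidenceBatch",
    "SimulationResult",
    "sample_decays",
    "emit_annihilation",
    "transport_photon",
    "detect_photon",
    "sort_coincidences",
    "classify_coincidence",
    "compton_scattered_energy",
    "sample_klein_nishina_costheta",
    "simulate",
]

E_ANNIHILATION_KEV = 511.0


# ---------------------------------------------------------------------------
# event records (scalar views used by the per-event API and tests)

@dataclass(frozen=True)
class DecayEvent:
    id: int
    time: float  # s
    position: tuple[float, float, float]  # cm
    source: str


@dataclass(frozen=True)
class SingleEvent:
    time: float  # s
    block: int
    energy: float  # keV, post-blur
    decay_id: int
    scattered: bool


@dataclass(frozen=True)
class CoincidenceEvent:
    first: SingleEvent
    second: SingleEvent
    kind: str  # "true" | "scattered" | "random"


# ---------------------------------------------------------------------------
# batch containers

@dataclass
class DecayBatch:
    times: np.ndarray  # (n,) s
    positions: np.ndarray  # (n, 3) cm
    source_index: np.ndarray  # (n,) timeline segment index
    ids: np.ndarray  # (n,) global decay ids

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SinglesBatch:
    times: np.ndarray
    blocks: np.ndarray
    energies: np.ndarray
    decay_ids: np.ndarray
    scattered: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "block": self.blocks,
                "energy_keV": self.energies,
                "decay_id": self.decay_ids,
                "scattered": self.scattered,
            }
        )

    @classmethod
    def concatenate(cls, batches) -> "SinglesBatch":
        batches = list(batches)
        return cls(
            times=np.concatenate([b.times for b in batches]) if batches else np.empty(0),
            blocks=np.concatenate([b.blocks for b in batches]) if batches else np.empty(0, int),
            energies=np.concatenate([b.energies for b in batches]) if batches else np.empty(0),
            decay_ids=np.concatenate([b.decay_ids for b in batches]) if batches else np.empty(0, np.int64),
            scattered=np.concatenate([b.scattered for b in batches]) if batches else np.empty(0, bool),
        )

    def sorted_by_time(self) -> "SinglesBatch":
        order = np.argsort(self.times, kind="stable")
        return SinglesBatch(
            self.times[order], self.blocks[order], self.energies[order],
            self.decay_ids[order], self.scattered[order],
        )


@dataclass
class CoincidenceBatch:
    """Pairs of singles indices into a (time-sorted) SinglesBatch."""

    first: np.ndarray  # (m,) indices
    second: np.ndarray
    kinds: np.ndarray  # (m,) str: "true" | "scattered" | "random"

    def __len__(self) -> int:
        return len(self.first)

    def count(self, kind: str) -> int:
        return int(np.sum(self.kinds == kind))


@dataclass
class SimulationResult:
    singles: SinglesBatch  # time-sorted, post-deadtime, post-window
    coincidences: CoincidenceBatch
    n_decays: int
    scanner: ScannerConfig

    @property
    def coincidence_times(self) -> np.ndarray:
        return self.singles.times[self.coincidences.first]

    @property
    def coincidence_kinds(self) -> np.ndarray:
        return self.coincidences.kinds

    def coincidences_dataframe(self) -> pd.DataFrame:
        i, j = self.coincidences.first, self.coincidences.second
        return pd.DataFrame(
            {
                "time_1_s": self.singles.times[i],
                "time_2_s": self.singles.times[j],
                "block_1": self.singles.blocks[i],
                "block_2": self.singles.blocks[j],
                "kind": self.coincidences.kinds,
            }
        )


# ---------------------------------------------------------------------------
# decay sampling

def sample_decays(
    timeline: ActivityTimeline,
    rng: np.random.Generator,
    *,
    id_offset: int = 0,
) -> DecayBatch:
    """Inhomogeneous-Poisson decays from an activity timeline.

    Per (segment, window) cell the count is Poisson(activity x duration),
    times are uniform within the window and positions uniform within the
    segment cylinder.  Events are returned time-sorted.
    """
    act = timeline.activity
    lam = act * timeline.durations[None, :]
    counts = rng.poisson(lam)
    n = int(counts.sum())
    seg_idx = np.repeat(
        np.broadcast_to(np.arange(act.shape[0])[:, None], act.shape).ravel(), counts.ravel()
    )
    win_idx = np.repeat(
        np.broadcast_to(np.arange(act.shape[1])[None, :], act.shape).ravel(), counts.ravel()
    )
    times = timeline.starts[win_idx] + rng.random(n) * timeline.durations[win_idx]
    r = timeline.seg_radius[seg_idx] * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    x = timeline.seg_x[seg_idx] + r * np.cos(phi)
    y = timeline.seg_y[seg_idx] + r * np.sin(phi)
    z = timeline.seg_z[seg_idx] + rng.uniform(-1.0, 1.0, n) * timeline.seg_half_length[seg_idx]
    order = np.argsort(times, kind="stable")
    return DecayBatch(
        times=times[order],
        positions=np.column_stack([x, y, z])[order],
        source_index=seg_idx[order],
        ids=id_offset + np.arange(n, dtype=np.int64),
    )


def isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform directions on the unit sphere, (n, 3)."""
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def emit_annihilation(decay: DecayEvent, rng: np.random.Generator):
    """Two back-to-back 511-keV photons from one decay (exactly antiparallel)."""
    d = isotropic_directions(1, rng)[0]
    pos = np.asarray(decay.position, dtype=float)
    return (
        (pos.copy(), d, E_ANNIHILATION_KEV),
        (pos.copy(), -d, E_ANNIHILATION_KEV),
    )


# ---------------------------------------------------------------------------
# Compton kinematics

def compton_scattered_energy(E_keV, cos_theta):
    """Compton formula E' = E / (1 + (E/511)(1 - cos theta))."""
    E_keV = np.asarray(E_keV, dtype=float)
    cos_theta = np.asarray(cos_theta, dtype=float)
    out = E_keV / (1.0 + (E_keV / E_ANNIHILATION_KEV) * (1.0 - cos_theta))
    return float(out) if out.ndim == 0 else out


def sample_klein_nishina_costheta(E_keV, rng: np.random.Generator) -> np.ndarray:
    """Klein-Nishina scattering-angle cosines by rejection sampling.

    The unnormalized density in cos(theta) is eps^2 (eps + 1/eps -
    sin^2 theta) with eps the Compton energy ratio; it is bounded by 2
    for every incident energy, which serves as the rejection envelope.
    """
    E_keV = np.atleast_1d(np.asarray(E_keV, dtype=float))
    alpha = E_keV / E_ANNIHILATION_KEV
    n = len(E_keV)
    out = np.empty(n)
    pending = np.arange(n)
    while len(pending):
        m = len(pending)
        mu = rng.uniform(-1.0, 1.0, m)
        eps = 1.0 / (1.0 + alpha[pending] * (1.0 - mu))
        f = eps * eps * (eps + 1.0 / eps - (1.0 - mu * mu))
        accept = rng.uniform(0.0, 2.0, m) < f
        out[pending[accept]] = mu[accept]
        pending = pending[~accept]
    return out


def _rotate_directions(d: np.ndarray, cos_theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate each direction by theta with a uniform azimuth."""
    n = len(d)
    helper = np.where(np.abs(d[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, None))
    out = (
        cos_theta[:, None] * d
        + sin_theta[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# phantom transport (batched)

class _PhantomArrays:
    """Flattened cylinder stack for vectorized attenuation queries.

    Volume 0 is the container; inner volumes carry (mu_k - mu_0) weights so
    the optical depth along a ray is a sum of clipped interval overlaps.
    """

    def __init__(self, phantom: PhantomModel):
        arr = phantom.as_arrays()
        self.cx = arr["cx"]
        self.cy = arr["cy"]
        self.r2 = arr["radius"] ** 2
        self.hl = arr["half_length"]
        self.mu = arr["mu"]
        self.cf = arr["compton_fraction"]
        self.n_volumes = len(self.cx)
        # optical-depth weights: container mu, then excess mu of inner volumes
        self.weights = self.mu.copy()
        self.weights[1:] -= self.mu[0]

    def intervals(self, pos: np.ndarray, d: np.ndarray):
        """Per-volume ray parameter intervals [t0, t1], clipped to t >= 0.

        Returns arrays of shape (n_volumes, n_photons); missing volumes
        produce empty intervals (t0 == t1 == 0).
        """
        px, py, pz = pos[:, 0], pos[:, 1], pos[:, 2]
        dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
        K, n = self.n_volumes, len(px)
        t0 = np.zeros((K, n))
        t1 = np.zeros((K, n))
        a = dx * dx + dy * dy
        axial = a < 1e-14
        a_safe = np.where(axial, 1.0, a)
        with np.errstate(divide="ignore", invalid="ignore"):
            for k in range(K):
                ox = px - self.cx[k]
                oy = py - self.cy[k]
                b = ox * dx + oy * dy
                c = ox * ox + oy * oy - self.r2[k]
                disc = b * b - a_safe * c
                sq = np.sqrt(np.clip(disc, 0.0, None))
                r_lo = (-b - sq) / a_safe
                r_hi = (-b + sq) / a_safe
                miss_radial = (~axial) & (disc <= 0)
                # axis-parallel rays: inside the circle or a miss
                r_lo = np.where(axial, -np.inf, r_lo)
                r_hi = np.where(axial, np.inf, r_hi)
                miss = miss_radial | (axial & (c > 0))
                dz_safe = np.where(np.abs(dz) < 1e-14, 1e-300, dz)
                z_a = (-self.hl[k] - pz) / dz_safe
                z_b = (self.hl[k] - pz) / dz_safe
                z_lo = np.minimum(z_a, z_b)
                z_hi = np.maximum(z_a, z_b)
                flat = np.abs(dz) < 1e-14
                z_lo = np.where(flat, -np.inf, z_lo)
                z_hi = np.where(flat, np.inf, z_hi)
                miss |= flat & (np.abs(pz) > self.hl[k])
                lo = np.maximum(np.maximum(r_lo, z_lo), 0.0)
                hi = np.maximum(np.minimum(r_hi, z_hi), lo)
                t0[k] = np.where(miss, 0.0, lo)
                t1[k] = np.where(miss, 0.0, hi)
        return t0, t1

    def optical_depth(self, t0, t1, t):
        """tau(t) along each ray given per-volume intervals."""
        seg = np.clip(np.minimum(t, t1) - np.minimum(t, t0), 0.0, None)
        # t0 >= 0, so min(t, t0) handles t inside/before the interval
        return np.einsum("k,kn->n", self.weights, seg)

    def volume_index_at(self, pos: np.ndarray) -> np.ndarray:
        """Highest-priority volume containing each point (container = 0)."""
        idx = np.zeros(len(pos), dtype=np.int64)
        for k in range(1, self.n_volumes):
            inside = (
                ((pos[:, 0] - self.cx[k]) ** 2 + (pos[:, 1] - self.cy[k]) ** 2 <= self.r2[k])
                & (np.abs(pos[:, 2]) <= self.hl[k])
            )
            idx[inside] = k
        return idx


def _transport_leg(geom: _PhantomArrays, pos, d, rng, n_bisect=32):
    """One free flight: returns (escaped, end_pos) and for the non-escaped
    the interaction position."""
    t0, t1 = geom.intervals(pos, d)
    t_exit = t1[0]  # container exit; inner volumes lie inside it
    tau_total = geom.optical_depth(t0, t1, t_exit)
    xi = rng.exponential(1.0, len(pos))
    escaped = xi >= tau_total
    inter = ~escaped
    t_hit = np.zeros(len(pos))
    if np.any(inter):
        lo = np.zeros(inter.sum())
        hi = t_exit[inter]
        t0i, t1i = t0[:, inter], t1[:, inter]
        xii = xi[inter]
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            tau_mid = geom.optical_depth(t0i, t1i, mid)
            go_right = tau_mid < xii
            lo = np.where(go_right, mid, lo)
            hi = np.where(go_right, hi, mid)
        t_hit[inter] = 0.5 * (lo + hi)
    return escaped, t_hit


def transport_batch(
    geom: _PhantomArrays,
    pos: np.ndarray,
    d: np.ndarray,
    rng: np.random.Generator,
):
    """Transport photons through the phantom with at most one Compton scatter.

    Returns (escaped mask, end positions, end directions, energies keV,
    scattered flags).  Non-escaping photons are absorbed (photoelectric, or
    any second interaction).
    """
    n = len(pos)
    energy = np.full(n, E_ANNIHILATION_KEV)
    scattered = np.zeros(n, dtype=bool)
    out_pos = pos.copy()
    out_dir = d.copy()
    escaped, t_hit = _transport_leg(geom, pos, d, rng)
    alive = escaped.copy()

    inter = ~escaped
    if np.any(inter):
        x_int = pos[inter] + d[inter] * t_hit[inter, None]
        vol = geom.volume_index_at(x_int)
        is_compton = rng.random(len(x_int)) < geom.cf[vol]
        idx_sc = np.nonzero(inter)[0][is_compton]
        if len(idx_sc):
            mu_cos = sample_klein_nishina_costheta(energy[idx_sc], rng)
            new_E = compton_scattered_energy(energy[idx_sc], mu_cos)
            new_d = _rotate_directions(d[idx_sc], mu_cos, rng)
            new_p = x_int[is_compton]
            # second flight: escape or be absorbed (single-scatter model)
            esc2, _ = _transport_leg(geom, new_p, new_d, rng)
            surv = idx_sc[esc2]
            alive[surv] = True
            scattered[surv] = True
            energy[surv] = new_E[esc2]
            out_pos[surv] = new_p[esc2]
            out_dir[surv] = new_d[esc2]
    return alive, out_pos, out_dir, energy, scattered


class _TransportOutcome:
    """Scalar outcome of :func:`transport_photon`."""

    def __init__(self, absorbed, position=None, direction=None, energy=None, scattered=False):
        self.absorbed = bool(absorbed)
        self.position = position
        self.direction = direction
        self.energy = energy
        self.scattered = bool(scattered)

    @property
    def escaped(self) -> bool:
        return not self.absorbed


def transport_photon(photon, phantom: PhantomModel, rng: np.random.Generator) -> _TransportOutcome:
    """Per-photon wrapper over :func:`transport_batch`.

    ``photon`` is (position, direction, energy_keV) with the position
    inside (or entering) the phantom.
    """
    pos, d, _energy = photon
    geom = phantom if isinstance(phantom, _PhantomArrays) else _PhantomArrays(phantom)
    alive, p, dd, e, sc = transport_batch(
        geom, np.asarray(pos, float)[None, :], np.asarray(d, float)[None, :], rng
    )
    if not alive[0]:
        return _TransportOutcome(absorbed=True)
    return _TransportOutcome(False, p[0], dd[0], float(e[0]), bool(sc[0]))


# ---------------------------------------------------------------------------
# detection (batched)

class _ScannerArrays:
    """Block geometry flattened for vectorized first-hit searches."""

    def __init__(self, scanner: ScannerConfig):
        self.scanner = scanner
        arr = scanner.as_arrays()
        self.cos_az = arr["cos_az"]
        self.sin_az = arr["sin_az"]
        self.cx, self.cy, self.cz = arr["cx"], arr["cy"], arr["cz"]
        self.ids = arr["ids"]
        self.n_blocks = len(self.ids)
        self.half_radial = 0.5 * BLOCK_RADIAL_CM
        self.half_tangential = 0.5 * BLOCK_TANGENTIAL_CM
        self.half_axial = 0.5 * BLOCK_AXIAL_CM
        self.z_min = float(self.cz.min() - self.half_axial)
        self.z_max = float(self.cz.max() + self.half_axial)
        rc = np.hypot(self.cx, self.cy)
        self.r_outer = float(np.max(np.hypot(rc + self.half_radial, self.half_tangential)))
        self.lambda_cm = scanner.material.attenuation_length_511_mm / 10.0

    def first_hit(self, pos, d):
        """First block index hit by each ray and the chord inside it.

        Returns (block_row, entry_t, chord); block_row == -1 on miss.
        """
        n = len(pos)
        px, py, pz = pos[:, 0], pos[:, 1], pos[:, 2]
        dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
        best_t = np.full(n, np.inf)
        best_chord = np.zeros(n)
        best_block = np.full(n, -1, dtype=np.int64)
        # cheap axial prefilter: does the ray reach the block z-band while
        # still within the outer radius of the detector assembly?
        cand = _axial_overlap(px, py, pz, dx, dy, dz, self.z_min, self.z_max, self.r_outer)
        if not np.any(cand):
            return best_block, best_t, best_chord
        sub = np.nonzero(cand)[0]
        px, py, pz, dx, dy, dz = px[sub], py[sub], pz[sub], dx[sub], dy[sub], dz[sub]
        m = len(sub)
        t_best = np.full(m, np.inf)
        c_best = np.zeros(m)
        b_best = np.full(m, -1, dtype=np.int64)
        with np.errstate(divide="ignore", invalid="ignore"):
            for k in range(self.n_blocks):
                ca, sa = self.cos_az[k], self.sin_az[k]
                u = (px - self.cx[k]) * ca + (py - self.cy[k]) * sa
                v = -(px - self.cx[k]) * sa + (py - self.cy[k]) * ca
                w = pz - self.cz[k]
                du = dx * ca + dy * sa
                dv = -dx * sa + dy * ca
                dw = dz
                t_lo, t_hi = _slab(u, du, self.half_radial)
                lo2, hi2 = _slab(v, dv, self.half_tangential)
                t_lo, t_hi = np.maximum(t_lo, lo2), np.minimum(t_hi, hi2)
                lo3, hi3 = _slab(w, dw, self.half_axial)
                t_lo, t_hi = np.maximum(t_lo, lo3), np.minimum(t_hi, hi3)
                hit = (t_hi > t_lo) & (t_hi > 0)
                entry = np.maximum(t_lo, 0.0)
                closer = hit & (entry < t_best)
                t_best = np.where(closer, entry, t_best)
                c_best = np.where(closer, t_hi - entry, c_best)
                b_best = np.where(closer, k, b_best)
        best_t[sub] = t_best
        best_chord[sub] = c_best
        best_block[sub] = b_best
        return best_block, best_t, best_chord


def _slab(p, dp, half):
    dp_safe = np.where(np.abs(dp) < 1e-300, 1e-300, dp)
    a = (-half - p) / dp_safe
    b = (half - p) / dp_safe
    return np.minimum(a, b), np.maximum(a, b)


def _axial_overlap(px, py, pz, dx, dy, dz, z_min, z_max, r_outer):
    """True when the forward ray has any z in [z_min, z_max] while its
    transaxial radius is still below r_outer."""
    a = dx * dx + dy * dy
    b = px * dx + py * dy
    c = px * px + py * py - r_outer * r_outer
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = np.clip(b * b - a * c, 0.0, None)
        sq = np.sqrt(disc)
        a_safe = np.where(a < 1e-14, 1.0, a)
        t_out = np.where(a < 1e-14, np.inf, (-b + sq) / a_safe)
    t_out = np.maximum(t_out, 0.0)
    z0 = pz
    z1 = pz + dz * np.minimum(t_out, 1e6)
    z_lo = np.minimum(z0, z1)
    z_hi = np.maximum(z0, z1)
    return (z_hi >= z_min) & (z_lo <= z_max)


def detect_batch(
    sarr: _ScannerArrays,
    pos: np.ndarray,
    d: np.ndarray,
    energies: np.ndarray,
    times: np.ndarray,
    decay_ids: np.ndarray,
    scattered: np.ndarray,
    rng: np.random.Generator,
    *,
    jitter_ns: float = 1.0,
) -> SinglesBatch:
    """Test escaped photons against the scanner; returns accepted singles.

    The first intersected block is tested with the chord interaction
    probability; an accepted hit deposits its full incident energy, which
    is then blurred and energy-windowed.
    """
    from .scanner import blur_energy  # local import to avoid cycle at module load

    block_row, _t, chord = sarr.first_hit(pos, d)
    hit = block_row >= 0
    if not np.any(hit):
        return SinglesBatch(
            np.empty(0), np.empty(0, int), np.empty(0), np.empty(0, np.int64), np.empty(0, bool)
        )
    idx = np.nonzero(hit)[0]
    p_det = 1.0 - np.exp(-chord[idx] / sarr.lambda_cm)
    accepted = rng.random(len(idx)) < p_det
    idx = idx[accepted]
    blurred = blur_energy(energies[idx], sarr.scanner.material, rng)
    low, high = sarr.scanner.energy_window_keV
    in_window = (blurred >= low) & (blurred <= high)
    idx = idx[in_window]
    blurred = blurred[in_window]
    t = times[idx] + rng.normal(0.0, jitter_ns * 1e-9, len(idx))
    return SinglesBatch(
        times=t,
        blocks=sarr.ids[block_row[idx]],
        energies=blurred,
        decay_ids=decay_ids[idx],
        scattered=scattered[idx],
    )


def detect_photon(photon, scanner: ScannerConfig, rng: np.random.Generator, *,
                  time: float = 0.0, decay_id: int = 0, scattered: bool = False,
                  jitter_ns: float = 0.0):
    """Per-photon wrapper over :func:`detect_batch`; None when not detected."""
    pos, d, energy = photon
    sarr = scanner if isinstance(scanner, _ScannerArrays) else _ScannerArrays(scanner)
    batch = detect_batch(
        sarr,
        np.asarray(pos, float)[None, :],
        np.asarray(d, float)[None, :],
        np.array([energy], float),
        np.array([time], float),
        np.array([decay_id], np.int64),
        np.array([scattered], bool),
        rng,
        jitter_ns=jitter_ns,
    )
    if len(batch) == 0:
        return None
    return SingleEvent(
        time=float(batch.times[0]),
        block=int(batch.blocks[0]),
        energy=float(batch.energies[0]),
        decay_id=int(batch.decay_ids[0]),
        scattered=bool(batch.scattered[0]),
    )


# ---------------------------------------------------------------------------
# deadtime, coincidence sorting, classification

def apply_deadtime_per_block(singles: SinglesBatch, tau_s: float) -> SinglesBatch:
    """Non-paralyzable deadtime applied independently per block.

    Input must be time-sorted; output remains time-sorted.
    """
    if len(singles) == 0 or tau_s == 0:
        return singles
    keep = np.zeros(len(singles), dtype=bool)
    for b in np.unique(singles.blocks):
        sel = np.nonzero(singles.blocks == b)[0]
        keep[sel] = apply_deadtime(singles.times[sel], tau_s)
    return SinglesBatch(
        singles.times[keep], singles.blocks[keep], singles.energies[keep],
        singles.decay_ids[keep], singles.scattered[keep],
    )


def sort_coincidences(singles: SinglesBatch, window_s: float) -> CoincidenceBatch:
    """Window-based coincidence sorting with the keep-if-all-are-good policy.

    A window opens at the earliest unconsumed single and collects every
    single within ``window_s``.  Exactly two collected on different blocks
    form one coincidence; three or more form all pairwise coincidences
    only when every pair is good (all blocks distinct), otherwise the
    whole multiple is discarded.  Consumed singles are not reused.
    """
    times = singles.times
    if np.any(np.diff(times) < 0):
        raise ValueError("singles must be sorted by time")
    n = len(times)
    first: list[int] = []
    second: list[int] = []
    if n:
        close = np.searchsorted(times, times + window_s, side="right")
        blocks = singles.blocks
        i = 0
        while i < n:
            j = int(close[i])
            k = j - i
            if k >= 2:
                cluster = blocks[i:j]
                if len(np.unique(cluster)) == k:  # every pair on distinct blocks
                    for p in range(i, j):
                        for q in range(p + 1, j):
                            first.append(p)
                            second.append(q)
            i = j
    first_a = np.array(first, dtype=np.int64)
    second_a = np.array(second, dtype=np.int64)
    kinds = _classify_batch(singles, first_a, second_a)
    return CoincidenceBatch(first=first_a, second=second_a, kinds=kinds)


def _classify_batch(singles: SinglesBatch, first: np.ndarray, second: np.ndarray) -> np.ndarray:
    same = singles.decay_ids[first] == singles.decay_ids[second]
    any_scatter = singles.scattered[first] | singles.scattered[second]
    kinds = np.where(~same, "random", np.where(any_scatter, "scattered", "true"))
    return kinds.astype("U9")


def classify_coincidence(coinc: CoincidenceEvent) -> str:
    """true: same decay, neither phantom-scattered; scattered: same decay,
    any scattered; random: different decays."""
    a, b = coinc.first, coinc.second
    if a.decay_id != b.decay_id:
        return "random"
    return "scattered" if (a.scattered or b.scattered) else "true"


# ---------------------------------------------------------------------------
# full pipeline

def simulate(
    timeline: ActivityTimeline,
    phantom: PhantomModel,
    scanners: dict[str, ScannerConfig],
    seed_seq: np.random.SeedSequence | int,
    *,
    jitter_ns: float = 1.0,
    chunk_decays: int = 250_000,
) -> dict[str, SimulationResult]:
    """Run the full chain for one timeline against one or more scanners.

    Decay sampling and phantom transport are shared across scanners (the
    phantom physics does not depend on the detector); detection and
    digitization use an independent substream per scanner, so a
    multi-scanner comparison sees the identical source realization.
    """
    if isinstance(seed_seq, (int, np.integer)):
        seed_seq = np.random.SeedSequence(int(seed_seq))
    children = seed_seq.spawn(2 + len(scanners))
    decay_rng = np.random.Generator(np.random.PCG64(children[0]))
    transport_rng = np.random.Generator(np.random.PCG64(children[1]))
    detect_rngs = {
        name: np.random.Generator(np.random.PCG64(child))
        for name, child in zip(scanners, children[2:])
    }
    geom = _PhantomArrays(phantom)
    sarrs = {name: _ScannerArrays(sc) for name, sc in scanners.items()}

    decays = sample_decays(timeline, decay_rng)
    n_decays = len(decays)
    per_scanner: dict[str, list[SinglesBatch]] = {name: [] for name in scanners}
    for start in range(0, n_decays, chunk_decays):
        sl = slice(start, min(start + chunk_decays, n_decays))
        pos = decays.positions[sl]
        t = decays.times[sl]
        ids = decays.ids[sl]
        d1 = isotropic_directions(len(t), transport_rng)
        pos2 = np.vstack([pos, pos])
        dirs = np.vstack([d1, -d1])
        t2 = np.concatenate([t, t])
        ids2 = np.concatenate([ids, ids])
        alive, p_out, d_out, e_out, sc_out = transport_batch(geom, pos2, dirs, transport_rng)
        if not np.any(alive):
            continue
        p_out, d_out = p_out[alive], d_out[alive]
        e_out, t_out = e_out[alive], t2[alive]
        id_out, flag_out = ids2[alive], sc_out[alive]
        for name, sarr in sarrs.items():
            per_scanner[name].append(
                detect_batch(
                    sarr, p_out, d_out, e_out, t_out, id_out, flag_out,
                    detect_rngs[name], jitter_ns=jitter_ns,
                )
            )

    results = {}
    for name, sc in scanners.items():
        singles = SinglesBatch.concatenate(per_scanner[name]).sorted_by_time()
        singles = apply_deadtime_per_block(singles, sc.deadtime_s)
        coinc = sort_coincidences(singles, sc.coincidence_window_ns * 1e-9)
        results[name] = SimulationResult(
            singles=singles, coincidences=coinc, n_decays=n_decays, scanner=sc
        )
    return results
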