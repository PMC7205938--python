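"""1-D plug-flow advection of tracer through the phantom vessels.

Each vessel is a plug-flow tube: the inlet concentration curve (the BTAC
model) is carried downstream without internal mixing, so the concentration
at distance ``x`` from the inlet at time ``t`` equals the inlet curve at
the retarded (emission) time tau solving

    displacement(t) - displacement(tau) = x .

Blood enters the arteries at the distal end and flows +Z; venous return
re-enters at +Z and flows -Z at 5 cm/s, carrying the dispersed venous
curve delayed by the tracer's venous delay.  Velocities are either uniform
or a pulsatile single-beat waveform repeated at the heart rate.

Units: cm, s, cm/s; activities Bq (concentrations kBq/ml are converted
via segment volume in ml, 1 kBq = 1000 Bq).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import AIFParams, aif_value
from .phantom import CylinderVolume, PhantomModel

__all__ = [
    "VelocityWaveform",
    "VesselFlow",
    "ActivityTimeline",
    "displacement",
    "retarded_time",
    "concentration_at",
    "activity_timeline",
    "point_source_timeline",
    "default_pulsatile_waveform",
]


@dataclass(frozen=True)
class VelocityWaveform:
    """Uniform or tabulated single-beat velocity profile, repeated periodically.

    ``samples`` tabulate v(phase) on ``phases`` in [0, 1] over one beat;
    the waveform must be non-negative everywhere.
    """

    kind: str  # "uniform" | "pulsatile"
    mean: float  # cm/s
    beat_period: float  # s
    phases: np.ndarray = field(repr=False)
    samples: np.ndarray = field(repr=False)  # cm/s

    def __post_init__(self) -> None:
        if self.beat_period <= 0:
            raise ValueError("beat_period must be > 0")
        if np.any(self.samples < 0):
            raise ValueError("velocity waveform must be >= 0 everywhere")
        if self.kind == "uniform" and np.ptp(self.samples) != 0:
            raise ValueError("uniform waveform must have constant samples")

    @classmethod
    def uniform(cls, mean: float, beat_period: float = 1.0) -> "VelocityWaveform":
        if mean < 0:
            raise ValueError("mean velocity must be >= 0")
        phases = np.array([0.0, 1.0])
        return cls("uniform", mean, beat_period, phases, np.full(2, float(mean)))

    @classmethod
    def from_samples(cls, phases, samples, beat_period: float = 1.0) -> "VelocityWaveform":
        phases = np.asarray(phases, dtype=float)
        samples = np.asarray(samples, dtype=float)
        mean = float(np.trapezoid(samples, phases) / (phases[-1] - phases[0]))
        return cls("pulsatile", mean, beat_period, phases, samples)

    def _period_displacement(self) -> float:
        return float(np.trapezoid(self.samples, self.phases) * self.beat_period)


def default_pulsatile_waveform(
    v_systolic: float = 40.0,
    v_diastolic: float = 5.0,
    systolic_width: float = 0.35,
    beat_period: float = 1.0,
    n: int = 512,
) -> VelocityWaveform:
    """Parametric single-beat radial-artery waveform.

    v(phi) = v_dia + (v_sys - v_dia) * max(0, sin(pi*phi/w))^2 for phase
    phi in [0, 1): a smooth systolic peak of width ``w`` on a diastolic
    baseline, repeated at the heart rate (default 60 bpm).  A parametric
    stand-in with the mean-flow role of a measured profile.
    """
    phi = np.linspace(0.0, 1.0, n)
    burst = np.where(phi < systolic_width, np.sin(np.pi * phi / systolic_width) ** 2, 0.0)
    v = v_diastolic + (v_systolic - v_diastolic) * burst
    return VelocityWaveform.from_samples(phi, v, beat_period)


def displacement(waveform: VelocityWaveform, t):
    """Integral of velocity from 0 to t (cm); strictly non-decreasing.

    Closed form for uniform waveforms; whole-beat bookkeeping plus
    trapezoidal quadrature of the tabulated beat otherwise.  Accepts
    scalar or array ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if waveform.kind == "uniform":
        out = waveform.mean * t_arr
        return float(out) if out.ndim == 0 else out
    period = waveform.beat_period
    n_beats = np.floor(t_arr / period)
    frac = t_arr / period - n_beats
    # cumulative displacement over one beat, tabulated on the phase grid
    cum = np.concatenate(
        [[0.0], np.cumsum(np.diff(waveform.phases) * 0.5 * (waveform.samples[1:] + waveform.samples[:-1]))]
    ) * period
    out = n_beats * cum[-1] + np.interp(frac, waveform.phases, cum)
    return float(out) if out.ndim == 0 else out


def retarded_time(waveform: VelocityWaveform, x: float, t: float):
    """Emission time tau <= t with displacement(t) - displacement(tau) = x.

    Returns ``None`` when the bolus front has not yet reached x
    (displacement(t) < x).  Uniform waveforms use the closed form
    tau = t - x/v; otherwise monotone bisection.
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    if x == 0:
        return t
    d_t = displacement(waveform, t)
    if d_t < x:
        return None
    if waveform.kind == "uniform":
        return t - x / waveform.mean
    lo, hi = 0.0, t  # g(tau) = d_t - disp(tau) - x: g(lo) >= 0 >= g(hi)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if d_t - displacement(waveform, mid) - x >= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class _DisplacementTable:
    """Dense displacement grid for vectorized retarded-time inversion."""

    def __init__(self, waveform: VelocityWaveform, horizon: float, dt: float = 2e-3):
        self.waveform = waveform
        self.t = np.arange(0.0, horizon + dt, dt)
        self.d = displacement(waveform, self.t)

    def retarded(self, x, t):
        """Vectorized tau (NaN where the front has not arrived)."""
        x = np.asarray(x, dtype=float)
        t = np.asarray(t, dtype=float)
        d_t = np.interp(t, self.t, self.d)
        target = d_t - x
        tau = np.interp(target, self.d, self.t)
        return np.where(target < 0, np.nan, tau)


@dataclass(frozen=True)
class VesselFlow:
    """Advection state of one vessel: inlet curve, waveform and direction."""

    vessel: CylinderVolume
    inlet: AIFParams
    inlet_delay: float  # s (0 for arteries, venous_delay for veins)
    waveform: VelocityWaveform
    direction: int  # +1 (artery, flows +Z) | -1 (vein, flows -Z)

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.inlet_delay < 0:
            raise ValueError("inlet_delay must be >= 0")

    @property
    def inlet_position(self) -> float:
        """Axial coordinate of the vessel end where blood enters."""
        return -self.direction * self.vessel.half_length

    def distance_from_inlet(self, z) -> np.ndarray:
        return (np.asarray(z, dtype=float) - self.inlet_position) * self.direction


def concentration_at(flow: VesselFlow, z: float, t: float) -> float:
    """Concentration at axial position z and time t (0 before front arrival)."""
    h = flow.vessel.half_length
    if not -h - 1e-9 <= z <= h + 1e-9:
        raise ValueError(f"z={z} outside vessel extent [-{h}, {h}]")
    dist = float(flow.distance_from_inlet(z))
    tau = retarded_time(flow.waveform, dist, t)
    if tau is None:
        return 0.0
    return float(aif_value(flow.inlet, tau - flow.inlet_delay))


@dataclass(frozen=True)
class ActivityTimeline:
    """Per-(vessel-segment, time-window) activity table, Bq.

    Windows are [starts[j], stops[j]) and may be disjoint (the decaying
    point-source schedule uses gaps); segments are short coaxial cylinders
    (or a point when ``radius``/``half_length`` are 0).
    """

    starts: np.ndarray  # (n_windows,) s
    stops: np.ndarray  # (n_windows,) s
    seg_x: np.ndarray  # (n_segments,) cm
    seg_y: np.ndarray
    seg_z: np.ndarray
    seg_radius: np.ndarray  # cm
    seg_half_length: np.ndarray  # cm
    seg_label: tuple[str, ...]
    activity: np.ndarray  # (n_segments, n_windows) Bq

    def __post_init__(self) -> None:
        if np.any(self.activity < 0):
            raise ValueError("activities must be >= 0")
        if np.any(self.stops <= self.starts):
            raise ValueError("windows must have positive duration")

    @property
    def n_segments(self) -> int:
        return len(self.seg_x)

    @property
    def durations(self) -> np.ndarray:
        return self.stops - self.starts

    def total_activity(self) -> np.ndarray:
        """Total phantom activity per window, Bq."""
        return self.activity.sum(axis=0)

    def expected_decays(self) -> float:
        return float(self.activity.sum(axis=0) @ self.durations)

    def to_dataframe(self) -> pd.DataFrame:
        seg, win = np.meshgrid(np.arange(self.n_segments), np.arange(len(self.starts)), indexing="ij")
        return pd.DataFrame(
            {
                "segment": seg.ravel(),
                "label": np.asarray(self.seg_label)[seg.ravel()],
                "z_cm": self.seg_z[seg.ravel()],
                "t_start_s": self.starts[win.ravel()],
                "t_stop_s": self.stops[win.ravel()],
                "activity_Bq": self.activity.ravel(),
            }
        )


def activity_timeline(
    phantom: PhantomModel,
    flows,
    time_step: float = 0.1,
    segment_length: float = 0.5,
    horizon: float = 300.0,
    *,
    scale: float = 1.0,
) -> ActivityTimeline:
    """Discretize vessel flows into a per-segment, per-bin activity table.

    Each vessel is split axially into ``segment_length`` pieces; the
    concentration is sampled at the segment midpoint and the bin midpoint
    and converted to activity by the exact segment volume (ml).  ``scale``
    multiplies all activities (the history scaling factor).
    """
    if time_step <= 0 or segment_length <= 0:
        raise ValueError("time_step and segment_length must be > 0")
    if time_step > horizon:
        raise ValueError("time_step larger than horizon")
    n_bins = int(round(horizon / time_step))
    edges = np.linspace(0.0, n_bins * time_step, n_bins + 1)
    mid_t = 0.5 * (edges[:-1] + edges[1:])

    seg_x, seg_y, seg_z, seg_r, seg_h, labels = [], [], [], [], [], []
    rows = []
    for flow in flows:
        vessel = flow.vessel
        n_seg = max(1, int(round(vessel.length / segment_length)))
        seg_len = vessel.length / n_seg
        z_centers = -vessel.half_length + (np.arange(n_seg) + 0.5) * seg_len
        dist = flow.distance_from_inlet(z_centers)
        table = _DisplacementTable(flow.waveform, horizon)
        tau = table.retarded(dist[:, None], mid_t[None, :])
        conc = np.where(
            np.isnan(tau), 0.0, aif_value(flow.inlet, np.nan_to_num(tau) - flow.inlet_delay)
        )  # kBq/ml
        seg_volume_ml = np.pi * vessel.radius**2 * seg_len
        rows.append(conc * seg_volume_ml * 1000.0 * scale)  # Bq
        seg_x.extend([vessel.center[0]] * n_seg)
        seg_y.extend([vessel.center[1]] * n_seg)
        seg_z.extend(z_centers)
        seg_r.extend([vessel.radius] * n_seg)
        seg_h.extend([0.5 * seg_len] * n_seg)
        labels.extend(f"{vessel.label}:{i}" for i in range(n_seg))
    return ActivityTimeline(
        starts=edges[:-1],
        stops=edges[1:],
        seg_x=np.array(seg_x),
        seg_y=np.array(seg_y),
        seg_z=np.array(seg_z),
        seg_radius=np.array(seg_r),
        seg_half_length=np.array(seg_h),
        seg_label=tuple(labels),
        activity=np.vstack(rows),
    )


def point_source_timeline(
    position,
    activities_Bq,
    starts,
    stops,
    *,
    label: str = "point-source",
    radius: float = 0.0,
    half_length: float = 0.0,
) -> ActivityTimeline:
    """Timeline for a small stationary source with per-window activity.

    Default extent is a true point; a small cube-equivalent source can be
    approximated by passing a matching radius/half-length.
    """
    x, y, z = position
    activities = np.atleast_1d(np.asarray(activities_Bq, dtype=float))
    return ActivityTimeline(
        starts=np.atleast_1d(np.asarray(starts, dtype=float)),
        stops=np.atleast_1d(np.asarray(stops, dtype=float)),
        seg_x=np.array([x]),
        seg_y=np.array([y]),
        seg_z=np.array([z]),
        seg_radius=np.array([radius]),
        seg_half_length=np.array([half_length]),
        seg_label=(label,),
        activity=activities[None, :],
    )
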