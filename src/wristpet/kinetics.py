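"""Blood time-activity curve (BTAC) model, fitting and export.

The arterial input function is a piecewise linear-exponential:

    AIF(t) = 0                                  for t <= t0
           = a*t + b                            for t0 < t < t1
           = c1*exp(d1*t) + c2*exp(d2*t)        for t >= t1

with the published rate constants d1, d2 stored exactly as printed
(negative), so the tail decays.  The breakpoints are not published: t0 is
the ramp zero-crossing clamped at 0, and t1 is the first ramp/tail
intersection, which makes the curve continuous and single-peaked by
construction.

This module is the synthetic-data generator of the study: the shipped
parameter sets stand in for curves measured with an automated arterial
blood sampler after injections of [15O]-H2O and [18F]-fallypride.
Concentrations are kBq/ml (a package convention, re-scalable in config);
times are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "AIFParams",
    "TracerSpec",
    "NoIntersectionError",
    "DegenerateFitError",
    "aif_value",
    "solve_breakpoints",
    "fit_aif",
    "decayed_activity",
    "export_curve",
    "read_curve",
    "TRACERS",
]


class NoIntersectionError(ValueError):
    """The ramp never meets the exponential tail within the horizon."""


class DegenerateFitError(ValueError):
    """The samples carry no curve shape to fit (constant or all zero)."""


@dataclass(frozen=True)
class AIFParams:
    """Coefficients of the linear-exponential BTAC model.

    ``d1``/``d2`` follow the printed sign convention (negative values used
    as-is inside exp(d*t)).  Breakpoints ``t0``/``t1`` are derived, not
    free: see :func:`solve_breakpoints`.
    """

    a: float  # ramp slope, concentration/s
    b: float  # ramp intercept, concentration
    c1: float  # tail amplitude, concentration
    c2: float  # tail amplitude, concentration
    d1: float  # tail rate constant, 1/s (negative as printed)
    d2: float  # tail rate constant, 1/s (negative as printed)
    t0: float  # s
    t1: float  # s
    unit: str = "kBq/ml"

    def __post_init__(self) -> None:
        if not self.t0 < self.t1:
            raise ValueError("breakpoints must satisfy t0 < t1")

    @classmethod
    def from_coefficients(
        cls, a, b, c1, c2, d1, d2, *, horizon: float = 600.0, unit: str = "kBq/ml"
    ) -> "AIFParams":
        t0, t1 = solve_breakpoints(a, b, c1, c2, d1, d2, horizon=horizon)
        return cls(a, b, c1, c2, d1, d2, t0, t1, unit=unit)

    @property
    def coefficients(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c1, self.c2, self.d1, self.d2)

    def peak(self, horizon: float = 600.0, n: int = 20001) -> float:
        t = np.linspace(0.0, horizon, n)
        return float(np.max(aif_value(self, t)))

def _tail(t, c1, c2, d1, d2):
    return c1 * np.exp(d1 * np.asarray(t, dtype=float)) + c2 * np.exp(
        d2 * np.asarray(t, dtype=float)
    )


def aif_value(params: AIFParams, t):
    """Evaluate the BTAC model; total function of t, vectorized, >= 0.

    Delays (e.g. the venous return) are applied by shifting the time
    argument: ``aif_value(params, t - delay)``.
    """
    t = np.asarray(t, dtype=float)
    ramp = params.a * t + params.b
    tail = _tail(t, params.c1, params.c2, params.d1, params.d2)
    out = np.where(t <= params.t0, 0.0, np.where(t < params.t1, ramp, tail))
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def solve_breakpoints(a, b, c1, c2, d1, d2, *, horizon: float = 600.0):
    """Derive (t0, t1) from the published coefficients.

    t0 = max(0, -b/a) (ramp zero-crossing, clamped at 0); t1 is the
    smallest t > t0 where the ramp meets the exponential tail, bracketed
    on a dense grid and polished by Brent's method to ~1e-12 s.
    """
    if a == 0:
        raise ValueError("ramp slope a must be nonzero")
    t0 = max(0.0, -b / a)
    if t0 >= horizon:
        raise NoIntersectionError("t0 beyond the search horizon")

    def f(t):
        return a * t + b - (c1 * np.exp(d1 * t) + c2 * np.exp(d2 * t))

    grid = np.linspace(t0, horizon, 20001)
    vals = f(grid)
    sign = np.signbit(vals)
    crossings = np.nonzero(sign[:-1] != sign[1:])[0]
    t1 = None
    for i in crossings:
        lo, hi = grid[i], grid[i + 1]
        if hi <= t0:
            continue
        root = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
        if root > t0 + 1e-12:
            t1 = root
            break
        # exact-zero at t0 (e.g. b clamp); keep searching
    # a grid node landing exactly on the root leaves no sign flip pair
    if t1 is None:
        exact = np.nonzero(vals == 0.0)[0]
        for i in exact:
            if grid[i] > t0 + 1e-12:
                t1 = float(grid[i])
                break
    if t1 is None:
        raise NoIntersectionError(
            f"ramp and tail do not intersect in ({t0}, {horizon}] s"
        )
    return t0, t1


def decayed_activity(A0: float, t: float, half_life: float):
    """Radioactive decay A0 * 2**(-t / half_life); accepts array t."""
    if A0 < 0:
        raise ValueError("A0 must be >= 0")
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = A0 * np.exp2(-t / half_life)
    return float(out) if out.ndim == 0 else out


def _model_curve(coeffs, t, horizon):
    a, b, c1, c2, d1, d2 = coeffs
    try:
        t0, t1 = solve_breakpoints(a, b, c1, c2, d1, d2, horizon=horizon)
    except (NoIntersectionError, ValueError):
        return None
    ramp = a * t + b
    tail = _tail(t, c1, c2, d1, d2)
    return np.maximum(np.where(t <= t0, 0.0, np.where(t < t1, ramp, tail)), 0.0)


def _initial_guess(t, y):
    """Crude curve-shape heuristic for a starting point."""
    i_peak = int(np.argmax(y))
    peak = y[i_peak]
    t_peak = max(t[i_peak], 1.0)
    nonzero = np.nonzero(y > 0.02 * peak)[0]
    t_start = t[nonzero[0]] if len(nonzero) else 0.0
    a = peak / max(t_peak - t_start, 1.0)
    b = -a * t_start
    d1, d2 = -4e-2, -1e-4
    c1 = peak * np.exp(-d1 * t_peak)
    c2 = max(y[-1] * np.exp(-d2 * t[-1]), 1e-3 * peak)
    return np.array([a, b, c1, c2, d1, d2])


def fit_aif(samples, initial_guess=None, *, horizon: float = 600.0):
    """Least-squares fit of the linear-exponential model to (t, conc) pairs.

    Continuity at t1 is enforced structurally: the breakpoints are
    re-solved from the trial coefficients at every evaluation, so the
    fitted curve is continuous by construction.  Returns
    ``(AIFParams, r_squared)``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] < 8:
        raise ValueError("need >= 8 (t, concentration) samples")
    t, y = samples[:, 0], samples[:, 1]
    if np.ptp(y) == 0.0:
        raise DegenerateFitError("samples are constant; nothing to fit")
    p0 = np.asarray(initial_guess, dtype=float) if initial_guess is not None else _initial_guess(t, y)
    scale = float(np.max(np.abs(y)))
    big = np.full_like(y, 10.0 * scale)

    def residuals(coeffs):
        model = _model_curve(coeffs, t, horizon)
        if model is None:
            return big
        return model - y

    sol = least_squares(residuals, p0, method="lm", max_nfev=20000)
    fitted = AIFParams.from_coefficients(*sol.x, horizon=horizon)
    model = aif_value(fitted, t)
    ss_res = float(np.sum((model - y) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return fitted, r2


def export_curve(
    params: AIFParams,
    step: float,
    horizon: float,
    path,
    *,
    delay: float = 0.0,
) -> Path:
    """Write the curve as a two-column CSV (time_s, concentration).

    ``delay`` shifts the curve right (used for the venous return, which
    starts ``venous_delay`` seconds after the arterial curve).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    t = np.arange(0.0, horizon + 0.5 * step, step)
    t = t[t <= horizon + 1e-12]
    conc = aif_value(params, t - delay)
    unit_col = f"concentration_{params.unit.replace('/', '_per_')}"
    df = pd.DataFrame({"time_s": t, unit_col: conc})
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_curve(path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass(frozen=True)
class TracerSpec:
    """A radiotracer with its fitted arterial and venous BTAC models."""

    name: str
    half_life: float  # s
    injected_activity_MBq: float  # study-context metadata
    arterial: AIFParams
    venous: AIFParams
    venous_delay: float = 5.0  # s, venous return reference delay

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")
        if self.venous_delay < 0:
            raise ValueError("venous_delay must be >= 0")


# Published fit coefficients, stored exactly as printed.  Half-lives are
# standard nuclear data (not printed in the source study).
O15_WATER = TracerSpec(
    name="[15O]H2O",
    half_life=122.24,
    injected_activity_MBq=1000.0,
    arterial=AIFParams.from_coefficients(9.248, 1.535e3, 1.959e5, 2.061, -3.902e-2, -8.271e-5),
    venous=AIFParams.from_coefficients(2.606, -4.458e2, 1.810e5, 2.060, -3.902e-2, -8.271e-4),
    venous_delay=5.0,
)

F18_FALLYPRIDE = TracerSpec(
    name="[18F]fallypride",
    half_life=6586.2,
    injected_activity_MBq=250.0,
    arterial=AIFParams.from_coefficients(2.956, -4.907e2, 6.088e4, 2.059, -3.902e-2, -8.271e-5),
    venous=AIFParams.from_coefficients(1.291e-1, -2.209e1, 1.197e4, 2.060, -3.902e-2, -8.271e-4),
    venous_delay=5.0,
)

TRACERS: dict[str, TracerSpec] = {
    "O15-water": O15_WATER,
    "F18-fallypride": F18_FALLYPRIDE,
}
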