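"""End-to-end reproductions of the study's four experiments.

Each runner takes a :class:`~wristpet.config.RunConfig` and returns a
python result object; when ``out_dir`` is set, it also writes a fixed
output layout (rates.csv / necr.csv / gains.csv / summary.json / run.log)
with the seed, history-scale and config hash recorded in every file.

History scaling: BTAC experiments run at ``scale`` times the clinical
activity and report rates per run, so rate *ratios* (volar fraction,
gains) are scale-invariant.  The decaying-source experiment instead
shortens acquisition windows at full activity, because deadtime and
randoms must act at physical rates there.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .flow import (
    VelocityWaveform,
    VesselFlow,
    activity_timeline,
    default_pulsatile_waveform,
)
from .kinetics import TRACERS, TracerSpec
from .phantom import PhantomModel, build_forearm_phantom, water_cylinder_phantom
from .scanner import CRYSTALS, HALF_RING_INDICES, ScannerConfig, build_wristpet1, build_wristpet2
from .engine import SimulationResult, simulate
from .rates import (
    CountRateCurve,
    NECRExperimentResult,
    bin_rates,
    gain_table,
    necr_experiment,
    sensitivity,
    singles_fraction,
)

__all__ = [
    "run_crystal_comparison",
    "run_necr_experiment",
    "run_btac_experiment",
    "run_ring_scaling",
    "build_flows",
    "build_timeline",
]

log = logging.getLogger("wristpet")


def _arterial_waveform(cfg: RunConfig) -> VelocityWaveform:
    f = cfg.flow
    if f["arterial_waveform"] == "uniform":
        return VelocityWaveform.uniform(f["arterial_mean_cm_s"])
    return default_pulsatile_waveform(
        v_systolic=f["v_systolic_cm_s"],
        v_diastolic=f["v_diastolic_cm_s"],
        systolic_width=f["systolic_width"],
        beat_period=f["beat_period_s"],
    )


def build_flows(
    phantom: PhantomModel,
    tracer: TracerSpec,
    cfg: RunConfig,
    *,
    arterial: bool = True,
    venous: bool = True,
) -> list[VesselFlow]:
    """Arterial (+Z) and venous-return (-Z) flows for the forearm phantom."""
    flows = []
    if arterial:
        wf = _arterial_waveform(cfg)
        for label in ("radial_artery", "ulnar_artery"):
            flows.append(VesselFlow(phantom.volume(label), tracer.arterial, 0.0, wf, +1))
    if venous:
        wf_v = VelocityWaveform.uniform(cfg.flow["venous_speed_cm_s"])
        for label in ("radial_vein", "ulnar_vein"):
            flows.append(
                VesselFlow(phantom.volume(label), tracer.venous, tracer.venous_delay, wf_v, -1)
            )
    return flows


def build_timeline(phantom, flows, cfg: RunConfig):
    return activity_timeline(
        phantom,
        flows,
        time_step=cfg.time_step_s,
        segment_length=cfg.segment_length_cm,
        horizon=cfg.horizon_s,
        scale=cfg.scale,
    )


def _build_scanner(cfg: RunConfig, *, system: str, material: str | None = None,
                   n_rings: int | None = None) -> ScannerConfig:
    s = cfg.scanner
    mat = CRYSTALS[material or s["material"]]
    kwargs = dict(
        inner_diameter=s["inner_diameter_cm"],
        energy_window_keV=tuple(s["energy_window_keV"]),
        deadtime_ns=s["deadtime_ns"],
    )
    if system == "wristpet1":
        return build_wristpet1(mat, **kwargs)
    return build_wristpet2(mat, n_rings if n_rings is not None else s["n_rings"], **kwargs)


def _mean_activity_integral_kBq_s(timeline) -> float:
    return timeline.expected_decays() / 1000.0


def _summarize(result: SimulationResult, curve: CountRateCurve, timeline) -> dict:
    kBq_s = _mean_activity_integral_kBq_s(timeline)
    if kBq_s <= 0:  # silent source (e.g. curve onset beyond the horizon)
        kBq_s = float("inf")
    return {
        "n_decays": result.n_decays,
        "n_singles": len(result.singles),
        "n_coincidences": len(result.coincidences),
        "n_trues": result.coincidences.count("true"),
        "n_scattered": result.coincidences.count("scattered"),
        "n_randoms": result.coincidences.count("random"),
        "peak_singles_cps": curve.peak_rate("singles"),
        "peak_coincidences_cps": curve.peak_rate("prompts"),
        "peak_trues_cps": curve.peak_rate("trues"),
        "sensitivity_singles_cps_per_kBq": sensitivity(len(result.singles), kBq_s, 1.0),
        "sensitivity_coincidences_cps_per_kBq": sensitivity(len(result.coincidences), kBq_s, 1.0),
    }


def _write_outputs(out_dir, cfg: RunConfig, summary: dict, tables: dict[str, pd.DataFrame]):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = cfg.metadata()
    header = "".join(f"# {k}: {v}\n" for k, v in meta.items())
    for name, df in tables.items():
        path = out / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump({**meta, **summary}, fh, indent=2, default=float)
    with open(out / "run.log", "a") as fh:
        fh.write(f"{meta}\n")


# ---------------------------------------------------------------------------

@dataclass
class CrystalComparisonResult:
    curves: dict[str, CountRateCurve]
    summaries: dict[str, dict]
    ranking: list[str]  # by peak coincidence rate, best first


def run_crystal_comparison(cfg: RunConfig, out_dir=None, *, materials=None) -> CrystalComparisonResult:
    """wristPET1 singles/coincidence rates per crystal material.

    Uniform arterial flow, no venous return (the closed-ring protocol).
    The decay realization and phantom transport are shared across
    materials; detection is resampled per material physics.
    """
    materials = list(materials or CRYSTALS)
    unknown = [m for m in materials if m not in CRYSTALS]
    if unknown:
        raise ValueError(f"unknown crystal material(s): {unknown}")
    if len(materials) < 1:
        raise ValueError("need at least one material")
    phantom = build_forearm_phantom(cfg.phantom or None)
    tracer = TRACERS[cfg.tracer]
    cfg_uniform = cfg
    if cfg.flow["arterial_waveform"] != "uniform":
        import copy

        cfg_uniform = copy.deepcopy(cfg)
        cfg_uniform.flow["arterial_waveform"] = "uniform"
    flows = build_flows(phantom, tracer, cfg_uniform, venous=False)
    timeline = build_timeline(phantom, flows, cfg_uniform)
    scanners = {m: _build_scanner(cfg, system="wristpet1", material=m) for m in materials}
    results = simulate(timeline, phantom, scanners, cfg.seed, jitter_ns=cfg.scanner["jitter_ns"])
    curves = {m: bin_rates(r, cfg.rate_bin_s, t_max=cfg.horizon_s) for m, r in results.items()}
    summaries = {m: _summarize(results[m], curves[m], timeline) for m in materials}
    ranking = sorted(materials, key=lambda m: summaries[m]["peak_coincidences_cps"], reverse=True)
    if out_dir:
        tables = {f"rates_{m}.csv": curves[m].to_dataframe() for m in materials}
        _write_outputs(out_dir, cfg, {"ranking": ranking, "per_material": summaries}, tables)
    return CrystalComparisonResult(curves=curves, summaries=summaries, ranking=ranking)


@dataclass
class NECRStudyResult:
    per_position: dict[float, NECRExperimentResult]
    necr_max: dict[float, float]
    ratios: dict[str, float]


def run_necr_experiment(cfg: RunConfig, out_dir=None) -> NECRStudyResult:
    """Decaying 18F point source in the 8-cm water phantom, wristPET2.

    Repeats the count-rate acquisition at each vertical source position
    and summarizes NECRmax and the cross-position trues/NECRmax ratios
    (most-ventral over least-ventral position).
    """
    n = cfg.necr
    phantom = water_cylinder_phantom(radius=4.0, length=20.0)
    scanner = _build_scanner(cfg, system="wristpet2", n_rings=1)
    half_life = TRACERS["F18-fallypride"].half_life
    per_position: dict[float, NECRExperimentResult] = {}
    seed_seq = np.random.SeedSequence(cfg.seed)
    children = seed_seq.spawn(len(n["positions_y_cm"]))
    for y, child in zip(n["positions_y_cm"], children):
        per_position[y] = necr_experiment(
            scanner,
            phantom,
            (0.0, y, 0.0),
            n["A0_MBq"],
            half_life,
            child,
            n_windows=n["n_windows"],
            span_half_lives=n["span_half_lives"],
            decays_per_window=n["decays_per_window"],
        )
    necr_max = {y: r.necr_max_cps for y, r in per_position.items()}
    ys = sorted(per_position)  # most ventral (most negative) first
    y_lo, y_hi = ys[0], ys[-1]
    trues_lo = per_position[y_lo].total_trues
    trues_hi = per_position[y_hi].total_trues
    ratios = {
        "trues_ratio": trues_lo / trues_hi if trues_hi else float("nan"),
        "necr_max_ratio": necr_max[y_lo] / necr_max[y_hi] if necr_max[y_hi] else float("nan"),
        "positions_compared": f"{y_lo} vs {y_hi} cm",
    }
    if out_dir:
        tables = {
            f"necr_y{y:+.0f}cm.csv".replace("+", "p").replace("-", "m"): r.to_dataframe()
            for y, r in per_position.items()
        }
        _write_outputs(out_dir, cfg, {"necr_max_cps": {str(y): v for y, v in necr_max.items()},
                                      "ratios": ratios}, tables)
    return NECRStudyResult(per_position=per_position, necr_max=necr_max, ratios=ratios)


@dataclass
class BTACResult:
    curves: dict[str, CountRateCurve]  # per component
    summaries: dict[str, dict]
    volar_fraction: float | None  # only meaningful for the full ring


def run_btac_experiment(
    cfg: RunConfig,
    out_dir=None,
    *,
    system: str = "wristpet2",
    components=("arterial", "venous", "combined"),
) -> BTACResult:
    """Dynamic BTAC acquisition with pulsatile flow and venous return.

    Simulates the requested source components (arterial-only, venous-only
    and/or combined) with independent seeds, producing singles/prompt rate
    curves for each.  For a wristPET1 run the per-block singles histogram
    yields the volar (blocks 4-11) singles fraction.
    """
    phantom = build_forearm_phantom(cfg.phantom or None)
    tracer = TRACERS[cfg.tracer]
    scanner = _build_scanner(cfg, system=system)
    curves: dict[str, CountRateCurve] = {}
    summaries: dict[str, dict] = {}
    volar_fraction = None
    seed_seq = np.random.SeedSequence(cfg.seed)
    children = dict(zip(("arterial", "venous", "combined"), seed_seq.spawn(3)))
    for comp in components:
        flows = build_flows(
            phantom, tracer, cfg,
            arterial=comp in ("arterial", "combined"),
            venous=comp in ("venous", "combined"),
        )
        timeline = build_timeline(phantom, flows, cfg)
        result = simulate(
            timeline, phantom, {comp: scanner}, children[comp],
            jitter_ns=cfg.scanner["jitter_ns"],
        )[comp]
        curves[comp] = bin_rates(result, cfg.rate_bin_s, t_max=cfg.horizon_s)
        summaries[comp] = _summarize(result, curves[comp], timeline)
        if system == "wristpet1":
            hist = pd.Series(result.singles.blocks).value_counts().to_dict()
            summaries[comp]["volar_singles_fraction"] = singles_fraction(
                hist, HALF_RING_INDICES
            )
    main = "combined" if "combined" in components else components[0]
    volar_fraction = summaries[main].get("volar_singles_fraction")
    if out_dir:
        tables = {f"rates_{c}.csv": curves[c].to_dataframe() for c in components}
        _write_outputs(out_dir, cfg, {"per_component": summaries,
                                      "volar_singles_fraction": volar_fraction}, tables)
    return BTACResult(curves=curves, summaries=summaries, volar_fraction=volar_fraction)


@dataclass
class RingScalingResult:
    curves: dict[int, CountRateCurve]
    summaries: dict[int, dict]
    gains: pd.DataFrame


def run_ring_scaling(cfg: RunConfig, out_dir=None, *, ring_counts=(1, 2, 3, 4)) -> RingScalingResult:
    """BTAC acquisition across 1-4 axial rings with cross-ring coincidences.

    All ring counts share the identical decay realization and phantom
    transport, so the gain table isolates the detector geometry.
    """
    ring_counts = sorted(set(int(n) for n in ring_counts))
    if not set(ring_counts) <= {1, 2, 3, 4}:
        raise ValueError("ring counts must be within {1, 2, 3, 4}")
    phantom = build_forearm_phantom(cfg.phantom or None)
    tracer = TRACERS[cfg.tracer]
    flows = build_flows(phantom, tracer, cfg)
    timeline = build_timeline(phantom, flows, cfg)
    scanners = {
        str(n): _build_scanner(cfg, system="wristpet2", n_rings=n) for n in ring_counts
    }
    results = simulate(timeline, phantom, scanners, cfg.seed, jitter_ns=cfg.scanner["jitter_ns"])
    kBq_s = _mean_activity_integral_kBq_s(timeline)
    curves, summaries, runs = {}, {}, {}
    for n in ring_counts:
        r = results[str(n)]
        curves[n] = bin_rates(r, cfg.rate_bin_s, t_max=cfg.horizon_s)
        summaries[n] = _summarize(r, curves[n], timeline)
        runs[n] = {**summaries[n], "tracer": cfg.tracer}
    gains = gain_table(runs, reference_rings=min(ring_counts))
    if out_dir:
        tables = {f"rates_{n}ring.csv": curves[n].to_dataframe() for n in ring_counts}
        tables["gains.csv"] = gains
        _write_outputs(out_dir, cfg, {"per_rings": summaries}, tables)
    return RingScalingResult(curves=curves, summaries=summaries, gains=gains)
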