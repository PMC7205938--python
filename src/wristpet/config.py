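"""Run configuration: defaults, file loading (YAML/JSON), hashing.

A :class:`RunConfig` bundles everything one experiment needs — tracer,
scanner settings, phantom overrides, flow model, discretization, history
scaling and the RNG seed — so that a run is fully reproducible from
(config, seed) alone.  The seed and the config hash are recorded verbatim
in every output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]

_SCANNER_DEFAULTS = {
    "material": "BGO",
    "n_rings": 1,
    "inner_diameter_cm": 11.0,
    "energy_window_keV": [350.0, 650.0],
    "deadtime_ns": None,  # default: 3 x crystal decay time
    "jitter_ns": 1.0,
}

_FLOW_DEFAULTS = {
    "arterial_waveform": "pulsatile",  # "uniform" for the wristPET1 study
    "arterial_mean_cm_s": 15.0,
    "v_systolic_cm_s": 40.0,
    "v_diastolic_cm_s": 5.0,
    "systolic_width": 0.35,
    "beat_period_s": 1.0,
    "venous_speed_cm_s": 5.0,
}

_NECR_DEFAULTS = {
    "A0_MBq": 14.0,
    "positions_y_cm": [-1.0, -2.0, -3.0],
    "n_windows": 20,
    "span_half_lives": 5.0,
    "decays_per_window": 2.5e5,
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment end to end."""

    experiment: str = "btac"
    tracer: str = "O15-water"
    seed: int = 1
    scale: float = 0.01  # history scaling factor, (0, 1]
    horizon_s: float = 300.0
    time_step_s: float = 0.1
    segment_length_cm: float = 0.5
    rate_bin_s: float = 1.0
    scanner: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    flow: dict = field(default_factory=dict)
    necr: dict = field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.scale <= 1.0:
            raise ValueError("scale must be in (0, 1]")
        self.scanner = {**_SCANNER_DEFAULTS, **(self.scanner or {})}
        self.flow = {**_FLOW_DEFAULTS, **(self.flow or {})}
        self.necr = {**_NECR_DEFAULTS, **(self.necr or {})}

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k not in ("seed", "out_dir")}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def metadata(self) -> dict:
        return {
            "experiment": self.experiment,
            "tracer": self.tracer,
            "seed": self.seed,
            "history_scale": self.scale,
            "config_hash": self.config_hash(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})


def load_config(path=None, **overrides) -> RunConfig:
    cfg = RunConfig.from_file(path) if path else RunConfig()
    for k, v in overrides.items():
        if v is not None:
            setattr(cfg, k, v)
    return cfg
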