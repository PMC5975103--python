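"""Structured configuration for the simulation pipeline.

All tunable constants live here rather than in code: geometric calibration
constants (frozen once by ``scripts/calibrate.py``), electrode-array
dimensions, stimulus defaults, scoring weights, fitting grids and the
distributions of the uncertain inputs.  A config is an ordinary nested
dataclass tree; :func:`load_config` reads a YAML mapping and overrides the
shipped defaults key by key.
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from dataclasses import asdict, dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "GeometryConfig",
    "ImplantConfig",
    "FieldConfig",
    "ActivationConfig",
    "ScoringConfig",
    "FittingConfig",
    "UQConfig",
    "Config",
    "default_config",
    "load_config",
    "config_hash",
]


@dataclass(frozen=True)
class GeometryConfig:
    """Parametric cochlea (logarithmic spiral) and fiber placement."""

    basal_radius_mm: float = 3.419280        # calibrated: lamina length 25.3 mm at zero weights
    radial_decay: float = 0.12           # 1/rad, logarithmic-spiral decay
    pitch_mm_per_turn: float = 1.0       # vertical rise of the spiral per turn
    turns: float = 2.75                  # angular extent / 2pi
    w1_gain: float = 0.043554               # calibrated: population lamina-length SD 1.1 mm
    w2_gain: float = 0.08                # basal-radius modulation (length-preserving)
    w3_gain: float = 0.15                # pitch modulation
    duct_offset_base_mm: float = 0.6     # lateral-wall offset of the duct at the base
    duct_offset_apex_mm: float = 0.2     # ... at the apex (scala narrows apically)
    n_bundles: int = 334
    total_fibers: int = 30000
    greenwood_A: float = 165.4           # Hz
    greenwood_a: float = 2.1
    greenwood_k: float = 0.88
    max_abs_weight: float = 3.0


@dataclass(frozen=True)
class ImplantConfig:
    n_contacts: int = 12
    active_range_mm: float = 23.1
    tip_mm: float = 1.0

    @property
    def spacing_mm(self) -> float:
        return self.active_range_mm / (self.n_contacts - 1)

    @property
    def min_insertion_mm(self) -> float:
        # full insertion: active range plus the tip must be inside the duct
        return self.active_range_mm + self.tip_mm


@dataclass(frozen=True)
class FieldConfig:
    distance_floor_mm: float = 0.1       # singularity guard for the point source


@dataclass(frozen=True)
class ActivationConfig:
    backend: str = "threshold"           # "threshold" | "hh"
    v_threshold: float = 1.041342            # V, calibrated: 3 mm activated arc at the default stimulus
    pulse_phase_us: float = 100.0
    pulse_amplitude_ua: float = 350.0
    hh_drive_gain: float = 225.6798          # uA/cm^2 per volt of extracellular potential, calibrated
    hh_dt_us: float = 1.0
    hh_window_ms: float = 1.0
    hh_spike_mv: float = 40.0            # depolarization above rest counted as a spike
    hh_temperature_c: float = 37.0


@dataclass(frozen=True)
class ScoringConfig:
    band_halfwidth_mm: float = 1.5       # 3 mm acceptable bandwidth
    band_edge_weight: float = 0.1        # Gaussian value at the band edge
    out_of_band_penalty: float = 0.25    # magnitude of the negative weight


@dataclass(frozen=True)
class FittingConfig:
    grid_min_ua: float = 10.0
    grid_max_ua: float = 1000.0
    grid_step_ua: float = 10.0
    refine_ua: float = 1.0
    cross_turn_lambda: float = 0.5


@dataclass(frozen=True)
class UQConfig:
    insertion_mean_mm: float = 27.0
    insertion_sd_population_mm: float = 1.0
    insertion_sd_patient_mm: float = 0.5
    resistivity_mean_ohm_m: float = 65.0
    resistivity_sd_group_ohm_m: float = 4.5
    resistivity_sd_full_ohm_m: float = 21.6
    weight_truncation_sd: float = 3.0
    mc_default_n: int = 250
    pcm_default_order: int = 2


@dataclass(frozen=True)
class Config:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    implant: ImplantConfig = field(default_factory=ImplantConfig)
    field_model: FieldConfig = field(default_factory=FieldConfig)
    activation: ActivationConfig = field(default_factory=ActivationConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    uq: UQConfig = field(default_factory=UQConfig)


_SECTION_TYPES = {
    "geometry": GeometryConfig,
    "implant": ImplantConfig,
    "field_model": FieldConfig,
    "activation": ActivationConfig,
    "scoring": ScoringConfig,
    "fitting": FittingConfig,
    "uq": UQConfig,
}


def _build(section_cls, mapping: dict):
    known = {f.name for f in fields(section_cls)}
    unknown = set(mapping) - known
    if unknown:
        raise KeyError(f"unknown {section_cls.__name__} keys: {sorted(unknown)}")
    return section_cls(**mapping)


def _from_mapping(mapping: dict) -> Config:
    sections = {}
    for name, cls in _SECTION_TYPES.items():
        if name in mapping:
            sections[name] = _build(cls, dict(mapping[name]))
    unknown = set(mapping) - set(_SECTION_TYPES)
    if unknown:
        raise KeyError(f"unknown config sections: {sorted(unknown)}")
    return Config(**sections)


@lru_cache(maxsize=1)
def default_config() -> Config:
    """Shipped defaults, including the frozen calibration constants."""
    text = resources.files("ciuq.data").joinpath("default_config.yaml").read_text()
    return _from_mapping(yaml.safe_load(text) or {})


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config, overriding the shipped defaults section by section."""
    cfg = default_config()
    if path is None:
        return cfg
    user = yaml.safe_load(Path(path).read_text()) or {}
    sections = {}
    for name, cls in _SECTION_TYPES.items():
        base = getattr(cfg, name)
        if name in user:
            sections[name] = replace(base, **dict(user[name]))
    unknown = set(user) - set(_SECTION_TYPES)
    if unknown:
        raise KeyError(f"unknown config sections: {sorted(unknown)}")
    return replace(cfg, **sections)


def config_hash(cfg: Config) -> str:
    """Short stable hash of a config, echoed in logs for provenance."""
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
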