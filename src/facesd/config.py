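"""Run configuration: every analysis constant in one serializable place.

All defaults are the study's values (15 s RT cutoff, +-60-step error cutoff,
23/46/69 bin edges via the wheel, 5,000 bootstrap iterations, 10,000
permutations, cluster-forming alpha 0.05).  A loaded YAML file is checked
against the schema; unknown keys are errors, so silent typos cannot change
an analysis.  The full effective configuration is serialized into every
run's output directory for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .morphwheel import MorphWheel
from .synthdata import DesignSpec, ErpModel, ResponseModel

__all__ = ["AnalysisParams", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class AnalysisParams:
    """Statistical constants of the analysis stages."""

    rt_max_s: float = 15.0
    max_abs_error: int = 60
    n_boot: int = 5000
    boot_level: float = 0.95
    n_perm: int = 10000
    cluster_alpha: float = 0.05
    adjacency_threshold: float = 0.55
    lowpass_hz: float = 30.0
    filter_order: int = 4
    baseline_ms: tuple = (-200.0, 0.0)
    roi_mode: str = "per_channel"
    bias_sign_convention: str = "cw_minus_ccw"
    topo_per_region_scaling: bool = False
    huber_c: float = 1.345
    jzs_scale: float = 0.7071067811865476


@dataclass(frozen=True)
class RunConfig:
    """Everything a full synthetic replication run needs."""

    design: DesignSpec = field(default_factory=DesignSpec)
    response_model: ResponseModel = field(default_factory=ResponseModel)
    erp_model: ErpModel = field(default_factory=ErpModel)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    # Shared brain-behavior latent: one z ~ N(0,1) per participant scales the
    # bias pulls by (1 + coupling*z) and the LPP modulation by
    # (1 + coupling_erp*z).  coupling = 0 decouples the modalities.
    coupling: float = 0.0
    coupling_erp: float = 1.0


_SECTION_TYPES = {
    "design": DesignSpec,
    "response_model": ResponseModel,
    "erp_model": ErpModel,
    "analysis": AnalysisParams,
}


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) under '{path}': {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        if name == "wheel" and isinstance(value, dict):
            value = _build(MorphWheel, value, f"{path}.wheel")
        elif name == "components" and isinstance(value, list):
            from .synthdata import ComponentTemplate

            value = tuple(
                _build(ComponentTemplate, v, f"{path}.components[{i}]")
                if isinstance(v, dict) else v
                for i, v in enumerate(value)
            )
        elif isinstance(value, list) and "tuple" in str(ftype):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - set(_SECTION_TYPES) - {"seed", "coupling", "coupling_erp"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            kwargs[section] = _build(cls, raw[section] or {}, section)
    for scalar in ("seed", "coupling", "coupling_erp"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    return RunConfig(**kwargs)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def save_config(config: RunConfig, path) -> None:
    """Serialize the full effective configuration (provenance record)."""
    Path(path).write_text(yaml.safe_dump(_as_plain(config), sort_keys=False))
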