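"""Experiment configuration: nested-section YAML with strict keys.

Unknown keys anywhere in the file are errors -- a typo in a force-field
name must never silently fall back to a default. The seed is mandatory:
every run artifact is traceable to (config, seed) and reruns are
bit-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .builders import MembraneSpec, ProteinSpec

__all__ = ["ExperimentConfig", "ForceFieldConfig", "RunConfig",
           "AnalysisConfig", "UnitsConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, section: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}' "
            f"(allowed: {sorted(allowed)})")
    return cls(**data)


@dataclass
class ForceFieldConfig:
    a_like: float = 25.0
    a_cross: float = 100.0
    cross_species_factor: float = 1.2
    gamma: float = 4.5
    r_c: float = 1.0
    k_BT: float = 1.0
    k_bond: float = 100.0
    l0: float = 0.45
    k_bend: float = 20.0


@dataclass
class RunConfig:
    steps: int = 20000
    equilibration_steps: int = 50000
    output_interval: int = 100
    dt: float = 0.02
    lam: float = 0.5
    rho: float = 3.0
    barostat_interval: int = 50
    barostat_gain: float = 2e-3
    target_tension: float = 0.0


@dataclass
class AnalysisConfig:
    profile_bin_width: float = 0.5
    msd_fit_window: tuple = (0.10, 0.25)
    umbrella_spacing: float = 0.25
    umbrella_k: float = 50.0
    contact_cutoff: float = 1.0
    pmf_bin_width: float = 0.05


@dataclass
class UnitsConfig:
    r_c_nm: float = 1.0     # length unit in nanometers
    tau_ns: float = 1.0     # time unit in nanoseconds


@dataclass
class ExperimentConfig:
    seed: int
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    proteins: list = field(default_factory=list)       # list of ProteinSpec
    protein_positions: list = field(default_factory=list)  # list of (x, y)
    forcefield: ForceFieldConfig = field(default_factory=ForceFieldConfig)
    run: RunConfig = field(default_factory=RunConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    units: UnitsConfig = field(default_factory=UnitsConfig)

    def resolved(self) -> dict:
        out = asdict(self)
        out["proteins"] = [asdict(p) if not isinstance(p, dict) else p
                           for p in self.proteins]
        return out


_SECTIONS = {
    "membrane": MembraneSpec,
    "forcefield": ForceFieldConfig,
    "run": RunConfig,
    "analysis": AnalysisConfig,
    "units": UnitsConfig,
}


def load_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of sections")
    known = set(_SECTIONS) | {"seed", "proteins", "protein_positions"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("a seed is mandatory")
    kwargs = {"seed": int(raw["seed"])}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _from_dict(cls, raw[name], name)
    prots = raw.get("proteins", [])
    kwargs["proteins"] = [_from_dict(ProteinSpec, p, "proteins[]")
                          for p in prots]
    kwargs["protein_positions"] = [tuple(p) for p in
                                   raw.get("protein_positions", [])]
    if len(kwargs["protein_positions"]) not in (0, len(kwargs["proteins"])):
        raise ConfigError("protein_positions must match proteins in length")
    return ExperimentConfig(**kwargs)
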