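"""Run configuration: YAML files validated into a structured config.

An empty file resolves to the reference defaults (Δt = 0.25 ps, 40 Å
cutoff, ε = 78.5, Debye length 7.8 Å, k_ex = 1, full HI, restrained DNA).
Unknown keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .energy import ForceFieldParams
from .engine import Protocol


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    dna_residues: int = 200
    a_pbp: float = 40.0
    q_dbp: float = 8.0
    backbone_theta0_deg: float = 180.0


@dataclass
class AnalysisConfig:
    fit_window_ns: tuple = (10.0, 250.0)
    hop_threshold: float = 40.0
    plateau: tuple = (80.0, 90.0)

    def __post_init__(self):
        self.fit_window_ns = tuple(self.fit_window_ns)
        self.plateau = tuple(self.plateau)


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    protocol: Protocol = field(default_factory=Protocol)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_prefix: str = "run"
    seeds: list = field(default_factory=lambda: [0])

    def resolved(self) -> dict:
        return asdict(self)


_SECTIONS = {"model": ModelConfig, "forcefield": ForceFieldParams,
             "protocol": Protocol, "analysis": AnalysisConfig}


def _build(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in {where}: {exc}") from exc


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top_known = {"model", "forcefield", "protocol", "analysis",
                 "output_prefix", "seeds"}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        sec = raw.get(name, {})
        if not isinstance(sec, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build(cls, sec, f"section {name!r}")
    if "output_prefix" in raw:
        kwargs["output_prefix"] = str(raw["output_prefix"])
    if "seeds" in raw:
        kwargs["seeds"] = [int(s) for s in raw["seeds"]]
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path) -> None:
    doc = cfg.resolved()
    for sec in doc.values():
        if isinstance(sec, dict):
            for k, v in sec.items():
                if isinstance(v, tuple):
                    sec[k] = list(v)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
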