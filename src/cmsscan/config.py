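"""Run configuration: one flat, sectioned parameter namespace.

Every tunable of every stage has a documented default here; a YAML file
with the same section/key structure overrides them, and unknown keys are
rejected so typos fail loudly.  Precedence: CLI flag > config file >
default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class AlignmentConfig:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class OrfConfig:
    min_protein_length: int = 101  # "longer than 100 aa"
    coverage_min: float = 0.90
    identity_min: float = 95.0


@dataclass
class TmConfig:
    threshold: float = 1.6
    window: int = 19
    min_segment_length: int = 19
    merge_gap: int = 5


@dataclass
class ChimeraConfig:
    min_fragment: int = 100
    min_identity: float = 90.0


@dataclass
class RepeatConfig:
    min_repeat_length: int = 500
    k: int = 31


@dataclass
class SyntenyConfig:
    k: int = 31
    #: chain gap ceiling; mitochondrial comparisons need to bridge the
    #: anchor deserts created by long (multi-kb) repeats, so the pipeline
    #: default exceeds the longest expected repeat
    max_gap: int = 12_000
    min_block: int = 500
    gap_identity_floor: float = 70.0
    max_unbalanced: int = 200


@dataclass
class SimulateConfig:
    seed: int = 0
    genome_length_recipient: int = 221_862
    genome_length_donor: int = 240_024
    donor_fraction: float = 0.90
    backbone_gc: float = 0.44


@dataclass
class RunConfig:
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    orf: OrfConfig = field(default_factory=OrfConfig)
    tm: TmConfig = field(default_factory=TmConfig)
    chimera: ChimeraConfig = field(default_factory=ChimeraConfig)
    repeats: RepeatConfig = field(default_factory=RepeatConfig)
    synteny: SyntenyConfig = field(default_factory=SyntenyConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for section, values in data.items():
            if section not in sections:
                raise ConfigError(f"unknown config section {section!r}")
            target = getattr(cfg, section)
            known = {f.name for f in dataclasses.fields(target)}
            for key, value in (values or {}).items():
                if key not in known:
                    raise ConfigError(f"unknown key {section}.{key!r}")
                setattr(target, key, value)
        return cfg
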