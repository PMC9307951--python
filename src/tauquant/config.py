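"""Pipeline configuration: one YAML document, validated, hashable, round-trippable.

Every output file the pipeline writes records the configuration hash and the
base seed, so any artifact can be traced to the exact run that produced it.
Per-stage seeds are derived deterministically from the base seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import yaml


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass
class PTMConfig:
    mod_type: str = "phospho"
    fdr_cutoff: float = 0.01
    isoform: str = "1N4R-P301S"
    truth: dict[int, float] = field(default_factory=lambda: {202: 0.3, 231: 0.65, 262: 0.2})
    samples: list[str] = field(default_factory=lambda: ["week4", "week6"])
    draws_per_site: int = 200
    background_depth: int = 2
    decoy_fraction: float = 0.1


@dataclass
class FretConfig:
    gate_quantile: float = 0.995
    n_events: int = 20_000
    replicates: int = 3
    #: condition label -> true FRET-positive fraction (control must be present)
    conditions: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "week4": 0.05, "week6": 0.4}
    )
    control_condition: str = "control"


@dataclass
class SECConfig:
    monomer_mw_kda: float = 45.9
    sigma_log10: float = 0.02


@dataclass
class RenderConfig:
    color_zero: list[int] = field(default_factory=lambda: [0, 255, 255])
    color_one: list[int] = field(default_factory=lambda: [255, 0, 255])


@dataclass
class PipelineConfig:
    seed: int = 42
    ptm: PTMConfig = field(default_factory=PTMConfig)
    fret: FretConfig = field(default_factory=FretConfig)
    sec: SECConfig = field(default_factory=SECConfig)
    render: RenderConfig = field(default_factory=RenderConfig)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "PipelineConfig":
        def fail(fieldname: str, why: str):
            raise ConfigError(f"{fieldname}: {why}")

        if not isinstance(self.seed, int) or self.seed < 0:
            fail("seed", "must be a non-negative integer")
        if not 0 < self.ptm.fdr_cutoff <= 1:
            fail("ptm.fdr_cutoff", f"must be in (0, 1], got {self.ptm.fdr_cutoff}")
        if self.ptm.mod_type not in ("phospho", "acetyl", "ubiquitin"):
            fail("ptm.mod_type", f"unknown modification type {self.ptm.mod_type!r}")
        for pos, f in self.ptm.truth.items():
            if not 0.0 <= float(f) <= 1.0:
                fail(f"ptm.truth[{pos}]", f"frequency {f} outside [0, 1]")
        if self.ptm.draws_per_site < 1:
            fail("ptm.draws_per_site", "must be >= 1")
        if not self.ptm.samples:
            fail("ptm.samples", "need at least one sample id")
        if not 0 < self.fret.gate_quantile < 1:
            fail("fret.gate_quantile", f"must be in (0, 1), got {self.fret.gate_quantile}")
        if self.fret.n_events < 1:
            fail("fret.n_events", "must be >= 1")
        if self.fret.replicates < 1:
            fail("fret.replicates", "must be >= 1")
        if self.fret.control_condition not in self.fret.conditions:
            fail("fret.control_condition", f"{self.fret.control_condition!r} missing from fret.conditions")
        for name, p in self.fret.conditions.items():
            if not 0.0 <= float(p) <= 1.0:
                fail(f"fret.conditions[{name}]", f"fraction {p} outside [0, 1]")
        if self.sec.monomer_mw_kda <= 0:
            fail("sec.monomer_mw_kda", "must be > 0")
        if self.sec.sigma_log10 < 0:
            fail("sec.sigma_log10", "must be >= 0")
        for key, color in (("render.color_zero", self.render.color_zero),
                           ("render.color_one", self.render.color_one)):
            if len(color) != 3 or any(not 0 <= int(c) <= 255 for c in color):
                fail(key, f"must be three RGB integers in 0..255, got {color}")
        return self

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data or {})
        cfg = cls(
            seed=data.get("seed", cls().seed),
            ptm=PTMConfig(**_coerce(data.get("ptm", {}), {"truth": _int_keys})),
            fret=FretConfig(**_coerce(data.get("fret", {}), {})),
            sec=SECConfig(**data.get("sec", {})),
            render=RenderConfig(**data.get("render", {})),
        )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        """One-line provenance stamp placed in every output file."""
        return f"tauquant config_sha256={self.config_hash()} seed={self.seed}"

    # -- derived per-stage seeds (all well below 2**31) ---------------------

    def seed_for(self, stage: str, index: int = 0) -> int:
        offsets = {"ptm": 100_000, "fret": 200_000, "sec": 300_000}
        return (self.seed * 1_000 + offsets[stage] + index) % (2**31 - 1)


def _int_keys(mapping):
    return {int(k): float(v) for k, v in mapping.items()}


def _coerce(section: Mapping, converters: Mapping) -> dict:
    out = dict(section)
    for key, conv in converters.items():
        if key in out:
            out[key] = conv(out[key])
    return out
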