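"""Structured pipeline configuration with strict schema validation.

The on-disk format is a YAML mapping with the sections below; unknown
keys anywhere are rejected so typos fail loudly instead of silently
running with defaults.

.. code-block:: yaml

    seed: 1
    panel:    {n_autosomal: 2000, n_y: 100, freq_low: 0.05, freq_high: 0.95}
    samples:  {n: 6, sex_ratio: 0.5, replicates_of: [ind000]}
    simulate: {preset: capture_like}           # or explicit fields
    calling:  {min_depth: 10, min_quality: 20.0, ...}
    match:    {base_error: 0.01, sample_error_factor: 2.0,
               n_select: 50000, min_snps: 150}
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calling import CallingThresholds
from .matching import ErrorModel, MatchRules
from .sim import SimulationConfig, preset


@dataclass(frozen=True)
class PanelSpec:
    n_autosomal: int = 2000
    n_y: int = 100
    freq_low: float = 0.05
    freq_high: float = 0.95


@dataclass(frozen=True)
class SampleSpec:
    n: int = 6
    sex_ratio: float = 0.5
    replicates_of: tuple = ()
    n_reps: int = 1


@dataclass
class PipelineConfig:
    seed: int = 0
    panel: PanelSpec = field(default_factory=PanelSpec)
    samples: SampleSpec = field(default_factory=SampleSpec)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    calling: CallingThresholds = field(default_factory=CallingThresholds)
    match_error: ErrorModel = field(default_factory=ErrorModel)
    match_rules: MatchRules = field(default_factory=MatchRules)
    n_select: int = 50000


def _build(cls, section: dict, where: str, **extra):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**section, **extra)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {"seed", "panel", "samples", "simulate", "calling", "match"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown section(s) {sorted(unknown)}")

    seed = int(raw.get("seed", 0))
    panel = _build(PanelSpec, raw.get("panel", {}) or {}, "panel")
    samples = dict(raw.get("samples", {}) or {})
    if "replicates_of" in samples:
        samples["replicates_of"] = tuple(samples["replicates_of"])
    samples = _build(SampleSpec, samples, "samples")

    sim_section = dict(raw.get("simulate", {}) or {})
    preset_name = sim_section.pop("preset", None)
    if preset_name is not None:
        sim = preset(preset_name, seed=seed, **sim_section)
    else:
        sim_section.setdefault("seed", seed)
        sim = _build(SimulationConfig, sim_section, "simulate")

    calling = _build(CallingThresholds, raw.get("calling", {}) or {}, "calling")

    match_section = dict(raw.get("match", {}) or {})
    n_select = int(match_section.pop("n_select", 50000))
    rules_keys = {"min_snps", "ln_lr_threshold"}
    rules = _build(MatchRules,
                   {k: match_section.pop(k) for k in list(match_section)
                    if k in rules_keys},
                   "match")
    err = _build(ErrorModel, match_section, "match")

    return PipelineConfig(seed=seed, panel=panel, samples=samples, simulate=sim,
                          calling=calling, match_error=err, match_rules=rules,
                          n_select=n_select)
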