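"""Configuration schema, per-stage seeding and run manifests.

A pipeline run is configured by a YAML/JSON document validated into
:class:`PipelineConfig`.  A single top-level seed expands deterministically
into per-stage seeds through numpy's SeedSequence spawning, so stages can be
re-run in isolation and still reproduce their outputs bit-identically.  Every
stage writes a manifest recording the tool version, config hash, seeds and
output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .simulator import SimulationParams

__all__ = ["PipelineConfig", "RunManifest", "load_config", "stage_seeds",
           "config_hash", "file_checksum"]

STAGES = ("synth", "qc", "tree", "sumstats", "abc", "gibbs")


def _demo_pair() -> SimulationParams:
    """Desk-scale pair used by the default demo pipeline (minutes, one CPU)."""
    return SimulationParams(
        n_hsc=2000, n_trans=800, donor_age_hct=30.0, donor_age_bd=40.0,
        n_colonies_donor=60, n_colonies_recipient=60,
    )


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end synthetic pipeline run."""

    pair: SimulationParams = field(default_factory=_demo_pair)
    seed: int = 0
    rate_per_year: float = 15.8
    birth_burden: float = 60.0
    terminal_shortening: float = 60.0
    abc_n_sims: int = 200
    abc_quantile: float = 0.05
    gibbs_iterations: int = 2000
    gibbs_burn_in: int = 1000
    gibbs_thin: int = 10
    gibbs_sigma: float = 50.0
    clone_cut: float = 100.0
    panel_fraction: float = 0.3
    targeted_depth: float = 1720.0
    colony_depth: float = 11.5


def _coerce_dataclass(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _coerce_dataclass(f.type, v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML (or JSON) pipeline config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    pair = data.pop("pair", {})
    cfg = _coerce_dataclass(PipelineConfig, data)
    if pair:
        known = {f.name for f in fields(SimulationParams)}
        bad = set(pair) - known
        if bad:
            raise ValueError(f"unknown pair key(s): {sorted(bad)}")
        cfg.pair = SimulationParams(**{k: v for k, v in pair.items()})
    return cfg


def stage_seeds(seed: int) -> dict[str, int]:
    """Expand one seed into a deterministic per-stage seed map (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {stage: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
            for stage, c in zip(STAGES, children)}


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every stage's outputs."""

    version: str
    seed: int
    stage_seeds: dict
    config_digest: str
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def add_output(self, name: str, path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": file_checksum(path)}

    def time_stage(self, stage: str, t0: float) -> None:
        self.timings[stage] = round(time.time() - t0, 3)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
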