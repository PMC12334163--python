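"""Experiment configuration and deterministic seed management.

A single experiment seed is expanded into independent per-stage child
seeds through ``numpy.random.SeedSequence.spawn`` keyed by stage order,
so any stage can be re-run in isolation and reproduce its output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import yaml

from .core import VoxelGrid
from .detect import DetectionParams
from .simulate import SimulationConfig, burst_profile
from .track import BacktrackParams, LinkingParams

__all__ = ["ExperimentConfig", "load_config", "stage_seed"]

_STAGES = ("simulate", "acquire", "detect", "track", "evaluate")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage (< 2**31)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return int(children[_STAGES.index(stage)].generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    """Everything needed to run the full trade-off experiment."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    conditions: Sequence[str] = ("1", "2", "3", "4", "5")
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    flow_source: Optional[str] = "ground_truth"
    n_repeats: int = 3
    seed: int = 1
    depth_bin: float = 5.0
    out_dir: str = "regentrack_out"

    def __post_init__(self) -> None:
        known = {"1", "2", "3", "4", "5"}
        bad = [c for c in self.conditions if str(c) not in known]
        if bad:
            raise ValueError(f"unknown condition name(s) {bad}; valid: {sorted(known)}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def _build_simulation(d: Dict) -> SimulationConfig:
    d = dict(d)
    if "grid" in d:
        g = d["grid"]
        d["grid"] = VoxelGrid(
            shape=tuple(g["shape"]),
            voxel_size=tuple(g.get("voxel_size", (1.24, 0.31, 0.31))),
            time_interval=float(g.get("time_interval", 10.0)),
        )
    if "division_profile" in d and isinstance(d["division_profile"], dict):
        p = d["division_profile"]
        d["division_profile"] = burst_profile(
            d.get("n_timepoints", 60),
            p["t_on"],
            p["t_off"],
            p["p_burst"],
            p.get("t_end"),
            p.get("p_decline", 0.0),
        )
    for k in ("recovery_times", "recovery_amplitudes", "psf_sigma"):
        if k in d:
            d[k] = tuple(d[k])
    return SimulationConfig(**d)


def load_config(path: Union[str, Path]) -> ExperimentConfig:
    """Read an experiment configuration from YAML or JSON."""
    text = Path(path).read_text(encoding="utf-8")
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    raw = dict(raw or {})
    kwargs: Dict = {}
    if "simulation" in raw:
        kwargs["simulation"] = _build_simulation(raw.pop("simulation"))
    if "detection" in raw:
        kwargs["detection"] = DetectionParams(**raw.pop("detection"))
    if "linking" in raw:
        kwargs["linking"] = LinkingParams(**raw.pop("linking"))
    kwargs.update(raw)
    return ExperimentConfig(**kwargs)
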