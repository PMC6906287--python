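"""Run configuration: structured, validated, YAML-serialisable.

One config file with per-module blocks drives simulation and analysis; every
default is materialised into the run manifest so runs are self-describing.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import yaml

__all__ = ["ScheduleConfig", "PopulationConfig", "NoiseConfig",
           "SimulateConfig", "AnalyzeConfig", "RunConfig"]

MODES = ("simulate", "track", "analyze", "report", "end_to_end")


def _from_dict(cls, data: dict):
    if data is None:
        return cls()
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if f.name in _NESTED:
            val = _from_dict(_NESTED[f.name], val)
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[f.name] = val
    return cls(**kwargs)


@dataclass
class ScheduleConfig:
    n_fov: int = 1
    n_channels: int = 2
    exposure_s: float = 0.1
    change_time_s: float = 0.5
    n_cycles: int = 200
    channel_labels: Tuple[str, ...] = ("pore", "ATTO655")

    def validate(self) -> None:
        if min(self.n_fov, self.n_channels, self.n_cycles) < 1:
            raise ValueError("schedule counts must be >= 1")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels must match n_channels")


@dataclass
class PopulationConfig:
    n_vesicles: int = 300
    lognormal_mu: float = math.log(200.0)
    lognormal_sigma: float = 0.35
    extent_px: float = 512.0
    min_separation_px: float = 10.0


@dataclass
class NoiseConfig:
    enabled: bool = True
    read_sigma: float = 2.0
    background: float = 100.0
    poisson: bool = True


@dataclass
class SimulateConfig:
    scenario: str = "L+"
    population: PopulationConfig = field(default_factory=PopulationConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    render: bool = False
    psf_sigma_px: float = 1.2
    drift_px_per_frame: Tuple[float, float] = (0.0, 0.0)
    scenario_overrides: dict = field(default_factory=dict)
    """Per-run overrides of the named scenario's parameters (e.g. a faster
    ``docking_rate`` so short acquisitions still capture events)."""

    def validate(self) -> None:
        self.schedule.validate()
        if self.population.n_vesicles < 1:
            raise ValueError("n_vesicles must be >= 1")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")


@dataclass
class AnalyzeConfig:
    detect_sigma_px: float = 1.2
    detect_k_mad: float = 5.0
    max_disp_px: float = 4.0
    max_gap_frames: int = 1
    coloc_radius_px: float = 2.0
    baseline_window: int = 10
    docking_k_sigma: float = 5.0
    docking_min_persist: int = 3
    min_drop: float = 0.3
    leaky_factor: float = 10.0
    aperture_radius_px: float = 3.0
    annulus_px: Tuple[float, float] = (5.0, 8.0)
    nominal_diameter_nm: float = 200.0
    size_cutoff_nm: float = 70.0
    size_bin_edges_nm: Tuple[float, ...] = (40., 80., 120., 160., 200.,
                                            240., 280., 320., 400.)

    def validate(self) -> None:
        if self.detect_sigma_px <= 0 or self.max_disp_px <= 0:
            raise ValueError("detection/linking scales must be positive")
        if not 0 <= self.min_drop <= 1:
            raise ValueError("min_drop must be in [0, 1]")


_NESTED = {
    "population": PopulationConfig,
    "schedule": ScheduleConfig,
    "noise": NoiseConfig,
    "simulate": SimulateConfig,
    "analyze": AnalyzeConfig,
}


@dataclass
class RunConfig:
    mode: str = "end_to_end"
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    analyze: AnalyzeConfig = field(default_factory=AnalyzeConfig)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.simulate.validate()
        self.analyze.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = _from_dict(cls, dict(data))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
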