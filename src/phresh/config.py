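"""Run configuration: a fully serialisable description of one pipeline run.

A run is reproducible from its config alone — every random draw derives
from ``seed``, and all geometry/optics/kinetics parameters live here.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .image_synthesis import NoiseModel, OpticsModel
from .reporter_kinetics import ReporterParams
from .synthetic_embryo import (MARKERS, PhaseSchedule, SpinalCordGeometry)

__all__ = ["RunConfig", "default_config"]


@dataclass
class CohortConfig:
    n_embryos: int = 8
    n_sections: int = 8
    cell_spacing_um: float = 2.5
    #: lognormal σ of per-embryo variability of planted domain fractions
    embryo_jitter_sigma: float = 0.03
    #: lognormal σ of per-cell expression variability
    cell_noise_sigma: float = 0.1


@dataclass
class RunConfig:
    seed: int = 0
    geometry: SpinalCordGeometry = field(default_factory=SpinalCordGeometry)
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    reporter: ReporterParams = field(default_factory=ReporterParams)
    optics: OpticsModel = field(default_factory=OpticsModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    #: Notch-inhibition timecourse endpoints (hours of LY-411575)
    timecourse_hours: tuple[float, ...] = (1.0, 2.0, 3.0)
    timecourse_markers: tuple[str, ...] = ("ptc2", "sox2")
    #: run the ectopic-Gli1 / rescue experiment
    include_gli1_rescue: bool = True
    #: conversion times (hpf) for the demonstration signalling map;
    #: empty tuple skips the map stage
    map_t0_grid: tuple[float, ...] = ()
    map_pathway: str = "hh"

    def validate(self) -> None:
        for m in self.timecourse_markers:
            if m not in MARKERS:
                raise ConfigError(f"comparison references unknown marker {m!r}")
        if self.map_pathway not in ("notch", "hh"):
            raise ConfigError(f"unknown map pathway {self.map_pathway!r}")
        if any(h < 0 for h in self.timecourse_hours):
            raise ConfigError("timecourse hours must be >= 0")
        if self.cohort.n_embryos < 1 or self.cohort.n_sections < 1:
            raise ConfigError("cohort sizes must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, dict):
            data = source
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, TypeError):
                data = yaml.safe_load(source)
        if data is None:
            data = {}
        try:
            cfg = cls(
                seed=int(data.get("seed", 0)),
                geometry=SpinalCordGeometry(**data.get("geometry", {})),
                schedule=PhaseSchedule(**{
                    k: tuple(v) for k, v in data.get("schedule", {}).items()}),
                reporter=ReporterParams(**data.get("reporter", {})),
                optics=OpticsModel(**_tupled(data.get("optics", {}),
                                             ("voxel_size", "psf_sigma"))),
                noise=NoiseModel(**data.get("noise", {})),
                cohort=CohortConfig(**data.get("cohort", {})),
                timecourse_hours=tuple(data.get("timecourse_hours",
                                                (1.0, 2.0, 3.0))),
                timecourse_markers=tuple(data.get("timecourse_markers",
                                                  ("ptc2", "sox2"))),
                include_gli1_rescue=bool(data.get("include_gli1_rescue",
                                                  True)),
                map_t0_grid=tuple(data.get("map_t0_grid", ())),
                map_pathway=data.get("map_pathway", "hh"),
            )
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _tupled(d: dict, keys) -> dict:
    out = dict(d)
    for k in keys:
        if k in out:
            out[k] = tuple(out[k])
    return out


def default_config(seed: int = 0) -> RunConfig:
    cfg = RunConfig(seed=seed)
    cfg.validate()
    return cfg
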