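"""Experiment configuration: schema, validation, YAML I/O, seed derivation.

Per-stage random seeds are derived from the master seed with a documented
counter scheme: ``SeedSequence([master_seed, STAGE_ID, group_index,
item_index])``.  Every stage is therefore independently reproducible —
rerunning ``simulate`` on saved phantoms consumes exactly the seeds the
full pipeline would have.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigError
from .forward import ArrayGeometry
from .phantom import DEFAULT_GROUP_SPECS, REFERENCE_CSA_MM2

#: stage identifiers of the seed-derivation counter scheme
STAGE_PHANTOM = 0
STAGE_ACQUIRE = 1
STAGE_OBSERVER = 2

GROUP_ORDER = "ABCD"


def stage_seed(master_seed: int, stage: int, group_index: int = 0,
               item_index: int = 0) -> list:
    """Entropy list for ``numpy.random.SeedSequence`` of one pipeline draw."""
    return [int(master_seed), int(stage), int(group_index), int(item_index)]


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated configuration of one end-to-end experiment."""

    groups: tuple = ("A", "B", "C", "D")
    n: int = 3  # phantoms per group
    master_seed: int = 0
    wavelengths: tuple = (760, 840, 910)
    relative_noise: float = 0.05  # per-frame noise sd / peak noiseless amplitude
    n_averages: int = 10
    spacing: float = 0.05  # mm, raster + reconstruction grid
    fov_mm: float = 12.8
    geometry: ArrayGeometry = field(default_factory=ArrayGeometry)
    observer_threshold_jitter: float = 0.03
    observer_sigma_jitter: float = 0.10
    respiration_depth: float = 0.15
    reference_csa: float = REFERENCE_CSA_MM2
    unmix_enabled: bool = True

    def group_spec(self, label: str):
        return DEFAULT_GROUP_SPECS[label]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["wavelengths"] = list(self.wavelengths)
        return d

    def checksum(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


_GEOMETRY_FIELDS = {f.name for f in dataclasses.fields(ArrayGeometry)}
_CONFIG_FIELDS = {f.name for f in dataclasses.fields(ExperimentConfig)}


def config_from_dict(d: dict) -> ExperimentConfig:
    """Build and validate a config, raising ConfigError with the field path."""
    d = dict(d or {})
    kwargs = {}
    geo = d.pop("geometry", None)
    for key in list(d):
        if key not in _CONFIG_FIELDS:
            raise ConfigError(key, "unknown configuration key")
    if geo is not None:
        for key in geo:
            if key not in _GEOMETRY_FIELDS:
                raise ConfigError(f"geometry.{key}", "unknown geometry key")
        try:
            kwargs["geometry"] = ArrayGeometry(**geo)
        except (TypeError, ValueError) as exc:
            raise ConfigError("geometry", str(exc)) from exc
    for key, val in d.items():
        kwargs[key] = val

    cfg_kwargs = {}
    defaults = ExperimentConfig()
    for key in _CONFIG_FIELDS:
        cfg_kwargs[key] = kwargs.get(key, getattr(defaults, key))
    if "groups" in kwargs:
        cfg_kwargs["groups"] = tuple(kwargs["groups"])
    if "wavelengths" in kwargs:
        cfg_kwargs["wavelengths"] = tuple(kwargs["wavelengths"])

    cfg = ExperimentConfig(**cfg_kwargs)
    _validate(cfg)
    return cfg


def _validate(cfg: ExperimentConfig):
    for g in cfg.groups:
        if g not in DEFAULT_GROUP_SPECS:
            raise ConfigError("groups", f"unknown group label {g!r}")
    if len(set(cfg.groups)) != len(cfg.groups):
        raise ConfigError("groups", "duplicate group labels")
    if not isinstance(cfg.n, (int, np.integer)) or cfg.n < 1:
        raise ConfigError("n", f"cohort size must be an integer >= 1, got {cfg.n!r}")
    if not cfg.wavelengths:
        raise ConfigError("wavelengths", "at least one wavelength required")
    if cfg.relative_noise < 0:
        raise ConfigError("relative_noise", "must be >= 0")
    if cfg.n_averages < 1:
        raise ConfigError("n_averages", "must be >= 1")
    if cfg.spacing <= 0:
        raise ConfigError("spacing", "must be > 0")
    if cfg.fov_mm <= 0:
        raise ConfigError("fov_mm", "must be > 0")
    if cfg.fov_mm / 2 * np.sqrt(2) >= cfg.geometry.arc_radius_mm:
        raise ConfigError("fov_mm", "field of view must fit inside the arc")
    if not 0 <= cfg.respiration_depth < 1:
        raise ConfigError("respiration_depth", "must lie in [0, 1)")
    if cfg.reference_csa <= 0:
        raise ConfigError("reference_csa", "must be > 0")


def load_config(path) -> ExperimentConfig:
    with open(path) as f:
        return config_from_dict(yaml.safe_load(f) or {})


def save_config(cfg: ExperimentConfig, path):
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=True)
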