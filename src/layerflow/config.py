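"""YAML run configuration.

A run config has up to five blocks -- ``medium``, ``instrument``,
``noise``, ``fit`` and ``study`` -- each mapping onto the corresponding
dataclass defaults.  Unknown blocks or keys are rejected so that typos
fail loudly.  The config hash (sha256 of the canonical JSON) and the seed
are embedded in every output file for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fitting import FitConfig
from .noise import DcsNoiseSpec, FdNoiseSpec
from .study import Instrument, SamplingRanges

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MediumConfig:
    mu_a1: float = 0.1
    mu_a2: float = 0.13
    mu_s_prime1: float = 10.0
    mu_s_prime2: float = 10.0
    F1: float = 1e-8
    F2: float = 6e-8
    thickness: float = 1.2
    radius: float = 30.0
    refractive_index: float = 1.4


@dataclass(frozen=True)
class NoiseConfig:
    amplitude_snr: float = 100.0
    phase_sigma_deg: float = 0.1
    count_rate_short: float = 200e3
    count_rate_long: float = 40e3
    integration_time: float = 10.0
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude_snr <= 0 or self.phase_sigma_deg < 0:
            raise ValueError("amplitude_snr must be > 0 and phase_sigma_deg >= 0")
        if self.count_rate_short <= 0 or self.count_rate_long <= 0:
            raise ValueError("count rates must be positive")
        if self.integration_time <= 0:
            raise ValueError("integration_time must be positive")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")


@dataclass(frozen=True)
class StudyConfig:
    combos_per_thickness: int = 150    # desk scale; the full campaign uses 2030
    thicknesses: tuple = (1.0, 1.2, 1.4, 1.6)
    integration_time: float = 10.0
    seed: int = 0


@dataclass
class RunConfig:
    medium: MediumConfig = field(default_factory=MediumConfig)
    instrument: Instrument = field(default_factory=Instrument)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    study: StudyConfig = field(default_factory=StudyConfig)
    seed: int = 0

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [enc(x) for x in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj
        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_BLOCKS = {
    "medium": MediumConfig,
    "instrument": Instrument,
    "noise": NoiseConfig,
    "fit": FitConfig,
    "study": StudyConfig,
}


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a YAML config file (or an equivalent dict)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    kwargs = {}
    for key, val in raw.items():
        if key == "seed":
            kwargs["seed"] = int(val)
            continue
        cls = _BLOCKS.get(key)
        if cls is None:
            raise ConfigError(f"unknown config block {key!r}")
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(val) - names
        if unknown:
            raise ConfigError(f"unknown keys in {key!r}: {sorted(unknown)}")
        val = {k: (tuple(v) if isinstance(v, list) else v) for k, v in val.items()}
        try:
            kwargs[key] = cls(**val)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid {key!r} block: {exc}") from exc
    return RunConfig(**kwargs)
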