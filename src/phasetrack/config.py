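"""Run configuration: one flat TOML file covering all pipeline stages.

Recognised sections: [simulate], [mrf], [detect], [motion], [prior],
[track], plus top-level keys seed, pixel_size_um, frame_interval_s,
verbosity.  Unknown sections or keys are rejected with a configuration
error, so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from .exceptions import ConfigurationError
from .pipeline import DetectParams, MOVIE_MRF_PARAMS
from .segmentation import MrfParams
from .simulate import SimConfig
from .tracking import CollectionPrior, MotionModel

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class TrackRunParams:
    n_iter: int = 30000
    thin: int = 10
    burn_in: float = 0.3


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters for the whole pipeline."""

    seed: int = 0
    pixel_size_um: float = 0.65
    frame_interval_s: float = 300.0
    verbosity: int = 1
    simulate: SimConfig = field(default_factory=SimConfig)
    mrf: MrfParams = field(default_factory=lambda: MOVIE_MRF_PARAMS)
    detect: DetectParams = field(default_factory=DetectParams)
    motion: MotionModel = field(default_factory=MotionModel)
    prior: CollectionPrior = field(default_factory=CollectionPrior)
    track: TrackRunParams = field(default_factory=TrackRunParams)


_SECTIONS = {
    "simulate": SimConfig,
    "mrf": MrfParams,
    "detect": DetectParams,
    "motion": MotionModel,
    "prior": CollectionPrior,
    "track": TrackRunParams,
}
_TOP_KEYS = {"seed", "pixel_size_um", "frame_interval_s", "verbosity"}


def _build(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in section [{section}]"
        )
    # TOML has no tuples; coerce lists for tuple-typed fields
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    try:
        return cls(**coerced)
    except Exception as exc:
        raise ConfigurationError(f"invalid value in section [{section}]: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigurationError(f"could not parse config {path!r}: {exc}") from exc
    unknown = set(raw) - _TOP_KEYS - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {k: raw[k] for k in _TOP_KEYS if k in raw}
    for name, cls in _SECTIONS.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ConfigurationError(f"section [{name}] must be a table")
            kwargs[name] = _build(cls, raw[name], name)
    return RunConfig(**kwargs)
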