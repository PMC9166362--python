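"""Validated run configuration.

All defaults mirror the acquisition and analysis constants used throughout
the pipeline: 15.28 px/μm scaling, a 0.8 μm midcell window, 5% age bins
with 95% confidence intervals, and the 133-molecules-per-cell calibration.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError


class RunConfig(BaseModel):
    """Shared parameters of every pipeline stage."""

    model_config = ConfigDict(extra="forbid")

    pixel_pitch: float = Field(default=15.28, gt=0, description="pixels per μm")
    midcell_width: float = Field(default=0.8, gt=0, description="midcell window, μm")
    bin_width: float = Field(default=0.05, gt=0, le=0.5, description="age-class width")
    ci_level: float = Field(default=0.95, gt=0, lt=1)
    molecules_per_cell: float = Field(default=133.0, gt=0)
    onset_persistence: int = Field(default=2, ge=1, description="consecutive positive bins required for t0")
    constriction_age: float = Field(default=0.8, ge=0, le=1)
    seed: int = Field(default=0, ge=0)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config file (if given) and apply flag overrides.

    Raises
    ------
    ConfigError
        Naming the offending key on unknown or out-of-range values.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a key-value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config key {key!r}: {first['msg']}") from exc
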