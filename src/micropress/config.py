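"""Pipeline configuration: validated, unit-annotated, reproducible.

A single `PipelineConfig` object carries every tunable the virtual-experiment
runner and the analysis stages use. Validation rejects unknown keys and
out-of-range values, enumerating all violations at once; a normalized config
round-trips through JSON unchanged and hashes stably, and the hash is stamped
into every output file header.
"""

from __future__ import annotations

import hashlib
import json

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .units import STANDARD_GRAVITY

__all__ = ["PipelineConfig", "validate_and_log", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration; message enumerates every violation."""


class PipelineConfig(BaseModel):
    """All pipeline tunables, with units in the field names or docs."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    seed: int = 0
    pixel_size: float = Field(0.1, gt=0, description="µm per pixel")
    high_strain_fraction: float = Field(
        0.3, gt=0, le=1, description="top fraction of achieved strain used for the modulus fit"
    )
    strain_checkpoint_low: float = Field(
        0.15, gt=0, lt=1, description="shallow (cytoplasm) rheology checkpoint strain"
    )
    strain_checkpoint_high: float = Field(
        0.45, gt=0, lt=1, description="deep (nucleus-engaged) rheology checkpoint strain"
    )
    bin_width: float = Field(1.0, gt=0, description="histogram bin width, kPa")
    gravity: float = Field(STANDARD_GRAVITY, gt=0, description="m/s^2")
    geometry_source: str = Field(
        "images",
        pattern="^(images|truth)$",
        description="measure geometry from rendered micrographs or use simulator ground truth",
    )
    force_noise_sd: float = Field(2.0, ge=0, description="additive force noise, nN")
    sample_rate: float = Field(50.0, gt=0, description="Hz")
    speed: float = Field(10.0, gt=0, description="plate speed, µm/s")
    max_strain: float = Field(0.5, gt=0, lt=1)
    L0: float = Field(15.0, gt=0, description="virtual cell diameter, µm")
    nucleus_fraction: float = Field(0.6, gt=0, lt=1)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_and_log(config: dict | PipelineConfig | None) -> tuple[PipelineConfig, str]:
    """Normalize a config mapping and build a log header.

    Returns (config, header). All schema violations are reported together in
    the raised :class:`ConfigError`, not just the first.
    """
    if config is None:
        config = {}
    if isinstance(config, PipelineConfig):
        cfg = config
    else:
        try:
            cfg = PipelineConfig(**config)
        except ValidationError as exc:
            msgs = [
                f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                for e in exc.errors()
            ]
            raise ConfigError("; ".join(msgs)) from None
    lines = [f"micropress {__version__} | config {cfg.config_hash()} | seed {cfg.seed}"]
    for name, value in cfg.model_dump().items():
        desc = PipelineConfig.model_fields[name].description or ""
        lines.append(f"  {name} = {value!r}" + (f"  # {desc}" if desc else ""))
    return cfg, "\n".join(lines)
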