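"""Run configuration: a strict YAML mapping with per-stage sections.

Unknown keys are rejected by name, types are checked against the dataclass
schema, and every stochastic stage draws its seed from the single top-level
``seed`` (stage-name hashed offsets, so adding or reordering stages never
silently changes another stage's draws).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import yaml

from .phantom import PhantomSpec


class ConfigError(ValueError):
    pass


@dataclass
class PhantomStageConfig:
    mode: str = "volumes"            # "volumes" (3D tubes) or "slices" (2D stacks)
    n_dissected: int = 3
    n_control: int = 3
    slices_per_subject: int = 200
    dissected_label: str = "THROMBOSED_FL"
    partial_fraction: float = 0.4    # share of PARTIAL_FL slices in "slices" mode
    spec: PhantomSpec = field(default_factory=PhantomSpec)


@dataclass
class ResliceStageConfig:
    fov_mm: float = 64.0
    grid_n: int = 64
    step_mm: float = 1.0
    window_lo: float = 0.0
    window_hi: float = 1.0


@dataclass
class VAEStageConfig:
    latent_dim: int = 2
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    conv_channels: Tuple[int, int] = (16, 32)
    kernel_size: int = 3
    stride: int = 2
    recon_loss: str = "bernoulli"
    hidden_units: int = 16


@dataclass
class ScoringStageConfig:
    mode: str = "auto"               # "auto" or "fixed"
    x0_fixed: float = -0.8
    axis: Union[int, str] = "auto"   # 0, 1, or "auto" (best-separating axis)
    colormap_bins: int = 10


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "flvae_run"
    log_level: str = "INFO"
    phantom: PhantomStageConfig = field(default_factory=PhantomStageConfig)
    reslice: ResliceStageConfig = field(default_factory=ResliceStageConfig)
    vae: VAEStageConfig = field(default_factory=VAEStageConfig)
    scoring: ScoringStageConfig = field(default_factory=ScoringStageConfig)

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the run seed and the stage name."""
        return (int(self.seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


_REQUIRED = {"seed"}

_TUPLE_FIELDS = {"conv_channels", "voxel_spacing_mm", "tl_radius_mm", "fl_radius_mm",
                 "thrombus_fraction", "intensity_lumen", "intensity_thrombus",
                 "intensity_background"}


_SECTIONS = {"phantom": PhantomStageConfig, "reslice": ResliceStageConfig,
             "vae": VAEStageConfig, "scoring": ScoringStageConfig,
             "spec": PhantomSpec}

_SCALARS = {"int": int, "float": float, "str": str}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{path or 'top level'}' must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigError(f"unknown key(s) in '{path or 'top level'}': "
                          + ", ".join(repr(k) for k in unknown))
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            continue
        val = data[name]
        sub = f"{path}.{name}" if path else name
        if name in _SECTIONS:
            kwargs[name] = _build(_SECTIONS[name], val, sub)
            continue
        if name in _TUPLE_FIELDS:
            if not isinstance(val, (list, tuple)):
                raise ConfigError(f"'{sub}': expected a list, got {type(val).__name__}")
            kwargs[name] = tuple(val)
            continue
        if name == "axis":
            if not ((isinstance(val, int) and not isinstance(val, bool))
                    or val == "auto"):
                raise ConfigError(f"'{sub}': expected an integer or 'auto'")
            kwargs[name] = val
            continue
        scalar = _SCALARS.get(str(f.type).replace("<class '", "").replace("'>", ""))
        if scalar is not None:
            ok = {int: (int,), float: (int, float), str: (str,)}[scalar]
            if isinstance(val, bool) or not isinstance(val, ok):
                raise ConfigError(f"'{sub}': expected {scalar.__name__}, "
                                  f"got {type(val).__name__} ({val!r})")
            kwargs[name] = scalar(val)
            continue
        kwargs[name] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid values in '{path or 'top level'}': {e}") from e


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a YAML mapping")
    missing = sorted(_REQUIRED - set(data))
    if missing:
        raise ConfigError("missing required key(s): " + ", ".join(missing))
    return _build(RunConfig, data, "")
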