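"""Layered pipeline configuration: defaults <- YAML file <- CLI overrides.

Every stage's parameters live in one :class:`PipelineConfig`; unknown
keys are rejected with the offending key named, and the fully resolved
configuration is echoed to the log (and written beside the outputs) so a
run is reproducible from its artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError as PydanticValidationError

from .camera import CameraIntrinsics, OrbitConfig
from .evaluate import ViewpointExperimentConfig
from .heatmap import HeatmapConfig
from .model import ModelConfig, TrainConfig
from .skeleton import ValidationError
from .synthetic import GeneratorConfig

log = logging.getLogger("skelact")


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    generator: GeneratorConfig = GeneratorConfig()
    intrinsics: CameraIntrinsics = CameraIntrinsics()
    orbit: OrbitConfig = OrbitConfig()
    heatmap: HeatmapConfig = HeatmapConfig(out_height=24, out_width=24, num_frames_out=8)
    model: ModelConfig = ModelConfig()
    training: TrainConfig = TrainConfig(max_epochs=30, max_updates=500)
    experiment: ViewpointExperimentConfig = ViewpointExperimentConfig()
    output_dir: str = "skelact_output"
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class ConfigError(ValueError):
    pass


def _set_dotted(tree: dict, dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    node = tree
    for p in parts[:-1]:
        node = node.setdefault(p, {})
        if not isinstance(node, dict):
            raise ConfigError(f"cannot override through non-mapping key {p!r}")
    node[parts[-1]] = value


def parse_config(
    file: str | Path | None = None,
    overrides: dict[str, Any] | None = None,
) -> PipelineConfig:
    """Build the resolved configuration.

    ``overrides`` maps dotted keys (``heatmap.sigma``) to values and takes
    precedence over the YAML file, which takes precedence over defaults.
    Unknown keys raise :class:`ConfigError` naming the key.
    """
    tree: dict = {}
    if file is not None:
        loaded = yaml.safe_load(Path(file).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {file} must contain a mapping")
        tree = loaded
    for key, value in (overrides or {}).items():
        if isinstance(value, str):
            value = yaml.safe_load(value)
        _set_dotted(tree, key, value)
    try:
        cfg = PipelineConfig(**tree)
    except PydanticValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"invalid configuration key {loc!r}: {first['msg']}") from err
    log.info("resolved config (hash %s): %s", cfg.config_hash(),
             json.dumps(cfg.model_dump(mode="json"), sort_keys=True))
    return cfg
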