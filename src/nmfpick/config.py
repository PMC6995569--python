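"""Pipeline configuration: aggregation of per-stage settings plus INI-style
load/save (one section per stage)."""

from __future__ import annotations

import ast
import configparser
import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError
from .factorization import NNMFConfig
from .picking import PickingConfig
from .scale_space import ScaleSpaceConfig
from .segmentation import SegmentationConfig


@dataclass
class EvaluationConfig:
    max_match_dist: float = 10.0

    def __post_init__(self) -> None:
        if self.max_match_dist <= 0:
            raise ConfigurationError("max_match_dist must be positive")


@dataclass
class PipelineConfig:
    """All tunables of the three-phase pipeline.

    ``seed`` feeds every source of randomness (currently the NNMF
    initialization); ``invert`` flips contrast after normalization so that
    conventionally dark particles become bright foreground.
    """

    scale_space: ScaleSpaceConfig = field(default_factory=ScaleSpaceConfig)
    nnmf: NNMFConfig = field(default_factory=NNMFConfig)
    picking: PickingConfig = field(default_factory=PickingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0
    log_level: str = "INFO"
    invert: bool = True

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = dataclasses.replace(self, seed=seed)
        cfg.nnmf = dataclasses.replace(cfg.nnmf, seed=seed)
        return cfg


_SECTIONS = ("scale_space", "nnmf", "picking", "segmentation", "evaluation")


def save_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    parser = configparser.ConfigParser()
    parser["pipeline"] = {
        "seed": str(config.seed),
        "log_level": config.log_level,
        "invert": str(config.invert),
    }
    for section in _SECTIONS:
        sub = getattr(config, section)
        parser[section] = {
            f.name: repr(getattr(sub, f.name)) for f in dataclasses.fields(sub)
        }
    with open(path, "w") as fh:
        parser.write(fh)


def _parse(raw: str, ftype) -> object:
    if ftype is bool or ftype == "bool":
        return raw in ("True", "true", "1")
    try:
        return ast.literal_eval(raw)
    except Exception as exc:
        raise ConfigurationError(f"cannot parse config value {raw!r}") from exc


def load_config(path: str | os.PathLike) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such config file: {path}")
    parser = configparser.ConfigParser()
    parser.read(path)
    kwargs = {}
    classes = {
        "scale_space": ScaleSpaceConfig,
        "nnmf": NNMFConfig,
        "picking": PickingConfig,
        "segmentation": SegmentationConfig,
        "evaluation": EvaluationConfig,
    }
    for section, cls in classes.items():
        if section in parser:
            fields = {f.name: f for f in dataclasses.fields(cls)}
            values = {
                k: _parse(v, fields[k].type) for k, v in parser[section].items()
                if k in fields
            }
            kwargs[section] = cls(**values)
    pl = parser["pipeline"] if "pipeline" in parser else {}
    return PipelineConfig(
        seed=int(pl.get("seed", 0)),
        log_level=str(pl.get("log_level", "INFO")),
        invert=str(pl.get("invert", "True")) in ("True", "true", "1"),
        **kwargs,
    )
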