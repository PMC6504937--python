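"""The merged run configuration and its YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .postprocess import PipelineConfig
from .proposals import LossConfig
from .synthetic import SceneSpec
from .train import TrainConfig

_TUPLE_FIELDS = {"scales", "ratios", "freeze", "minor_axis", "aspect",
                 "contrast", "crop_sizes", "densities", "train_crop"}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.default_factory()) \
                if f.default_factory is not dataclasses.MISSING else False:
            v = _build(type(f.default_factory()), v)
        elif f.name in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Everything one run needs: model size, thresholds, data, training."""

    backbone: str = "tiny"
    k: int = 7
    num_classes: int = 1
    sth: float = 0.5
    nth: float = 0.5
    seed: int = 0
    scene: SceneSpec = field(default_factory=SceneSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    data_dir: str = "data"
    model_path: str = "model.npz"

    @property
    def pipe(self) -> PipelineConfig:
        return self.train.pipe

    @property
    def loss(self) -> LossConfig:
        return self.train.loss

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(self), sort_keys=False))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return _build(RunConfig, data)
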