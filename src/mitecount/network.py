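"""The convolutional stack: truncated-ZF-style backbone, neck, RPN heads,
and the position-sensitive score-map head.

Two size presets are provided.  ``zf-like`` follows the Zeiler-Fergus layer
plan truncated after its fourth convolution (7x7/96 s2, pool, 5x5/256 s2,
pool, 3x3/384, 3x3/384; total stride 16), then a 3x3 256-d "conv5" and a
1x1 1024-d "conv6" neck.  ``tiny`` is a three-conv, stride-8 backbone with
proportionally narrow channels, small enough to train in minutes on one CPU
core; it is the default everywhere in the test suite and the synthetic
experiments.

The score head emits ``k^2 * (C+1)`` channels laid out class-major:
channel ``c*k^2 + i*k + j`` holds the evidence map for class ``c`` at RoI
bin row ``i``, column ``j`` (class 0 is background).  The RPN heads emit
``2A`` objectness logits and ``4A`` box deltas per position, anchor-major,
matching the (row, col, anchor) flattening of
:func:`mitecount.geometry.generate_anchors`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn


@dataclass(frozen=True)
class BackboneConfig:
    """Layer plan of the feature extractor plus neck/head widths.

    ``layers`` is a sequence of ("conv", in_ch, out_ch, kernel, stride) and
    ("pool", kernel, stride) entries; ``total_stride`` must equal the
    product of all layer strides.
    """

    variant: str
    layers: tuple
    total_stride: int
    neck_mid: int       # "conv5" width
    neck_out: int       # "conv6" 1x1 width
    rpn_mid: int        # RPN 3x3 trunk width

    def __post_init__(self):
        prod = 1
        for spec in self.layers:
            prod *= spec[4] if spec[0] == "conv" else spec[2]
        if prod != self.total_stride:
            raise ValueError(f"declared stride {self.total_stride} != "
                             f"product of layer strides {prod}")

    @staticmethod
    def tiny() -> "BackboneConfig":
        return BackboneConfig(
            variant="tiny",
            layers=(("conv", 3, 16, 3, 2),
                    ("conv", 16, 24, 3, 2),
                    ("conv", 24, 32, 3, 2)),
            total_stride=8, neck_mid=48, neck_out=96, rpn_mid=48)

    @staticmethod
    def zf_like() -> "BackboneConfig":
        return BackboneConfig(
            variant="zf-like",
            layers=(("conv", 3, 96, 7, 2), ("pool", 3, 2),
                    ("conv", 96, 256, 5, 2), ("pool", 3, 2),
                    ("conv", 256, 384, 3, 1),
                    ("conv", 384, 384, 3, 1)),
            total_stride=16, neck_mid=256, neck_out=1024, rpn_mid=256)


@dataclass
class NetOutputs:
    """One forward pass: shared features plus every head's raw maps."""

    features: np.ndarray      # (neck_out, Hf, Wf)
    rpn_cls: np.ndarray       # (2A, Hf, Wf) objectness logits
    rpn_reg: np.ndarray       # (4A, Hf, Wf) box deltas
    score_maps: np.ndarray    # (k^2*(C+1), Hf, Wf)
    stride: int

    def rpn_cls_flat(self) -> np.ndarray:
        """(N_anchors, 2) logits in (row, col, anchor) order."""
        a = self.rpn_cls.shape[0] // 2
        return self.rpn_cls.reshape(a, 2, *self.rpn_cls.shape[1:]) \
                           .transpose(2, 3, 0, 1).reshape(-1, 2)

    def rpn_reg_flat(self) -> np.ndarray:
        """(N_anchors, 4) deltas in (row, col, anchor) order."""
        a = self.rpn_reg.shape[0] // 4
        return self.rpn_reg.reshape(a, 4, *self.rpn_reg.shape[1:]) \
                           .transpose(2, 3, 0, 1).reshape(-1, 4)


class PestNet:
    """Fully-convolutional detector network (single image per pass)."""

    def __init__(self, cfg: BackboneConfig | None = None,
                 anchors_per_position: int = 9, k: int = 7,
                 num_classes: int = 1, seed: int = 0):
        self.cfg = cfg or BackboneConfig.tiny()
        self.A = anchors_per_position
        self.k = k
        self.num_classes = num_classes

        stages = []
        self._stage_names: list[str] = []
        conv_idx = 0
        for spec in self.cfg.layers:
            if spec[0] == "conv":
                conv_idx += 1
                stages.append(nn.Sequential(
                    nn.Conv2d(spec[1], spec[2], spec[3], spec[4]), nn.ReLU()))
                self._stage_names.append(f"conv{conv_idx}")
            else:
                stages.append(nn.MaxPool2d(spec[1], spec[2]))
                self._stage_names.append(f"pool{conv_idx}")
        self.backbone = stages
        last_ch = [s for s in self.cfg.layers if s[0] == "conv"][-1][2]
        self.neck = nn.Sequential(
            nn.Conv2d(last_ch, self.cfg.neck_mid, 3), nn.ReLU(),
            nn.Conv2d(self.cfg.neck_mid, self.cfg.neck_out, 1), nn.ReLU())
        self.rpn_trunk = nn.Sequential(
            nn.Conv2d(self.cfg.neck_out, self.cfg.rpn_mid, 3), nn.ReLU())
        self.rpn_cls = nn.Conv2d(self.cfg.rpn_mid, 2 * self.A, 1)
        self.rpn_reg = nn.Conv2d(self.cfg.rpn_mid, 4 * self.A, 1)
        self.score_head = nn.Conv2d(self.cfg.neck_out,
                                    k * k * (num_classes + 1), 1)
        self.init_weights(seed)

    # -- parameters ------------------------------------------------------
    def named_params(self) -> dict[str, nn.Param]:
        out: dict[str, nn.Param] = {}

        def add(prefix, layer):
            for i, p in enumerate(layer.params()):
                out[f"{prefix}.{i}"] = p

        for name, stage in zip(self._stage_names, self.backbone):
            add(name, stage)
        add("neck", self.neck)
        add("rpn_trunk", self.rpn_trunk)
        add("rpn_cls", self.rpn_cls)
        add("rpn_reg", self.rpn_reg)
        add("score_head", self.score_head)
        return out

    def params(self) -> list[nn.Param]:
        return list(self.named_params().values())

    def init_weights(self, seed: int = 0, std: float = 0.01) -> None:
        """All layers drawn N(0, std^2), biases zero, reproducibly."""
        nn.init_gaussian(self.params(), std=std, seed=seed)

    def freeze(self, stage_names=("conv1",)) -> None:
        """Mark the named backbone stages as not trainable."""
        named = self.named_params()
        for key, p in named.items():
            p.frozen = any(key.startswith(s + ".") for s in stage_names)

    # -- forward / backward ---------------------------------------------
    @property
    def stride(self) -> int:
        return self.cfg.total_stride

    def extract_features(self, image: np.ndarray) -> np.ndarray:
        """Backbone + neck features for a (3, H, W) image in [0, 1]."""
        if image.ndim != 3 or image.shape[0] != 3:
            raise ValueError("expected (3, H, W) image")
        h, w = image.shape[1:]
        s = self.stride
        if h < s or w < s:
            raise ValueError(f"image {w}x{h} smaller than the minimum "
                             f"{s}x{s} (one stride)")
        x = image.astype(np.float32) - 0.5
        for stage in self.backbone:
            x = stage.forward(x)
        return self.neck.forward(x)

    def forward(self, image: np.ndarray) -> NetOutputs:
        feats = self.extract_features(image)
        trunk = self.rpn_trunk.forward(feats)
        return NetOutputs(
            features=feats,
            rpn_cls=self.rpn_cls.forward(trunk),
            rpn_reg=self.rpn_reg.forward(trunk),
            score_maps=self.score_head.forward(feats),
            stride=self.stride)

    def backward(self, d_rpn_cls, d_rpn_reg, d_score_maps) -> None:
        """Accumulate parameter gradients from head-output gradients."""
        d_trunk = self.rpn_cls.backward(d_rpn_cls) \
            + self.rpn_reg.backward(d_rpn_reg)
        d_feats = self.rpn_trunk.backward(d_trunk) \
            + self.score_head.backward(d_score_maps)
        dx = self.neck.backward(d_feats)
        stages = list(self.backbone)
        for i in range(len(stages) - 1, -1, -1):
            # nothing below a fully-frozen prefix needs gradients
            if all(p.frozen for s in stages[:i + 1] for p in s.params()):
                break
            dx = stages[i].backward(dx)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- persistence -----------------------------------------------------
    def save(self, path, meta: dict | None = None) -> None:
        base = {"variant": self.cfg.variant, "A": self.A, "k": self.k,
                "C": self.num_classes}
        nn.save_checkpoint(path, self.named_params(), {**base, **(meta or {})})

    @staticmethod
    def load(path, cfg: BackboneConfig | None = None) -> "PestNet":
        with np.load(path, allow_pickle=False) as z:
            variant = str(z["meta/variant"])
            a = int(z["meta/A"]); k = int(z["meta/k"]); c = int(z["meta/C"])
        if cfg is None:
            cfg = (BackboneConfig.tiny() if variant == "tiny"
                   else BackboneConfig.zf_like())
        net = PestNet(cfg, anchors_per_position=a, k=k, num_classes=c)
        nn.load_checkpoint(path, net.named_params())
        return net
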