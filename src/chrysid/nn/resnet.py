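"""Residual backbone with three parallel softmax heads, in NumPy.

One shared convolutional trunk ends in a global-average-pooled feature
vector (the "flatten" feature, 512-dim at the default 18-layer preset); three
independent affine+softmax classifiers predict cultivar name, flower type
and petal type from that one feature.  The network is trained from scratch
(no pretraining) with He initialization, because flower color is
label-bearing and texture-biased pretrained features discard it.

Presets
-------
``paper18`` — the standard 18-layer residual topology: 7x7/2 stem + 3x3/2
max pool, four stages of two basic blocks with widths 64/128/256/512,
224-px input, feature_dim 512.
``tiny``    — a two-stage miniature (widths 8/16, one block each, 48-px
input, feature_dim 16) that trains in seconds on one CPU and is used by the
synthetic end-to-end experiments.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .layers import (BatchNorm2d, Conv2d, GlobalAvgPool, Layer, Linear,
                     MaxPool2d, ReLU)

__all__ = ["BackboneConfig", "HeadConfig", "MultiHeadOutput", "MultiHeadResNet",
           "build_network", "he_initialize", "softmax", "save_checkpoint",
           "load_checkpoint"]


@dataclass(frozen=True)
class BackboneConfig:
    widths: tuple[int, ...] = (64, 128, 256, 512)
    blocks: tuple[int, ...] = (2, 2, 2, 2)
    input_size: int = 224
    # "imagenet": 7x7/2 conv + 3x3/2 maxpool; "simple": 3x3/1 conv;
    # "simple2": 3x3/2 conv (small inputs)
    stem: str = "imagenet"

    def __post_init__(self) -> None:
        if len(self.widths) != len(self.blocks) or not self.widths:
            raise ValueError("widths and blocks must be equal-length, non-empty")
        if self.stem not in ("imagenet", "simple", "simple2"):
            raise ValueError("stem must be 'imagenet', 'simple' or 'simple2'")
        if self.input_size < 2 ** (len(self.widths) + (2 if self.stem == "imagenet" else 0)):
            raise ValueError("input size too small for this depth")

    @property
    def feature_dim(self) -> int:
        """Length of the shared flatten feature (final stage width)."""
        return self.widths[-1]

    @classmethod
    def preset(cls, name: str) -> "BackboneConfig":
        if name == "paper18":
            return cls()
        if name == "tiny":
            return cls(widths=(8, 16), blocks=(1, 1), input_size=48, stem="simple2")
        raise ValueError(f"unknown preset {name!r}")


@dataclass(frozen=True)
class HeadConfig:
    n_cultivars: int
    n_flower_types: int
    n_petal_types: int

    def __post_init__(self) -> None:
        for n in (self.n_cultivars, self.n_flower_types, self.n_petal_types):
            if n < 2:
                raise ValueError("every head needs >= 2 classes")

    def as_dict(self) -> dict[str, int]:
        return {"cultivar": self.n_cultivars, "flower": self.n_flower_types,
                "petal": self.n_petal_types}


@dataclass
class MultiHeadOutput:
    """Probabilities of the three heads plus the shared feature vectors."""

    cultivar: np.ndarray  # (N, n_cultivars)
    flower: np.ndarray    # (N, n_flower_types)
    petal: np.ndarray     # (N, n_petal_types)
    features: np.ndarray  # (N, feature_dim)

    def head(self, name: str) -> np.ndarray:
        return getattr(self, name)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class BasicBlock:
    """conv3x3-BN-ReLU-conv3x3-BN plus (projected) shortcut, then ReLU."""

    def __init__(self, in_ch: int, out_ch: int, stride: int) -> None:
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.short_conv: Conv2d | None = Conv2d(in_ch, out_ch, 1, stride, pad=0)
            self.short_bn: BatchNorm2d | None = BatchNorm2d(out_ch)
        else:
            self.short_conv = self.short_bn = None

    def layers(self) -> list[Layer]:
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2]
        if self.short_conv is not None:
            out += [self.short_conv, self.short_bn]
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)
        y = self.bn2.forward(self.conv2.forward(y, training), training)
        if self.short_conv is not None:
            s = self.short_bn.forward(self.short_conv.forward(x, training), training)
        else:
            s = x
        return self.relu2.forward(y + s, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        if self.short_conv is not None:
            dshort = self.short_conv.backward(self.short_bn.backward(d))
        else:
            dshort = d
        return dmain + dshort


class MultiHeadResNet:
    """The shared trunk plus three affine softmax heads."""

    HEADS = ("cultivar", "flower", "petal")

    def __init__(self, backbone: BackboneConfig, heads: HeadConfig) -> None:
        self.backbone_config = backbone
        self.head_config = heads

        stem: list[Layer] = []
        if backbone.stem == "imagenet":
            stem += [Conv2d(3, backbone.widths[0], 7, 2, pad=3),
                     BatchNorm2d(backbone.widths[0]), ReLU(), MaxPool2d(3, 2, 1)]
        else:
            stride = 2 if backbone.stem == "simple2" else 1
            stem += [Conv2d(3, backbone.widths[0], 3, stride),
                     BatchNorm2d(backbone.widths[0]), ReLU()]
        self.stem = stem

        self.blocks: list[BasicBlock] = []
        in_ch = backbone.widths[0]
        for si, (width, n_blocks) in enumerate(zip(backbone.widths, backbone.blocks)):
            for bi in range(n_blocks):
                stride = 2 if (bi == 0 and si > 0) else 1
                self.blocks.append(BasicBlock(in_ch, width, stride))
                in_ch = width
        self.pool = GlobalAvgPool()
        d = backbone.feature_dim
        self.heads = {name: Linear(d, n)
                      for name, n in heads.as_dict().items()}

    # -- parameter plumbing -------------------------------------------------
    def layers(self) -> list[Layer]:
        out = list(self.stem)
        for b in self.blocks:
            out += b.layers()
        out.append(self.pool)
        out += [self.heads[h] for h in self.HEADS]
        return out

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers() for name in layer.params]

    def n_parameters(self) -> int:
        """Trainable parameter count (conv/linear weights, biases, BN affine)."""
        return int(sum(layer.params[name].size for layer, name in self.parameters()))

    def zero_grads(self) -> None:
        for layer in self.layers():
            layer.zero_grads()

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False
                       ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != self.backbone_config.input_size \
                or x.shape[3] != self.backbone_config.input_size:
            raise ValueError(
                f"expected input (N, 3, {self.backbone_config.input_size}, "
                f"{self.backbone_config.input_size}), got {x.shape}")
        h = x.astype(np.float32)
        for layer in self.stem:
            h = layer.forward(h, training)
        for block in self.blocks:
            h = block.forward(h, training)
        feats = self.pool.forward(h, training)
        logits = {name: self.heads[name].forward(feats, training) for name in self.HEADS}
        return logits, feats

    def forward(self, x: np.ndarray, training: bool = False) -> MultiHeadOutput:
        logits, feats = self.forward_logits(x, training)
        return MultiHeadOutput(cultivar=softmax(logits["cultivar"]),
                               flower=softmax(logits["flower"]),
                               petal=softmax(logits["petal"]),
                               features=feats)

    def backward(self, dlogits: dict[str, np.ndarray]) -> None:
        dfeat = None
        for name in self.HEADS:
            d = self.heads[name].backward(dlogits[name])
            dfeat = d if dfeat is None else dfeat + d
        dh = self.pool.backward(dfeat)
        for block in reversed(self.blocks):
            dh = block.backward(dh)
        for layer in reversed(self.stem):
            dh = layer.backward(dh)


def build_network(backbone: BackboneConfig, heads: HeadConfig) -> MultiHeadResNet:
    return MultiHeadResNet(backbone, heads)


def he_initialize(net: MultiHeadResNet, seed: int = 0) -> MultiHeadResNet:
    """He-normal initialization: weights ~ N(0, 2/fan_in), biases zero.

    Deterministic: layers are visited in topological order with one seeded
    generator.  Batch-norm scale/shift are set to 1/0 and running statistics
    reset.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 42]))
    for layer in net.layers():
        if isinstance(layer, (Conv2d, Linear)):
            std = np.sqrt(2.0 / layer.fan_in)
            layer.params["W"] = rng.normal(0.0, std, layer.params["W"].shape).astype(np.float32)
            if "b" in layer.params:
                layer.params["b"] = np.zeros_like(layer.params["b"])
        elif isinstance(layer, BatchNorm2d):
            layer.params["gamma"][:] = 1.0
            layer.params["beta"][:] = 0.0
            layer.running_mean[:] = 0.0
            layer.running_var[:] = 1.0
    net.zero_grads()
    return net


# -- checkpointing ----------------------------------------------------------

def _vocab_hash(vocab_lists: dict[str, list[str]]) -> str:
    blob = json.dumps(vocab_lists, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_checkpoint(net: MultiHeadResNet, path: str | Path,
                    vocab_lists: dict[str, list[str]] | None = None,
                    meta: dict | None = None) -> None:
    """Weights as .npz plus a JSON sidecar with configs and vocabulary hash."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(net.layers()):
        for name, arr in layer.params.items():
            arrays[f"{i}.{name}"] = arr
        if isinstance(layer, BatchNorm2d):
            arrays[f"{i}.running_mean"] = layer.running_mean
            arrays[f"{i}.running_var"] = layer.running_var
    np.savez(path, **arrays)
    sidecar = {
        "backbone": {"widths": list(net.backbone_config.widths),
                     "blocks": list(net.backbone_config.blocks),
                     "input_size": net.backbone_config.input_size,
                     "stem": net.backbone_config.stem},
        "heads": net.head_config.as_dict(),
        "vocab": vocab_lists or {},
        "vocab_hash": _vocab_hash(vocab_lists or {}),
        "meta": meta or {},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path) -> tuple[MultiHeadResNet, dict]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    if sidecar.get("vocab"):
        if _vocab_hash(sidecar["vocab"]) != sidecar["vocab_hash"]:
            raise ValueError("checkpoint vocabulary hash mismatch")
    b = sidecar["backbone"]
    backbone = BackboneConfig(widths=tuple(b["widths"]), blocks=tuple(b["blocks"]),
                              input_size=b["input_size"], stem=b["stem"])
    h = sidecar["heads"]
    net = MultiHeadResNet(backbone, HeadConfig(h["cultivar"], h["flower"], h["petal"]))
    data = np.load(str(path))
    for i, layer in enumerate(net.layers()):
        for name in layer.params:
            layer.params[name] = data[f"{i}.{name}"]
        if isinstance(layer, BatchNorm2d):
            layer.running_mean = data[f"{i}.running_mean"]
            layer.running_var = data[f"{i}.running_var"]
    net.zero_grads()
    return net, sidecar
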