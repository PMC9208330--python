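"""Training loop: summed three-head cross-entropy, label smoothing, SGD+momentum.

The total loss is the unweighted sum of the cultivar-name, flower-type and
petal-type cross-entropies.  Targets are label-smoothed with the uniform
convention: the true class gets ``1 - eps + eps/K`` and every other class
``eps/K`` (eps defaults to 0.1).  Weights follow classical momentum SGD,

    v <- m * v - alpha * g,    W <- W + v,

with m = 0.9; alpha follows one of the four decay schedules.  Mini-batches of
32 are reshuffled every epoch with the run seed; the trailing short batch is
kept.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn.resnet import MultiHeadResNet, softmax
from .pipeline import PatchSet
from .schedules import ScheduleConfig, learning_rate

__all__ = ["smooth_labels", "multitask_loss", "LossBreakdown", "SGDMomentum",
           "TrainingLog", "train"]

HEADS = ("cultivar", "flower", "petal")


def smooth_labels(class_index: int, K: int, eps: float = 0.1) -> np.ndarray:
    """Uniformly smoothed target distribution over K classes."""
    if not (0 <= class_index < K):
        raise ValueError("class_index out of range")
    if not (0.0 <= eps < 1.0):
        raise ValueError("eps must lie in [0, 1)")
    t = np.full(K, eps / K)
    t[class_index] += 1.0 - eps
    return t


def smooth_label_matrix(indices: np.ndarray, K: int, eps: float) -> np.ndarray:
    t = np.full((len(indices), K), eps / K)
    t[np.arange(len(indices)), indices] += 1.0 - eps
    return t


@dataclass(frozen=True)
class LossBreakdown:
    """Per-head cross-entropies; the total is their exact sum."""

    cultivar: float
    flower: float
    petal: float

    @property
    def total(self) -> float:
        return self.cultivar + self.flower + self.petal


def multitask_loss(out, targets: dict[str, np.ndarray]) -> LossBreakdown:
    """Cross-entropy of each head's probabilities against smoothed targets.

    ``out`` is a MultiHeadOutput (or any object with per-head probability
    arrays); batched inputs are averaged over the batch.
    """
    vals = {}
    for name in HEADS:
        p = np.atleast_2d(out.head(name) if hasattr(out, "head") else out[name])
        t = np.atleast_2d(targets[name])
        if p.shape != t.shape:
            raise ValueError(f"head {name!r}: target shape {t.shape} != {p.shape}")
        vals[name] = float(-(t * np.log(np.clip(p, 1e-12, None))).sum(axis=1).mean())
    return LossBreakdown(**vals)


class SGDMomentum:
    """Classical momentum descent over a network's (layer, name) parameters."""

    def __init__(self, net: MultiHeadResNet, momentum: float = 0.9) -> None:
        self.net = net
        self.momentum = momentum
        self.velocity = {
            (id(layer), name): np.zeros_like(layer.params[name])
            for layer, name in net.parameters()
        }

    def step(self, alpha: float) -> None:
        if alpha < 0:
            raise ValueError("learning rate must be >= 0")
        m = self.momentum
        for layer, name in self.net.parameters():
            key = (id(layer), name)
            g = layer.grads[name]
            if g.shape != layer.params[name].shape:
                raise ValueError("gradient/weight shape mismatch")
            v = m * self.velocity[key] - alpha * g
            self.velocity[key] = v
            layer.params[name] += v


@dataclass
class TrainingLog:
    """One record per epoch: learning rate plus six per-head losses."""

    strategy: str
    seed: int
    records: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _epoch_losses(net: MultiHeadResNet, X: np.ndarray, targets: dict[str, np.ndarray],
                  batch: int = 64) -> LossBreakdown:
    sums = {h: 0.0 for h in HEADS}
    n = len(X)
    for s in range(0, n, batch):
        logits, _ = net.forward_logits(X[s:s + batch], training=False)
        for h in HEADS:
            p = softmax(logits[h])
            t = targets[h][s:s + batch]
            sums[h] += float(-(t * np.log(np.clip(p, 1e-12, None))).sum())
    return LossBreakdown(**{h: sums[h] / n for h in HEADS})


def train(
    net: MultiHeadResNet,
    patches: PatchSet,
    cfg: ScheduleConfig,
    seed: int = 0,
    batch_size: int = 32,
    epochs: int | None = None,
    smoothing_eps: float = 0.1,
    momentum: float = 0.9,
    val_data: tuple[np.ndarray, dict[str, np.ndarray]] | None = None,
) -> tuple[MultiHeadResNet, TrainingLog]:
    """Run ``epochs`` (default ``cfg.echos``) epochs of mini-batch SGD.

    ``val_data`` is an optional (images NCHW, integer-label dict) pair;
    validation losses use the same smoothing so train/validation curves are
    comparable.  Returns the trained network and the per-epoch log.
    """
    if len(patches) == 0:
        raise ValueError("empty patch set")
    epochs = cfg.echos if epochs is None else epochs
    labels = patches.label_arrays()
    K = {h: net.head_config.as_dict()[h] for h in HEADS}
    for h in HEADS:
        if labels[h].max() >= K[h]:
            raise ValueError(f"label index out of range for head {h!r}")

    opt = SGDMomentum(net, momentum=momentum)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    log = TrainingLog(strategy=cfg.strategy, seed=seed)

    val_targets = None
    if val_data is not None:
        val_X, val_idx = val_data
        val_targets = {h: smooth_label_matrix(val_idx[h], K[h], smoothing_eps)
                       for h in HEADS}

    iteration = 0
    n = len(patches)
    for epoch in range(epochs):
        order = rng.permutation(n)
        sums = {h: 0.0 for h in HEADS}
        alpha_epoch = learning_rate(cfg, epoch, iteration)
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            X = patches.load(idx)
            targets = {h: smooth_label_matrix(labels[h][idx], K[h], smoothing_eps)
                       for h in HEADS}
            logits, _ = net.forward_logits(X, training=True)
            net.zero_grads()
            dlogits = {}
            for h in HEADS:
                p = softmax(logits[h])
                sums[h] += float(-(targets[h] * np.log(np.clip(p, 1e-12, None))).sum())
                dlogits[h] = ((p - targets[h]) / len(idx)).astype(np.float32)
            net.backward(dlogits)
            alpha = learning_rate(cfg, epoch, iteration)
            opt.step(alpha)
            iteration += 1

        rec = {
            "epoch": epoch,
            "lr": alpha_epoch,
            "train_loss_cultivar": sums["cultivar"] / n,
            "train_loss_flower": sums["flower"] / n,
            "train_loss_petal": sums["petal"] / n,
        }
        rec["train_loss_total"] = (rec["train_loss_cultivar"]
                                   + rec["train_loss_flower"]
                                   + rec["train_loss_petal"])
        if val_targets is not None:
            vb = _epoch_losses(net, val_X, val_targets)
            rec.update(val_loss_cultivar=vb.cultivar, val_loss_flower=vb.flower,
                       val_loss_petal=vb.petal, val_loss_total=vb.total)
        log.records.append(rec)
    return net, log
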