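"""Evaluation protocol: cultivar-macro Top-k, macro recall/F1, ANOVA contrast.

Top-k accuracy is computed per image (true class among the k most probable),
averaged within each cultivar, then averaged *unweighted* across cultivars
and reported as a percentage — so cultivars with many test images do not
dominate.  Recall and F1 are per-class (macro) averages of the Top-1
predictions.  The cropping vs non-cropping model contrast is tested with a
one-way ANOVA over the two models' per-cultivar accuracy vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .manifest import Manifest
from .nn.resnet import MultiHeadResNet
from .pipeline import load_eval_images

__all__ = ["topk_hits", "topk_accuracy", "macro_recall_f1", "one_way_anova",
           "EvalReport", "evaluate_outputs", "evaluate_model",
           "generalization_eval", "ComparisonResult", "compare_reports"]

HEADS = ("cultivar", "flower", "petal")


def topk_hits(probs: np.ndarray, y_true: np.ndarray, k: int) -> np.ndarray:
    """Boolean per-item hits; probability ties break toward the lower index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    probs = np.asarray(probs, dtype=float)
    k = min(k, probs.shape[1])
    # stable sort on -p keeps the lower class index first among ties
    order = np.argsort(-probs, axis=1, kind="stable")[:, :k]
    return (order == np.asarray(y_true)[:, None]).any(axis=1)


def topk_accuracy(probs: np.ndarray, y_true: np.ndarray, k: int,
                  groups: np.ndarray | None = None,
                  return_per_group: bool = False):
    """Cultivar-macro Top-k accuracy in percent.

    ``groups`` assigns each item to a cultivar; per-group mean hit rates are
    averaged unweighted.  Without groups this reduces to the plain (micro)
    image-level rate.
    """
    hits = topk_hits(probs, y_true, k).astype(float)
    if groups is None:
        value = 100.0 * hits.mean()
        return (value, None) if return_per_group else value
    groups = np.asarray(groups)
    if len(groups) != len(hits):
        raise ValueError("groups must cover all items")
    per = pd.Series(hits).groupby(pd.Series(groups)).mean()
    value = 100.0 * float(per.mean())
    return (value, per) if return_per_group else value


def macro_recall_f1(y_pred: np.ndarray, y_true: np.ndarray,
                    n_classes: int | None = None) -> tuple[float, float]:
    """Macro-averaged recall and F1 of hard Top-1 predictions.

    F1 is computed per class (harmonic mean of that class's precision and
    recall) and then averaged; classes absent from the truth are excluded
    from both macro averages.
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    recalls, f1s = [], []
    for c in range(n_classes):
        actual = y_true == c
        if not actual.any():
            continue
        predicted = y_pred == c
        tp = float((actual & predicted).sum())
        rec = tp / actual.sum()
        prec = tp / predicted.sum() if predicted.any() else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        recalls.append(rec)
        f1s.append(f1)
    return float(np.mean(recalls)), float(np.mean(f1s))


def one_way_anova(*groups: np.ndarray) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Degenerate case: if every observation is identical (zero between- and
    within-group variance) the statistic is defined as F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs n >= 2")
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    if np.isnan(f):  # zero within-group variance with non-zero between
        return float("inf"), 0.0
    return float(f), float(p)


@dataclass
class HeadMetrics:
    top1: float
    top5: float
    recall: float
    f1: float
    per_cultivar_top1: pd.Series = field(repr=False, default=None)


@dataclass
class EvalReport:
    """Table-style report: per head Top-1/Top-5 (%), macro recall and F1."""

    heads: dict[str, HeadMetrics]
    n_images: int

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name, m in self.heads.items():
            rows[name] = {"Top-1 (%)": m.top1, "Top-5 (%)": m.top5,
                          "recall": m.recall, "F1-score": m.f1}
        return pd.DataFrame(rows).T

    def to_json(self) -> str:
        payload = {
            "n_images": self.n_images,
            "heads": {
                name: {"top1": m.top1, "top5": m.top5, "recall": m.recall,
                       "f1": m.f1,
                       "per_cultivar_top1": (m.per_cultivar_top1.to_dict()
                                             if m.per_cultivar_top1 is not None else None)}
                for name, m in self.heads.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        payload = json.loads(text)
        heads = {}
        for name, m in payload["heads"].items():
            per = (pd.Series(m["per_cultivar_top1"])
                   if m["per_cultivar_top1"] is not None else None)
            heads[name] = HeadMetrics(top1=m["top1"], top5=m["top5"],
                                      recall=m["recall"], f1=m["f1"],
                                      per_cultivar_top1=per)
        return cls(heads=heads, n_images=payload["n_images"])


def evaluate_outputs(probs: dict[str, np.ndarray], y_true: dict[str, np.ndarray],
                     cultivar_groups: np.ndarray, n_classes: dict[str, int],
                     head_masks: dict[str, np.ndarray] | None = None) -> EvalReport:
    """Build an EvalReport from per-head probabilities and true indices."""
    heads = {}
    n_images = 0
    for name in probs:
        mask = None if head_masks is None else head_masks.get(name)
        p = probs[name] if mask is None else probs[name][mask]
        t = y_true[name] if mask is None else y_true[name][mask]
        g = cultivar_groups if mask is None else cultivar_groups[mask]
        if len(t) == 0:
            raise ValueError(f"no evaluable images for head {name!r}")
        n_images = max(n_images, len(t))
        top1, per = topk_accuracy(p, t, 1, groups=g, return_per_group=True)
        top5 = topk_accuracy(p, t, 5, groups=g)
        pred = np.argmax(p, axis=1)
        rec, f1 = macro_recall_f1(pred, t, n_classes=n_classes[name])
        heads[name] = HeadMetrics(top1=top1, top5=top5, recall=rec, f1=f1,
                                  per_cultivar_top1=per)
    return EvalReport(heads=heads, n_images=n_images)


def predict_probs(net: MultiHeadResNet, X: np.ndarray, batch: int = 64
                  ) -> dict[str, np.ndarray]:
    """Per-head probabilities for a batch of preprocessed images."""
    outs = {h: [] for h in HEADS}
    for s in range(0, len(X), batch):
        mh = net.forward(X[s:s + batch], training=False)
        for h in HEADS:
            outs[h].append(mh.head(h))
    return {h: np.concatenate(outs[h]) for h in HEADS}


def evaluate_model(net: MultiHeadResNet, m: Manifest, mode: str = "crop",
                   source_size: int | None = None) -> EvalReport:
    """Evaluate a trained network on a manifest (validation protocol)."""
    size = net.backbone_config.input_size
    src = source_size or round(size * 256 / 224)
    X = load_eval_images(m, patch_size=size, source_size=src, mode=mode)
    probs = predict_probs(net, X)
    idx = m.label_indices()
    y = {h: idx[h].to_numpy(int) for h in HEADS}
    return evaluate_outputs(probs, y, m.df["cultivar_id"].to_numpy(),
                            n_classes=net.head_config.as_dict())


def generalization_eval(net: MultiHeadResNet, test: Manifest,
                        train_cultivars: list[str], mode: str = "crop",
                        source_size: int | None = None) -> EvalReport:
    """Evaluate on a later-season test set sharing cultivars with training.

    The flower- and petal-type heads are scored on every test image; the
    cultivar head only on images of cultivars present in the training
    vocabulary (unknown cultivars cannot be predicted by a closed-set head).
    """
    shared = [c for c in train_cultivars if c in set(test.df["cultivar_id"])]
    if not shared:
        raise ValueError("test manifest shares no cultivar with the training vocabulary")
    # map test labels onto the training vocabulary
    v = test.vocab
    cult_map = {c: i for i, c in enumerate(train_cultivars)}
    size = net.backbone_config.input_size
    src = source_size or round(size * 256 / 224)
    X = load_eval_images(test, patch_size=size, source_size=src, mode=mode)
    probs = predict_probs(net, X)
    y = {
        "cultivar": test.df["cultivar_id"].map(cult_map).fillna(-1).to_numpy(int),
        "flower": test.df["flower_type"].map(
            {c: i for i, c in enumerate(v.flower_types)}).to_numpy(int),
        "petal": test.df["petal_type"].map(
            {c: i for i, c in enumerate(v.petal_types)}).to_numpy(int),
    }
    masks = {"cultivar": y["cultivar"] >= 0}
    return evaluate_outputs(probs, y, test.df["cultivar_id"].to_numpy(),
                            n_classes=net.head_config.as_dict(), head_masks=masks)


@dataclass
class ComparisonResult:
    """Cropping vs non-cropping contrast with per-head ANOVA."""

    report_a: EvalReport
    report_b: EvalReport
    label_a: str
    label_b: str
    anova: dict[str, tuple[float, float]]  # head -> (F, p)
    alpha: float = 0.05

    def significant(self, head: str) -> bool:
        return self.anova[head][1] < self.alpha


def compare_reports(a: EvalReport, b: EvalReport, label_a: str = "cropping",
                    label_b: str = "non-cropping", alpha: float = 0.05
                    ) -> ComparisonResult:
    anova = {}
    for head in a.heads:
        ga = a.heads[head].per_cultivar_top1.to_numpy(float)
        gb = b.heads[head].per_cultivar_top1.to_numpy(float)
        anova[head] = one_way_anova(ga, gb)
    return ComparisonResult(report_a=a, report_b=b, label_a=label_a,
                            label_b=label_b, anova=anova, alpha=alpha)
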