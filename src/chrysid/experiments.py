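"""Reference end-to-end experiments on the synthetic flower generator.

The "tiny color task" is the package's standard desk-scale study: twelve
synthetic cultivars spanning 3 color series x 2 petal types x 2 flower-type
variants, ~200 images in total, a tiny two-stage residual backbone, and ten
training epochs.  It exercises the full chain — generation, balancing,
splitting, crop expansion, multi-head training, evaluation, feature
extraction, AP clustering — in well under a minute per run on one CPU.

The conditions (class structure, jitter level, image counts, input sizes)
are fixed here so that tests, the command line and the acceptance script all
run the same study.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import (adjusted_rand_index, affinity_propagation, APConfig,
                       cultivar_mean_features, extract_features)
from .manifest import Manifest
from .nn.resnet import (BackboneConfig, HeadConfig, MultiHeadResNet,
                        build_network, he_initialize)
from .pipeline import (PatchSet, build_training_patches, load_eval_images,
                       split_manifest)
from .schedules import ScheduleConfig
from .evaluation import EvalReport, evaluate_outputs, predict_probs
from .synthetic import (CultivarSpec, SyntheticDatasetConfig, VariationParams,
                        generate_dataset)
from .training import TrainingLog, train
from .vocab import COLOR_ANCHORS, LabelVocabulary

__all__ = ["TINY_COLORS", "TINY_PETALS", "TINY_FLOWERS", "tiny_cultivar_specs",
           "tiny_vocab", "generate_tiny_dataset", "TinyRun", "run_tiny_experiment",
           "color_clustering_ari"]

TINY_COLORS = ("white", "yellow", "red")
TINY_PETALS = ("flat", "tubular")
# cross-cutting flower-type variants applicable under either petal type
TINY_FLOWERS = ("sparse-form", "dense-form")

# geometry of the scaled-down pipeline: render 80 px, resize 56, crop 48
# (the 56 -> 48 crop keeps the 256 -> 224 ratio of the full-scale protocol)
TINY_RENDER = 80
TINY_SOURCE = 56
TINY_PATCH = 48
TINY_CROPS = 10  # same tenfold expansion as the full-scale pipeline
TINY_IMAGES_PER_CULTIVAR = 17  # 12 cultivars -> 204 images (~200)


def tiny_vocab() -> LabelVocabulary:
    n = len(TINY_COLORS) * len(TINY_PETALS) * len(TINY_FLOWERS)
    return LabelVocabulary(
        cultivars=[f"cv_{i:04d}" for i in range(n)],
        petal_types=list(TINY_PETALS),
        flower_types=list(TINY_FLOWERS),
        colors=list(TINY_COLORS),
    )


def tiny_cultivar_specs(seed: int = 0) -> list[CultivarSpec]:
    """Twelve cultivars covering the 3 x 2 x 2 label product."""
    specs = []
    i = 0
    for color in TINY_COLORS:
        for petal in TINY_PETALS:
            for flower in TINY_FLOWERS:
                rng = np.random.default_rng(np.random.SeedSequence([seed, 909, i]))
                sparse = flower == "sparse-form"
                h0, s0, v0 = COLOR_ANCHORS[color]
                specs.append(CultivarSpec(
                    cultivar_id=f"cv_{i:04d}",
                    color_class=color,
                    petal_type=petal,
                    flower_type=flower,
                    petal_count=(9 if sparse else 26) + int(rng.integers(-1, 2)),
                    petal_aspect=float(rng.uniform(0.95, 1.05)),
                    disk_frac=(0.24 if sparse else 0.08) * float(rng.uniform(0.95, 1.05)),
                    base_hsv=(
                        float((h0 + rng.uniform(-0.008, 0.008)) % 1.0),
                        float(np.clip(s0 * rng.uniform(0.95, 1.05), 0.0, 1.0)),
                        float(np.clip(v0 * rng.uniform(0.96, 1.04), 0.05, 1.0)),
                    ),
                ))
                i += 1
    return specs


def tiny_color_of() -> dict[str, str]:
    return {s.cultivar_id: s.color_class for s in tiny_cultivar_specs()}


def generate_tiny_dataset(out_dir: str | Path, seed: int = 0,
                          images_per_cultivar: int = TINY_IMAGES_PER_CULTIVAR,
                          drift_level: float = 0.0,
                          year_tag: str = "2018") -> Manifest:
    vocab = tiny_vocab()
    config = SyntheticDatasetConfig(
        n_cultivars=len(vocab.cultivars),
        images_per_cultivar=images_per_cultivar,
        image_size=TINY_RENDER,
        seed=seed,
        year_tag=year_tag,
        drift_level=drift_level,
        variation=VariationParams.low(),
    )
    return generate_dataset(config, out_dir, vocab=vocab,
                            specs=tiny_cultivar_specs(seed=0))


@dataclass
class TinyRun:
    """Everything one seeded tiny-task training run produces."""

    net: MultiHeadResNet
    log: TrainingLog
    report: EvalReport
    train_patches: PatchSet
    val_manifest: Manifest
    val_X: np.ndarray
    val_y: dict[str, np.ndarray]
    seed: int
    strategy: str


def run_tiny_experiment(workdir: str | Path, seed: int = 0, strategy: str = "poly",
                        epochs: int = 10, manifest: Manifest | None = None
                        ) -> TinyRun:
    """Generate (or reuse) the tiny dataset, train the tiny net, evaluate it."""
    workdir = Path(workdir)
    if manifest is None:
        manifest = generate_tiny_dataset(workdir, seed=seed)
    split = split_manifest(manifest, train_frac=0.8, seed=seed)
    patches = build_training_patches(split, n_crops=TINY_CROPS, seed=seed,
                                     source_size=TINY_SOURCE, patch_size=TINY_PATCH)
    val_X = load_eval_images(split.val, patch_size=TINY_PATCH,
                             source_size=TINY_SOURCE, mode="crop")
    idx = split.val.label_indices()
    val_y = {h: idx[h].to_numpy(int) for h in ("cultivar", "flower", "petal")}

    vocab = manifest.vocab
    net = build_network(
        BackboneConfig.preset("tiny"),
        HeadConfig(n_cultivars=len(vocab.cultivars),
                   n_flower_types=len(vocab.flower_types),
                   n_petal_types=len(vocab.petal_types)),
    )
    he_initialize(net, seed=seed)
    # schedule constants stay at the full-protocol values (echos=40 horizon);
    # only the number of epochs actually run is reduced
    cfg = ScheduleConfig.for_strategy(strategy)
    net, log = train(net, patches, cfg, seed=seed, epochs=epochs,
                     val_data=(val_X, val_y))

    probs = predict_probs(net, val_X)
    report = evaluate_outputs(probs, val_y, split.val.df["cultivar_id"].to_numpy(),
                              n_classes=net.head_config.as_dict())
    return TinyRun(net=net, log=log, report=report, train_patches=patches,
                   val_manifest=split.val, val_X=val_X, val_y=val_y,
                   seed=seed, strategy=strategy)


def color_clustering_ari(run: TinyRun, ap_config: APConfig | None = None
                         ) -> tuple[float, int]:
    """AP-cluster per-cultivar mean features; agreement with color labels.

    Returns (adjusted Rand index against the color series, cluster count).
    """
    fm = extract_features(run.net, run.val_X,
                          row_labels=run.val_manifest.df["cultivar_id"].tolist())
    pooled = cultivar_mean_features(fm, run.val_manifest, color_of=tiny_color_of())
    res = affinity_propagation(pooled, ap_config or APConfig())
    colors = pooled.annotations["color_class"].to_numpy()
    _, color_idx = np.unique(colors, return_inverse=True)
    return adjusted_rand_index(color_idx, res.labels), res.n_clusters
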