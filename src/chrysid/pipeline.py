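"""Dataset construction: ingestion, balancing, splitting and crop expansion.

The protocol mirrors standard practice for training a from-scratch CNN on a
balanced cultivar collection: take a fixed number of images per cultivar
(default 80), split 80/20 stratified by cultivar, scale every training image
to 256x256 and expand it into ten random 224x224 patches.  Color jitter,
grayscale, rotation and flips are deliberately NOT offered: flower color is
label-bearing and the flower is radially symmetric, so those augmentations
either destroy information or do nothing.

Crops are represented lazily as (source row, rectangle) pairs; pixels are
materialized on demand, so patch counting and geometry checks cost nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
from PIL import Image

from .manifest import Manifest
from .vocab import LabelVocabulary

__all__ = [
    "read_voc_annotation",
    "balance_manifest",
    "split_manifest",
    "SplitResult",
    "resize_image",
    "random_crops",
    "center_crop",
    "PatchSet",
    "build_training_patches",
    "load_eval_images",
]


def read_voc_annotation(xml_document: str, vocab_table: pd.DataFrame) -> dict:
    """Parse one LabelImg-style Pascal-VOC annotation into a labeled record.

    The object name carries the cultivar id; petal and flower types are
    joined from ``vocab_table`` (columns cultivar_id, petal_type,
    flower_type), since the three labels are bound per cultivar.
    """
    try:
        root = ET.fromstring(xml_document)
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML: {exc}") from exc
    objects = root.findall("object")
    if not objects:
        raise ValueError("VOC annotation contains no object")
    name_el = objects[0].find("name")
    if name_el is None or not (name_el.text or "").strip():
        raise ValueError("VOC object has no name")
    cultivar = name_el.text.strip()
    fn_el = root.find("filename")
    filename = fn_el.text.strip() if fn_el is not None and fn_el.text else ""
    match = vocab_table.loc[vocab_table["cultivar_id"] == cultivar]
    if match.empty:
        raise KeyError(f"cultivar {cultivar!r} absent from vocabulary table")
    row = match.iloc[0]
    return {
        "filename": filename,
        "cultivar_id": cultivar,
        "petal_type": row["petal_type"],
        "flower_type": row["flower_type"],
    }


def balance_manifest(m: Manifest, per_cultivar: int = 80, seed: int = 0,
                     allow_fewer: bool = False) -> Manifest:
    """Uniform random selection of exactly ``per_cultivar`` rows per cultivar."""
    if len(m) == 0:
        raise ValueError("empty manifest")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    pieces = []
    for cid, group in m.df.groupby("cultivar_id", sort=True):
        n = len(group)
        if n < per_cultivar:
            if not allow_fewer:
                raise ValueError(
                    f"cultivar {cid!r} has {n} images, below the quota {per_cultivar}")
            pieces.append(group)
            continue
        take = rng.choice(n, size=per_cultivar, replace=False)
        pieces.append(group.iloc[np.sort(take)])
    return Manifest(pd.concat(pieces, ignore_index=True), vocab=m.vocab)


@dataclass
class SplitResult:
    train: Manifest
    val: Manifest
    train_frac: float
    seed: int


def split_manifest(m: Manifest, train_frac: float = 0.8, seed: int = 0) -> SplitResult:
    """Stratified per-cultivar train/validation split.

    Per cultivar, ``floor(n * (1 - train_frac))`` rows go to validation and
    the remainder to training, so fractional counts favor training and no
    cultivar can vanish from the training set.  With 80 rows per cultivar at
    the default fraction this yields 64 train / 16 validation each.
    """
    if len(m) == 0:
        raise ValueError("empty manifest")
    if not (0.0 < train_frac <= 1.0):
        raise ValueError("train_frac must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    train_parts, val_parts = [], []
    for _, group in m.df.groupby("cultivar_id", sort=True):
        n = len(group)
        # round before flooring: 80 * (1 - 0.8) is 15.999... in floats
        n_val = int(np.floor(np.round(n * (1.0 - train_frac), 9)))
        perm = rng.permutation(n)
        val_parts.append(group.iloc[np.sort(perm[:n_val])])
        train_parts.append(group.iloc[np.sort(perm[n_val:])])
    train = Manifest(pd.concat(train_parts, ignore_index=True), vocab=m.vocab)
    val_df = (pd.concat(val_parts, ignore_index=True) if any(len(p) for p in val_parts)
              else m.df.iloc[0:0])
    val = Manifest(val_df.reset_index(drop=True), vocab=m.vocab)
    return SplitResult(train=train, val=val, train_frac=train_frac, seed=seed)


def resize_image(img: np.ndarray, target: int = 256) -> np.ndarray:
    """Bilinear resize of an RGB raster to ``target`` x ``target``."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB raster of shape (H, W, 3)")
    if img.shape[0] == target and img.shape[1] == target:
        return img
    pil = Image.fromarray(img.astype(np.uint8))
    return np.asarray(pil.resize((target, target), Image.BILINEAR))


def random_crops(source_size: int, size: int = 224, n: int = 10,
                 seed: int = 0) -> np.ndarray:
    """Rectangles of ``n`` random crops from a square source.

    Top-left corners are drawn uniformly (with replacement) from the
    ``(source_size - size + 1)^2`` valid grid positions; coordinates are
    0-based and half-open: a rectangle (r, c, r+size, c+size).
    """
    if size > source_size:
        raise ValueError("crop size exceeds source size")
    span = source_size - size + 1
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    rc = rng.integers(0, span, size=(n, 2))
    return np.concatenate([rc, rc + size], axis=1)


def center_crop(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    if size > h or size > w:
        raise ValueError("crop size exceeds image")
    r = (h - size) // 2
    c = (w - size) // 2
    return img[r:r + size, c:c + size]


def _load_rgb(path: str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


@dataclass
class PatchSet:
    """Lazy collection of training patches (source row + crop rectangle).

    ``entries`` repeats the manifest row of every patch; ``rects`` holds the
    0-based half-open crop rectangles against the resized source.  Pixels are
    materialized on demand in ``load``; resized sources are cached because
    consecutive patches share them.
    """

    entries: pd.DataFrame
    rects: np.ndarray          # (n, 4) int: r0, c0, r1, c1
    source_size: int
    patch_size: int
    vocab: LabelVocabulary

    def __post_init__(self) -> None:
        self._cache: dict[str, np.ndarray] = {}
        if len(self.entries) != len(self.rects):
            raise ValueError("entries/rects length mismatch")

    def __len__(self) -> int:
        return len(self.rects)

    def label_arrays(self) -> dict[str, np.ndarray]:
        v = self.vocab
        maps = {
            "cultivar": {c: i for i, c in enumerate(v.cultivars)},
            "flower": {c: i for i, c in enumerate(v.flower_types)},
            "petal": {c: i for i, c in enumerate(v.petal_types)},
        }
        return {
            "cultivar": self.entries["cultivar_id"].map(maps["cultivar"]).to_numpy(int),
            "flower": self.entries["flower_type"].map(maps["flower"]).to_numpy(int),
            "petal": self.entries["petal_type"].map(maps["petal"]).to_numpy(int),
        }

    def _source(self, path: str) -> np.ndarray:
        arr = self._cache.get(path)
        if arr is None:
            arr = resize_image(_load_rgb(path), self.source_size)
            self._cache[path] = arr
        return arr

    def load(self, indices: np.ndarray) -> np.ndarray:
        """Patch pixels as float32 NCHW in [0, 1]."""
        out = np.empty((len(indices), 3, self.patch_size, self.patch_size),
                       dtype=np.float32)
        for k, i in enumerate(indices):
            src = self._source(self.entries.iloc[int(i)]["path"])
            r0, c0, r1, c1 = self.rects[int(i)]
            out[k] = (src[r0:r1, c0:c1].astype(np.float32) / 255.0).transpose(2, 0, 1)
        return out


def build_training_patches(split: SplitResult, n_crops: int = 10, seed: int = 0,
                           source_size: int = 256, patch_size: int = 224) -> PatchSet:
    """Expand the training manifest ``n_crops``-fold by random cropping.

    Only training images are cropped; validation images are evaluated at
    full view (resize, optionally center-crop) elsewhere.  Every patch
    inherits the labels of its source row.
    """
    train = split.train
    if len(train) == 0:
        raise ValueError("empty training manifest")
    n_img = len(train)
    entries = train.df.loc[np.repeat(np.arange(n_img), n_crops)].reset_index(drop=True)
    rects = np.empty((n_img * n_crops, 4), dtype=int)
    for i in range(n_img):
        rects[i * n_crops:(i + 1) * n_crops] = random_crops(
            source_size, patch_size, n_crops,
            seed=int(np.random.SeedSequence([seed, 404, i]).generate_state(1)[0] % (2**31)))
    return PatchSet(entries=entries, rects=rects, source_size=source_size,
                    patch_size=patch_size, vocab=train.vocab)


def load_eval_images(m: Manifest, patch_size: int = 224, source_size: int | None = 256,
                     mode: str = "crop") -> np.ndarray:
    """Evaluation-time preprocessing.

    ``mode='crop'``   — resize to ``source_size`` then center-crop to
                        ``patch_size`` (matches training on cropped patches);
    ``mode='nocrop'`` — resize directly to ``patch_size`` (the non-cropping
                        model variant).
    """
    out = np.empty((len(m), 3, patch_size, patch_size), dtype=np.float32)
    for i, path in enumerate(m.df["path"]):
        img = _load_rgb(path)
        if mode == "crop":
            img = center_crop(resize_image(img, source_size or patch_size), patch_size)
        elif mode == "nocrop":
            img = resize_image(img, patch_size)
        else:
            raise ValueError("mode must be 'crop' or 'nocrop'")
        out[i] = (img.astype(np.float32) / 255.0).transpose(2, 0, 1)
    return out
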