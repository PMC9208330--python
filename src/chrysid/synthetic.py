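"""Procedural generator of labeled chrysanthemum-like flower images.

No public image collection exists for the three-level cultivar/petal/flower
labeling this package targets, so this module synthesizes one with the same
statistical structure: every cultivar has a fixed color series, petal type
and flower type; images of one cultivar share that morphology but vary in
viewpoint, scale, lighting and petal count; a second "year" of the same
cultivars can be generated with drifted morphology to probe generalization.

Petals are drawn as 2-D radial archetypes on a near-black background:

* ``flat``     — broad overlapping ellipses,
* ``spoon``    — a narrow stalk ending in an oval tip,
* ``tubular``  — thin straight rays,
* ``anemone``  — flat outer ray florets around an enlarged raised disk,
* ``peculiar`` — irregular lobed petals with per-petal phase noise.

Everything is deterministic: the same configuration yields byte-identical
manifests and pixels.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
from PIL import Image

from .manifest import Manifest
from .vocab import (
    COLOR_ANCHORS,
    FLOWER_TYPES,
    LabelVocabulary,
    cultivar_name_pool,
    flower_types_of_family,
)

__all__ = [
    "CultivarSpec",
    "VariationParams",
    "SyntheticDatasetConfig",
    "sample_cultivar_spec",
    "render_flower_image",
    "generate_dataset",
    "LabeledImage",
]


@dataclass(frozen=True)
class CultivarSpec:
    """Morphology of one synthetic cultivar; all its images share the labels."""

    cultivar_id: str
    color_class: str
    petal_type: str
    flower_type: str
    petal_count: int            # >= 5
    petal_aspect: float         # width multiplier of the petal archetype
    disk_frac: float            # center-disk radius as a fraction of flower radius
    base_hsv: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.petal_count < 5:
            raise ValueError("petal_count must be >= 5")
        if not (0.0 < self.disk_frac < 0.6):
            raise ValueError("disk_frac out of range (0, 0.6)")
        if not all(0.0 <= c <= 1.0 for c in self.base_hsv):
            raise ValueError("base_hsv components must lie in [0, 1]")


@dataclass(frozen=True)
class VariationParams:
    """Bounded intra-cultivar image-to-image variation.

    Bounds are kept small enough that the three labels stay visually
    recoverable; ``none()`` disables all jitter for exact-determinism tests.
    """

    view: str = "top"                 # "top" | "oblique"
    scale_jitter: float = 0.10        # radius multiplied by U(1-s, 1+s)
    rotation: float = 360.0           # whole-flower rotation, U(0, rotation) degrees
    hue_jitter: float = 0.02
    brightness_jitter: float = 0.06
    petal_count_jitter: int = 1
    noise_level: float = 0.01         # additive Gaussian pixel noise (0-1 scale)

    @classmethod
    def none(cls, view: str = "top") -> "VariationParams":
        return cls(view=view, scale_jitter=0.0, rotation=0.0, hue_jitter=0.0,
                   brightness_jitter=0.0, petal_count_jitter=0, noise_level=0.0)

    @classmethod
    def low(cls, view: str = "top") -> "VariationParams":
        """Mild jitter: classes remain cleanly separable."""
        return cls(view=view, scale_jitter=0.08, rotation=360.0, hue_jitter=0.015,
                   brightness_jitter=0.05, petal_count_jitter=1, noise_level=0.01)


@dataclass(frozen=True)
class LabeledImage:
    """An RGB raster plus its three labels and provenance."""

    image: np.ndarray  # uint8, (H, W, 3)
    cultivar_id: str
    petal_type: str
    flower_type: str
    year: str = ""
    view: str = "top"


@dataclass
class SyntheticDatasetConfig:
    n_cultivars: int
    images_per_cultivar: int
    image_size: int = 64
    seed: int = 0
    year_tag: str = "2018"
    drift_level: float = 0.0
    variation: VariationParams = field(default_factory=VariationParams.low)
    emit_voc: bool = False


def sample_cultivar_spec(
    pool_index: int,
    vocab: LabelVocabulary,
    rng_seed: int,
    name_pool: list[str] | None = None,
) -> CultivarSpec:
    """Deterministic cultivar morphology for slot ``pool_index``.

    Color series and petal types are assigned round-robin so that any block
    of >= 9 (colors) or >= 5 (petal types) consecutive indices covers every
    class; flower types cycle within the petal family.  Continuous
    morphology parameters are drawn from an rng keyed by (seed, index).
    """
    if not vocab.colors or not vocab.petal_types or not vocab.flower_types:
        raise ValueError("vocabulary must be non-empty at all three levels")
    names = name_pool if name_pool is not None else cultivar_name_pool()
    if pool_index >= len(names):
        raise ValueError("pool_index exceeds cultivar name pool")

    color = vocab.colors[pool_index % len(vocab.colors)]
    petal = vocab.petal_types[pool_index % len(vocab.petal_types)]
    family = flower_types_of_family(petal)
    family = [ft for ft in family if ft.name in vocab.flower_types]
    if not family:
        # cross-cutting vocabulary: fall back to cycling the full flower list
        family = [ft for ft in FLOWER_TYPES if ft.name in vocab.flower_types]
    if not family:
        raise ValueError("no flower type available for petal family " + petal)
    ftype = family[(pool_index // len(vocab.petal_types)) % len(family)]

    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, pool_index]))
    petal_count = max(5, int(round(ftype.petal_count_base * rng.uniform(0.85, 1.15))))
    aspect = float(np.clip(ftype.aspect * rng.uniform(0.85, 1.15), 0.5, 1.8))
    disk = float(np.clip(ftype.disk_frac * rng.uniform(0.85, 1.15), 0.03, 0.55))
    h0, s0, v0 = COLOR_ANCHORS[color]
    hsv = (
        float((h0 + rng.uniform(-0.012, 0.012)) % 1.0),
        float(np.clip(s0 * rng.uniform(0.92, 1.08), 0.0, 1.0)),
        float(np.clip(v0 * rng.uniform(0.94, 1.06), 0.05, 1.0)),
    )
    return CultivarSpec(
        cultivar_id=names[pool_index],
        color_class=color,
        petal_type=petal,
        flower_type=ftype.name,
        petal_count=petal_count,
        petal_aspect=aspect,
        disk_frac=disk,
        base_hsv=hsv,
    )


def drift_spec(spec: CultivarSpec, drift_level: float, rng_seed: int) -> CultivarSpec:
    """Perturb morphology (never labels) to emulate a later growing season."""
    if drift_level <= 0:
        return spec
    rng = np.random.default_rng(
        np.random.SeedSequence([rng_seed, 7_777, _stable_hash(spec.cultivar_id)]))
    d = float(drift_level)
    petal_count = max(5, int(round(spec.petal_count * (1 + rng.uniform(-0.5, 0.5) * d))))
    aspect = float(np.clip(spec.petal_aspect * (1 + rng.uniform(-0.4, 0.4) * d), 0.5, 1.8))
    disk = float(np.clip(spec.disk_frac * (1 + rng.uniform(-0.5, 0.5) * d), 0.03, 0.55))
    h, s, v = spec.base_hsv
    hsv = (
        float((h + rng.uniform(-0.04, 0.04) * d) % 1.0),
        float(np.clip(s * (1 + rng.uniform(-0.25, 0.25) * d), 0.0, 1.0)),
        float(np.clip(v * (1 + rng.uniform(-0.25, 0.25) * d), 0.05, 1.0)),
    )
    return replace(spec, petal_count=petal_count, petal_aspect=aspect,
                   disk_frac=disk, base_hsv=hsv)


def _stable_hash(s: str) -> int:
    """Process-independent 31-bit hash (str hash() is salted per process)."""
    return zlib.crc32(s.encode("utf-8")) & 0x7FFFFFFF


def _hsv_to_rgb(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorized HSV -> RGB on arrays in [0, 1]; returns (..., 3)."""
    h = np.mod(h, 1.0) * 6.0
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p = v * (1 - s)
    q = v * (1 - s * f)
    t = v * (1 - s * (1 - f))
    rgb = np.empty(h.shape + (3,), dtype=np.float64)
    conds = [i == k for k in range(6)]
    comps = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)]
    for c in range(3):
        rgb[..., c] = np.select(conds, [comp[c] for comp in comps])
    return rgb


_BACKGROUND_VALUE = 0.04  # near-black, emulating background-free acquisition


def render_flower_image(
    spec: CultivarSpec,
    var: VariationParams,
    rng_seed: int,
    size: int = 64,
) -> LabeledImage:
    """Draw one flower; deterministic given (spec, var, rng_seed, size)."""
    if size < 32:
        raise ValueError("image size must be >= 32 pixels")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed]))

    scale = 1.0 + rng.uniform(-var.scale_jitter, var.scale_jitter)
    rot = np.deg2rad(rng.uniform(0.0, var.rotation)) if var.rotation > 0 else 0.0
    dh = rng.uniform(-var.hue_jitter, var.hue_jitter)
    dv = rng.uniform(-var.brightness_jitter, var.brightness_jitter)
    n_petals = max(5, spec.petal_count + int(rng.integers(-var.petal_count_jitter,
                                                          var.petal_count_jitter + 1))
                   if var.petal_count_jitter > 0 else spec.petal_count)

    ax = np.linspace(-1.0, 1.0, size)
    xx, yy = np.meshgrid(ax, ax)
    if var.view == "oblique":
        yy = yy / 0.62  # foreshortened vertical axis
    r = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx) - rot

    radius = 0.88 * scale
    rn = r / radius
    frac = np.mod(theta * n_petals / (2 * np.pi), 1.0) - 0.5  # in [-0.5, 0.5)
    petal_index = np.floor(np.mod(theta * n_petals / (2 * np.pi), n_petals)).astype(int)

    a = spec.petal_aspect
    inside = rn < 1.0
    if spec.petal_type == "flat":
        width = 0.46 * a * np.clip(1.0 - rn**2, 0.0, None) ** 0.25
        mask = inside & (np.abs(frac) < width)
    elif spec.petal_type == "spoon":
        stalk = (rn < 0.58) & (np.abs(frac) < 0.07 * a)
        tip = (((rn - 0.76) / 0.26) ** 2 + (frac / (0.30 * a)) ** 2) < 1.0
        mask = inside & (stalk | tip)
    elif spec.petal_type == "tubular":
        # dense fine rays: thin relative to flat petals but still covering
        # most of the bloom, as real tubular cultivars do
        mask = inside & (np.abs(frac) < 0.17 * a)
    elif spec.petal_type == "anemone":
        width = 0.40 * a * np.clip(1.0 - rn**2, 0.0, None) ** 0.3
        mask = inside & (np.abs(frac) < width)
    elif spec.petal_type == "peculiar":
        phases = np.random.default_rng(
            np.random.SeedSequence([_stable_hash(spec.cultivar_id), 11])
        ).uniform(0, 2 * np.pi, n_petals)
        lobes = 0.55 + 0.45 * np.sin(2 * np.pi * 1.5 * rn + phases[petal_index % n_petals])
        mask = inside & (np.abs(frac) < 0.30 * a * np.clip(lobes, 0.05, None))
    else:
        raise ValueError(f"unknown petal type {spec.petal_type!r}")

    disk_frac = spec.disk_frac * (1.6 if spec.petal_type == "anemone" else 1.0)
    disk = r < disk_frac * radius

    h0, s0, v0 = spec.base_hsv
    h = np.full_like(r, (h0 + dh) % 1.0)
    s = np.full_like(r, s0)
    # gentle radial shading so petals are not flat color fields
    v = np.clip(v0 + dv, 0.05, 1.0) * (0.82 + 0.18 * np.clip(1.0 - rn, 0.0, 1.0))

    img = np.full((size, size, 3), _BACKGROUND_VALUE, dtype=np.float64)
    petal_rgb = _hsv_to_rgb(h, s, v)
    img[mask] = petal_rgb[mask]

    disk_v = 0.85 if spec.petal_type == "anemone" else 0.70
    disk_rgb = _hsv_to_rgb(np.full_like(r, 0.13), np.full_like(r, 0.85),
                           np.full_like(r, np.clip(disk_v + dv, 0.1, 1.0)))
    img[disk] = disk_rgb[disk]

    if var.noise_level > 0:
        img = img + rng.normal(0.0, var.noise_level, img.shape)

    out = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    return LabeledImage(image=out, cultivar_id=spec.cultivar_id,
                        petal_type=spec.petal_type, flower_type=spec.flower_type,
                        view=var.view)


def foreground_fraction(img: np.ndarray, threshold: int = 30) -> float:
    """Fraction of pixels brighter than the background (pixel-count oracle)."""
    return float((img.max(axis=-1) > threshold).mean())


def write_voc_xml(path: Path, image_path: Path, size: int, cultivar_id: str) -> None:
    """Emit a minimal LabelImg-style Pascal-VOC annotation (full-image box)."""
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = str(image_path.parent.name)
    ET.SubElement(root, "filename").text = image_path.name
    sz = ET.SubElement(root, "size")
    ET.SubElement(sz, "width").text = str(size)
    ET.SubElement(sz, "height").text = str(size)
    ET.SubElement(sz, "depth").text = "3"
    obj = ET.SubElement(root, "object")
    ET.SubElement(obj, "name").text = cultivar_id
    ET.SubElement(obj, "pose").text = "Unspecified"
    box = ET.SubElement(obj, "bndbox")
    ET.SubElement(box, "xmin").text = "1"
    ET.SubElement(box, "ymin").text = "1"
    ET.SubElement(box, "xmax").text = str(size)
    ET.SubElement(box, "ymax").text = str(size)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=False)


def make_specs(config: SyntheticDatasetConfig, vocab: LabelVocabulary | None = None,
               name_pool: list[str] | None = None) -> list[CultivarSpec]:
    """The cultivar specs a config implies (drift applied when requested)."""
    vocab = vocab or LabelVocabulary()
    specs = [sample_cultivar_spec(i, vocab, config.seed, name_pool=name_pool)
             for i in range(config.n_cultivars)]
    if config.drift_level > 0:
        specs = [drift_spec(s, config.drift_level, config.seed) for s in specs]
    return specs


def generate_dataset(
    config: SyntheticDatasetConfig,
    out_dir: str | Path,
    vocab: LabelVocabulary | None = None,
    specs: list[CultivarSpec] | None = None,
) -> Manifest:
    """Render ``n_cultivars x images_per_cultivar`` PNGs plus a manifest.

    Image file names encode (year, cultivar, index) so that regeneration with
    a different ``year_tag`` never collides.  Views alternate top/oblique.
    When ``specs`` is given, those cultivars are reused (drift still applied),
    which is how a second-season set of the *same* cultivars is produced.
    """
    vocab = vocab or LabelVocabulary()
    out_dir = Path(out_dir)
    img_dir = out_dir / f"images_{config.year_tag}"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {img_dir}: {exc}") from exc
    if not os.access(img_dir, os.W_OK):
        raise OSError(f"output directory {img_dir} is not writable")

    if specs is None:
        specs = make_specs(config, vocab)
    else:
        if len(specs) != config.n_cultivars:
            raise ValueError("len(specs) != n_cultivars")
        if config.drift_level > 0:
            specs = [drift_spec(s, config.drift_level, config.seed) for s in specs]

    rows = []
    for ci, spec in enumerate(specs):
        for j in range(config.images_per_cultivar):
            view = "top" if j % 2 == 0 else "oblique"
            var = replace(config.variation, view=view)
            img_seed = int(np.random.SeedSequence(
                [config.seed, 1_000_003, ci, j]).generate_state(1)[0] % (2**31))
            labeled = render_flower_image(spec, var, img_seed, size=config.image_size)
            fname = f"{config.year_tag}_{spec.cultivar_id}_{j:03d}.png"
            fpath = img_dir / fname
            Image.fromarray(labeled.image).save(fpath)
            if config.emit_voc:
                write_voc_xml(fpath.with_suffix(".xml"), fpath,
                              config.image_size, spec.cultivar_id)
            rows.append({
                "path": str(fpath),
                "cultivar_id": spec.cultivar_id,
                "petal_type": spec.petal_type,
                "flower_type": spec.flower_type,
                "year": config.year_tag,
                "view": view,
            })

    df = pd.DataFrame(rows)
    mvocab = LabelVocabulary(
        cultivars=[s.cultivar_id for s in specs],
        petal_types=list(vocab.petal_types),
        flower_types=list(vocab.flower_types),
        colors=list(vocab.colors),
    )
    return Manifest(df, vocab=mvocab)
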