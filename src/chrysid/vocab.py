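"""Label vocabularies for large-flowered chrysanthemum classification.

The horticultural classification of the traditional Chinese large-flowered
chrysanthemum (*Chrysanthemum x morifolium*) uses three label levels:

* 9 flower-color series,
* 5 petal types (flat, spoon, tubular, anemone, peculiar),
* 30 flower types, each nested under a petal-type family and describing
  petal details and their combination.

A cultivar carries one value at each level, so a vocabulary table keyed by
cultivar id resolves the petal/flower labels of any annotated image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

# 9 color series with HSV anchors used by the synthetic renderer.
# Anchors are chosen to be mutually separable, not colorimetric measurements.
COLOR_ANCHORS: dict[str, tuple[float, float, float]] = {
    "white": (0.10, 0.03, 0.97),
    "yellow": (0.155, 0.90, 0.95),
    "yellow-green": (0.23, 0.70, 0.85),
    "orange": (0.07, 0.95, 0.95),
    "pink": (0.93, 0.45, 0.97),
    "purple": (0.77, 0.70, 0.70),
    "red": (0.995, 0.92, 0.85),
    "dark-red": (0.985, 0.95, 0.42),
    "pink-purple": (0.84, 0.65, 0.82),
}

COLOR_CLASSES: tuple[str, ...] = tuple(COLOR_ANCHORS)

PETAL_TYPES: tuple[str, ...] = ("flat", "spoon", "tubular", "anemone", "peculiar")

# 30 flower-type codes, six per petal-type family.  Morphology modifiers
# (relative petal count, center-disk radius fraction, petal aspect) give each
# code a distinct procedural appearance within its family.
# (family, name, petal_count_base, disk_frac, aspect)
_FLOWER_TYPE_ROWS: list[tuple[str, str, int, float, float]] = [
    ("flat", "lotus-like", 16, 0.14, 1.20),
    ("flat", "lotus-set-like", 24, 0.10, 1.00),
    ("flat", "reflexed-broad", 20, 0.12, 1.35),
    ("flat", "incurved-broad", 28, 0.08, 0.90),
    ("flat", "flat-pan", 14, 0.18, 1.10),
    ("flat", "peony-form", 34, 0.06, 0.80),
    ("spoon", "spherical-spoon", 30, 0.08, 1.00),
    ("spoon", "spoon-set", 18, 0.14, 1.20),
    ("spoon", "long-spoon", 14, 0.12, 0.85),
    ("spoon", "curled-spoon", 24, 0.10, 1.10),
    ("spoon", "radiating-spoon", 20, 0.12, 0.95),
    ("spoon", "loose-spoon", 12, 0.16, 1.30),
    ("tubular", "tubiform-pan", 26, 0.12, 1.00),
    ("tubular", "dragon-claw-like", 18, 0.10, 1.25),
    ("tubular", "fine-tube", 40, 0.06, 0.70),
    ("tubular", "straight-tube", 30, 0.08, 1.00),
    ("tubular", "hooked-tube", 22, 0.12, 1.10),
    ("tubular", "spider-form", 16, 0.14, 1.40),
    ("anemone", "tubiform-anemone", 18, 0.30, 1.00),
    ("anemone", "flat-anemone", 14, 0.34, 1.15),
    ("anemone", "raised-anemone", 20, 0.38, 0.95),
    ("anemone", "cushion-anemone", 24, 0.32, 0.85),
    ("anemone", "quill-anemone", 16, 0.30, 1.20),
    ("anemone", "crested-anemone", 12, 0.40, 1.05),
    ("peculiar", "dragon-beard", 20, 0.12, 1.00),
    ("peculiar", "phoenix-feather", 16, 0.14, 1.25),
    ("peculiar", "tousled-form", 26, 0.10, 0.90),
    ("peculiar", "sparse-peculiar", 10, 0.18, 1.35),
    ("peculiar", "brush-form", 30, 0.08, 0.80),
    ("peculiar", "windblown-form", 18, 0.12, 1.10),
]


@dataclass(frozen=True)
class FlowerType:
    """One flower-type code and the morphology modifiers it implies."""

    name: str
    petal_family: str
    petal_count_base: int
    disk_frac: float
    aspect: float


FLOWER_TYPES: tuple[FlowerType, ...] = tuple(
    FlowerType(name=n, petal_family=f, petal_count_base=c, disk_frac=d, aspect=a)
    for f, n, c, d, a in _FLOWER_TYPE_ROWS
)


def flower_types_of_family(family: str) -> list[FlowerType]:
    return [ft for ft in FLOWER_TYPES if ft.petal_family == family]


@dataclass
class LabelVocabulary:
    """The three label vocabularies plus the color series.

    ``flower_types`` may be any subset of codes; a cultivar's flower type is
    not required to be nested under its petal family (the synthetic tiny
    tasks use cross-cutting variants), but the default 30-code vocabulary is
    nested the way the horticultural system is.
    """

    cultivars: list[str] = field(default_factory=list)
    petal_types: list[str] = field(default_factory=lambda: list(PETAL_TYPES))
    flower_types: list[str] = field(default_factory=lambda: [ft.name for ft in FLOWER_TYPES])
    colors: list[str] = field(default_factory=lambda: list(COLOR_CLASSES))

    def __post_init__(self) -> None:
        for name, level in (
            ("cultivars", self.cultivars),
            ("petal_types", self.petal_types),
            ("flower_types", self.flower_types),
            ("colors", self.colors),
        ):
            if name != "cultivars" and len(level) == 0:
                raise ValueError(f"vocabulary level {name!r} is empty")

    @property
    def n_cultivars(self) -> int:
        return len(self.cultivars)

    def index(self, level: str, value: str) -> int:
        pool: list[str] = getattr(self, level)
        try:
            return pool.index(value)
        except ValueError:
            raise KeyError(f"{value!r} not in vocabulary level {level!r}") from None


def cultivar_name_pool(size: int = 512) -> list[str]:
    """Deterministic pool of synthetic cultivar identifiers."""
    return [f"cv_{i:04d}" for i in range(size)]


def cultivar_table(specs) -> pd.DataFrame:
    """Vocabulary table binding each cultivar id to its petal and flower type.

    This is the join table used when ingesting Pascal-VOC annotations, whose
    object names carry only the cultivar id.
    """
    return pd.DataFrame(
        {
            "cultivar_id": [s.cultivar_id for s in specs],
            "petal_type": [s.petal_type for s in specs],
            "flower_type": [s.flower_type for s in specs],
        }
    )
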