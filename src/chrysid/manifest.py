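"""Tabular image manifests: the unit of balancing, splitting and evaluation.

A manifest is a DataFrame with one row per image and the columns

    path, cultivar_id, petal_type, flower_type, year, view

plus the three label vocabularies.  All dataset-construction operations and
the evaluation protocol are defined on manifests, never on loose file lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .vocab import LabelVocabulary

MANIFEST_COLUMNS = ["path", "cultivar_id", "petal_type", "flower_type", "year", "view"]


@dataclass
class Manifest:
    df: pd.DataFrame
    vocab: LabelVocabulary = field(default_factory=LabelVocabulary)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        if not self.vocab.cultivars:
            self.vocab = LabelVocabulary(
                cultivars=sorted(self.df["cultivar_id"].unique().tolist()),
                petal_types=self.vocab.petal_types,
                flower_types=self.vocab.flower_types,
                colors=self.vocab.colors,
            )

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        """Check vocabulary membership and path uniqueness."""
        if self.df["path"].duplicated().any():
            raise ValueError("duplicate image paths in manifest")
        for col, level in (("cultivar_id", "cultivars"),
                           ("petal_type", "petal_types"),
                           ("flower_type", "flower_types")):
            pool = set(getattr(self.vocab, level))
            bad = set(self.df[col].unique()) - pool
            if bad:
                raise ValueError(f"labels {sorted(bad)} absent from vocabulary {level}")

    def counts_per_cultivar(self) -> pd.Series:
        return self.df.groupby("cultivar_id").size()

    def subset(self, index) -> "Manifest":
        return Manifest(self.df.loc[index].reset_index(drop=True), vocab=self.vocab)

    def restrict_to_cultivars(self, cultivars) -> "Manifest":
        keep = self.df["cultivar_id"].isin(set(cultivars))
        return Manifest(self.df[keep].reset_index(drop=True), vocab=self.vocab)

    def to_csv(self, path: str | Path) -> None:
        self.df[MANIFEST_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, vocab: LabelVocabulary | None = None) -> "Manifest":
        df = pd.read_csv(path, dtype=str)
        return cls(df, vocab=vocab or LabelVocabulary())

    def label_indices(self) -> dict[str, "pd.Series"]:
        """Integer class indices for the three heads, per vocabulary order."""
        v = self.vocab
        return {
            "cultivar": self.df["cultivar_id"].map({c: i for i, c in enumerate(v.cultivars)}),
            "flower": self.df["flower_type"].map({c: i for i, c in enumerate(v.flower_types)}),
            "petal": self.df["petal_type"].map({c: i for i, c in enumerate(v.petal_types)}),
        }
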