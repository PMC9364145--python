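"""Expression and accessibility matrices with TSV round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = ["ExpressionMatrix", "AccessibilityMatrix", "parse_region_key"]


def parse_region_key(key: str) -> GenomicInterval:
    """Parse a ``chrom:start-end`` (1-based inclusive) row key back to an interval."""
    chrom, _, span = key.rpartition(":")
    start_s, _, end_s = span.partition("-")
    return GenomicInterval(chrom, int(start_s) - 1, int(end_s))


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.genes)}, {len(self.samples)})"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class AccessibilityMatrix:
    """Consensus regions x samples matrix of accessibility signal."""

    regions: list[GenomicInterval]
    samples: list[str]
    values: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.regions)}, {len(self.samples)})"
            )

    def row(self, region: GenomicInterval) -> np.ndarray:
        return self.values[self.regions.index(region)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=[r.display() for r in self.regions], columns=self.samples
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="region")

    @classmethod
    def from_tsv(cls, path, normalization: str = "unknown") -> "AccessibilityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        regions = [parse_region_key(k) for k in df.index]
        return cls(regions, list(df.columns), df.to_numpy(dtype=float), normalization)
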