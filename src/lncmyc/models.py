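"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open ([start, end)), the BED
convention.  GTF input/output is converted at the I/O boundary so that no
other module ever sees 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CODING = "coding"
LNCRNA = "lncRNA"

HIGH_MYC = "high_myc"
LOW_MYC = "low_myc"

RIBO = "ribo_depleted"
POLYA = "polyA"


@dataclass(frozen=True)
class GeneModel:
    """A gene (or any annotation unit) with a strand-aware TSS.

    ``tss`` is the first transcribed base: ``start`` on the + strand and
    ``end - 1`` on the - strand (coordinates half-open).
    """

    gene_id: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end ({self.start} >= {self.end})")
        if self.biotype not in (CODING, LNCRNA):
            raise ValueError(f"{self.gene_id}: biotype must be {CODING!r} or {LNCRNA!r}")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e > self.end or s >= e:
                raise ValueError(f"{self.gene_id}: exons must be sorted, non-overlapping, within the gene body")
            prev = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq binding interval with a summit point estimate."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.name}: start must be < end ({self.start} >= {self.end})")
        if not self.start <= self.summit < self.end:
            raise ValueError(f"peak {self.name}: summit {self.summit} outside [{self.start},{self.end})")


@dataclass(frozen=True)
class SampleMeta:
    name: str
    condition: str
    library: str
    cell_line: str = "synthetic"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.condition not in (HIGH_MYC, LOW_MYC):
            raise ValueError(f"sample {self.name}: condition must be {HIGH_MYC!r} or {LOW_MYC!r}")
        if self.library not in (RIBO, POLYA):
            raise ValueError(f"sample {self.name}: library must be {RIBO!r} or {POLYA!r}")
        if self.replicate < 1:
            raise ValueError(f"sample {self.name}: replicate must be >= 1")


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    ``counts`` is a DataFrame indexed by gene_id with one column per sample
    name, in the order of ``samples``.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample names in metadata")
        if list(self.counts.columns) != names:
            raise ValueError("count columns do not match sample metadata order")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id(s): {dups[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, keep: Sequence[str]) -> "CountMatrix":
        keep = list(keep)
        meta = [s for s in self.samples if s.name in set(keep)]
        return CountMatrix(self.counts[[m.name for m in meta]], meta)

    def subset_genes(self, keep: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(keep)], list(self.samples))

    def select(self, condition: str | None = None, library: str | None = None,
               cell_line: str | None = None) -> "CountMatrix":
        meta = [
            s for s in self.samples
            if (condition is None or s.condition == condition)
            and (library is None or s.library == library)
            and (cell_line is None or s.cell_line == cell_line)
        ]
        return CountMatrix(self.counts[[m.name for m in meta]], meta)


@dataclass(frozen=True)
class TSSOccupancy:
    """Nearest-peak assignment for one gene's TSS.

    ``distance`` is signed: positive downstream of the TSS in the gene's
    direction of transcription (flipped on the - strand).  ``None`` when the
    gene's chromosome carries no peak.
    """

    gene_id: str
    tss: int
    nearest_peak: str | None
    distance: int | None
    bound: bool
    window: int


# Fig-5-style bidirectional promoter categories.
NO_TRANSCRIPTION = "no_transcription"
UNIDIR_UNREG = "unidirectional_unregulated"
UNIDIR_REG = "unidirectional_regulated"
BIDIR_UNREG = "bidirectional_unregulated"
BIDIR_CONCORDANT = "bidirectional_concordant"
BIDIR_DISCORDANT = "bidirectional_discordant"

CATEGORIES = (
    NO_TRANSCRIPTION,
    UNIDIR_UNREG,
    UNIDIR_REG,
    BIDIR_UNREG,
    BIDIR_CONCORDANT,
    BIDIR_DISCORDANT,
)


@dataclass
class BidirectionalPromoter:
    """A divergent (head-to-head) gene pair sharing a promoter region.

    ``gene_a`` is on the - strand (leftward), ``gene_b`` on the + strand
    (rightward); their TSS face away from each other, ``gap`` bp apart.
    """

    gene_a: str
    gene_b: str
    gap: int
    myc_bound: bool = False
    n_expressed: int = 0
    category: str | None = None

    def __post_init__(self) -> None:
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
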