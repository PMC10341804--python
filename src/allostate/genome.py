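"""Core genomic value types shared by every pipeline stage.

All coordinates are 0-based, half-open (BED convention). GFF3 input is
converted on read. Intervals are validated against a :class:`GenomeLayout`,
which carries chromosome lengths and the A/D subgenome membership of each
chromosome of the allotetraploid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

MARKS = ("H3K4me3", "H3K27me3", "H3K36me3", "H3K27ac", "H3K9ac", "DNase")
HISTONE_MARKS = MARKS[:5]


class Interval(NamedTuple):
    """A half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names, lengths and subgenome labels.

    Parameters
    ----------
    chroms : sequence of (name, length, subgenome)
        ``subgenome`` is ``"A"`` or ``"D"``.
    """

    names: tuple[str, ...]
    lengths: dict[str, int]
    subgenome: dict[str, str]

    @classmethod
    def from_records(cls, chroms: Iterable[tuple[str, int, str]]) -> "GenomeLayout":
        names, lengths, sub = [], {}, {}
        for name, length, sg in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            if name in lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if sg not in ("A", "D"):
                raise ValueError(f"subgenome for {name!r} must be 'A' or 'D', got {sg!r}")
            names.append(name)
            lengths[name] = int(length)
            sub[name] = sg
        return cls(tuple(names), lengths, sub)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def subgenome_length(self, sg: str) -> int:
        return sum(l for c, l in self.lengths.items() if self.subgenome[c] == sg)

    def n_bins(self, chrom: str, bin_width: int) -> int:
        return math.ceil(self.lengths[chrom] / bin_width)

    def bin_sizes(self, chrom: str, bin_width: int) -> np.ndarray:
        """Width in bases of each bin; the last bin may be partial."""
        n = self.n_bins(chrom, bin_width)
        sizes = np.full(n, bin_width, dtype=np.int64)
        rem = self.lengths[chrom] - (n - 1) * bin_width
        sizes[-1] = rem
        return sizes

    def validate_interval(self, iv: Interval) -> None:
        if iv.chrom not in self.lengths:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if not (0 <= iv.start < iv.end <= self.lengths[iv.chrom]):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside "
                f"[0, {self.lengths[iv.chrom]})"
            )


@dataclass
class GeneModel:
    """A gene body with exons, strand, subgenome label and new-gene flag."""

    gene_id: str
    body: Interval
    exons: list[Interval] = field(default_factory=list)
    subgenome: str = "A"
    is_new_gene: bool = False

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        exons = sorted(self.exons, key=lambda e: e.start)
        for e in exons:
            if e.start < self.body.start or e.end > self.body.end:
                raise ValueError(f"gene {self.gene_id}: exon outside body")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        self.exons = exons

    @property
    def tss(self) -> int:
        """Transcription start: body.start on '+', body.end - 1 on '-'."""
        return self.body.start if self.body.strand == "+" else self.body.end - 1

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def promoter(self, length: int = 500) -> Interval:
        """The ``length`` bases immediately upstream of the TSS, strand-aware,
        clamped to the chromosome start (upper clamping is the caller's job)."""
        if self.body.strand == "+":
            start = max(0, self.body.start - length)
            return Interval(self.body.chrom, start, self.body.start, "+")
        return Interval(self.body.chrom, self.body.end, self.body.end + length, "-")


@dataclass
class BinnedTrack:
    """Fixed-width per-bin fragment counts of one mark on one genome layout."""

    mark: str
    condition: str
    replicate: int
    bin_width: int
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, c in self.counts.items():
            c = np.asarray(c)
            if np.any(c < 0):
                raise ValueError(f"negative counts on {chrom}")
            self.counts[chrom] = c

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def stacked(self, order: Iterable[str] | None = None) -> np.ndarray:
        chroms = list(order) if order is not None else list(self.counts)
        return np.concatenate([self.counts[c] for c in chroms])

    def same_layout_as(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and set(self.counts) == set(other.counts)
            and all(len(self.counts[c]) == len(other.counts[c]) for c in self.counts)
        )
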