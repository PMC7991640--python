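"""Core genomic data model.

All coordinates are 0-based, half-open (BED convention). Inputs in other
conventions are converted at the parser boundary so no downstream code ever
reasons about off-by-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = ["GenomeInterval", "GenomeTable", "GeneModel"]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded); ``name`` and
    ``score`` are optional annotations carried through interval arithmetic
    unchanged.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint, rounded down."""
        return (self.start + self.end) // 2

    def shifted(self, offset: int) -> "GenomeInterval":
        return GenomeInterval(
            self.chrom, self.start + offset, self.end + offset, self.strand,
            self.name, self.score,
        )


class GenomeTable:
    """Ordered map of chromosome name to length in bp."""

    def __init__(self, lengths: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, Mapping) else list(lengths)
        seen: dict[str, int] = {}
        for name, length in items:
            if name in seen:
                raise ValueError(f"duplicate chromosome {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            seen[name] = int(length)
        self._lengths = seen

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeTable):
            return NotImplemented
        return self._lengths == other._lengths

    def items(self) -> Iterable[tuple[str, int]]:
        return self._lengths.items()

    def total_size(self) -> int:
        return sum(self._lengths.values())

    def validate_interval(self, iv: GenomeInterval) -> None:
        """Raise if ``iv`` lies off the declared genome."""
        if iv.chrom not in self._lengths:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self._lengths[iv.chrom]}"
            )

    def clip(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Clip ``[start, end)`` to chromosome bounds."""
        return max(0, start), min(self._lengths[chrom], end)


@dataclass
class GeneModel:
    """A gene with strand-aware TSS/TES and exon structure.

    On the + strand ``tss < tes``; on the - strand ``tss > tes``. Exons are
    stored as unstranded intervals within the gene body. ``fpkm`` is the
    expression level, or ``None`` when unmeasured.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: Sequence[GenomeInterval] = field(default_factory=tuple)
    fpkm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")
        if self.fpkm is not None and self.fpkm < 0:
            raise ValueError(f"gene {self.gene_id}: negative FPKM")
        exons = sorted(self.exons, key=lambda e: e.start)
        lo, hi = self.body_start, self.body_end
        prev_end = lo
        for e in exons:
            if e.chrom != self.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if e.start < prev_end or e.end > hi:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or exceed the gene body"
                )
            prev_end = e.end
        self.exons = tuple(exons)

    @property
    def body_start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def body_end(self) -> int:
        return max(self.tss, self.tes)

    @property
    def body(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.body_start, self.body_end,
                              self.strand, self.gene_id)

    @property
    def length(self) -> int:
        return self.body_end - self.body_start
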