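"""Interval algebra: overlap, subtraction, merging, nearest-TSS and shuffling.

These primitives back every peak comparison in the pipeline. Indexed queries
go through :mod:`intervaltree`; the naive O(n^2) counterparts used as test
oracles live in the test suite, not here.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome import GeneModel, GenomeInterval, GenomeTable

__all__ = [
    "overlaps",
    "intersection_length",
    "build_index",
    "overlaps_any",
    "subtract",
    "merge",
    "nearest_tss",
    "shuffle_intervals",
    "ShufflePlacementError",
]


def intersection_length(a: GenomeInterval, b: GenomeInterval) -> int:
    """Number of shared base pairs between two intervals (0 if different chrom)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomeInterval, b: GenomeInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` base pairs.

    Half-open semantics: book-ended intervals (``a.end == b.start``) share
    zero bases and do not overlap.
    """
    return intersection_length(a, b) >= min_bp


def build_index(intervals: Iterable[GenomeInterval]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over ``intervals`` for repeated queries."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        trees[iv.chrom].addi(iv.start, iv.end, iv)
    return dict(trees)


def overlaps_any(
    query: GenomeInterval,
    index: dict[str, IntervalTree],
    min_bp: int = 1,
) -> bool:
    """True iff ``query`` overlaps any indexed interval by >= ``min_bp``."""
    tree = index.get(query.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(query.start, query.end):
        if min(query.end, hit.end) - max(query.start, hit.begin) >= min_bp:
            return True
    return False


def subtract(
    a: Sequence[GenomeInterval],
    b: Sequence[GenomeInterval],
    mode: str = "whole",
) -> list[GenomeInterval]:
    """Remove ``b`` from ``a``.

    ``mode="whole"`` drops any member of ``a`` that overlaps (>= 1 bp) any
    member of ``b``; ``mode="base"`` trims the overlapping bases out,
    possibly splitting intervals. Input order of ``a`` is preserved.
    """
    if mode not in ("whole", "base"):
        raise ValueError(f"unknown subtract mode {mode!r}")
    index = build_index(b)
    out: list[GenomeInterval] = []
    for iv in a:
        tree = index.get(iv.chrom)
        if tree is None:
            out.append(iv)
            continue
        hits = sorted(
            (max(iv.start, h.begin), min(iv.end, h.end))
            for h in tree.overlap(iv.start, iv.end)
        )
        hits = [(s, e) for s, e in hits if e > s]
        if not hits:
            out.append(iv)
            continue
        if mode == "whole":
            continue
        cursor = iv.start
        for s, e in hits:
            if s > cursor:
                out.append(GenomeInterval(iv.chrom, cursor, s, iv.strand,
                                          iv.name, iv.score))
            cursor = max(cursor, e)
        if cursor < iv.end:
            out.append(GenomeInterval(iv.chrom, cursor, iv.end, iv.strand,
                                      iv.name, iv.score))
    return out


def merge(intervals: Iterable[GenomeInterval], gap: int = 0) -> list[GenomeInterval]:
    """Unite intervals that overlap or are separated by <= ``gap`` bp.

    Book-ended intervals merge at ``gap=0``. Output is sorted and
    non-overlapping; strand/name/score are dropped (merged spans are new loci).
    """
    by_chrom: dict[str, list[GenomeInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    out: list[GenomeInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e + gap:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomeInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomeInterval(chrom, cur_s, cur_e))
    return out


def nearest_tss(
    query: GenomeInterval,
    genes: Sequence[GeneModel],
    max_dist: int,
) -> Optional[tuple[str, int]]:
    """Closest-TSS gene for ``query``, or ``None`` beyond ``max_dist``.

    Distance is ``|TSS - query midpoint|`` in bp, same-chromosome genes only.
    Ties are broken toward the lexicographically smaller ``gene_id`` so the
    result is deterministic. The returned distance is signed: positive when
    the TSS lies 3' of the midpoint on the gene's strand would be ambiguous,
    so the sign simply reports ``TSS - midpoint`` in genome coordinates.
    """
    if not genes:
        raise ValueError("nearest_tss requires a non-empty gene list")
    mid = query.midpoint
    best: Optional[tuple[int, str, int]] = None  # (|d|, gene_id, signed d)
    for g in genes:
        if g.chrom != query.chrom:
            continue
        d = g.tss - mid
        key = (abs(d), g.gene_id, d)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None or best[0] > max_dist:
        return None
    return best[1], best[2]


class ShufflePlacementError(RuntimeError):
    """Raised when a shuffled interval cannot be placed clear of exclusions."""


def shuffle_intervals(
    intervals: Sequence[GenomeInterval],
    genome: GenomeTable,
    seed: int | np.random.Generator,
    exclude: Sequence[GenomeInterval] = (),
    max_tries: int = 1000,
) -> list[GenomeInterval]:
    """Chromosome- and length-matched random repositioning of ``intervals``.

    Each interval is placed uniformly on its own chromosome, keeping its
    length, rejecting placements that overlap ``exclude``. Deterministic for
    a fixed integer seed. Placed intervals may overlap one another, matching
    the usual shuffled-peak null.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excl_index = build_index(exclude)
    out: list[GenomeInterval] = []
    for iv in intervals:
        genome.validate_interval(iv)
        length = len(iv)
        chrom_len = genome[iv.chrom]
        if length >= chrom_len:
            raise ShufflePlacementError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} is as long as its chromosome"
            )
        placed = None
        for _ in range(max_tries):
            start = int(rng.integers(0, chrom_len - length + 1))
            cand = GenomeInterval(iv.chrom, start, start + length, iv.strand,
                                  iv.name, iv.score)
            if not overlaps_any(cand, excl_index):
                placed = cand
                break
        if placed is None:
            raise ShufflePlacementError(
                f"could not place shuffled copy of {iv.chrom}:{iv.start}-{iv.end} "
                f"after {max_tries} tries"
            )
        out.append(placed)
    return out
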