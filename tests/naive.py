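"""Naive O(n^2) reference implementations used as independent oracles.

Deliberately brute-force and structurally unlike the library code: plain
loops over every pair, no indexing, no early exit.
"""

from __future__ import annotations

import math

from chiprx.genome import GeneModel, GenomeInterval


def naive_overlap(a: GenomeInterval, b: GenomeInterval, min_bp: int = 1) -> bool:
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


def naive_subtract_whole(a, b):
    out = []
    for x in a:
        if not any(x.chrom == y.chrom and x.start < y.end and y.start < x.end
                   for y in b):
            out.append(x)
    return out


def naive_subtract_base(a, b):
    out = []
    for x in a:
        keep = [pos for pos in range(x.start, x.end)
                if not any(y.chrom == x.chrom and y.start <= pos < y.end
                           for y in b)]
        run_start = None
        prev = None
        for pos in keep + [None]:
            if run_start is None and pos is not None:
                run_start, prev = pos, pos
            elif pos is not None and pos == prev + 1:
                prev = pos
            else:
                if run_start is not None:
                    out.append(GenomeInterval(x.chrom, run_start, prev + 1,
                                              x.strand, x.name, x.score))
                run_start, prev = (pos, pos) if pos is not None else (None, None)
    return out


def naive_merge(intervals, gap: int = 0):
    """Pairwise union to fixpoint."""
    spans = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                ci, si, ei = spans[i]
                cj, sj, ej = spans[j]
                if ci == cj and si <= ej + gap and sj <= ei + gap:
                    spans[i] = (ci, min(si, sj), max(ei, ej))
                    spans.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(GenomeInterval(c, s, e) for c, s, e in spans)


def coverage_merge(intervals, genome):
    """Merge oracle via a per-base coverage mask (gap=0 only)."""
    import numpy as np

    out = []
    for chrom, length in genome.items():
        mask = np.zeros(length + 2, dtype=bool)
        for x in intervals:
            if x.chrom == chrom:
                mask[x.start + 1: x.end + 1] = True
        edges = np.diff(mask.astype(int))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            out.append(GenomeInterval(chrom, int(s), int(e)))
    return out


def naive_nearest_tss(query: GenomeInterval, genes: list[GeneModel],
                      max_dist: int):
    mid = (query.start + query.end) // 2
    candidates = []
    for g in genes:
        if g.chrom == query.chrom:
            candidates.append((abs(g.tss - mid), g.gene_id, g.tss - mid))
    if not candidates:
        return None
    candidates.sort()
    dist, gid, signed = candidates[0]
    if dist > max_dist:
        return None
    return gid, signed


def naive_decompose(peaks_a, peaks_b):
    common_a = [p for p in peaks_a
                if any(naive_overlap(p, q) for q in peaks_b)]
    unique_a = [p for p in peaks_a if p not in common_a]
    common_b = [q for q in peaks_b
                if any(naive_overlap(q, p) for p in peaks_a)]
    unique_b = [q for q in peaks_b if q not in common_b]
    return common_a, common_b, unique_a, unique_b


def naive_base_density(track, interval) -> float:
    """Per-base mean computed by visiting every base."""
    total = 0.0
    for pos in range(interval.start, interval.end):
        total += track.values[interval.chrom][pos // track.bin_size]
    return total / (interval.end - interval.start)


def naive_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
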