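"""Per-interval densities and scaled metagene profiles.

Densities are length-weighted means of binned signal, so a constant track
gives exactly its constant over any interval regardless of bin alignment.
Metagene profiles rescale gene bodies to a fixed number of bins and attach
fixed-resolution flanks, flipping minus-strand genes so column 0 is always
biological upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageTrack
from .genome import GeneModel, GenomeInterval

__all__ = [
    "DensityRecord",
    "ProfileMatrix",
    "interval_density",
    "interval_densities",
    "metagene_profile",
    "GroupDensityResult",
    "group_mean_density",
]


@dataclass(frozen=True)
class DensityRecord:
    interval: GenomeInterval
    density: float
    mark: Optional[str] = None
    sample: Optional[str] = None


def _range_mean(track: CoverageTrack, chrom: str, a: float, b: float) -> float:
    """Length-weighted mean of bin values over the real interval [a, b)."""
    if b <= a:
        raise ValueError("empty range")
    bs = track.bin_size
    v = track.values[chrom]
    i0 = int(np.floor(a / bs))
    i1 = int(np.ceil(b / bs))
    idx = np.arange(i0, i1)
    lo = np.maximum(idx * bs, a)
    hi = np.minimum((idx + 1) * bs, b)
    w = hi - lo
    return float(np.dot(v[idx], w) / (b - a))


def interval_density(
    track: CoverageTrack,
    interval: GenomeInterval,
    mark: Optional[str] = None,
    sample: Optional[str] = None,
) -> DensityRecord:
    """Mean signal over an interval (length-weighted across bins)."""
    track.genome.validate_interval(interval)
    d = _range_mean(track, interval.chrom, interval.start, interval.end)
    return DensityRecord(interval=interval, density=d, mark=mark, sample=sample)


def interval_densities(
    track: CoverageTrack, intervals: Sequence[GenomeInterval]
) -> np.ndarray:
    """Vector of mean densities, one per interval, in input order."""
    return np.array([interval_density(track, iv).density for iv in intervals])


@dataclass
class ProfileMatrix:
    """Genes x bins matrix of mean signal: flank | scaled body | flank."""

    gene_ids: list[str]
    matrix: np.ndarray  # shape (n_genes, upstream + body + downstream)
    upstream_bins: int
    body_bins: int
    downstream_bins: int
    flank_bin_size: int
    dropped: list[str] = field(default_factory=list)
    mark: Optional[str] = None
    sample: Optional[str] = None

    @property
    def n_columns(self) -> int:
        return self.upstream_bins + self.body_bins + self.downstream_bins

    def aggregate(self) -> np.ndarray:
        """Mean profile over genes."""
        return self.matrix.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f"up_{i}" for i in range(self.upstream_bins)]
            + [f"body_{i}" for i in range(self.body_bins)]
            + [f"down_{i}" for i in range(self.downstream_bins)]
        )
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.8g")


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    flank: int = 5000,
    body_bins: int = 100,
    flank_bin_size: int = 100,
) -> ProfileMatrix:
    """Scaled gene-body profile with fixed-bp flanks beyond TSS and TES.

    Genes whose body is shorter than ``body_bins`` bp, or whose flanks run
    off the chromosome, are dropped and listed in ``dropped``.
    """
    if not genes:
        raise ValueError("metagene_profile requires at least one gene")
    if flank % flank_bin_size != 0:
        raise ValueError("flank must be a multiple of flank_bin_size")
    n_flank = flank // flank_bin_size
    rows, ids, dropped = [], [], []
    for g in genes:
        if g.length < body_bins:
            dropped.append(g.gene_id)
            continue
        lo = g.body_start - flank
        hi = g.body_end + flank
        if lo < 0 or hi > track.genome[g.chrom]:
            dropped.append(g.gene_id)
            continue
        # left-to-right in genome coordinates, flipped afterwards if needed
        left = [
            _range_mean(track, g.chrom, lo + i * flank_bin_size,
                        lo + (i + 1) * flank_bin_size)
            for i in range(n_flank)
        ]
        edges = np.linspace(g.body_start, g.body_end, body_bins + 1)
        body = [
            _range_mean(track, g.chrom, edges[i], edges[i + 1])
            for i in range(body_bins)
        ]
        right = [
            _range_mean(track, g.chrom, g.body_end + i * flank_bin_size,
                        g.body_end + (i + 1) * flank_bin_size)
            for i in range(n_flank)
        ]
        row = np.array(left + body + right)
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(g.gene_id)
    if not rows:
        raise ValueError("no gene passed the length/bounds filters")
    return ProfileMatrix(
        gene_ids=ids,
        matrix=np.vstack(rows),
        upstream_bins=n_flank,
        body_bins=body_bins,
        downstream_bins=n_flank,
        flank_bin_size=flank_bin_size,
        dropped=dropped,
    )


@dataclass
class GroupDensityResult:
    summary: pd.DataFrame    # group, n, mean, median
    contrasts: pd.DataFrame  # group_a, group_b, statistic, p_value, p_adj


def group_mean_density(groups: Mapping[str, Sequence[float]]) -> GroupDensityResult:
    """Per-group density summaries with rank-based pairwise contrasts.

    Each contrast is a two-sided Mann-Whitney U test; p-values are
    Benjamini-Hochberg corrected across the contrasts of this call.
    """
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 members")
    summary = pd.DataFrame(
        [
            {
                "group": name,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
            }
            for name, vals in groups.items()
        ]
    )
    rows = []
    for a, b in combinations(groups, 2):
        stat, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b,
                     "statistic": float(stat), "p_value": float(p)})
    contrasts = pd.DataFrame(rows,
                             columns=["group_a", "group_b", "statistic", "p_value"])
    if len(contrasts):
        contrasts["p_adj"] = multipletests(contrasts["p_value"], method="fdr_bh")[1]
    else:
        contrasts["p_adj"] = []
    return GroupDensityResult(summary=summary, contrasts=contrasts)
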