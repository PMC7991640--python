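"""Fixed-bin coverage tracks in raw-count or spike-in-normalized (RRPM) units."""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .genome import GenomeInterval, GenomeTable

__all__ = ["CoverageTrack"]

UNITS = ("raw", "RRPM")


class CoverageTrack:
    """Per-chromosome signal vectors at a fixed bin size.

    The last bin of each chromosome may be partial; its value is still the
    signal over that bin. ``units`` is ``"raw"`` (counts) or ``"RRPM"``
    (reference-adjusted reads per million, i.e. spike-in normalized).
    """

    def __init__(
        self,
        genome: GenomeTable,
        bin_size: int,
        values: Mapping[str, np.ndarray],
        units: str = "raw",
    ):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if units not in UNITS:
            raise ValueError(f"units must be one of {UNITS}")
        self.genome = genome
        self.bin_size = int(bin_size)
        self.units = units
        self.values: dict[str, np.ndarray] = {}
        for chrom in genome:
            if chrom not in values:
                raise ValueError(f"missing values for chromosome {chrom!r}")
            v = np.asarray(values[chrom], dtype=np.float64)
            expected = self.n_bins(chrom)
            if v.shape != (expected,):
                raise ValueError(
                    f"{chrom!r}: expected {expected} bins, got {v.shape}"
                )
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{chrom!r}: values must be finite and >= 0")
            self.values[chrom] = v

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.genome[chrom] / self.bin_size)

    @classmethod
    def zeros(cls, genome: GenomeTable, bin_size: int, units: str = "raw") -> "CoverageTrack":
        vals = {c: np.zeros(math.ceil(L / bin_size)) for c, L in genome.items()}
        return cls(genome, bin_size, vals, units)

    @classmethod
    def constant(cls, genome: GenomeTable, bin_size: int, value: float,
                 units: str = "raw") -> "CoverageTrack":
        vals = {c: np.full(math.ceil(L / bin_size), float(value))
                for c, L in genome.items()}
        return cls(genome, bin_size, vals, units)

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(self.genome, self.bin_size,
                             {c: v.copy() for c, v in self.values.items()},
                             self.units)

    def scaled(self, factor: float, units: str | None = None) -> "CoverageTrack":
        return CoverageTrack(
            self.genome, self.bin_size,
            {c: v * factor for c, v in self.values.items()},
            units or self.units,
        )

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if (other.genome != self.genome or other.bin_size != self.bin_size
                or other.units != self.units):
            raise ValueError("tracks are not addition-compatible")
        return CoverageTrack(
            self.genome, self.bin_size,
            {c: self.values[c] + other.values[c] for c in self.values},
            self.units,
        )

    def total(self) -> float:
        """Sum of all bin values (total reads when units are raw)."""
        return float(sum(v.sum() for v in self.values.values()))

    def bin_bounds(self, chrom: str, i: int) -> GenomeInterval:
        start = i * self.bin_size
        end = min((i + 1) * self.bin_size, self.genome[chrom])
        return GenomeInterval(chrom, start, end)

    def allclose(self, other: "CoverageTrack", **kw) -> bool:
        return (self.genome == other.genome and self.bin_size == other.bin_size
                and all(np.allclose(self.values[c], other.values[c], **kw)
                        for c in self.values))
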