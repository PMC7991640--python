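"""Spike-in (ChIP-Rx) normalization.

A fixed amount of foreign-genome chromatin is spiked into every ChIP, so the
number of reads mapping to the spike-in genome measures effective sequencing
depth per unit chromatin. Scaling each sample by ``1e6 / spike_reads`` puts
all tracks on a common absolute scale — reference-adjusted reads per million
(RRPM) — in which genome-wide gains or losses of a mark remain visible,
unlike conventional per-million-target-read scaling which normalizes any
global shift away.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .coverage import CoverageTrack

__all__ = [
    "NormFactor",
    "compute_norm_factor",
    "normalize_track",
    "rpm_normalize_track",
    "read_norm_factors",
    "write_norm_factors",
]


@dataclass(frozen=True)
class NormFactor:
    """Per-sample spike-in scaling record.

    ``factor = 1e6 / spike_reads``; ``target_reads`` is carried for
    reporting only and never enters the factor.
    """

    sample_id: str
    target_reads: int
    spike_reads: int
    factor: float

    def __post_init__(self) -> None:
        if self.spike_reads <= 0:
            raise ValueError(
                f"sample {self.sample_id}: spike-in reads must be positive "
                "(spike-in absent?)"
            )
        if self.factor <= 0:
            raise ValueError(f"sample {self.sample_id}: factor must be positive")


def compute_norm_factor(sample_id: str, target_reads: int, spike_reads: int) -> NormFactor:
    """Spike-in normalization factor ``1e6 / spike_reads`` for one sample."""
    if spike_reads <= 0:
        raise ValueError(
            f"sample {sample_id}: spike_reads must be > 0 (spike-in absent)"
        )
    return NormFactor(
        sample_id=sample_id,
        target_reads=int(target_reads),
        spike_reads=int(spike_reads),
        factor=1e6 / spike_reads,
    )


def normalize_track(track: CoverageTrack, nf: NormFactor) -> CoverageTrack:
    """Scale a raw track into RRPM units by the sample's spike-in factor."""
    if track.units != "raw":
        raise ValueError(
            f"track is already in {track.units} units; refusing to re-normalize"
        )
    return track.scaled(nf.factor, units="RRPM")


def rpm_normalize_track(track: CoverageTrack) -> CoverageTrack:
    """Conventional per-million-target-read scaling (no spike-in).

    Provided for samples sequenced without spike-in and as the contrast that
    demonstrates what spike-in normalization rescues: a uniform global
    depletion is invisible in RPM units.
    """
    if track.units != "raw":
        raise ValueError(f"track is already in {track.units} units")
    total = track.total()
    if total <= 0:
        raise ValueError("cannot RPM-normalize an all-zero track")
    return track.scaled(1e6 / total, units="RRPM")


def write_norm_factors(factors: Sequence[NormFactor], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "target_reads": f.target_reads,
                "spike_reads": f.spike_reads,
                "factor": f.factor,
            }
            for f in factors
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_norm_factors(path: str | Path) -> dict[str, NormFactor]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[row.sample_id] = NormFactor(
            sample_id=str(row.sample_id),
            target_reads=int(row.target_reads),
            spike_reads=int(row.spike_reads),
            factor=float(row.factor),
        )
    return out
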