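"""Readers and writers for the pipeline's interchange formats.

All tabular formats are plain TSV. Genomic coordinates on disk follow BED
conventions (0-based, half-open) throughout, including the simplified gene
annotation, so no coordinate conversion happens outside this module.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome import GeneModel, GenomeInterval, GenomeTable

__all__ = [
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_genome_table",
    "write_genome_table",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_fpkm_table",
    "write_fpkm_table",
    "read_de_status",
    "write_de_status",
]


class BedParseError(ValueError):
    """A malformed line in a BED-family file; message names the line number."""


def read_bed(
    path: str | Path,
    genome: Optional[GenomeTable] = None,
) -> list[GenomeInterval]:
    """Read a 3-6 column BED file into intervals, preserving input order.

    When ``genome`` is given, each interval is validated against it.
    """
    out: list[GenomeInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3 or len(fields) > 6:
                raise BedParseError(
                    f"{path}:{lineno}: expected 3-6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 and fields[3] != "." else None
                score = (float(fields[4])
                         if len(fields) > 4 and fields[4] != "." else None)
                strand = fields[5] if len(fields) > 5 else "."
                iv = GenomeInterval(chrom, start, end, strand, name, score)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if genome is not None:
                try:
                    genome.validate_interval(iv)
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(
    intervals: Sequence[GenomeInterval],
    path: str | Path,
    extra_columns: Optional[Sequence[Sequence]] = None,
) -> None:
    """Write BED6 (+ optional extra columns, one sequence per interval)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [
                iv.chrom, str(iv.start), str(iv.end),
                iv.name if iv.name is not None else ".",
                format(iv.score, "g") if iv.score is not None else ".",
                iv.strand,
            ]
            if extra_columns is not None:
                fields.extend(str(x) for x in extra_columns[i])
            fh.write("\t".join(fields) + "\n")


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a fixed-bin track as bedGraph (one line per bin, zeros included)."""
    with open(path, "w") as fh:
        for chrom in track.genome:
            length = track.genome[chrom]
            bs = track.bin_size
            for i, v in enumerate(track.values[chrom]):
                end = min((i + 1) * bs, length)
                fh.write(f"{chrom}\t{i * bs}\t{end}\t{v:.10g}\n")


def read_bedgraph(
    path: str | Path,
    genome: GenomeTable,
    bin_size: int,
    units: str = "raw",
) -> CoverageTrack:
    """Read a bedGraph whose lines align to the fixed bin grid.

    Bins absent from the file are zero. Lines that do not start on a bin
    boundary or span more than one bin are rejected.
    """
    values = {c: np.zeros(math.ceil(L / bin_size)) for c, L in genome.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in genome:
                raise BedParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if s % bin_size != 0 or (e - s > bin_size) or e > genome[chrom]:
                raise BedParseError(
                    f"{path}:{lineno}: line not aligned to {bin_size} bp bins"
                )
            values[chrom][s // bin_size] = v
    return CoverageTrack(genome, bin_size, values, units)


def read_genome_table(path: str | Path) -> GenomeTable:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64})
    return GenomeTable(zip(df["chrom"], df["length"]))


def write_genome_table(genome: GenomeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


ANNOTATION_COLUMNS = [
    "gene_id", "chrom", "strand", "txStart", "txEnd", "exonStarts", "exonEnds",
]


def read_gene_annotation(
    path: str | Path,
    fpkm: Optional[dict[str, float]] = None,
) -> list[GeneModel]:
    """Read the simplified RefSeq-flat annotation (headered TSV).

    Columns: gene_id, chrom, strand, txStart, txEnd, exonStarts, exonEnds;
    coordinates 0-based half-open, exon lists comma-separated. The TSS is
    txStart on + genes and txEnd on - genes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    genes: list[GeneModel] = []
    for row in df.itertuples(index=False):
        tx_start, tx_end = int(row.txStart), int(row.txEnd)
        starts = [int(x) for x in str(row.exonStarts).split(",") if x]
        ends = [int(x) for x in str(row.exonEnds).split(",") if x]
        if len(starts) != len(ends):
            raise ValueError(f"{path}: gene {row.gene_id}: exon list mismatch")
        exons = [GenomeInterval(row.chrom, s, e) for s, e in zip(starts, ends)]
        if row.strand == "+":
            tss, tes = tx_start, tx_end
        else:
            tss, tes = tx_end, tx_start
        genes.append(GeneModel(
            gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
            tss=tss, tes=tes, exons=exons,
            fpkm=fpkm.get(row.gene_id) if fpkm else None,
        ))
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
            "txStart": g.body_start, "txEnd": g.body_end,
            "exonStarts": ",".join(str(e.start) for e in g.exons),
            "exonEnds": ",".join(str(e.end) for e in g.exons),
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fpkm_table(path: str | Path) -> dict[str, float]:
    """Read a headered TSV with columns gene_id, fpkm."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "fpkm": float})
    return dict(zip(df["gene_id"], df["fpkm"]))


def write_fpkm_table(fpkm: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(fpkm), "fpkm": [float(v) for v in fpkm.values()]}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_status(path: str | Path) -> dict[str, str]:
    """Read a headered TSV with columns gene_id, status (up/down/unchanged)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    bad = set(df["status"]) - {"up", "down", "unchanged"}
    if bad:
        raise ValueError(f"{path}: unknown DE statuses {sorted(bad)}")
    return dict(zip(df["gene_id"], df["status"]))


def write_de_status(status: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(status), "status": list(status.values())}
    ).to_csv(path, sep="\t", index=False)
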