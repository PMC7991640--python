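"""Enhancer calling, three-state classification, transitions and gene assignment.

Enhancers are H3K4me1 peaks that overlap neither an H3K4me3 peak nor an
annotated promoter (2 kb upstream / 500 bp downstream of the TSS,
strand-aware). States follow the H3K27 marks: H3K27ac present = active,
else H3K27me3 present = poised, else primed. An enhancer that is active in
wild type but no longer active in a mutant condition is "inactivated".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeInterval, GenomeTable
from .intervals import build_index, nearest_tss, overlaps_any

__all__ = [
    "STATES",
    "Enhancer",
    "EnhancerTransition",
    "define_promoters",
    "call_enhancers",
    "classify_enhancers",
    "dual_mark_fraction",
    "enhancer_transitions",
    "inactivated_fraction",
    "assign_enhancers",
    "enhancer_stats",
    "write_enhancer_bed",
    "write_transitions_tsv",
]

STATES = ("active", "primed", "poised")

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500


@dataclass(frozen=True)
class Enhancer:
    interval: GenomeInterval
    state: Optional[str] = None
    assigned_gene: Optional[str] = None
    tss_distance: Optional[int] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        if self.state is not None and self.state not in STATES:
            raise ValueError(f"unknown enhancer state {self.state!r}")


@dataclass(frozen=True)
class EnhancerTransition:
    """Fate of one wild-type-active enhancer in a mutant condition.

    ``mutant_state`` is the state of the overlapping mutant enhancer, or
    ``"lost"`` when no mutant enhancer overlaps the locus. An enhancer is
    inactivated whenever its mutant state is anything but active.
    """

    wt_enhancer: Enhancer
    mutant_state: str
    inactivated: bool

    def __post_init__(self) -> None:
        if self.mutant_state not in STATES + ("lost",):
            raise ValueError(f"unknown mutant state {self.mutant_state!r}")
        if self.inactivated != (self.mutant_state != "active"):
            raise ValueError("inactivated flag inconsistent with mutant state")


def define_promoters(
    genes: Sequence[GeneModel], genome: GenomeTable
) -> list[GenomeInterval]:
    """Strand-aware promoter windows, one per gene, clipped to chromosome ends.

    On the + strand the window is [TSS-2000, TSS+500); on the - strand it is
    mirrored to [TSS-500, TSS+2000).
    """
    out = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - PROMOTER_UPSTREAM, g.tss + PROMOTER_DOWNSTREAM
        else:
            start, end = g.tss - PROMOTER_DOWNSTREAM, g.tss + PROMOTER_UPSTREAM
        start, end = genome.clip(g.chrom, start, end)
        out.append(GenomeInterval(g.chrom, start, end, g.strand, g.gene_id))
    return out


def call_enhancers(
    h3k4me1_peaks: Sequence[GenomeInterval],
    h3k4me3_peaks: Sequence[GenomeInterval],
    promoters: Sequence[GenomeInterval],
    condition: Optional[str] = None,
) -> list[Enhancer]:
    """H3K4me1 peaks minus anything touching an H3K4me3 peak or promoter.

    Exclusion is whole-interval: one shared base pair with either exclusion
    set removes the peak entirely.
    """
    excl = build_index(list(h3k4me3_peaks) + list(promoters))
    return [
        Enhancer(interval=p, condition=condition)
        for p in h3k4me1_peaks
        if not overlaps_any(p, excl)
    ]


def classify_enhancers(
    enhancers: Sequence[Enhancer],
    h3k27ac_peaks: Sequence[GenomeInterval],
    h3k27me3_peaks: Sequence[GenomeInterval],
) -> list[Enhancer]:
    """Assign active / poised / primed states from the H3K27 marks.

    Precedence is active > poised: an enhancer carrying both H3K27ac and
    H3K27me3 is called active. Use :func:`dual_mark_fraction` to report how
    many enhancers the precedence rule actually decided.
    """
    ac = build_index(h3k27ac_peaks)
    me3 = build_index(h3k27me3_peaks)
    out = []
    for e in enhancers:
        if overlaps_any(e.interval, ac):
            state = "active"
        elif overlaps_any(e.interval, me3):
            state = "poised"
        else:
            state = "primed"
        out.append(replace(e, state=state))
    return out


def dual_mark_fraction(
    enhancers: Sequence[Enhancer],
    h3k27ac_peaks: Sequence[GenomeInterval],
    h3k27me3_peaks: Sequence[GenomeInterval],
) -> float:
    """Fraction of enhancers overlapping both H3K27ac and H3K27me3 peaks."""
    if not enhancers:
        return 0.0
    ac = build_index(h3k27ac_peaks)
    me3 = build_index(h3k27me3_peaks)
    n_dual = sum(
        1 for e in enhancers
        if overlaps_any(e.interval, ac) and overlaps_any(e.interval, me3)
    )
    return n_dual / len(enhancers)


def enhancer_transitions(
    wt: Sequence[Enhancer], mut: Sequence[Enhancer]
) -> list[EnhancerTransition]:
    """Map each wild-type-active enhancer to its mutant state.

    A WT enhancer is matched to the mutant enhancer with the largest base
    overlap (>= 1 bp); with no overlapping mutant enhancer its state is
    "lost". Only WT-active enhancers are considered, since inactivation is
    defined on them.
    """
    for e in list(wt) + list(mut):
        if e.state is None:
            raise ValueError("enhancer_transitions requires classified enhancers")
    index = build_index(e.interval for e in mut)
    by_key = {(e.interval.chrom, e.interval.start, e.interval.end): e for e in mut}
    out = []
    for e in wt:
        if e.state != "active":
            continue
        tree = index.get(e.interval.chrom)
        best, best_olap = None, 0
        if tree is not None:
            for hit in tree.overlap(e.interval.start, e.interval.end):
                olap = min(e.interval.end, hit.end) - max(e.interval.start, hit.begin)
                if olap > best_olap:
                    best_olap = olap
                    best = by_key[(e.interval.chrom, hit.begin, hit.end)]
        state = best.state if best is not None else "lost"
        out.append(EnhancerTransition(
            wt_enhancer=e, mutant_state=state, inactivated=state != "active",
        ))
    return out


def inactivated_fraction(n_inactivated: int, n_wt_active: int) -> float:
    """Percentage of WT-active enhancers inactivated in the mutant.

    The reporting arithmetic behind statements like "32,249 (61.2%) of
    52,672 active enhancers were inactivated".
    """
    if n_wt_active <= 0:
        raise ValueError("need at least one WT-active enhancer")
    if not 0 <= n_inactivated <= n_wt_active:
        raise ValueError("inactivated count out of range")
    return 100.0 * n_inactivated / n_wt_active


def assign_enhancers(
    enhancers: Sequence[Enhancer],
    genes: Sequence[GeneModel],
    max_dist: int = 500_000,
) -> list[Enhancer]:
    """Assign each enhancer to the closest TSS within ``max_dist`` bp.

    Distance is measured from the enhancer midpoint; enhancers farther than
    ``max_dist`` from every TSS stay unassigned.
    """
    out = []
    for e in enhancers:
        hit = nearest_tss(e.interval, genes, max_dist)
        if hit is None:
            out.append(replace(e, assigned_gene=None, tss_distance=None))
        else:
            gene_id, signed = hit
            out.append(replace(e, assigned_gene=gene_id, tss_distance=abs(signed)))
    return out


def enhancer_stats(
    enhancers_by_group: dict[str, Sequence[Enhancer]]
) -> pd.DataFrame:
    """Count, length and distance-to-TSS summaries per enhancer group.

    Groups are caller-defined (per condition, or common/unique classes).
    Distance statistics cover assigned enhancers only.
    """
    rows = []
    for group, enhancers in enhancers_by_group.items():
        if not enhancers:
            raise ValueError(f"group {group!r} is empty")
        lengths = np.array([len(e.interval) for e in enhancers], dtype=float)
        dists = np.array(
            [e.tss_distance for e in enhancers if e.tss_distance is not None],
            dtype=float,
        )
        rows.append({
            "group": group,
            "count": len(enhancers),
            "length_mean": float(lengths.mean()),
            "length_median": float(np.median(lengths)),
            "n_assigned": int(dists.size),
            "tss_dist_mean": float(dists.mean()) if dists.size else np.nan,
            "tss_dist_median": float(np.median(dists)) if dists.size else np.nan,
        })
    return pd.DataFrame(rows)


def write_enhancer_bed(enhancers: Sequence[Enhancer], path: str | Path) -> None:
    """BED6+3 export: state, assigned gene and TSS distance as extra columns."""
    with open(path, "w") as fh:
        for e in enhancers:
            iv = e.interval
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end),
                iv.name or ".", ".", iv.strand,
                e.state or ".",
                e.assigned_gene or ".",
                str(e.tss_distance) if e.tss_distance is not None else ".",
            ]) + "\n")


def write_transitions_tsv(
    transitions: Sequence[EnhancerTransition], path: str | Path
) -> None:
    rows = []
    for t in transitions:
        iv = t.wt_enhancer.interval
        rows.append({
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "assigned_gene": t.wt_enhancer.assigned_gene or ".",
            "mutant_state": t.mutant_state,
            "inactivated": int(t.inactivated),
        })
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "assigned_gene",
                 "mutant_state", "inactivated"],
    ).to_csv(path, sep="\t", index=False)
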