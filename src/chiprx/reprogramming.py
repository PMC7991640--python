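"""Locus-dependence statistics: peak decomposition, genomic-element annotation,
expression stratification, mark-change correlations and enhancer-gene
association tests.

These are the analyses that distinguish a global loss of a histone mark from
a locus-specific redistribution tied to where the mutant histone sits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enhancers import Enhancer, EnhancerTransition
from .genome import GeneModel, GenomeInterval
from .intervals import build_index, overlaps_any

__all__ = [
    "PeakDecomposition",
    "DeltaRecord",
    "decompose_peaks",
    "annotate_elements",
    "stratify_expression",
    "delta_correlation",
    "log2_fold_change",
    "AssociationResult",
    "inactivation_gene_association",
    "class_expression_summary",
]

ELEMENTS = ("promoter", "exon", "intron", "intergenic")


@dataclass
class PeakDecomposition:
    """Common/unique split of two peak sets, Venn style.

    A peak is common if it overlaps (>= 1 bp) any peak of the other set.
    Because overlaps can be many-to-one, the common count differs by
    perspective; both are kept.
    """

    common_a: list[GenomeInterval]
    common_b: list[GenomeInterval]
    unique_a: list[GenomeInterval]
    unique_b: list[GenomeInterval]

    def venn_counts(self) -> dict[str, int]:
        return {
            "a_only": len(self.unique_a),
            "b_only": len(self.unique_b),
            "common_a_perspective": len(self.common_a),
            "common_b_perspective": len(self.common_b),
        }


def decompose_peaks(
    peaks_a: Sequence[GenomeInterval], peaks_b: Sequence[GenomeInterval]
) -> PeakDecomposition:
    """Split two peak sets into common and condition-unique peaks."""
    idx_a = build_index(peaks_a)
    idx_b = build_index(peaks_b)
    common_a = [p for p in peaks_a if overlaps_any(p, idx_b)]
    unique_a = [p for p in peaks_a if not overlaps_any(p, idx_b)]
    common_b = [p for p in peaks_b if overlaps_any(p, idx_a)]
    unique_b = [p for p in peaks_b if not overlaps_any(p, idx_a)]
    return PeakDecomposition(common_a, common_b, unique_a, unique_b)


def annotate_elements(
    peaks: Sequence[GenomeInterval],
    genes: Sequence[GeneModel],
    promoters: Sequence[GenomeInterval],
) -> pd.DataFrame:
    """Assign each peak one genomic element by midpoint position.

    Precedence promoter > exon > intron > intergenic; the returned table has
    one row per element with count and fraction (fractions sum to 1).
    """
    prom_idx = build_index(promoters)
    exon_idx = build_index(e for g in genes for e in g.exons)
    body_idx = build_index(g.body for g in genes)
    counts = dict.fromkeys(ELEMENTS, 0)
    for p in peaks:
        mid = p.midpoint
        point = GenomeInterval(p.chrom, mid, mid + 1)
        if overlaps_any(point, prom_idx):
            counts["promoter"] += 1
        elif overlaps_any(point, exon_idx):
            counts["exon"] += 1
        elif overlaps_any(point, body_idx):
            counts["intron"] += 1
        else:
            counts["intergenic"] += 1
    total = max(1, len(peaks))
    return pd.DataFrame(
        {
            "element": list(ELEMENTS),
            "count": [counts[e] for e in ELEMENTS],
            "fraction": [counts[e] / total for e in ELEMENTS],
        }
    )


def stratify_expression(
    fpkm: Mapping[str, float], n_strata: int = 3
) -> dict[str, str]:
    """Rank-split genes into expression strata of near-equal size.

    Default tertiles labelled low/medium/high; for other ``n_strata`` the
    labels are ``stratum_0`` (lowest) upward. Ties break by gene_id and
    zero-FPKM genes always land in the lowest stratum.
    """
    if len(fpkm) < n_strata:
        raise ValueError(f"need at least {n_strata} genes to form {n_strata} strata")
    if n_strata == 3:
        labels = ["low", "medium", "high"]
    else:
        labels = [f"stratum_{i}" for i in range(n_strata)]
    ranked = sorted(fpkm, key=lambda g: (fpkm[g], g))
    n = len(ranked)
    out: dict[str, str] = {}
    for i, gene in enumerate(ranked):
        stratum = min(i * n_strata // n, n_strata - 1)
        if fpkm[gene] == 0:
            stratum = 0
        out[gene] = labels[stratum]
    return out


@dataclass(frozen=True)
class DeltaRecord:
    """Change of a mark at one locus, paired with mutant-histone occupancy."""

    interval: GenomeInterval
    mark: str
    delta: float       # density(mutant) - density(wild type), RRPM
    occupancy: float   # H3K36M density at the same locus

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta) and np.isfinite(self.occupancy)):
            raise ValueError("delta and occupancy must be finite")


def delta_correlation(
    records: Sequence[DeltaRecord],
    x_field: str = "occupancy",
    y_field: str = "delta",
) -> tuple[float, int]:
    """Pearson product-moment correlation between two DeltaRecord fields."""
    if len(records) < 3:
        raise ValueError("need at least 3 records for a correlation")
    x = np.array([getattr(r, x_field) for r in records], dtype=float)
    y = np.array([getattr(r, y_field) for r in records], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one field; correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r), len(records)


def log2_fold_change(
    fpkm_wt: Mapping[str, float],
    fpkm_mut: Mapping[str, float],
    pseudocount: float = 1.0,
) -> dict[str, float]:
    """log2((FPKM_mut + 1) / (FPKM_wt + 1)) per gene present in both tables."""
    return {
        g: float(np.log2((fpkm_mut[g] + pseudocount) / (fpkm_wt[g] + pseudocount)))
        for g in fpkm_wt
        if g in fpkm_mut
    }


@dataclass
class AssociationResult:
    """Inactivated-enhancer vs differential-expression association tables."""

    de_fractions: pd.DataFrame   # status, n_genes, n_with_inactivated, fraction
    count_bins: pd.DataFrame     # bin, n_genes, median_log2fc, mean_log2fc


COUNT_BIN_EDGES = (0, 1, 2)  # final bin is ">= last edge + 1"


def _bin_label(m: int) -> str:
    last = COUNT_BIN_EDGES[-1]
    return str(m) if m <= last else f">={last + 1}"


def inactivation_gene_association(
    transitions: Sequence[EnhancerTransition],
    de_status: Mapping[str, str],
    log2fc: Mapping[str, float],
) -> AssociationResult:
    """Relate inactivated enhancers (via their assigned genes) to expression.

    Produces (i) per DE class, the fraction of genes with at least one
    assigned inactivated enhancer, and (ii) genes binned by the number of
    assigned inactivated enhancers (0 / 1 / 2 / >=3) with log2 fold-change
    summaries per bin. Transitions must carry gene assignments on their
    wild-type enhancers.
    """
    inact_per_gene: dict[str, int] = {g: 0 for g in de_status}
    for t in transitions:
        gene = t.wt_enhancer.assigned_gene
        if gene is None or gene not in inact_per_gene:
            continue
        if t.inactivated:
            inact_per_gene[gene] += 1

    frac_rows = []
    for status in ("up", "down", "unchanged"):
        genes = [g for g, s in de_status.items() if s == status]
        n_with = sum(1 for g in genes if inact_per_gene[g] >= 1)
        frac_rows.append({
            "status": status,
            "n_genes": len(genes),
            "n_with_inactivated": n_with,
            "fraction": n_with / len(genes) if genes else 0.0,
        })

    bin_rows = []
    labels = [_bin_label(m) for m in COUNT_BIN_EDGES] + [_bin_label(COUNT_BIN_EDGES[-1] + 1)]
    for label in labels:
        genes = [g for g in de_status if _bin_label(min(inact_per_gene[g],
                 COUNT_BIN_EDGES[-1] + 1)) == label and g in log2fc]
        lfc = np.array([log2fc[g] for g in genes], dtype=float)
        bin_rows.append({
            "bin": label,
            "n_genes": len(genes),
            "median_log2fc": float(np.median(lfc)) if lfc.size else np.nan,
            "mean_log2fc": float(lfc.mean()) if lfc.size else np.nan,
        })

    return AssociationResult(
        de_fractions=pd.DataFrame(frac_rows),
        count_bins=pd.DataFrame(bin_rows),
    )


def class_expression_summary(
    enhancers: Sequence[Enhancer],
    fpkm: Mapping[str, float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression of genes assigned to each enhancer state.

    Returns a per-state summary (n, mean, median FPKM of assigned genes) and
    a pairwise Mann-Whitney contrast table with BH-corrected p-values.
    Contrasts where either state has no assigned genes are skipped.
    """
    by_state: dict[str, list[float]] = {}
    for e in enhancers:
        if e.state is None or e.assigned_gene is None:
            continue
        if e.assigned_gene in fpkm:
            by_state.setdefault(e.state, []).append(fpkm[e.assigned_gene])
    summary = pd.DataFrame(
        [
            {
                "state": s,
                "n": len(v),
                "mean_fpkm": float(np.mean(v)),
                "median_fpkm": float(np.median(v)),
            }
            for s, v in sorted(by_state.items())
        ]
    )
    rows = []
    states = sorted(by_state)
    for i, a in enumerate(states):
        for b in states[i + 1:]:
            if len(by_state[a]) < 2 or len(by_state[b]) < 2:
                continue
            stat, p = stats.mannwhitneyu(by_state[a], by_state[b],
                                         alternative="two-sided")
            rows.append({"state_a": a, "state_b": b,
                         "statistic": float(stat), "p_value": float(p)})
    contrasts = pd.DataFrame(rows, columns=["state_a", "state_b",
                                            "statistic", "p_value"])
    if len(contrasts):
        contrasts["p_adj"] = multipletests(contrasts["p_value"], method="fdr_bh")[1]
    else:
        contrasts["p_adj"] = []
    return summary, contrasts
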