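"""End-to-end orchestration: normalize -> decompose -> enhancers ->
transitions -> assignment -> statistics, with provenance capture.

The pipeline consumes a study directory in the layout the synthetic
generator emits (and that real-data adapters can produce): a genome table,
gene annotation, per-mark/condition peak BEDs and bedGraph tracks, a
norm-factor table, FPKM tables and a DE-status table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .coverage import CoverageTrack
from .enhancers import (
    assign_enhancers,
    call_enhancers,
    classify_enhancers,
    define_promoters,
    dual_mark_fraction,
    enhancer_stats,
    enhancer_transitions,
    inactivated_fraction,
    write_enhancer_bed,
    write_transitions_tsv,
)
from .genome import GenomeInterval
from .intervals import build_index, overlaps_any, shuffle_intervals
from .normalization import normalize_track, read_norm_factors, rpm_normalize_track
from .profiles import group_mean_density, interval_densities, metagene_profile
from .reprogramming import (
    DeltaRecord,
    annotate_elements,
    class_expression_summary,
    decompose_peaks,
    delta_correlation,
    inactivation_gene_association,
    log2_fold_change,
    stratify_expression,
)

logger = logging.getLogger("chiprx")

CLASSIFICATION_CONVENTION = (
    "active=H3K4me1+/H3K27ac+; poised=H3K4me1+/H3K27me3+ (H3K27ac-); "
    "primed=H3K4me1 only; precedence active>poised"
)


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    input_dir: str
    output_dir: str
    mutant: str = "H3.3K36M"
    bin_size: int = 50
    seed: int = 0
    max_assign_dist: int = 500_000
    flank: int = 5000
    body_bins: int = 100
    flank_bin_size: int = 100
    normalization: str = "rrpm"  # rrpm (spike-in) or rpm (per-million target)
    de_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.normalization not in ("rrpm", "rpm"):
            raise ValueError("normalization must be 'rrpm' or 'rpm'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def params_dict(self) -> dict:
        """Analysis parameters only — paths excluded so the provenance
        digest identifies the analysis, not where it ran."""
        d = self.to_dict()
        d.pop("input_dir")
        d.pop("output_dir")
        return d

    def digest(self) -> str:
        blob = json.dumps(self.params_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tsv(df: pd.DataFrame, path: Path, digest: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chiprx config={digest}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.8g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write tables plus a summary JSON.

    Returns the output directory. Any stage failure raises with the stage
    name so partial runs are recognizable; outputs written before a failure
    are flagged by the absence of ``summary.json``.
    """
    t_start = time.perf_counter()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    conditions = ("WT", config.mutant)
    stage = "load"
    try:
        genome = cio.read_genome_table(indir / "genome.tsv")
        genes = cio.read_gene_annotation(indir / "genes.tsv")
        fpkm_wt = cio.read_fpkm_table(indir / "fpkm_WT.tsv")
        fpkm_mut = cio.read_fpkm_table(indir / f"fpkm_{config.mutant}.tsv")
        de_status = cio.read_de_status(indir / "de_status.tsv")
        norm = read_norm_factors(indir / "norm_factors.tsv")
        for g in genes:
            g.fpkm = fpkm_wt.get(g.gene_id)
        peaks: dict[tuple[str, str], list[GenomeInterval]] = {}
        for p in sorted((indir / "peaks").glob("*.bed")):
            mark, condition = p.stem.rsplit("_", 1)
            peaks[(mark, condition)] = cio.read_bed(p, genome)

        def load_track(mark: str, condition: str) -> CoverageTrack:
            sid = f"{mark}_{condition}"
            raw = cio.read_bedgraph(indir / "tracks" / f"{sid}.bedgraph",
                                    genome, config.bin_size)
            if config.normalization == "rrpm":
                return normalize_track(raw, norm[sid])
            return rpm_normalize_track(raw)

        stage = "normalize"
        tracks = {
            (mark, condition): load_track(mark, condition)
            for mark in ("H3K27ac", "H3K36me2", "H3K36M")
            for condition in conditions
        }
        logger.info("loaded %d peak sets and %d tracks (%s units)",
                    len(peaks), len(tracks), config.normalization.upper())

        stage = "enhancers"
        promoters = define_promoters(genes, genome)
        enh = {}
        for condition in conditions:
            called = call_enhancers(
                peaks[("H3K4me1", condition)], peaks[("H3K4me3", condition)],
                promoters, condition=condition)
            enh[condition] = classify_enhancers(
                called, peaks[("H3K27ac", condition)],
                peaks[("H3K27me3", condition)])
        ambiguous = {
            condition: dual_mark_fraction(
                enh[condition], peaks[("H3K27ac", condition)],
                peaks[("H3K27me3", condition)])
            for condition in conditions
        }
        state_counts = {
            condition: {
                s: sum(1 for e in enh[condition] if e.state == s)
                for s in ("active", "primed", "poised")
            }
            for condition in conditions
        }

        stage = "assignment"
        enh = {c: assign_enhancers(v, genes, config.max_assign_dist)
               for c, v in enh.items()}

        stage = "transitions"
        transitions = enhancer_transitions(enh["WT"], enh[config.mutant])
        n_inact = sum(t.inactivated for t in transitions)
        inact_pct = inactivated_fraction(n_inact, len(transitions))
        write_transitions_tsv(transitions, outdir / "transitions.tsv")
        for condition in conditions:
            write_enhancer_bed(enh[condition],
                               outdir / f"enhancers_{condition}.bed")

        stage = "decomposition"
        enh_decomp = decompose_peaks(
            [e.interval for e in enh["WT"]],
            [e.interval for e in enh[config.mutant]])
        venn: dict[str, dict] = {"enhancers": enh_decomp.venn_counts()}
        me2_decomp = decompose_peaks(peaks[("H3K36me2", "WT")],
                                     peaks[("H3K36me2", config.mutant)])
        venn["H3K36me2"] = me2_decomp.venn_counts()

        stage = "enhancer_stats"
        mut_index = build_index(e.interval for e in enh[config.mutant])
        common_enh = [e for e in enh["WT"] if overlaps_any(e.interval, mut_index)]
        wt_index = build_index(e.interval for e in enh["WT"])
        unique_enh = [e for e in enh[config.mutant]
                      if not overlaps_any(e.interval, wt_index)]
        stats_groups = {
            "WT": enh["WT"],
            config.mutant: enh[config.mutant],
            "common": common_enh,
            f"{config.mutant}_unique": unique_enh,
        }
        stats_df = enhancer_stats(stats_groups)
        _tsv(stats_df, outdir / "enhancer_stats.tsv", digest)

        stage = "densities"
        rng = np.random.default_rng(config.seed)
        shuffled_unique = shuffle_intervals(
            [e.interval for e in unique_enh], genome, rng)
        k27_mut = tracks[("H3K27ac", config.mutant)]
        k27ac_groups = {
            "common": interval_densities(k27_mut,
                                         [e.interval for e in common_enh]),
            "unique": interval_densities(k27_mut,
                                         [e.interval for e in unique_enh]),
            "shuffled": interval_densities(k27_mut, shuffled_unique),
        }
        k27ac_result = group_mean_density(k27ac_groups)
        _tsv(k27ac_result.summary, outdir / "h3k27ac_enhancer_density.tsv", digest)
        _tsv(k27ac_result.contrasts,
             outdir / "h3k27ac_enhancer_density_tests.tsv", digest)

        me2_mut = tracks[("H3K36me2", config.mutant)]
        shuffled_me2 = shuffle_intervals(me2_decomp.unique_b, genome, rng)
        me2_groups = {
            "common": interval_densities(me2_mut, me2_decomp.common_b),
            "unique": interval_densities(me2_mut, me2_decomp.unique_b),
            "shuffled": interval_densities(me2_mut, shuffled_me2),
        }
        me2_result = group_mean_density(me2_groups)
        _tsv(me2_result.summary, outdir / "h3k36me2_peak_density.tsv", digest)
        _tsv(me2_result.contrasts, outdir / "h3k36me2_peak_density_tests.tsv",
             digest)

        stage = "elements"
        element_rows = []
        for mark in ("H3K36M", "H3K36me2", "H3K36me3"):
            pk = peaks.get((mark, config.mutant), [])
            if not pk:
                continue
            tbl = annotate_elements(pk, genes, promoters)
            tbl.insert(0, "mark", mark)
            element_rows.append(tbl)
        elements = (pd.concat(element_rows, ignore_index=True)
                    if element_rows else pd.DataFrame())
        _tsv(elements, outdir / "peak_elements.tsv", digest)

        stage = "correlations"
        me2_wt_index = build_index(peaks[("H3K36me2", "WT")])
        qualifying = [e for e in enh["WT"]
                      if e.state == "active"
                      and overlaps_any(e.interval, me2_wt_index)]
        occ_track = tracks[("H3K36M", config.mutant)]
        records = {"H3K27ac": [], "H3K36me2": []}
        for mark in records:
            d_wt = interval_densities(tracks[(mark, "WT")],
                                      [e.interval for e in qualifying])
            d_mut = interval_densities(tracks[(mark, config.mutant)],
                                       [e.interval for e in qualifying])
            occ = interval_densities(occ_track,
                                     [e.interval for e in qualifying])
            records[mark] = [
                DeltaRecord(interval=e.interval, mark=mark,
                            delta=float(dm - dw), occupancy=float(o))
                for e, dw, dm, o in zip(qualifying, d_wt, d_mut, occ)
            ]
        correlations = []
        for mark, recs in records.items():
            r, n = delta_correlation(recs, "occupancy", "delta")
            correlations.append({"x": "H3K36M_occupancy", "y": f"delta_{mark}",
                                 "r": r, "n": n})
        if records["H3K27ac"]:
            d27 = np.array([r.delta for r in records["H3K27ac"]])
            d36 = np.array([r.delta for r in records["H3K36me2"]])
            paired = [DeltaRecord(interval=r.interval, mark="paired",
                                  delta=float(a), occupancy=float(b))
                      for r, a, b in zip(records["H3K27ac"], d27, d36)]
            r, n = delta_correlation(paired, "occupancy", "delta")
            correlations.append({"x": "delta_H3K36me2", "y": "delta_H3K27ac",
                                 "r": r, "n": n})
        delta_rows = pd.DataFrame([
            {"chrom": r.interval.chrom, "start": r.interval.start,
             "end": r.interval.end, "mark": r.mark, "delta": r.delta,
             "occupancy": r.occupancy}
            for recs in records.values() for r in recs
        ])
        _tsv(delta_rows, outdir / "delta_records.tsv", digest)

        stage = "expression"
        expressed = {g: v for g, v in fpkm_wt.items() if v > 0}
        strata = stratify_expression(expressed)
        strata_rows = []
        genes_by_id = {g.gene_id: g for g in genes}
        for label in ("low", "medium", "high"):
            ids = [g for g, s in strata.items() if s == label]
            body_occ = interval_densities(
                occ_track, [genes_by_id[g].body for g in ids if g in genes_by_id])
            strata_rows.append({
                "stratum": label, "n_genes": len(ids),
                "mean_body_occupancy": float(body_occ.mean()),
            })
        strata_df = pd.DataFrame(strata_rows)
        _tsv(strata_df, outdir / "expression_strata_occupancy.tsv", digest)

        lfc = log2_fold_change(fpkm_wt, fpkm_mut,
                               pseudocount=config.de_pseudocount)
        assoc = inactivation_gene_association(transitions, de_status, lfc)
        _tsv(assoc.de_fractions, outdir / "de_inactivated_fractions.tsv", digest)
        _tsv(assoc.count_bins, outdir / "inactivated_count_bins.tsv", digest)

        class_summary, class_tests = class_expression_summary(enh["WT"], fpkm_wt)
        _tsv(class_summary, outdir / "class_expression.tsv", digest)
        _tsv(class_tests, outdir / "class_expression_tests.tsv", digest)

        stage = "summary"
        summary = {
            "config": config.params_dict(),
            "config_digest": digest,
            "classification_convention": CLASSIFICATION_CONVENTION,
            "normalization_mode": config.normalization,
            "enhancer_counts": {c: len(enh[c]) for c in conditions},
            "state_counts": state_counts,
            "state_fractions": {
                c: {s: n / max(1, len(enh[c]))
                    for s, n in state_counts[c].items()}
                for c in conditions
            },
            "ambiguous_dual_mark_fraction": ambiguous,
            "wt_active": len(transitions),
            "inactivated": int(n_inact),
            "inactivated_pct": inact_pct,
            "venn": venn,
            "correlations": correlations,
            "k27ac_density_means": dict(zip(
                k27ac_result.summary["group"],
                k27ac_result.summary["mean"].astype(float))),
            "k36me2_density_means": dict(zip(
                me2_result.summary["group"],
                me2_result.summary["mean"].astype(float))),
            "de_fractions": assoc.de_fractions.to_dict(orient="records"),
            "inactivated_count_bins": assoc.count_bins.replace(
                {np.nan: None}).to_dict(orient="records"),
            "strata_occupancy": strata_rows,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t_start)
    return outdir
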