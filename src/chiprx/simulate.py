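"""Synthetic ChIP-Rx data generator with known ground truth.

Emulates the study design the pipeline analyzes: a wild-type line and a
mutant-histone (H3.3K36M- or H3.1K36M-like) line profiled for six histone
marks plus the mutant histone itself, with drosophila-style spike-in counts.
Injected effects:

* a global, spike-in-only-recoverable depletion of H3K36me2/me3 (and a
  milder one of H3K27ac) in the mutant;
* locus-specific extra depletion proportional to local mutant-histone
  occupancy (coupling constant ``locus_effect``), the cis effect the
  correlation analyses are designed to detect;
* variant-specific occupancy compartments: the H3.3-like mutant sits in
  introns of expressed genes and at intergenic enhancers, the H3.1-like
  mutant in exons of repressed genes;
* enhancer-state reprogramming: a configurable fraction of wild-type-active
  enhancers becomes primed/poised or disappears in the mutant, with the
  inactivation probability increasing with local occupancy;
* expression coupling: genes anchored to more inactivated enhancers are
  downregulated proportionally.

Everything is deterministic for a fixed seed, and every emitted file parses
through the package's own readers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .coverage import CoverageTrack
from .enhancers import define_promoters
from .genome import GeneModel, GenomeInterval, GenomeTable
from .intervals import build_index, merge, overlaps_any
from .normalization import NormFactor, compute_norm_factor, write_norm_factors
from . import io as cio

__all__ = [
    "MARKS",
    "SimConfig",
    "SimEnhancer",
    "SimTruth",
    "SimData",
    "simulate_genome",
    "simulate_marks",
    "simulate_expression_effects",
    "simulate_all",
    "write_simdata",
]

MARKS = (
    "H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3",
    "H3K36me2", "H3K36me3", "H3K36M",
)

# marks whose mutant signal carries the cis (occupancy-coupled) depletion
COUPLED_MARKS = ("H3K36me2", "H3K36me3", "H3K27ac")

DEFAULT_DEPLETION = {
    "H3K4me1": 1.0, "H3K4me3": 1.0, "H3K27ac": 0.7, "H3K27me3": 1.0,
    "H3K36me2": 0.5, "H3K36me3": 0.5,
}

# per-mutant defaults: inactivation rate of WT-active enhancers and
# common/unique enhancer-to-TSS distance means (bp). Distances keep the
# observed common < unique ordering and ~1.7x ratio of the H3.3-like mutant,
# scaled to the toy genome's intergenic spacing.
MUTANT_PRESETS = {
    "H3.3K36M": {"inactivation_rate": 0.612,
                 "common_tss_distance_mean": 8000,
                 "unique_tss_distance_mean": 13600},
    "H3.1K36M": {"inactivation_rate": 0.555,
                 "common_tss_distance_mean": 7200,
                 "unique_tss_distance_mean": 7200},
}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults give a two-condition toy study.

    The scale (2 x 5 Mb, 300 genes, ~1,500 wild-type enhancers at 50 bp
    bins) keeps a full run in seconds; enhancer-to-TSS distances are scaled
    down with the genome so nearest-TSS geometry stays realistic.
    """

    seed: int = 0
    # genome / annotation
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    bin_size: int = 50
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (2000, 5000)
    min_gene_gap: int = 28_000
    edge_margin: int = 10_000
    fraction_expressed: float = 0.7
    # enhancers
    enhancers_per_gene: float = 5.0
    mutant_unique_factor: float = 1.0
    anchor_gene_fraction: float = 0.65
    enhancer_length_range: tuple[int, int] = (800, 1600)
    unique_enhancer_length_range: tuple[int, int] = (400, 800)
    common_tss_distance_mean: Optional[float] = None
    unique_tss_distance_mean: Optional[float] = None
    distance_min: int = 3200
    # exponential packs gracefully on a dense toy genome; uniform keeps the
    # configured mean unbiased when there is room (sparse genomes)
    distance_law: str = "exponential"
    # condition design
    mutant: str = "H3.3K36M"
    wt_state_probs: tuple[float, float, float] = (0.684, 0.200, 0.116)
    mutant_unique_state_probs: tuple[float, float, float] = (0.15, 0.60, 0.25)
    inactivation_rate: Optional[float] = None
    inactivation_occ_coupling: float = 0.4
    lost_fraction: float = 0.15
    # sequencing model
    spike_fraction: float = 0.1
    depth: dict[str, float] = field(default_factory=dict)
    global_depletion: Optional[dict[str, float]] = None
    locus_effect: float = 0.5
    background: float = 0.5
    # signal amplitudes (expected reads per bin over a compartment)
    amp_enhancer_k4me1: float = 8.0
    amp_promoter_k4me1: float = 4.0
    amp_promoter_k4me3: float = 12.0
    amp_enhancer_k27ac: float = 10.0
    amp_promoter_k27ac: float = 6.0
    amp_enhancer_k27me3: float = 6.0
    amp_body_k27me3: float = 5.0
    amp_body_k36me2: float = 9.0
    amp_enhancer_k36me2: float = 12.0
    amp_body_k36me3: float = 12.0
    amp_occupancy: float = 6.0
    # K36me2 intergenic domains & redistribution
    # enhancer-attached K36me2 domains span the enhancer plus domain_pad bp
    # on each side; 0 keeps neighbouring loci' signals independent
    k36me2_domain_cover: float = 0.85
    domain_pad: int = 0
    redistribution_fraction: float = 0.3
    redistribution_amp: float = 6.0
    occ_peak_threshold: float = 0.25
    # peak emission
    peaks_mode: str = "noiseless"
    jitter_bp: int = 100
    # expression coupling
    effect_size: float = 0.8
    lfc_noise_sd: float = 0.3
    up_fraction: float = 0.12
    up_boost_mean: float = 1.8
    up_boost_sd: float = 0.3
    de_lfc_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.mutant not in MUTANT_PRESETS:
            raise ValueError(f"unknown mutant {self.mutant!r}")
        preset = MUTANT_PRESETS[self.mutant]
        if self.inactivation_rate is None:
            self.inactivation_rate = preset["inactivation_rate"]
        if self.common_tss_distance_mean is None:
            self.common_tss_distance_mean = preset["common_tss_distance_mean"]
        if self.unique_tss_distance_mean is None:
            self.unique_tss_distance_mean = preset["unique_tss_distance_mean"]
        if self.global_depletion is None:
            self.global_depletion = dict(DEFAULT_DEPLETION)
        else:
            merged = dict(DEFAULT_DEPLETION)
            merged.update(self.global_depletion)
            self.global_depletion = merged
        for mark, g in self.global_depletion.items():
            if not 0 < g <= 1:
                raise ValueError(f"global_depletion[{mark!r}] must be in (0, 1]")
        if not 0 < self.spike_fraction < 0.5:
            raise ValueError("spike_fraction must be in (0, 0.5)")
        if self.peaks_mode not in ("noiseless", "jitter"):
            raise ValueError("peaks_mode must be 'noiseless' or 'jitter'")
        if self.distance_law not in ("exponential", "uniform"):
            raise ValueError("distance_law must be 'exponential' or 'uniform'")

    def sample_id(self, mark: str, condition: str) -> str:
        return f"{mark}_{condition}"

    def sample_depth(self, sample_id: str) -> float:
        return float(self.depth.get(sample_id, 1.0))


@dataclass
class SimEnhancer:
    """Ground-truth record for one simulated enhancer locus."""

    chrom: str
    start: int
    end: int
    cls: str                      # common / wt_only / mut_only
    wt_state: Optional[str]       # None when absent in WT
    mut_state: Optional[str]      # None when absent in mutant; "lost" if gone
    inactivated: Optional[bool]   # defined for WT-active enhancers only
    anchor_gene: str
    tss_distance: int
    occupancy: float              # normalized mutant-histone occupancy in [0, 1]
    in_k36me2_domain: bool

    @property
    def interval(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end)


@dataclass
class SimTruth:
    """Everything needed to score recovery without re-running the generator."""

    enhancers: list[SimEnhancer]
    k36me2_domains: list[GenomeInterval]
    occ_track: CoverageTrack                  # normalized occupancy, [0, 1]
    global_depletion: dict[str, float]
    locus_effect: float
    spike_reads: dict[str, int]
    inactivation_rate: float
    gene_true_lfc: dict[str, float] = field(default_factory=dict)

    def wt_active_in_domain(self) -> list[SimEnhancer]:
        return [e for e in self.enhancers
                if e.wt_state == "active" and e.in_k36me2_domain]


@dataclass
class SimData:
    """Bundle of one full simulated study."""

    config: SimConfig
    genome: GenomeTable
    genes: list[GeneModel]
    tracks: dict[str, CoverageTrack]           # sample_id -> raw track
    peaks: dict[tuple[str, str], list[GenomeInterval]]  # (mark, condition)
    norm_factors: dict[str, NormFactor]
    truth: SimTruth
    fpkm_wt: dict[str, float] = field(default_factory=dict)
    fpkm_mut: dict[str, float] = field(default_factory=dict)
    de_status: dict[str, str] = field(default_factory=dict)

    @property
    def conditions(self) -> tuple[str, str]:
        return ("WT", self.config.mutant)


# ---------------------------------------------------------------------------
# genome & annotation


def simulate_genome(cfg: SimConfig) -> tuple[GenomeTable, list[GeneModel]]:
    """Toy genome with non-overlapping multi-exon genes and log-normal FPKM."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[0])
    genome = GenomeTable(
        {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    )
    genes: list[GeneModel] = []
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    counter = 0
    for ci, chrom in enumerate(genome):
        n = per_chrom[ci]
        if n == 0:
            continue
        lengths = rng.integers(cfg.gene_length_range[0],
                               cfg.gene_length_range[1] + 1, size=n)
        used = int(lengths.sum()) + n * cfg.min_gene_gap + 2 * cfg.edge_margin
        free = cfg.chrom_length - used
        if free < 0:
            raise ValueError(
                "genes cannot be placed without overlap at this density; "
                "increase chrom_length or reduce n_genes"
            )
        cuts = np.sort(rng.uniform(0, free, size=n))
        cursor = cfg.edge_margin
        offsets = np.concatenate([[cuts[0]], np.diff(cuts)])
        for j in range(n):
            start = int(cursor + offsets[j])
            end = start + int(lengths[j])
            cursor = end + cfg.min_gene_gap
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _draw_exons(rng, chrom, start, end)
            if rng.random() < cfg.fraction_expressed:
                fpkm = float(rng.lognormal(mean=math.log(10.0), sigma=1.0))
            else:
                fpkm = 0.0
            counter += 1
            gid = f"g{counter:04d}"
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                                   tss=tss, tes=tes, exons=exons, fpkm=fpkm))
    return genome, genes


def _draw_exons(rng, chrom: str, start: int, end: int) -> list[GenomeInterval]:
    n_ex = int(rng.integers(2, 9))
    n_cuts = 2 * n_ex - 2
    cuts = np.sort(rng.choice(np.arange(start + 1, end), size=n_cuts,
                              replace=False))
    bounds = np.concatenate([[start], cuts, [end]])
    return [GenomeInterval(chrom, int(bounds[i]), int(bounds[i + 1]))
            for i in range(0, len(bounds) - 1, 2)]


def _introns(g: GeneModel) -> list[GenomeInterval]:
    out = []
    for a, b in zip(g.exons[:-1], g.exons[1:]):
        if b.start > a.end:
            out.append(GenomeInterval(g.chrom, a.end, b.start))
    return out


# ---------------------------------------------------------------------------
# marks, tracks, peaks, spike-in


def _paint(values: dict[str, np.ndarray], iv: GenomeInterval, amount: float,
           bin_size: int, mode: str = "add") -> None:
    b0 = iv.start // bin_size
    b1 = math.ceil(iv.end / bin_size)
    if mode == "add":
        values[iv.chrom][b0:b1] += amount
    else:
        np.maximum(values[iv.chrom][b0:b1], amount,
                   out=values[iv.chrom][b0:b1])


def _expression_scale(genes: Sequence[GeneModel]) -> dict[str, float]:
    """log1p-FPKM rescaled to (0, 1] over expressed genes; 0 when silent."""
    fmax = max((math.log1p(g.fpkm) for g in genes if g.fpkm), default=1.0)
    return {g.gene_id: (math.log1p(g.fpkm) / fmax if g.fpkm else 0.0)
            for g in genes}


def _place_enhancers(cfg, rng, genome, genes, promoters):
    """Place WT (common + lost) and mutant-unique enhancer loci intergenic,
    anchored upstream of a uniformly chosen subset of genes.

    Distances to the anchor TSS are distance_min plus an exponential with
    the configured mean, so the mean is exact where placement is sparse and
    degrades gracefully (outward) where the near shell around a TSS fills."""
    excl = build_index(list(promoters) + [g.body for g in genes])
    from intervaltree import IntervalTree
    placed: dict[str, IntervalTree] = {c: IntervalTree() for c in genome}
    n_eligible = max(1, round(cfg.anchor_gene_fraction * len(genes)))
    eligible = rng.choice(len(genes), size=n_eligible, replace=False)

    def _one(mean_dist: float, length_range: tuple[int, int]):
        if mean_dist <= cfg.distance_min:
            raise ValueError("tss distance mean must exceed distance_min")
        for attempt in range(2000):
            g = genes[int(rng.choice(eligible))]
            if cfg.distance_law == "exponential":
                d = cfg.distance_min + rng.exponential(
                    mean_dist - cfg.distance_min)
            else:
                d = rng.uniform(cfg.distance_min,
                                2 * mean_dist - cfg.distance_min)
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            center = int(g.tss - d) if g.strand == "+" else int(g.tss + d)
            start = center - length // 2
            end = start + length
            if start < 0 or end > genome[g.chrom]:
                continue
            cand = GenomeInterval(g.chrom, start, end)
            if overlaps_any(cand, excl):
                continue
            if placed[g.chrom].overlap(start - 100, end + 100):
                continue
            placed[g.chrom].addi(start, end)
            dist = abs(g.tss - cand.midpoint)
            return cand, g.gene_id, dist
        raise RuntimeError(
            "could not place an enhancer after bounded retries; "
            "increase genome size or reduce enhancer count"
        )

    n_wt = round(cfg.n_genes * cfg.enhancers_per_gene)
    n_mut_only = round(cfg.mutant_unique_factor * n_wt)
    records: list[SimEnhancer] = []
    for _ in range(n_wt):
        iv, gid, dist = _one(cfg.common_tss_distance_mean,
                             cfg.enhancer_length_range)
        records.append(SimEnhancer(
            chrom=iv.chrom, start=iv.start, end=iv.end, cls="common",
            wt_state=None, mut_state=None, inactivated=None,
            anchor_gene=gid, tss_distance=dist,
            occupancy=float(rng.uniform(0.0, 1.0)),
            in_k36me2_domain=bool(rng.random() < cfg.k36me2_domain_cover),
        ))
    for _ in range(n_mut_only):
        iv, gid, dist = _one(cfg.unique_tss_distance_mean,
                             cfg.unique_enhancer_length_range)
        # mutant-only loci lie outside the wild-type H3K36me2 domain set
        records.append(SimEnhancer(
            chrom=iv.chrom, start=iv.start, end=iv.end, cls="mut_only",
            wt_state=None, mut_state=None, inactivated=None,
            anchor_gene=gid, tss_distance=dist,
            occupancy=float(rng.uniform(0.0, 1.0)),
            in_k36me2_domain=False,
        ))
    return records


def _draw_states(cfg: SimConfig, rng, records: list[SimEnhancer]) -> None:
    states = np.array(["active", "primed", "poised"])
    for e in records:
        if e.cls == "mut_only":
            e.mut_state = str(rng.choice(states,
                                         p=cfg.mutant_unique_state_probs))
            continue
        e.wt_state = str(rng.choice(states, p=cfg.wt_state_probs))
        if e.wt_state == "active":
            p_inact = float(np.clip(
                cfg.inactivation_rate
                + cfg.inactivation_occ_coupling * (e.occupancy - 0.5),
                0.02, 0.98,
            ))
            e.inactivated = bool(rng.random() < p_inact)
            if not e.inactivated:
                e.mut_state = "active"
            elif rng.random() < cfg.lost_fraction:
                e.cls = "wt_only"
                e.mut_state = "lost"
            else:
                e.mut_state = "primed" if rng.random() < 0.7 else "poised"
        else:
            # non-active enhancers mostly keep their state, never activate
            other = "poised" if e.wt_state == "primed" else "primed"
            e.mut_state = e.wt_state if rng.random() < 0.9 else other


def simulate_marks(
    cfg: SimConfig,
    genome: GenomeTable,
    genes: Sequence[GeneModel],
) -> tuple[dict[str, CoverageTrack], dict[tuple[str, str], list[GenomeInterval]],
           dict[str, NormFactor], SimTruth]:
    """Simulate coverage tracks, peak sets, spike-in counts and ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[1])
    if cfg.locus_effect < 0 or cfg.locus_effect > 1:
        raise ValueError("locus_effect times occupancy may not exceed 1 "
                         "(negative signal requested)")
    bs = cfg.bin_size
    promoters = define_promoters(genes, genome)
    prom_by_gene = {p.name: p for p in promoters}
    escale = _expression_scale(genes)
    expressed = [g for g in genes if g.fpkm]
    repressed = [g for g in genes if not g.fpkm]

    records = _place_enhancers(cfg, rng, genome, genes, promoters)
    _draw_states(cfg, rng, records)

    def zeros():
        return {c: np.zeros(math.ceil(L / bs)) for c, L in genome.items()}

    # --- normalized mutant-histone occupancy in [0, 1]
    occ = zeros()
    if cfg.mutant == "H3.3K36M":
        for g in expressed:
            for intr in _introns(g):
                _paint(occ, intr, 0.8 * escale[g.gene_id], bs, "max")
            for ex in g.exons:
                _paint(occ, ex, 0.2 * escale[g.gene_id], bs, "max")
    else:
        for g in repressed:
            for ex in g.exons:
                _paint(occ, ex, 0.7, bs, "max")
            for intr in _introns(g):
                _paint(occ, intr, 0.2, bs, "max")
    for e in records:
        pad = GenomeInterval(e.chrom, max(0, e.start - cfg.domain_pad),
                             min(genome[e.chrom], e.end + cfg.domain_pad))
        _paint(occ, pad, e.occupancy, bs, "max")
    max_occ = max(float(v.max()) for v in occ.values())
    if cfg.locus_effect * max_occ > 1:
        raise ValueError("locus_effect * occupancy exceeds 1 somewhere")

    # --- compartment interval sets
    wt_enh = [e for e in records if e.cls in ("common", "wt_only")]
    mut_enh = [e for e in records if e.cls in ("common", "mut_only")]
    wt_active = [e.interval for e in wt_enh if e.wt_state == "active"]
    wt_poised = [e.interval for e in wt_enh if e.wt_state == "poised"]
    mut_active = [e.interval for e in mut_enh if e.mut_state == "active"]
    mut_poised = [e.interval for e in mut_enh if e.mut_state == "poised"]
    expr_promoters = [prom_by_gene[g.gene_id] for g in expressed]
    repr_bodies = [g.body for g in repressed]
    # one domain per expressed gene body / covered enhancer; kept unmerged in
    # the truth ledger (density ratios are computed over them), merged for
    # peak emission below
    domain_list = (
        [g.body for g in expressed]
        + [GenomeInterval(e.chrom, max(0, e.start - cfg.domain_pad),
                          min(genome[e.chrom], e.end + cfg.domain_pad))
           for e in records if e.in_k36me2_domain]
    )
    domains = merge(domain_list)
    redist_pool = repressed
    n_red = round(cfg.redistribution_fraction * len(redist_pool))
    red_idx = rng.choice(len(redist_pool), size=n_red, replace=False) if n_red else []
    if cfg.mutant == "H3.3K36M":
        redistributed = [ex for i in red_idx for ex in redist_pool[i].exons]
    else:
        redistributed = [iv for i in red_idx for iv in _introns(redist_pool[i])]

    # --- expected reads per bin (lambda) per mark and condition
    def base_lambda(mark: str, condition: str) -> dict[str, np.ndarray]:
        lam = {c: np.full_like(v, cfg.background) for c, v in occ.items()}
        is_mut = condition != "WT"
        active = mut_active if is_mut else wt_active
        poised = mut_poised if is_mut else wt_poised
        enh_all = mut_enh if is_mut else wt_enh
        if mark == "H3K4me1":
            for e in enh_all:
                _paint(lam, e.interval, cfg.amp_enhancer_k4me1, bs)
            for p in expr_promoters:
                _paint(lam, p, cfg.amp_promoter_k4me1, bs)
        elif mark == "H3K4me3":
            for p in expr_promoters:
                _paint(lam, p, cfg.amp_promoter_k4me3, bs)
        elif mark == "H3K27ac":
            for iv in active:
                _paint(lam, iv, cfg.amp_enhancer_k27ac, bs)
            for p in expr_promoters:
                _paint(lam, p, cfg.amp_promoter_k27ac, bs)
        elif mark == "H3K27me3":
            for iv in poised:
                _paint(lam, iv, cfg.amp_enhancer_k27me3, bs)
            for b in repr_bodies:
                _paint(lam, b, cfg.amp_body_k27me3, bs)
        elif mark == "H3K36me2":
            for g in expressed:
                _paint(lam, g.body, cfg.amp_body_k36me2, bs)
            for e in records:
                if e.in_k36me2_domain:
                    pad = GenomeInterval(
                        e.chrom, max(0, e.start - cfg.domain_pad),
                        min(genome[e.chrom], e.end + cfg.domain_pad))
                    _paint(lam, pad, cfg.amp_enhancer_k36me2, bs)
        elif mark == "H3K36me3":
            for g in expressed:
                _paint(lam, g.body, cfg.amp_body_k36me3 * escale[g.gene_id], bs)
        elif mark == "H3K36M":
            if is_mut:
                for c in lam:
                    lam[c] = lam[c] + cfg.amp_occupancy * occ[c]
        return lam

    tracks: dict[str, CoverageTrack] = {}
    norm_factors: dict[str, NormFactor] = {}
    spike_reads: dict[str, int] = {}
    peaks: dict[tuple[str, str], list[GenomeInterval]] = {}

    for mark in MARKS:
        lam_wt = base_lambda(mark, "WT")
        t0 = sum(float(v.sum()) for v in lam_wt.values())
        f = cfg.spike_fraction
        s0 = f / (1.0 - f) * max(t0, 1.0)
        for condition in ("WT", cfg.mutant):
            sid = cfg.sample_id(mark, condition)
            if condition == "WT":
                lam = lam_wt
            else:
                lam = base_lambda(mark, condition)
                g = cfg.global_depletion.get(mark, 1.0)
                if mark in COUPLED_MARKS:
                    lam = {c: lam[c] * g * (1.0 - cfg.locus_effect * occ[c])
                           for c in lam}
                else:
                    lam = {c: lam[c] * g for c in lam}
                if mark == "H3K36me2":
                    for iv in redistributed:
                        _paint(lam, iv, cfg.redistribution_amp, bs)
            depth = cfg.sample_depth(sid)
            counts = {c: rng.poisson(depth * v).astype(np.float64)
                      for c, v in lam.items()}
            track = CoverageTrack(genome, bs, counts, units="raw")
            tracks[sid] = track
            spike = max(1, int(round(depth * s0)))
            spike_reads[sid] = spike
            norm_factors[sid] = compute_norm_factor(
                sid, target_reads=int(track.total()), spike_reads=spike)

    # --- peak sets
    def jitter(ivs: list[GenomeInterval]) -> list[GenomeInterval]:
        if cfg.peaks_mode == "noiseless":
            return list(ivs)
        out = []
        for iv in ivs:
            ds = int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1))
            de = int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1))
            s, e = max(0, iv.start + ds), min(genome[iv.chrom], iv.end + de)
            if e - s >= 50:
                out.append(GenomeInterval(iv.chrom, s, e))
        return out

    occ_runs = _threshold_runs(occ, bs, genome, cfg.occ_peak_threshold)
    for condition in ("WT", cfg.mutant):
        is_mut = condition != "WT"
        enh_all = mut_enh if is_mut else wt_enh
        active = mut_active if is_mut else wt_active
        poised = mut_poised if is_mut else wt_poised
        peaks[("H3K4me1", condition)] = jitter(
            [e.interval for e in enh_all] + list(expr_promoters))
        peaks[("H3K4me3", condition)] = jitter(list(expr_promoters))
        peaks[("H3K27ac", condition)] = jitter(list(active) + list(expr_promoters))
        peaks[("H3K27me3", condition)] = jitter(list(poised) + list(repr_bodies))
        me2 = domains if not is_mut else merge(list(domains) + redistributed)
        peaks[("H3K36me2", condition)] = jitter(list(me2))
        peaks[("H3K36me3", condition)] = jitter([g.body for g in expressed])
        peaks[("H3K36M", condition)] = jitter(occ_runs) if is_mut else []

    truth = SimTruth(
        enhancers=records,
        k36me2_domains=list(domain_list),
        occ_track=CoverageTrack(genome, bs, occ, units="raw"),
        global_depletion=dict(cfg.global_depletion),
        locus_effect=cfg.locus_effect,
        spike_reads=spike_reads,
        inactivation_rate=float(cfg.inactivation_rate),
    )
    return tracks, peaks, norm_factors, truth


def _threshold_runs(values, bin_size, genome, threshold) -> list[GenomeInterval]:
    out = []
    for chrom, v in values.items():
        above = np.concatenate([[False], v >= threshold, [False]])
        d = np.diff(above.astype(int))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            out.append(GenomeInterval(chrom, int(s * bin_size),
                                      min(int(e * bin_size), genome[chrom])))
    return out


# ---------------------------------------------------------------------------
# expression coupling


def simulate_expression_effects(
    cfg: SimConfig,
    genes: Sequence[GeneModel],
    truth: SimTruth,
) -> tuple[dict[str, float], dict[str, float], dict[str, str]]:
    """Couple inactivated enhancers to downregulation of their anchor genes.

    Returns WT FPKM, mutant FPKM and DE status tables; true log2 fold
    changes are stored in ``truth.gene_true_lfc``. DE statuses cover genes
    expressed in the wild type; the threshold (|log2FC| >= de_lfc_threshold
    on the true fold change) is recorded in the truth ledger implicitly via
    the config.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    inact_count = {g.gene_id: 0 for g in genes}
    for e in truth.enhancers:
        if e.inactivated:
            inact_count[e.anchor_gene] += 1
    fpkm_wt = {g.gene_id: float(g.fpkm or 0.0) for g in genes}
    fpkm_mut: dict[str, float] = {}
    de: dict[str, str] = {}
    for g in genes:
        lfc = (-cfg.effect_size * inact_count[g.gene_id]
               + rng.normal(0.0, cfg.lfc_noise_sd))
        if rng.random() < cfg.up_fraction:
            lfc += rng.normal(cfg.up_boost_mean, cfg.up_boost_sd)
        fpkm_mut[g.gene_id] = fpkm_wt[g.gene_id] * 2.0 ** lfc
        if fpkm_wt[g.gene_id] > 0:
            truth.gene_true_lfc[g.gene_id] = float(lfc)
            if lfc >= cfg.de_lfc_threshold:
                de[g.gene_id] = "up"
            elif lfc <= -cfg.de_lfc_threshold:
                de[g.gene_id] = "down"
            else:
                de[g.gene_id] = "unchanged"
    return fpkm_wt, fpkm_mut, de


def simulate_all(cfg: SimConfig) -> SimData:
    """Run the full generator: genome, marks, spike-ins and expression."""
    genome, genes = simulate_genome(cfg)
    tracks, peaks, norm_factors, truth = simulate_marks(cfg, genome, genes)
    fpkm_wt, fpkm_mut, de = simulate_expression_effects(cfg, genes, truth)
    return SimData(
        config=cfg, genome=genome, genes=genes, tracks=tracks, peaks=peaks,
        norm_factors=norm_factors, truth=truth,
        fpkm_wt=fpkm_wt, fpkm_mut=fpkm_mut, de_status=de,
    )


# ---------------------------------------------------------------------------
# file emission


def write_simdata(sim: SimData, outdir: str | Path) -> Path:
    """Emit the study as files the pipeline's readers consume."""
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)
    cio.write_genome_table(sim.genome, out / "genome.tsv")
    cio.write_gene_annotation(sim.genes, out / "genes.tsv")
    cio.write_fpkm_table(sim.fpkm_wt, out / "fpkm_WT.tsv")
    cio.write_fpkm_table(sim.fpkm_mut, out / f"fpkm_{sim.config.mutant}.tsv")
    cio.write_de_status(sim.de_status, out / "de_status.tsv")
    write_norm_factors(list(sim.norm_factors.values()), out / "norm_factors.tsv")
    for (mark, condition), ivs in sim.peaks.items():
        cio.write_bed(ivs, out / "peaks" / f"{mark}_{condition}.bed")
    for sid, track in sim.tracks.items():
        cio.write_bedgraph(track, out / "tracks" / f"{sid}.bedgraph")
    truth = {
        "mutant": sim.config.mutant,
        "seed": sim.config.seed,
        "global_depletion": sim.truth.global_depletion,
        "locus_effect": sim.truth.locus_effect,
        "inactivation_rate": sim.truth.inactivation_rate,
        "spike_reads": sim.truth.spike_reads,
        "gene_true_lfc": sim.truth.gene_true_lfc,
        "enhancers": [asdict(e) for e in sim.truth.enhancers],
        "k36me2_domains": [
            [d.chrom, d.start, d.end] for d in sim.truth.k36me2_domains
        ],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return out
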