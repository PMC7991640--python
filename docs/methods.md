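# Methods

This note documents the models, conventions and numerical choices behind
`chiprx`, what its synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinates and interval algebra

All genomic spans are 0-based, half-open (`[start, end)`, BED convention)
everywhere in memory and on disk; the simplified gene-annotation format is
defined in the same convention so no conversion happens outside the
parsers. "Overlap" means ≥1 shared base pair by default (`min_bp` is
exposed); book-ended intervals do not overlap, but `merge(gap=0)` unites
them, matching the usual peak-pooling semantics. Pooling of replicate peak
calls is union followed by `merge(gap=0)` — the most inclusive
deterministic reading of "pooled". Shuffled nulls are chromosome-matched
(each interval is re-placed uniformly on its own chromosome, preserving its
length), which preserves per-chromosome background better than genome-wide
placement; placement retries are bounded and failure is an error naming the
interval. Nearest-TSS distances are measured from the query midpoint, with
ties broken toward the lexicographically smaller gene id so assignment is
deterministic.

## Spike-in (RRPM) normalization

The normalization factor is `1e6 / spike_reads`, the standard ChIP-Rx
convention; target reads are recorded for reporting but never enter the
factor. The scaled unit is "reference-adjusted reads per million" (RRPM).
The defining property — a uniform global depletion that per-million-target
(RPM) scaling hides is quantitative in RRPM — is asserted by simulation in
the test suite. Re-normalizing an already-normalized track is an error.
Tracks for samples sequenced without spike-in (the mutant-histone ChIP in
the motivating design) can be scaled per-million-target instead; every
summary records which mode produced it.

## Density, profiles and tests

Interval density is the length-weighted mean of binned signal, exact for
bin-aligned intervals and within one bin's resolution otherwise. Metagene
profiles use 5 kb flanks at 100 bp resolution and 100 scaled body bins by
default (the flank width is the only part of the layout fixed by the study
design; the bin counts are exposed configuration). Genes shorter than the
body bin count, or whose flanks run off the chromosome, are dropped and
listed rather than interpolated, avoiding upsampling artifacts.
Minus-strand genes are flipped so column 0 is always biological upstream.

Group density comparisons use the two-sided Mann–Whitney U test —
densities are heavy-tailed, so a rank test is the robust default — with
Benjamini–Hochberg correction across the contrasts of one call. A label
permutation test in the suite checks type-I calibration at α = 0.05.

## Promoters, enhancers, states

Promoters are strand-aware windows from 2 kb upstream to 500 bp downstream
of the TSS, clipped at chromosome ends. Enhancers are H3K4me1 peaks with no
overlap (whole-peak exclusion) with H3K4me3 peaks or promoters; base-level
trimming is available in the interval layer for sensitivity analyses but is
not the default, because the definition reads as peak-level filtering.
States: overlap with H3K27ac ⇒ active; else H3K27me3 ⇒ poised; else primed.
The two marks are not mutually exclusive in real data, so the classifier
applies the precedence active > poised and the dual-marked fraction is
always computed and reported, making the rule's impact visible. (This
active/primed/poised vocabulary follows the main-text convention of the
motivating study; its figure legend swaps primed and poised, and the
convention string is embedded in every summary so downstream readers know
which was used.)

Transitions map each wild-type-active enhancer to the overlapping mutant
enhancer with the largest base overlap; no overlap means "lost".
Inactivated = mutant state ≠ active, lost included — the published
inactivation percentages are arithmetic over all wild-type-active
enhancers, which implies lost loci count. Enhancer–gene assignment
delegates to nearest-TSS with a 500 kb cap.

## Locus-dependence statistics

Peak decomposition is Venn-style: a peak is common if it overlaps any peak
of the other condition. Because overlaps can be many-to-one the common
count depends on perspective; both perspectives are always reported rather
than reconciled. Element annotation assigns each peak by its midpoint with
precedence promoter > exon > intron > intergenic, so fractions always
partition; midpoint assignment avoids double counting boundary-spanning
peaks. Expression strata are rank tertiles with ties broken by gene id and
zero-FPKM genes forced into the lowest stratum. Fold changes are
`log2((FPKM_mut + 1)/(FPKM_wt + 1))`; the pseudocount guards zeros and is
configurable. Occupancy correlations are Pearson product-moment r over the
filtered enhancer set (wild-type-active enhancers within wild-type
H3K36me2 peaks), with n always reported; zero variance in either variable
is an error rather than a NaN. Inactivated-enhancer counts per gene are
binned 0 / 1 / 2 / ≥3.

## The synthetic-data generator

The generator emulates the two-condition ChIP-Rx study design: a wild type
and one mutant (H3.3K36M-like or H3.1K36M-like), seven tracks each
(H3K4me1/me3, H3K27ac/me3, H3K36me2/me3 and the mutant histone itself),
peak sets, spike-in counts, FPKM and DE tables, and a complete truth
ledger.

Scale: 2 chromosomes × 5 Mb, 300 genes, ~1,500 wild-type enhancers,
50 bp bins — a full run takes a few seconds, and the correlation analyses
reach n ≈ 1,000 qualifying enhancers with a modestly larger genome
(350 genes on 2 × 6.5 Mb), the size used by the acceptance script.

Design of the injected truths, with defaults:

* **Sequencing model.** Expected reads per bin are compartment base rates
  (background 0.5; promoter/enhancer/gene-body amplitudes 4–12 reads per
  bin) Poisson-sampled per bin. Spike-in reads are a deterministic count
  proportional to per-sample depth (the pipeline only consumes the count),
  set so the wild-type spike fraction is 0.1. Doubling depth doubles both
  target and spike reads, which is exactly what RRPM must cancel.
* **Global depletion.** Mutant H3K36me2/me3 rates × 0.5, H3K27ac × 0.7,
  other marks unchanged — a genome-wide effect recoverable only via
  spike-in.
* **Cis coupling.** A normalized occupancy field occ(x) ∈ [0, 1] encodes
  where the mutant histone sits: introns of expressed genes (scaled by
  expression) plus intergenic enhancers for the H3.3-like variant; exons of
  repressed genes for the H3.1-like variant; per-enhancer occupancy is
  uniform on [0, 1]. Coupled marks are further multiplied by
  `1 − k·occ(x)` with k = 0.5, producing the negative Δmark–occupancy
  correlation the analysis is designed to detect; requesting k·occ > 1
  (negative signal) is an error. The mutant additionally gains H3K36me2 in
  redistributed compartments (exons or introns of a 30% subset of repressed
  genes, by variant), giving mutant-unique peaks.
* **Enhancer truth.** 68.4% of wild-type enhancers are active, 20% primed,
  11.6% poised (the active share follows the published wild-type counts).
  Wild-type-active enhancers are inactivated with mean probability 0.612
  (H3.3-like) or 0.555 (H3.1-like) — the published percentages — with the
  probability increasing mildly with local occupancy; 15% of inactivated
  enhancers disappear entirely ("lost"). The mutant carries an equal number
  of additional unique enhancers, shorter (400–800 bp vs 800–1,600 bp) and
  farther from TSSs than common ones, reproducing the observed "more but
  shorter and less active" enhancer landscape at toy scale.
* **Geometry.** Genes (2–5 kb, 2–8 exons) are placed without overlap with
  ≥28 kb gaps; enhancers anchor upstream of a 65% subset of genes at
  distances `distance_min + Exponential(mean − distance_min)` (means 8.0 /
  13.6 kb common/unique for the H3.3-like variant, 7.2 kb for the
  H3.1-like), placed by rejection against gene bodies, promoters and other
  enhancers. On the default dense genome, rejection pushes accepted
  distances outward, so configured means are exact only where there is
  room; a `uniform` distance law is provided and used by the
  distance-recovery test on a sparse genome at the real study's 40/68 kb
  scale. Anchoring only a subset of genes leaves a realistic population of
  enhancer-free genes, which is what makes the up- vs down-regulated
  association contrast meaningful.
* **Expression coupling.** A gene's true log2 fold change is
  `−0.8 × (number of its inactivated enhancers) + N(0, 0.3)`, plus an
  independent `+N(1.8, 0.3)` trans-activation for a random 12% of genes so
  an upregulated class exists. DE status thresholds the true fold change at
  |log2FC| ≥ 1 over genes expressed in wild type.

Determinism: one integer seed drives three spawned generator streams
(genome, marks, expression); identical configs give byte-identical emitted
files, and every file parses through the package's own readers.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artifacts (mappability, GC, duplicate
reads), input-DNA background structure, peak-caller behavior (noiseless
peaks are the truth intervals; a jitter mode exists for robustness checks
but classification accuracy under it is reported, not asserted),
replicate-to-replicate variability, many-to-many enhancer–gene regulation,
and negative-binomial overdispersion beyond Poisson counts.

## Pipeline and provenance

`run_pipeline` chains normalize → enhancers → transitions → decomposition →
densities/shuffled nulls → element annotation → correlations → expression
associations, writing TSVs whose first line carries a digest of the
resolved analysis parameters (paths excluded, so identical analyses in
different directories produce byte-identical tables). `summary.json` holds
the machine-readable results plus the classification convention and
normalization mode. Reports are rendered with fixed SVG hash salts and no
timestamps, so they are reproducible byte-for-byte.

## Known limitations

* Venn "common" counts are reported from both perspectives; there is no
  single middle number when overlaps are many-to-one.
* The shuffled null excludes nothing by default; callers wanting
  blacklist-style exclusions pass them explicitly.
* `interval_density` is exact only for bin-aligned intervals; off-grid
  boundaries are resolved by length-weighting within the boundary bins.
* The whole pipeline is single-threaded; the intended scale is toy genomes
  and moderately sized real peak sets, not base-resolution whole-genome
  tracks.
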