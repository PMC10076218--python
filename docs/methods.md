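# Methods

This note documents the models and procedures implemented in `coseq`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions.

## Cobarcoding model and demultiplexing

Each tissue pixel is addressed by the combination of a barcode A (delivered
along one microfluidic flow direction) and a barcode B (perpendicular
flow), ligated in situ. Read 2 of the sequencing library is a fixed
concatenation of segments — by default barcode B (8 bp), ligation linker 2
(30 bp), barcode A (8 bp), ligation linker 1 (30 bp), and a 10 bp UMI for
the RNA library. Because the chemistry is ligation-based, segment offsets
are constant; demultiplexing therefore parses at fixed offsets and makes no
attempt at indel alignment. Linker and whitelist sequences are configuration,
not code: real chips load their published barcode tables (TSV or FASTA),
and the simulators draw random whitelists with pairwise Hamming
distance ≥ 3.

Decisions per read pair:

1. both linkers must match within `max_linker_mismatch` substitutions
   (default 2; `N` counts as a mismatch) → otherwise `linker_fail`;
2. each barcode must resolve to a *unique* whitelist entry within Hamming
   distance `max_distance` (default 1) → `barcode_fail` if none,
   `ambiguous` if two or more entries tie at the minimum distance;
3. accepted chromatin reads are re-emitted as (untouched genomic read,
   synthetic 16 bp A+B barcode read) so 10x-style ATAC tooling can consume
   them; accepted RNA reads yield (genomic read, pixel id, raw UMI). UMIs
   are never error-corrected at extraction; collapse happens at counting.

With whitelists at pairwise distance ≥ 3 and `max_distance` 1, any read
whose barcode regions carry at most one substitution per barcode is
provably assigned to its true pixel (the true entry is within distance 1,
every other entry at distance ≥ 2); the test suite verifies this
exhaustively on small whitelists. Defaults (2 linker mismatches, distance-1
barcode correction) are the standard operating point for 8-mer whitelists
of ≤ 100 entries; both are exposed as flags.

## Fragments and count matrices

Aligned, pixel-tagged paired templates become BED-convention fragments
(0-based half-open). A Tn5 shift of (+4, −5) is applied to both ATAC and
CUT&Tag templates — both chemistries are tagmentation-based — and is
configurable off. Templates below MAPQ 30 (default) or without a pixel tag
are dropped and counted. Duplicates collapse on (chrom, start, end, pixel)
with their multiplicity kept as `duplicate_count`; the output is sorted and
round-trips losslessly through a plain-text, bgzip-compatible TSV.

RNA counting deduplicates by (gene, pixel, UMI). The default is exact UMI
identity — the simplest faithful policy; a `directional` mode additionally
absorbs UMI *u* into *v* when Hamming(u, v) = 1 and
count(v) ≥ 2·count(u) − 1 (the standard directional-network rule for
PCR/sequencing artefacts). Deduplicating by (gene, pixel, UMI, position)
would be stricter for long genes; we document the choice and note that at
spatial-pixel depths the difference is marginal. Gene assignment uses exon
overlap on an interval tree: one overlapping gene assigns the read, two or
more make it `ambiguous` (dropped and counted), none leaves it intergenic.
Assignment is unstranded by default because post-amplification library
orientation is not reliable for this chemistry; a stranded mode exists.

## QC metrics

A fragment is "in" an interval set iff it overlaps any interval by ≥ 1 bp;
peaks are merged first, making FRiP invariant to peak ordering and to
splitting peaks into abutting pieces. TSS regions are TSS ± 2,000 bp
(the term is otherwise underspecified; the window is a parameter and is
echoed in the report header). Fractions are computed over deduplicated
fragments; weighting by duplicate count is available but off by default,
and an empty fragment set yields a missing value, never 0. Replicate
concordance is the Pearson correlation of per-feature pseudobulk sums
after log1p.

## Gene activity and chromatin silencing scores

The gene-score family summarizes fragments near a gene into a per-pixel
activity proxy. Our model: a fragment's midpoint is the distance anchor;
weight 1 (`body_weight`) if the midpoint lies inside the gene body,
`exp(−d/c)` for midpoints d bp from the nearest body edge, zero beyond the
extension limit. Defaults: decay constant c = 5,000 bp, extension 100 kb,
per-pixel depth normalization to 10,000 followed by log1p. These are
declared simplifications of the ArchR-style exponential-decay gene-score
model, chosen to be exactly testable — the implementation is verified
against a brute-force double loop to 1e-9 on random toy instances — and
every choice is a parameter. Truncation at neighboring gene bodies is off
by default. On an H3K27me3 library the same aggregate is interpreted as a
chromatin silencing score: matrices carry a `direction` flag
(`activating` for ATAC/H3K27ac/H3K4me3, `repressive` for H3K27me3) so
downstream quadrant labeling is sign-aware without touching values.

Raw scores are non-negative and monotone in fragments; as c → ∞ with
unbounded extension each gene's raw score tends to the pixel's total
fragment count (both properties are tested).

## Peak-to-gene linkage

Pairs tested: peak center within 250 kb of the gene's TSS. Pixels are
aggregated into 100 pseudo-groups (metacells) by k-means on the
log-normalized gene matrix with a fixed seed recorded in the output
metadata; Pearson r and its p-value are computed across group mean
profiles and BH-adjusted over all tested pairs. A link is significant at
|r| ≥ 0.45 and q ≤ 0.05. The correlation and FDR cutoffs follow the
conventions of correlation-linkage tools in this field; window, cutoffs,
group count and seed are all parameters. Fewer than 3 groups is an error
(correlation undefined).

## Region markers and quadrant analysis

Counts are normalized to counts-per-10k and log2(1 + x) — base-2 logs so
that differences of group means read directly as log2 fold changes. The
avg_log2FC is the difference of group means of log-normalized values
(simpler than ratio-of-means and monotone-equivalent for ranking; an
SCTransform-style variance-stabilization step is intentionally out of
scope). RNA markers: two-sided Wilcoxon rank-sum region vs rest, after
prefiltering to detection fraction ≥ 0.25 in either group and
|log2FC| ≥ 0.25, Bonferroni-adjusted over all features (the wrapped
single-cell tooling's default; BH available), with markers selected at
adjusted P < 1e-5. Score enrichment applies the same statistic to GAS/CSS
matrices, restricted to the RNA marker list, with BH FDR ≤ 0.05 and
|Log2FC| ≥ 0.1.

Exact rank-sum p-values: for small problems (C(n1+n2, n1) ≤ 5,000) the
permutation null of the rank-sum statistic is enumerated with average
ranks for ties, two-sided as P(|S − μ| ≥ |s_obs − μ|); this equals the
classical exact two-sided Mann-Whitney p when there are no ties (tested)
and remains well-defined under ties. Larger problems use the
tie-corrected normal approximation. Constant pooled samples give p = 1.

Quadrants: x = RNA log2FC, y = score log2FC; I = (+,+), II = (−,+),
III = (−,−), IV = (+,−); genes on an axis (either value exactly 0, or
non-finite) are unassigned. For a repressive mark quadrant II reads "high
silencing, low expression" and IV "low silencing, high expression" — the
expected anticorrelated pattern — while quadrant I collects candidate
poised/bivalent genes. The multi-mark export concatenates each gene's
+/−/absent status across marks (absent = not passing that mark's cutoffs)
and emits pattern counts for Venn/upset-style summaries.

## Synthetic data: what it emulates and what it does not

The generators produce the statistical structure the analyses assume, at
desk scale, with every draw seeded and truth tables emitted:

- **Reads**: uniform pixel usage, i.i.d. substitution noise (default
  0.5%), fixed-layout read 2. No indels, no quality-score model, no
  chimeric ligation products.
- **Templates**: fragment centers from a peak (0.30) / TSS (0.20) /
  background (0.50) mixture, insert sizes from a two-component Gaussian
  mixture at 60 ± 15 bp and 200 ± 30 bp (sub- and mono-nucleosomal),
  duplicates injected at 15%. No sequence content, no chromatin
  periodicity beyond the two modes, no mappability structure.
- **Co-profiles**: a 20×20 grid split into two 200-pixel regions;
  negative-binomial counts (dispersion size 10 — standard overdispersion
  for UMI data) with planted region markers at |log2FC| = 1 in RNA and
  score, sign patterns covering all four quadrants with the
  anticorrelated quadrants II/IV dominant and a bivalent minority in I.
  The peak–gene generator couples each true pair through a shared
  per-pixel log-normal latent strong enough that the planted correlation
  survives Poisson counting noise and depth normalization (r ≥ 0.9 at the
  metacell level), with decoy peaks equally close to TSSs but driven by
  independent latents, and one far (> 400 kb) peak to exercise the
  distance window.

Real tissue adds everything these omit: spatially smooth cell-type
mixtures, depth gradients, batch and section effects, mappability and GC
structure, and per-gene dispersion far from any single value. Passing the
planted-recovery tests therefore certifies the statistical machinery —
conservation, calibration, sign conventions, error control — not
performance on real data, whose headline per-sample metrics (tens of
thousands of unique fragments per pixel, tens of thousands of
peak-to-gene links) depend on deposited sequencing data and sit far above
desk scale. Problem sizes in the tests and acceptance script (10,000
reads, a few thousand fragments, 400 pixels, ≤ 300 genes) were chosen as
the smallest at which the statistical claims are testable with margin.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open throughout; GTF input is converted on
read; the TSS of a −-strand gene is its last base. Pixel ids are
"AxB" strings with 1-based barcode indices; grids iterate A-major. Fragment
midpoints at half-integer positions are kept exact (no rounding). Sorting
keys and tie-breaks are lexicographic on (chrom, start, end, pixel).
Zero-variance profiles are errors in correlation contexts, p = 1 in test
contexts. Empty fragment sets make overlap fractions missing rather than
zero. The k-means pseudo-grouping seed, the distance window, and every
threshold named above are recorded in outputs or config echoes so a run
can be reproduced from its artifacts.
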