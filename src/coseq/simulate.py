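"""Ground-truth synthetic data for every pipeline stage.

Three generators, all bit-reproducible under a fixed seed and all
emitting machine-readable truth tables:

* :func:`simulate_reads` — raw cobarcoded FASTQ pairs with planted
  (barcode A, barcode B, UMI) addresses and per-segment substitution
  noise, for exercising demultiplexing.
* :func:`simulate_fragments` — pixel-tagged aligned templates drawn from
  a peak / TSS / background mixture with a bimodal (sub- and
  mono-nucleosomal) insert-size distribution and injected duplicates,
  for fragment building and QC.
* :func:`simulate_coprofiles` — paired epigenetic-score and RNA count
  matrices over a spatial region layout with planted region markers of
  known sign, emulating the anticorrelation of a repressive mark with
  expression (plus a bivalent minority positive in both), for the marker
  / quadrant statistics. :func:`simulate_peak_gene` plants linear
  peak-gene couplings for the linkage test, and
  :func:`simulate_multimark` plants consistent sign patterns across
  three histone marks.

Counts are negative-binomial with configurable dispersion — the standard
overdispersed model for UMI data. The generators emulate the statistical
structure the analyses assume, not real genome sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .demux import FastqRead
from .matrices import AlignedPair, GeneModel, PixelMatrix
from .schema import BarcodeSchema, PixelGrid, pixel_id, random_whitelist

__all__ = [
    "SimConfig",
    "make_schema",
    "make_toy_genome",
    "simulate_reads",
    "simulate_fragments",
    "simulate_coprofiles",
    "simulate_peak_gene",
    "simulate_multimark",
    "write_fastq",
]

DNA = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the generators (defaults are the test conditions).

    seed is mandatory; everything else has a default matching the scale
    at which the statistical checks are specified (0.5% substitution
    noise, nucleosomal insert mixture, 2 spatial regions of 200 pixels,
    planted |log2FC| = 1 markers, NB dispersion size 10).
    """

    seed: int
    n_a: int = 20
    n_b: int = 20
    reads_per_pixel: float = 25.0
    substitution_rate: float = 0.005
    insert_means: tuple[float, ...] = (60.0, 200.0)
    insert_sds: tuple[float, ...] = (15.0, 30.0)
    insert_weights: tuple[float, ...] = (0.4, 0.6)
    mixture_weights: dict = field(
        default_factory=lambda: {"peak": 0.30, "tss": 0.20, "background": 0.50}
    )
    duplicate_rate: float = 0.15
    n_regions: int = 2
    n_genes: int = 300
    rna_effect_log2fc: float = 1.0
    score_effect_log2fc: float = 1.0
    n_markers_per_quadrant: dict = field(
        default_factory=lambda: {"I": 10, "II": 20, "III": 10, "IV": 20}
    )
    nb_dispersion: float = 10.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0, 1]")
        if abs(sum(self.mixture_weights.values()) - 1) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def make_schema(
    n_a: int = 20,
    n_b: int = 20,
    modality: str = "atac",
    barcode_len: int = 8,
    umi_len: int = 10,
    linker_len: int = 30,
    min_distance: int = 3,
    seed: int = 0,
) -> BarcodeSchema:
    """Random but valid chemistry schema for simulations and tests."""
    rng = np.random.default_rng((seed, 101))
    wl_a = random_whitelist(n_a, barcode_len, min_distance, rng)
    wl_b = random_whitelist(n_b, barcode_len, min_distance, rng)
    linker1 = "".join(DNA[rng.integers(0, 4, linker_len)])
    linker2 = "".join(DNA[rng.integers(0, 4, linker_len)])
    return BarcodeSchema(
        barcode_a_whitelist=tuple(wl_a),
        barcode_b_whitelist=tuple(wl_b),
        linker1_seq=linker1,
        linker2_seq=linker2,
        modality=modality,
        barcode_len=barcode_len,
        umi_len=umi_len,
    )


def make_toy_genome(
    n_genes: int = 20,
    chrom: str = "chr1",
    gene_length: int = 10_000,
    spacing: int = 500_000,
    peak_offset: int = 120_000,
    peak_width: int = 600,
    seed: int = 0,
) -> tuple[list[GeneModel], list[tuple[str, int, int]], int]:
    """Toy single-chromosome genome: evenly spaced genes plus intergenic peaks.

    Peaks are placed ``peak_offset`` bp downstream of each gene body so
    that peak, TSS-window and gene-body intervals are disjoint (keeps the
    placement mixture components identifiable in QC tests).
    """
    rng = np.random.default_rng((seed, 202))
    genes, peaks = [], []
    for i in range(n_genes):
        start = 100_000 + i * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"gene{i:03d}", chrom, strand, start, start + gene_length)
        )
        peak_start = start + gene_length + peak_offset
        peaks.append((chrom, peak_start, peak_start + peak_width))
    genome_length = 100_000 + n_genes * spacing + 200_000
    return genes, peaks, genome_length


# ---------------------------------------------------------------------------
# raw reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, np.ndarray]:
    """Substitute bases i.i.d. at ``rate``; returns sequence + hit positions."""
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), hits


def simulate_reads(
    config: SimConfig,
    schema: BarcodeSchema,
    n_reads: Optional[int] = None,
    read1_length: int = 50,
) -> tuple[list[tuple[FastqRead, FastqRead]], pd.DataFrame]:
    """Cobarcoded read pairs with a per-read ground-truth table.

    Each read plants a uniformly drawn (barcode A, barcode B) address
    (plus a random UMI in RNA mode), concatenates the schema's read-2
    layout, and applies i.i.d. substitution noise. The truth table
    records the planted address and the number of substitutions falling
    in each layout segment.
    """
    rng = config.rng(1)
    if n_reads is None:
        n_reads = int(round(config.reads_per_pixel * schema.n_a * schema.n_b))
    seg_of_pos = np.empty(schema.read2_length, dtype=object)
    for name, off, length in schema.layout:
        seg_of_pos[off : off + length] = name

    pairs: list[tuple[FastqRead, FastqRead]] = []
    truth_rows = []
    for i in range(n_reads):
        a = int(rng.integers(1, schema.n_a + 1))
        b = int(rng.integers(1, schema.n_b + 1))
        umi = "".join(DNA[rng.integers(0, 4, schema.umi_len)]) if schema.modality == "rna" else ""
        parts = []
        for name, off, length in schema.layout:
            if name == "barcode_a":
                parts.append(schema.barcode_a_whitelist[a - 1])
            elif name == "barcode_b":
                parts.append(schema.barcode_b_whitelist[b - 1])
            elif name == "linker1":
                parts.append(schema.linker1_seq)
            elif name == "linker2":
                parts.append(schema.linker2_seq)
            else:
                parts.append(umi)
        clean2 = "".join(parts)
        read2_seq, hits = _mutate(clean2, config.substitution_rate, rng)
        read1_seq, _ = _mutate(
            "".join(DNA[rng.integers(0, 4, read1_length)]), config.substitution_rate, rng
        )
        name = f"read{i:06d}"
        pairs.append(
            (
                FastqRead(name, read1_seq, "I" * read1_length),
                FastqRead(name, read2_seq, "I" * len(read2_seq)),
            )
        )
        seg_hits = {f"subs_{seg}": 0 for seg, _, _ in schema.layout}
        for pos in hits:
            seg_hits[f"subs_{seg_of_pos[pos]}"] += 1
        truth_rows.append({"read_id": name, "a": a, "b": b, "umi": umi, **seg_hits})
    return pairs, pd.DataFrame(truth_rows)


def write_fastq(reads: Sequence[FastqRead], path) -> None:
    with open(path, "wt") as out:
        for r in reads:
            out.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality or 'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# aligned templates


def simulate_fragments(
    config: SimConfig,
    grid: PixelGrid,
    genes: Sequence[GeneModel],
    peaks: Sequence[tuple[str, int, int]],
    genome_length: int,
    n_fragments: Optional[int] = None,
    tss_window: int = 2000,
) -> tuple[list[AlignedPair], pd.DataFrame]:
    """Pixel-tagged templates from a peak / TSS / background placement mixture.

    Fragment centers fall uniformly in a random peak, in a random TSS
    +/- ``tss_window`` interval, or uniformly on the genome, according to
    ``config.mixture_weights``; insert sizes come from the configured
    Gaussian mixture (clipped at 20 bp); each molecule is re-emitted as a
    duplicate with probability ``config.duplicate_rate``. The truth table
    has one row per emitted template with its component and duplicate flag.
    """
    rng = config.rng(2)
    if n_fragments is None:
        n_fragments = int(round(config.reads_per_pixel * grid.n_on_tissue))
    on_pixels = grid.pixel_ids(on_tissue_only=True)
    chrom = genes[0].chrom if genes else (peaks[0][0] if peaks else "chr1")
    components = list(config.mixture_weights)
    weights = np.array([config.mixture_weights[c] for c in components])
    insert_w = np.asarray(config.insert_weights) / np.sum(config.insert_weights)

    templates: list[AlignedPair] = []
    rows = []
    for _ in range(n_fragments):
        comp = components[int(rng.choice(len(components), p=weights))]
        if comp == "peak" and peaks:
            c, s, e = peaks[int(rng.integers(0, len(peaks)))]
            center = int(rng.integers(s, e))
        elif comp == "tss" and genes:
            g = genes[int(rng.integers(0, len(genes)))]
            center = int(rng.integers(max(0, g.tss - tss_window), g.tss + tss_window + 1))
            c = g.chrom
        else:
            comp = "background"
            c = chrom
            center = int(rng.integers(0, genome_length))
        k = int(rng.choice(len(insert_w), p=insert_w))
        size = max(20, int(round(rng.normal(config.insert_means[k], config.insert_sds[k]))))
        start = max(0, center - size // 2)
        end = start + size
        pixel = on_pixels[int(rng.integers(0, len(on_pixels)))]
        n_copies = 1 + (1 if rng.random() < config.duplicate_rate else 0)
        for copy in range(n_copies):
            templates.append(AlignedPair(c, start, end, pixel, mapq=60))
            rows.append({
                "chrom": c, "start": start, "end": end, "pixel": pixel,
                "component": comp, "insert_component": k,
                "is_duplicate": copy > 0,
            })
    order = rng.permutation(len(templates))
    templates = [templates[i] for i in order]
    truth = pd.DataFrame([rows[i] for i in order])
    return templates, truth


# ---------------------------------------------------------------------------
# count matrices


def _nb_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws with mean ``mean`` and size ``dispersion``."""
    mean = np.clip(mean, 1e-9, None)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _region_layout(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Pixels in A-major order split into vertical blocks of columns."""
    grid = PixelGrid(config.n_a, config.n_b)
    pixels = grid.pixel_ids()
    cols = np.array([int(p.split("x")[1]) - 1 for p in pixels])
    block = np.minimum(cols * config.n_regions // config.n_b, config.n_regions - 1)
    labels = np.array([f"R{i + 1}" for i in block])
    return pixels, labels


QUADRANT_SIGNS = {"I": (1, 1), "II": (-1, 1), "III": (-1, -1), "IV": (1, -1)}


def simulate_coprofiles(
    config: SimConfig,
    score_modality: str = "h3k27me3",
) -> tuple[PixelMatrix, PixelMatrix, np.ndarray, pd.DataFrame]:
    """Paired (score, RNA) NB count matrices with planted quadrant structure.

    The grid is split into ``n_regions`` vertical blocks; planted marker
    genes of the first region ("R1") carry RNA and score fold changes
    whose sign pattern places them in a known quadrant — dominated by the
    anticorrelated quadrants II (score up, RNA down) and IV (RNA up,
    score down) for a repressive mark, with a bivalent minority in I.
    Returns (score matrix, rna matrix, region labels, truth table); the
    truth table lists each gene's planted signs and expected quadrant
    (``None`` for null genes).
    """
    rng = config.rng(3)
    pixels, labels = _region_layout(config)
    in_region = labels == "R1"
    n_genes = config.n_genes
    genes = [f"gene{i:04d}" for i in range(n_genes)]

    base_rna = rng.lognormal(mean=1.3, sigma=0.6, size=n_genes)
    base_score = rng.lognormal(mean=1.3, sigma=0.6, size=n_genes)

    rna_sign = np.zeros(n_genes, dtype=int)
    score_sign = np.zeros(n_genes, dtype=int)
    expected = np.array([None] * n_genes, dtype=object)
    cursor = 0
    for quadrant, n in config.n_markers_per_quadrant.items():
        rs, ss = QUADRANT_SIGNS[quadrant]
        rna_sign[cursor : cursor + n] = rs
        score_sign[cursor : cursor + n] = ss
        expected[cursor : cursor + n] = quadrant
        cursor += n

    rna_fc = 2.0 ** (config.rna_effect_log2fc * rna_sign)
    score_fc = 2.0 ** (config.score_effect_log2fc * score_sign)
    rna_mean = np.outer(base_rna, np.ones(len(pixels)))
    score_mean = np.outer(base_score, np.ones(len(pixels)))
    rna_mean[:, in_region] *= rna_fc[:, None]
    score_mean[:, in_region] *= score_fc[:, None]

    rna_X = _nb_counts(rna_mean, config.nb_dispersion, rng)
    score_X = _nb_counts(score_mean, config.nb_dispersion, rng)

    rna = PixelMatrix(genes, pixels, sp.csr_matrix(rna_X), modality="rna", direction="activating")
    score = PixelMatrix(
        genes, pixels, sp.csr_matrix(score_X), modality=score_modality,
        direction="repressive" if score_modality == "h3k27me3" else "activating",
    )
    truth = pd.DataFrame({
        "gene": genes,
        "region": "R1",
        "rna_sign": rna_sign,
        "score_sign": score_sign,
        "expected_quadrant": expected,
    })
    return score, rna, labels, truth


def simulate_peak_gene(
    config: SimConfig,
    n_pixels: int = 200,
    n_coupled: int = 20,
    n_decoy: int = 60,
    coupling_sd: float = 1.5,
    noise_sd: float = 0.1,
    gene_log_mean: float = 3.5,
    peak_log_mean: float = 3.0,
) -> tuple[PixelMatrix, PixelMatrix, list[GeneModel], dict[str, tuple[str, int, int]], pd.DataFrame]:
    """Planted linear peak-gene couplings across pixels.

    Each coupled (peak, gene) pair shares a per-pixel latent log-activity
    (sd ``coupling_sd``) plus independent noise, producing strongly
    correlated Poisson counts; decoy peaks sit equally close to a gene's
    TSS but follow an independent latent, so their correlations are null.
    One far peak (> 400 kb) checks the distance-window rule. Returns
    (peak matrix, gene matrix, gene models, peak intervals, truth table).
    """
    rng = config.rng(4)
    n_genes = n_coupled + n_decoy
    genes_models, _, _ = make_toy_genome(n_genes, spacing=1_200_000, seed=config.seed)
    pixels = [pixel_id(1 + i // 20, 1 + i % 20) for i in range(n_pixels)]

    peaks: dict[str, tuple[str, int, int]] = {}
    rows_truth = []
    gene_X = np.zeros((n_genes, n_pixels))
    peak_ids: list[str] = []
    peak_X_rows: list[np.ndarray] = []

    for i, gene in enumerate(genes_models):
        latent = rng.normal(0.0, coupling_sd, n_pixels)
        gene_log = gene_log_mean + latent + rng.normal(0.0, noise_sd, n_pixels)
        gene_X[i] = rng.poisson(np.exp(gene_log))
        peak_name = f"peak{i:03d}"
        near = (gene.chrom, gene.tss + 30_000, gene.tss + 30_600)
        coupled = i < n_coupled
        if coupled:
            peak_log = peak_log_mean + latent + rng.normal(0.0, noise_sd, n_pixels)
        else:
            peak_log = peak_log_mean + rng.normal(0.0, coupling_sd, n_pixels) + rng.normal(0.0, noise_sd, n_pixels)
        peaks[peak_name] = near
        peak_ids.append(peak_name)
        peak_X_rows.append(rng.poisson(np.exp(peak_log)))
        rows_truth.append({"peak": peak_name, "gene": gene.gene_id, "coupled": coupled})

    # distance-window control: strongly coupled but 450 kb from its gene TSS
    far_gene = genes_models[0]
    far_name = "peak_far"
    peaks[far_name] = (far_gene.chrom, far_gene.tss + 450_000, far_gene.tss + 450_600)
    peak_X_rows.append(gene_X[0] + rng.poisson(1.0, n_pixels))
    peak_ids.append(far_name)
    rows_truth.append({"peak": far_name, "gene": far_gene.gene_id, "coupled": False})

    peak_matrix = PixelMatrix(peak_ids, pixels, sp.csr_matrix(np.vstack(peak_X_rows)), modality="atac")
    gene_matrix = PixelMatrix(
        [g.gene_id for g in genes_models], pixels, sp.csr_matrix(gene_X), modality="rna"
    )
    return peak_matrix, gene_matrix, genes_models, peaks, pd.DataFrame(rows_truth)


def simulate_multimark(
    config: SimConfig,
) -> tuple[dict[str, PixelMatrix], PixelMatrix, np.ndarray, pd.DataFrame]:
    """Three histone-mark score matrices with a consistent planted design.

    Genes active in the focal region are planted high in the activating
    marks (H3K4me3+, H3K27ac+) and low in the repressive mark
    (H3K27me3-); repressed genes carry the opposite pattern; a bivalent
    minority is high in both H3K4me3 and H3K27me3. RNA follows the
    active/repressed sign. Truth lists the expected +/- pattern per mark.
    """
    rng = config.rng(5)
    pixels, labels = _region_layout(config)
    in_region = labels == "R1"
    n_active, n_repressed, n_bivalent, n_null = 20, 20, 8, config.n_genes - 48
    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    classes = (
        ["active"] * n_active + ["repressed"] * n_repressed
        + ["bivalent"] * n_bivalent + ["null"] * n_null
    )
    sign_by_class = {
        # (rna, H3K4me3, H3K27ac, H3K27me3)
        "active": (1, 1, 1, -1),
        "repressed": (-1, -1, -1, 1),
        "bivalent": (1, 1, 0, 1),
        "null": (0, 0, 0, 0),
    }
    marks = ("h3k4me3", "h3k27ac", "h3k27me3")
    effect = config.score_effect_log2fc

    matrices: dict[str, PixelMatrix] = {}
    signs = np.array([sign_by_class[c] for c in classes])
    for mi, mark in enumerate(marks, start=1):
        base = rng.lognormal(mean=1.3, sigma=0.6, size=config.n_genes)
        mean = np.outer(base, np.ones(len(pixels)))
        fc = 2.0 ** (effect * signs[:, mi])
        mean[:, in_region] *= fc[:, None]
        X = _nb_counts(mean, config.nb_dispersion, rng)
        matrices[mark] = PixelMatrix(
            genes, pixels, sp.csr_matrix(X), modality=mark,
            direction="repressive" if mark == "h3k27me3" else "activating",
        )
    base_rna = rng.lognormal(mean=1.3, sigma=0.6, size=config.n_genes)
    rna_mean = np.outer(base_rna, np.ones(len(pixels)))
    rna_mean[:, in_region] *= 2.0 ** (config.rna_effect_log2fc * signs[:, 0])[:, None]
    rna = PixelMatrix(
        genes, pixels, sp.csr_matrix(_nb_counts(rna_mean, config.nb_dispersion, rng)),
        modality="rna", direction="activating",
    )
    truth = pd.DataFrame({
        "gene": genes,
        "class": classes,
        "rna_sign": signs[:, 0],
        "h3k4me3_sign": signs[:, 1],
        "h3k27ac_sign": signs[:, 2],
        "h3k27me3_sign": signs[:, 3],
    })
    return matrices, rna, labels, truth
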