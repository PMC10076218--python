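"""Spatial fragment files and feature x pixel count matrices.

Aligned, pixel-tagged templates become (a) a sorted, deduplicated
BED-like fragments file — chrom, start, end, pixel barcode, duplicate
count, 0-based half-open — and (b) a UMI-collapsed gene x pixel count
matrix. Both carry the spatial address (barcode A x barcode B) as the
column/barcode identity, which is what makes downstream maps spatial.

Coordinate conventions: BED-style 0-based half-open everywhere; GTF input
(1-based closed) is converted on read. A Tn5 shift of (+4, -5) is applied
by default to both ATAC and CUT&Tag templates, since both chemistries use
Tn5 tagmentation.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pysam
import scipy.io
import scipy.sparse as sp
from intervaltree import IntervalTree

__all__ = [
    "AlignedPair",
    "FragmentRecord",
    "PixelMatrix",
    "GeneModel",
    "GeneIndex",
    "build_fragments",
    "assign_gene",
    "count_umis",
    "write_fragments",
    "read_fragments",
    "write_matrix",
    "read_matrix",
    "read_gtf",
    "read_tagged_sam",
    "read_bed",
    "write_bed",
]


class AlignedPair(NamedTuple):
    """A paired-end template: outer span on the reference plus pixel tag."""

    chrom: str
    start: int  # leftmost aligned position, 0-based
    end: int  # rightmost aligned end, half-open
    pixel: str
    mapq: int = 60


class FragmentRecord(NamedTuple):
    """One deduplicated fragment at one pixel (BED-like)."""

    chrom: str
    start: int
    end: int
    pixel: str
    duplicate_count: int = 1


@dataclass
class GeneModel:
    """Minimal gene model: body, strand-appropriate TSS, exons (all 0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PixelMatrix:
    """Sparse feature x pixel matrix (counts or scores).

    ``direction`` records how high values read biologically:
    ``"activating"`` (ATAC / H3K27ac / H3K4me3 gene activity, RNA) or
    ``"repressive"`` (H3K27me3 chromatin silencing).
    """

    features: list[str]
    pixels: list[str]
    X: sp.spmatrix
    modality: Optional[str] = None
    direction: Optional[str] = None

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.features), len(self.pixels)):
            raise ValueError(
                f"matrix shape {self.X.shape} != ({len(self.features)}, {len(self.pixels)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())

    def subset_pixels(self, pixels: Sequence[str]) -> "PixelMatrix":
        index = {p: j for j, p in enumerate(self.pixels)}
        cols = [index[p] for p in pixels]
        return PixelMatrix(
            list(self.features), list(pixels), self.X[:, cols], self.modality, self.direction
        )

    def restrict_to_tissue(self, grid) -> "PixelMatrix":
        on = set(grid.pixel_ids(on_tissue_only=True))
        keep = [p for p in self.pixels if p in on]
        return self.subset_pixels(keep)


# ---------------------------------------------------------------------------
# fragments


def build_fragments(
    pairs: Iterable[AlignedPair],
    mapq_min: int = 30,
    shift: tuple[int, int] = (4, -5),
    counters: Optional[Counter] = None,
) -> list[FragmentRecord]:
    """Collapse aligned pixel-tagged templates into sorted unique fragments.

    Per template the fragment is ``[start + shift[0], end + shift[1])``;
    duplicates (same chrom/start/end/pixel) collapse with their count
    recorded. Templates below ``mapq_min``, without a pixel tag, or whose
    shifted interval is empty are skipped and tallied in ``counters``.
    """
    counts: dict[tuple[str, int, int, str], int] = defaultdict(int)
    tally = counters if counters is not None else Counter()
    for pair in pairs:
        if not pair.pixel:
            tally["missing_pixel_tag"] += 1
            continue
        if pair.mapq < mapq_min:
            tally["low_mapq"] += 1
            continue
        start = pair.start + shift[0]
        end = pair.end + shift[1]
        if start >= end or start < 0:
            tally["empty_after_shift"] += 1
            continue
        counts[(pair.chrom, start, end, pair.pixel)] += 1
        tally["retained"] += 1
    return [
        FragmentRecord(chrom, start, end, pixel, n)
        for (chrom, start, end, pixel), n in sorted(counts.items())
    ]


def read_tagged_sam(
    path: str | Path, tag: str = "CB", counters: Optional[Counter] = None
) -> Iterator[AlignedPair]:
    """Yield paired templates from a SAM/BAM whose reads carry a pixel tag.

    Mates are joined by query name; the template spans the leftmost start
    to the rightmost end of the primary alignments of the pair, with the
    pair MAPQ taken as the minimum of the two mates.
    """
    tally = counters if counters is not None else Counter()
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                tally["unusable_alignment"] += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            if mate.reference_name != read.reference_name:
                tally["interchromosomal"] += 1
                continue
            pixel = ""
            for r in (read, mate):
                if r.has_tag(tag):
                    pixel = str(r.get_tag(tag))
                    break
            yield AlignedPair(
                chrom=read.reference_name,
                start=min(read.reference_start, mate.reference_start),
                end=max(read.reference_end, mate.reference_end),
                pixel=pixel,
                mapq=min(read.mapping_quality, mate.mapping_quality),
            )
    tally["unpaired"] += len(pending)


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def write_fragments(fragments: Iterable[FragmentRecord], path: str | Path) -> None:
    """Write a position-sorted fragments file (TSV, bgzip-compatible text).

    Columns: chrom, start, end, pixel barcode, duplicate count. Raises if
    the input stream is not sorted by (chrom, start, end, pixel).
    """
    last = None
    with _open_text(path, "wt") as out:
        for frag in fragments:
            key = (frag.chrom, frag.start, frag.end, frag.pixel)
            if last is not None and key < last:
                raise ValueError("fragments must be sorted by (chrom, start, end, pixel)")
            last = key
            out.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\t{frag.pixel}\t{frag.duplicate_count}\n")


def read_fragments(path: str | Path) -> list[FragmentRecord]:
    records = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, pixel, count = line.rstrip("\n").split("\t")
            records.append(FragmentRecord(chrom, int(start), int(end), pixel, int(count)))
    return records


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Plain BED3 intervals (peaks, TSS windows...)."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        for chrom, start, end in intervals:
            out.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# gene models


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Gene models from a GTF (1-based closed converted to 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        )
        models.append(
            GeneModel(
                gene_id=gene.attributes.get("gene_id", [gene.id])[0],
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=exons or [(gene.start - 1, gene.end)],
            )
        )
    return models


class GeneIndex:
    """Interval-tree index over exons for read-to-gene assignment."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            for s, e in g.exons:
                self._trees[(g.chrom, g.strand)].addi(s, e, g.gene_id)

    def overlapping(self, chrom: str, start: int, end: int, strand: Optional[str] = None) -> set[str]:
        hits: set[str] = set()
        strands = "+-" if strand is None else strand
        for st in strands:
            hits |= {iv.data for iv in self._trees[(chrom, st)].overlap(start, end)}
        return hits


def assign_gene(
    interval: tuple[str, int, int],
    index: GeneIndex,
    strand: Optional[str] = None,
    strand_mode: str = "unstranded",
) -> Optional[str]:
    """Assign a read interval to the single gene whose exons it overlaps.

    Returns the gene id, the sentinel ``"ambiguous"`` when exons of two or
    more genes overlap the read, or ``None`` for intergenic reads.
    ``strand_mode="stranded"`` restricts candidates to the read's strand.
    """
    chrom, start, end = interval
    use_strand = strand if strand_mode == "stranded" else None
    hits = index.overlapping(chrom, start, end, use_strand)
    if not hits:
        return None
    if len(hits) > 1:
        return "ambiguous"
    return hits.pop()


# ---------------------------------------------------------------------------
# UMI counting


def _directional_cluster_count(umi_counts: dict[str, int]) -> int:
    """Number of molecules under directional UMI collapse.

    UMI u is absorbed into v when Hamming(u, v) == 1 and
    count(v) >= 2 * count(u) - 1, following the adjacency rule of
    directional network collapse; components grown greedily from
    highest-count nodes.
    """
    umis = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    assigned: set[str] = set()
    n_clusters = 0
    for root in umis:
        if root in assigned:
            continue
        n_clusters += 1
        stack = [root]
        assigned.add(root)
        while stack:
            node = stack.pop()
            for other in umis:
                if other in assigned:
                    continue
                if _hamming1(node, other) and umi_counts[node] >= 2 * umi_counts[other] - 1:
                    assigned.add(other)
                    stack.append(other)
    return n_clusters


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    seen = False
    for x, y in zip(a, b):
        if x != y:
            if seen:
                return False
            seen = True
    return seen


def count_umis(
    triples: Iterable[tuple[str, str, str]],
    collapse_mode: str = "exact",
    pixels: Optional[Sequence[str]] = None,
    modality: str = "rna",
) -> PixelMatrix:
    """UMI-collapsed gene x pixel matrix from (gene, pixel, UMI) triples.

    ``exact`` counts distinct UMIs per (gene, pixel); ``directional``
    additionally merges single-substitution PCR/sequencing artefacts.
    ``pixels`` fixes the column universe (e.g. all on-tissue pixels);
    otherwise columns are the pixels observed.
    """
    if collapse_mode not in ("exact", "directional"):
        raise ValueError(f"unknown collapse mode {collapse_mode!r}")
    per_cell: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for gene, pixel, umi in triples:
        per_cell[(gene, pixel)][umi] += 1

    genes = sorted({g for g, _ in per_cell})
    if pixels is None:
        pixels = sorted({p for _, p in per_cell})
    gene_idx = {g: i for i, g in enumerate(genes)}
    pixel_idx = {p: j for j, p in enumerate(pixels)}

    rows, cols, vals = [], [], []
    for (gene, pixel), umis in per_cell.items():
        if pixel not in pixel_idx:
            continue
        if collapse_mode == "exact":
            n = len(umis)
        else:
            n = _directional_cluster_count(dict(umis))
        rows.append(gene_idx[gene])
        cols.append(pixel_idx[pixel])
        vals.append(n)
    X = sp.coo_matrix((vals, (rows, cols)), shape=(len(genes), len(pixels)), dtype=np.int64)
    return PixelMatrix(genes, list(pixels), X.tocsr(), modality=modality,
                       direction="activating" if modality == "rna" else None)


# ---------------------------------------------------------------------------
# matrix IO (Matrix Market triplet + index TSVs)


def write_matrix(matrix: PixelMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.features.tsv`` / ``<prefix>.pixels.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", sp.coo_matrix(matrix.X))
    Path(str(prefix) + ".features.tsv").write_text("".join(f"{f}\n" for f in matrix.features))
    Path(str(prefix) + ".pixels.tsv").write_text("".join(f"{p}\n" for p in matrix.pixels))


def read_matrix(prefix: str | Path, modality: Optional[str] = None) -> PixelMatrix:
    prefix = str(prefix)
    X = sp.csr_matrix(scipy.io.mmread(prefix + ".mtx"))
    features = Path(prefix + ".features.tsv").read_text().splitlines()
    pixels = Path(prefix + ".pixels.tsv").read_text().splitlines()
    return PixelMatrix(features, pixels, X, modality=modality)
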