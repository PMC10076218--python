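"""Per-pixel and library-level quality-control metrics.

The standard chromatin QC panel for spatial tagmentation data: unique
fragments per pixel, fraction of fragments in peaks (FRiP), fraction near
transcription start sites, insert-size distribution (nucleosomal banding)
and pseudobulk replicate correlation; plus genes/UMIs per pixel on the
RNA side.

A fragment is "in" an interval set iff it overlaps any interval by at
least 1 bp. Fractions are computed on deduplicated fragments by default;
weighting by duplicate count is available but off, and the choice is
recorded in the report header.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .matrices import FragmentRecord, PixelMatrix

__all__ = [
    "merge_intervals",
    "frip",
    "tss_fraction",
    "tss_windows",
    "insert_size_histogram",
    "pixel_summary",
    "pseudobulk_correlation",
    "qc_report",
]

DEFAULT_TSS_WINDOW = 2000


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> dict[str, np.ndarray]:
    """Merge overlapping/abutting intervals; returns per-chrom (n, 2) arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, start, end in intervals:
        if start >= end:
            raise ValueError(f"empty interval ({chrom}, {start}, {end})")
        by_chrom[chrom].append((start, end))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=np.int64)
    return merged


def _overlaps_any(merged: dict[str, np.ndarray], chrom: str, start: int, end: int) -> bool:
    ivs = merged.get(chrom)
    if ivs is None or len(ivs) == 0:
        return False
    # candidate: last interval starting before `end`
    i = int(np.searchsorted(ivs[:, 0], end, side="left")) - 1
    return i >= 0 and ivs[i, 1] > start


def _fraction_in(
    fragments: Sequence[FragmentRecord],
    merged: dict[str, np.ndarray],
    weight_duplicates: bool,
) -> tuple[Optional[float], dict[str, Optional[float]]]:
    total: Counter = Counter()
    hit: Counter = Counter()
    for frag in fragments:
        w = frag.duplicate_count if weight_duplicates else 1
        total[frag.pixel] += w
        if _overlaps_any(merged, frag.chrom, frag.start, frag.end):
            hit[frag.pixel] += w
    grand_total = sum(total.values())
    overall = (sum(hit.values()) / grand_total) if grand_total else None
    per_pixel = {p: hit[p] / n for p, n in total.items()}
    return overall, per_pixel


def frip(
    fragments: Sequence[FragmentRecord],
    peaks: Iterable[tuple[str, int, int]],
    weight_duplicates: bool = False,
) -> tuple[Optional[float], dict[str, float]]:
    """Fraction of fragments in peaks, overall and per pixel.

    Peaks are merged first, so the metric is invariant to peak ordering
    and to splitting a peak into abutting pieces. An empty fragment set is
    undefined and reported as ``None``, never 0.
    """
    return _fraction_in(fragments, merge_intervals(peaks), weight_duplicates)


def tss_windows(
    tss: Iterable[tuple[str, int]], window: int = DEFAULT_TSS_WINDOW
) -> list[tuple[str, int, int]]:
    """TSS positions to +/- window intervals (clipped at 0)."""
    return [(chrom, max(0, pos - window), pos + window + 1) for chrom, pos in tss]


def tss_fraction(
    fragments: Sequence[FragmentRecord],
    tss: Iterable[tuple[str, int]],
    window: int = DEFAULT_TSS_WINDOW,
    weight_duplicates: bool = False,
) -> tuple[Optional[float], dict[str, float]]:
    """Fraction of fragments within +/- ``window`` bp of any TSS."""
    return _fraction_in(fragments, merge_intervals(tss_windows(tss, window)), weight_duplicates)


def insert_size_histogram(
    fragments: Iterable[FragmentRecord], max_len: int = 1000
) -> dict[int, int]:
    """Counts of fragment lengths (end - start), truncated at ``max_len``."""
    hist: Counter = Counter()
    for frag in fragments:
        size = frag.end - frag.start
        if size <= max_len:
            hist[size] += 1
    return dict(sorted(hist.items()))


def pixel_summary(
    fragments: Sequence[FragmentRecord],
    gene_matrix: Optional[PixelMatrix] = None,
    pixels: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-pixel QC table plus distribution summaries.

    Pixels absent from the fragments (but present in ``pixels`` or the
    gene matrix) appear with zero counts.
    """
    unique_frags: Counter = Counter()
    total_frags: Counter = Counter()
    for frag in fragments:
        unique_frags[frag.pixel] += 1
        total_frags[frag.pixel] += frag.duplicate_count

    universe: list[str] = list(pixels) if pixels is not None else []
    if not universe:
        seen = set(unique_frags)
        if gene_matrix is not None:
            seen |= set(gene_matrix.pixels)
        universe = sorted(seen)

    table = pd.DataFrame({
        "pixel": universe,
        "unique_fragments": [unique_frags.get(p, 0) for p in universe],
        "total_fragments": [total_frags.get(p, 0) for p in universe],
    })
    if gene_matrix is not None:
        X = gene_matrix.X.tocsc()
        col = {p: j for j, p in enumerate(gene_matrix.pixels)}
        n_genes, n_umis = [], []
        for p in universe:
            j = col.get(p)
            if j is None:
                n_genes.append(0)
                n_umis.append(0)
            else:
                column = X[:, j]
                n_genes.append(int((column > 0).sum()))
                n_umis.append(int(column.sum()))
        table["n_genes"] = n_genes
        table["n_umis"] = n_umis

    summary = {
        "n_pixels": len(universe),
        "median_unique_fragments": float(table["unique_fragments"].median()) if len(table) else None,
        "mean_unique_fragments": float(table["unique_fragments"].mean()) if len(table) else None,
    }
    if "n_genes" in table:
        summary["mean_genes_per_pixel"] = float(table["n_genes"].mean())
        summary["mean_umis_per_pixel"] = float(table["n_umis"].mean())
        summary["median_umis_per_pixel"] = float(table["n_umis"].median())
    return table, summary


def pseudobulk_correlation(
    matrix_rep1: PixelMatrix,
    matrix_rep2: PixelMatrix,
    transform: str = "log1p",
) -> float:
    """Pearson correlation of pseudobulk (per-feature summed) profiles.

    The replicate-concordance metric: both matrices are collapsed to one
    profile by summing counts per feature over pixels, optionally log1p
    transformed, and correlated over the shared feature space.
    """
    shared = sorted(set(matrix_rep1.features) & set(matrix_rep2.features))
    if len(shared) < 3:
        raise ValueError("replicates share fewer than 3 features")

    def profile(m: PixelMatrix) -> np.ndarray:
        sums = np.asarray(m.X.sum(axis=1)).ravel()
        idx = {f: i for i, f in enumerate(m.features)}
        v = np.array([sums[idx[f]] for f in shared], dtype=float)
        if transform == "log1p":
            v = np.log1p(v)
        elif transform != "none":
            raise ValueError(f"unknown transform {transform!r}")
        return v

    v1, v2 = profile(matrix_rep1), profile(matrix_rep2)
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("zero-variance pseudobulk profile")
    return float(pearsonr(v1, v2).statistic)


def qc_report(
    fragments: Sequence[FragmentRecord],
    peaks: Optional[Iterable[tuple[str, int, int]]] = None,
    tss: Optional[Iterable[tuple[str, int]]] = None,
    gene_matrix: Optional[PixelMatrix] = None,
    tss_window: int = DEFAULT_TSS_WINDOW,
    weight_duplicates: bool = False,
    out_prefix: Optional[str | Path] = None,
) -> dict:
    """Bundle the QC panel into one JSON-serializable report (+ optional files)."""
    table, summary = pixel_summary(fragments, gene_matrix)
    report = {
        "settings": {
            "tss_window_bp": tss_window,
            "overlap_rule": ">=1bp",
            "duplicate_weighting": weight_duplicates,
        },
        "summary": summary,
    }
    if peaks is not None:
        overall, _ = frip(fragments, peaks, weight_duplicates)
        report["frip"] = overall
    if tss is not None:
        overall, _ = tss_fraction(fragments, tss, tss_window, weight_duplicates)
        report["tss_fraction"] = overall
    report["insert_size_histogram"] = {
        str(k): v for k, v in insert_size_histogram(fragments).items()
    }
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(f"{out_prefix}.pixel_qc.tsv", sep="\t", index=False)
        Path(f"{out_prefix}.qc.json").write_text(json.dumps(report, indent=2))
    return report
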