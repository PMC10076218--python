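"""Peak-to-gene linkage and region-wise quadrant concordance analysis.

Two halves:

* **Linkage** — for every (peak, gene) pair with the peak center within a
  genomic window of the gene's TSS, correlate peak signal with gene
  expression across pseudo-groups of pixels (k-means metacells), and call
  links significant by |r| and BH-adjusted p. Across a tissue this
  recovers enhancer-target candidates.

* **Quadrant analysis** — per tissue region, compute region-vs-rest RNA
  marker statistics (Wilcoxon rank-sum on log-normalized counts with
  detection and fold-change prefilters) and the matching epigenetic-score
  enrichment, then classify each gene by the signs of its RNA log2
  fold-change (x axis) and score log2 fold-change (y axis):
  quadrant I = (+,+), II = (-,+), III = (-,-), IV = (+,-). For a
  repressive mark (CSS), quadrant II reads "high silencing, low
  expression" and IV "low silencing, high expression" — the expected
  anticorrelated pattern; quadrant I flags candidate poised/bivalent
  genes. A multi-mark pattern export supports Venn/upset summaries of
  high(+)/low(-) calls across histone modifications.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, pearsonr, rankdata
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .matrices import GeneModel, PixelMatrix

__all__ = [
    "lognormalize",
    "peak_gene_links",
    "rank_sum_p",
    "rank_sum_markers",
    "score_region_enrichment",
    "quadrant_assign",
    "build_quadrant_table",
    "multimark_pattern",
]

QUADRANTS = ("I", "II", "III", "IV")

#: significance defaults for linkage (ArchR-style correlation linkage)
DEFAULT_MAX_DISTANCE = 250_000
DEFAULT_R_CUTOFF = 0.45
DEFAULT_Q_CUTOFF = 0.05
DEFAULT_N_GROUPS = 100

_EXACT_ENUM_LIMIT = 5000  # max C(n, m) enumerated for exact rank-sum p


def lognormalize(X: sp.spmatrix | np.ndarray, target: float = 10_000.0) -> np.ndarray:
    """Counts-per-``target`` + log2(1 + x) normalization (dense).

    Base-2 logs so that differences of group means read directly as log2
    fold changes.
    """
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    depth = X.sum(axis=0)
    scale = np.divide(target, depth, out=np.ones_like(depth), where=depth > 0)
    return np.log2(1.0 + X * scale)


# ---------------------------------------------------------------------------
# peak-to-gene linkage


def _shared_pixels(a: PixelMatrix, b: PixelMatrix) -> list[str]:
    shared = [p for p in a.pixels if p in set(b.pixels)]
    if not shared:
        raise ValueError("matrices share no pixels")
    return shared


def pseudo_group_labels(
    gene_matrix: PixelMatrix, n_groups: int = DEFAULT_N_GROUPS, seed: int = 0
) -> np.ndarray:
    """Deterministic k-means pseudo-grouping of pixels on the log-normalized
    gene matrix (metacell aggregation for correlation stability)."""
    if n_groups < 3:
        raise ValueError("need >= 3 pseudo-groups for correlation")
    X = lognormalize(gene_matrix.X).T  # pixels x genes
    n_groups = min(n_groups, X.shape[0])
    km = KMeans(n_clusters=n_groups, random_state=seed, n_init=10)
    return km.fit_predict(X)


def peak_gene_links(
    peak_matrix: PixelMatrix,
    gene_matrix: PixelMatrix,
    genes: Sequence[GeneModel],
    peaks: dict[str, tuple[str, int, int]],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    r_cutoff: float = DEFAULT_R_CUTOFF,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    n_groups: int = DEFAULT_N_GROUPS,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation linkage of peaks to nearby genes across pixel pseudo-groups.

    Pairs tested: peak center within ``max_distance`` bp of the gene TSS.
    Pixels are aggregated into ``n_groups`` k-means pseudo-groups computed
    on the log-normalized gene matrix (fixed ``seed``, recorded in the
    output attrs); Pearson r and its p-value are computed across group
    mean profiles, with BH FDR over all tested pairs. A link is
    ``significant`` iff |r| >= ``r_cutoff`` and q <= ``q_cutoff``.
    """
    if n_groups < 3:
        raise ValueError("need >= 3 pseudo-groups for correlation")
    shared = _shared_pixels(gene_matrix, peak_matrix)
    gm = gene_matrix.subset_pixels(shared)
    pm = peak_matrix.subset_pixels(shared)

    labels = pseudo_group_labels(gm, n_groups, seed)
    groups = np.unique(labels)
    if len(groups) < 3:
        raise ValueError("fewer than 3 non-empty pseudo-groups")

    G = lognormalize(gm.X)
    P = lognormalize(pm.X)
    gene_means = np.stack([G[:, labels == g].mean(axis=1) for g in groups], axis=1)
    peak_means = np.stack([P[:, labels == g].mean(axis=1) for g in groups], axis=1)

    gene_row = {g: i for i, g in enumerate(gm.features)}
    peak_row = {p: i for i, p in enumerate(pm.features)}

    rows = []
    for gene in genes:
        gi = gene_row.get(gene.gene_id)
        if gi is None:
            continue
        for peak_id, (chrom, start, end) in peaks.items():
            pi = peak_row.get(peak_id)
            if pi is None or chrom != gene.chrom:
                continue
            center = (start + end) // 2
            distance = abs(center - gene.tss)
            if distance > max_distance:
                continue
            x, y = peak_means[pi], gene_means[gi]
            if x.std() == 0 or y.std() == 0:
                continue
            res = pearsonr(x, y)
            rows.append((peak_id, gene.gene_id, distance, res.statistic, res.pvalue))

    links = pd.DataFrame(rows, columns=["peak", "gene", "distance", "r", "p"])
    if len(links):
        links["q"] = multipletests(links["p"], method="fdr_bh")[1]
        links["significant"] = (links["r"].abs() >= r_cutoff) & (links["q"] <= q_cutoff)
    else:
        links["q"] = pd.Series(dtype=float)
        links["significant"] = pd.Series(dtype=bool)
    links.attrs["n_groups"] = int(len(groups))
    links.attrs["seed"] = seed
    links.attrs["max_distance"] = max_distance
    return links


# ---------------------------------------------------------------------------
# rank-sum marker statistics


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for group x vs group y.

    Small samples (C(n1+n2, n1) <= 5000) use the exact permutation null
    of the rank-sum statistic with average ranks for ties, two-sided as
    P(|S - mu| >= |s_obs - mu|); larger samples use the tie-corrected
    normal approximation (Mann-Whitney U with continuity correction off).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    if comb(n1 + n2, n1) <= _EXACT_ENUM_LIMIT:
        ranks = rankdata(pooled)
        mu = n1 * (n1 + n2 + 1) / 2.0
        s_obs = ranks[:n1].sum()
        dev = abs(s_obs - mu)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                hits += 1
        return hits / total
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=False)
    return float(res.pvalue)


def _marker_stats(
    X: np.ndarray,
    features: Sequence[str],
    in_group: np.ndarray,
    min_pct: float,
    logfc_threshold: float,
    adjust_method: str,
    n_total_features: int,
) -> pd.DataFrame:
    """Region-vs-rest marker statistics on a log-normalized dense matrix."""
    out_group = ~in_group
    if in_group.sum() < 2 or out_group.sum() < 2:
        raise ValueError("need >= 2 pixels in the region and in the rest")

    Xin, Xout = X[:, in_group], X[:, out_group]
    pct_in = (Xin > 0).mean(axis=1)
    pct_out = (Xout > 0).mean(axis=1)
    log2fc = Xin.mean(axis=1) - Xout.mean(axis=1)

    tested = np.nonzero(
        (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(log2fc) >= logfc_threshold)
    )[0]
    pvals = np.array([rank_sum_p(Xin[i], Xout[i]) for i in tested])

    if adjust_method == "bonferroni":
        adj = np.minimum(pvals * n_total_features, 1.0)
    elif adjust_method in ("bh", "fdr_bh"):
        adj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    else:
        raise ValueError(f"unknown adjustment {adjust_method!r}")

    return pd.DataFrame({
        "gene": [features[i] for i in tested],
        "log2fc": log2fc[tested],
        "pct_in": pct_in[tested],
        "pct_out": pct_out[tested],
        "p": pvals,
        "p_adj": adj,
    })


def rank_sum_markers(
    matrix: PixelMatrix,
    region_labels: Sequence[str],
    region: str,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    adjust_method: str = "bonferroni",
) -> pd.DataFrame:
    """Region-vs-rest RNA marker genes (Wilcoxon rank-sum).

    Counts are log-normalized (counts-per-10k, log2(1+x)); genes are
    prefiltered by detection fraction >= ``min_pct`` in either group and
    |log2FC| >= ``logfc_threshold`` (log2FC = difference of group means
    of log-normalized values). Adjustment defaults to Bonferroni over all
    features in the matrix; BH is available.
    """
    labels = np.asarray(region_labels)
    if len(labels) != len(matrix.pixels):
        raise ValueError("one region label per pixel required")
    X = lognormalize(matrix.X)
    return _marker_stats(
        X, matrix.features, labels == region, min_pct, logfc_threshold,
        adjust_method, n_total_features=len(matrix.features),
    ).assign(region=region)


def score_region_enrichment(
    score_matrix: PixelMatrix,
    region_labels: Sequence[str],
    region: str,
    fdr_cutoff: float = 0.05,
    log2fc_cutoff: float = 0.1,
    genes: Optional[Iterable[str]] = None,
    normalized: bool = True,
) -> pd.DataFrame:
    """GAS/CSS region-vs-rest enrichment with FDR and fold-change cutoffs.

    The same rank-sum machinery as the RNA markers, applied to a score
    matrix (already normalized by default, so values enter the test
    as-is), restricted to ``genes`` when given (e.g. the RNA marker
    list), BH-adjusted, and filtered to FDR <= ``fdr_cutoff`` and
    |log2FC| >= ``log2fc_cutoff``.
    """
    labels = np.asarray(region_labels)
    if len(labels) != len(score_matrix.pixels):
        raise ValueError("one region label per pixel required")
    X = (
        np.asarray(score_matrix.X.todense(), dtype=float)
        if normalized
        else lognormalize(score_matrix.X)
    )
    table = _marker_stats(
        X, score_matrix.features, labels == region,
        min_pct=0.0, logfc_threshold=0.0, adjust_method="bh",
        n_total_features=len(score_matrix.features),
    )
    if genes is not None:
        gene_set = set(genes)
        table = table[table["gene"].isin(gene_set)].copy()
        if len(table):
            table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    kept = table[(table["p_adj"] <= fdr_cutoff) & (table["log2fc"].abs() >= log2fc_cutoff)]
    return kept.assign(region=region).reset_index(drop=True)


# ---------------------------------------------------------------------------
# quadrants


def quadrant_assign(rna_log2fc: float, score_log2fc: float) -> Optional[str]:
    """Quadrant of a gene from the signs of its RNA and score fold changes.

    x = RNA avg_log2FC, y = score log2FC: I = (+,+), II = (-,+),
    III = (-,-), IV = (+,-). Genes on an axis (either value 0) or with
    non-finite values are unassigned (``None``).
    """
    if not (np.isfinite(rna_log2fc) and np.isfinite(score_log2fc)):
        return None
    if rna_log2fc == 0 or score_log2fc == 0:
        return None
    if rna_log2fc > 0:
        return "I" if score_log2fc > 0 else "IV"
    return "II" if score_log2fc > 0 else "III"


def build_quadrant_table(
    rna_markers: pd.DataFrame,
    score_enrichment: pd.DataFrame,
    region: Optional[str] = None,
) -> pd.DataFrame:
    """Join RNA markers with score enrichment and label quadrants.

    Only genes present in both tables (i.e. passing both sets of cutoffs)
    receive a quadrant.
    """
    merged = rna_markers.merge(
        score_enrichment, on="gene", suffixes=("_rna", "_score")
    )
    merged["rna_log2fc"] = merged["log2fc_rna"]
    merged["score_log2fc"] = merged["log2fc_score"]
    merged["quadrant"] = [
        quadrant_assign(r, s) for r, s in zip(merged["rna_log2fc"], merged["score_log2fc"])
    ]
    cols = ["gene", "rna_log2fc", "score_log2fc", "quadrant"]
    out = merged[cols].copy()
    if region is not None:
        out["region"] = region
    return out


def multimark_pattern(
    mark_tables: dict[str, pd.DataFrame],
    order: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene high(+)/low(-) sign pattern across histone marks.

    ``mark_tables`` maps mark name (e.g. ``"H3K27me3"``) to its
    :func:`score_region_enrichment` output for one region. Genes absent
    from a mark's table get ``.`` in that slot; genes absent from all
    tables are excluded. Returns the per-gene table plus pattern counts
    for Venn/upset-style export.
    """
    marks = list(order) if order is not None else list(mark_tables)
    signs: dict[str, dict[str, str]] = {}
    for mark in marks:
        table = mark_tables[mark]
        signs[mark] = {
            g: ("+" if fc > 0 else "-")
            for g, fc in zip(table["gene"], table["log2fc"])
            if fc != 0
        }
    all_genes = sorted(set().union(*[set(s) for s in signs.values()])) if signs else []
    rows = []
    for gene in all_genes:
        pattern = "".join(signs[mark].get(gene, ".") for mark in marks)
        label = "/".join(
            f"{mark}{signs[mark][gene]}" for mark in marks if gene in signs[mark]
        )
        rows.append((gene, pattern, label))
    table = pd.DataFrame(rows, columns=["gene", "pattern", "label"])
    table.attrs["marks"] = marks
    counts = table["pattern"].value_counts().to_dict() if len(table) else {}
    return table, counts
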