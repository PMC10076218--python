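"""Rank-sum markers, peak-gene linkage, quadrant semantics and multi-mark patterns."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

from coseq import (
    PixelMatrix,
    SimConfig,
    build_quadrant_table,
    multimark_pattern,
    peak_gene_links,
    quadrant_assign,
    rank_sum_markers,
    rank_sum_p,
    score_region_enrichment,
    simulate_coprofiles,
    simulate_multimark,
    simulate_peak_gene,
)
from coseq.links import lognormalize


def _enumeration_oracle(x, y):
    """Exact two-sided rank-sum p by full enumeration (independent code)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    # average ranks computed by counting, not scipy
    ranks = []
    for v in pooled:
        less = sum(1 for w in pooled if w < v)
        equal = sum(1 for w in pooled if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    mu = n1 * (len(pooled) + 1) / 2.0
    dev = abs(sum(ranks[:n1]) - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


class TestRankSumP:
    def test_identical_groups_p_one(self):
        assert rank_sum_p([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_complete_separation_3v3(self):
        # the only two as-extreme outcomes out of C(6,3)=20 assignments
        assert rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("n1", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("n2", [1, 2, 3, 4, 5])
    def test_exact_enumeration_all_small_sizes(self, n1, n2):
        """Agreement with independent enumeration for every group size <= 5,
        with and without ties."""
        rng = np.random.default_rng((n1, n2))
        for trial in range(4):
            values = rng.integers(0, 4, n1 + n2).astype(float)  # heavy ties
            if np.ptp(values) == 0:
                values[0] += 1
            x, y = values[:n1], values[n2:] if False else values[n1:]
            assert rank_sum_p(x, y) == pytest.approx(_enumeration_oracle(x, y), abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(3, 4), (5, 5), (4, 2)])
    def test_matches_scipy_exact_without_ties(self, n1, n2):
        rng = np.random.default_rng((n1, n2, 7))
        x = rng.permutation(np.arange(n1 + n2, dtype=float))[:n1]
        y = np.setdiff1d(np.arange(n1 + n2, dtype=float), x)
        expected = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert rank_sum_p(x, y) == pytest.approx(float(expected), abs=1e-12)

    def test_large_sample_tie_corrected_asymptotic(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 200).astype(float)
        y = rng.integers(0, 5, 200).astype(float) + 0.5
        expected = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                use_continuity=False).pvalue
        assert rank_sum_p(x, y) == pytest.approx(float(expected))


def _matrix_from_counts(X, modality="rna"):
    X = np.asarray(X)
    return PixelMatrix(
        [f"g{i:03d}" for i in range(X.shape[0])],
        [f"{j+1}x1" for j in range(X.shape[1])],
        X,
        modality=modality,
    )


class TestMarkers:
    def test_identical_groups_no_markers(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 20, (30, 1))
        X = np.tile(col, (1, 10))
        m = _matrix_from_counts(X)
        labels = ["A"] * 5 + ["B"] * 5
        out = rank_sum_markers(m, labels, "A", logfc_threshold=0.0)
        assert (out["log2fc"] == 0).all()
        assert (out["p_adj"] == 1.0).all()

    def test_logfc_threshold_excludes_small_effects(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(10.0, (20, 40))
        m = _matrix_from_counts(X)
        labels = ["A"] * 20 + ["B"] * 20
        out = rank_sum_markers(m, labels, "A", logfc_threshold=0.25)
        assert (out["log2fc"].abs() >= 0.25).all()

    def test_min_pct_filter(self):
        X = np.zeros((2, 20))
        X[0, :2] = 5  # detected in 20% of region A only
        X[1] = np.arange(20) + 1
        m = _matrix_from_counts(X)
        labels = ["A"] * 10 + ["B"] * 10
        out = rank_sum_markers(m, labels, "A", min_pct=0.25, logfc_threshold=0.0)
        assert "g000" not in set(out["gene"])

    def test_planted_markers_recovered_with_power(self):
        """|log2FC| = 1 markers at 200 pixels/group reach adjusted P < 1e-5
        with power >= 0.9 (Bonferroni-adjusted rank-sum)."""
        score_m, rna_m, labels, truth = simulate_coprofiles(SimConfig(seed=51))
        out = rank_sum_markers(rna_m, labels, "R1")
        sig = out[out["p_adj"] < 1e-5]
        planted = truth[truth["rna_sign"] != 0]
        recovered = planted["gene"].isin(set(sig["gene"]))
        assert recovered.mean() >= 0.9
        # sign agreement for the recovered markers
        fc = dict(zip(out["gene"], out["log2fc"]))
        signs = [np.sign(fc[g]) for g in planted["gene"][recovered.values]]
        assert signs == list(planted["rna_sign"][recovered.values])

    def test_null_simulation_controls_false_positives(self):
        cfg = SimConfig(seed=52, rna_effect_log2fc=0.0, score_effect_log2fc=0.0)
        _, rna_m, labels, _ = simulate_coprofiles(cfg)
        out = rank_sum_markers(rna_m, labels, "R1")
        assert (out["p_adj"] < 1e-5).sum() == 0


class TestScoreEnrichment:
    def _scored(self, m):
        return PixelMatrix(m.features, m.pixels, lognormalize(m.X), m.modality, m.direction)

    def test_uniform_gene_not_retained(self):
        X = np.tile(np.arange(1, 11).reshape(-1, 1), (1, 20)).astype(float)
        m = _matrix_from_counts(X, "h3k27me3")
        out = score_region_enrichment(m, ["A"] * 10 + ["B"] * 10, "A")
        assert len(out) == 0

    def test_small_fold_change_excluded_by_cutoff(self):
        rng = np.random.default_rng(2)
        X = rng.normal(10, 0.05, (5, 400))
        X[0, :200] += 0.05  # tiny but highly significant shift, log2fc < 0.1
        m = _matrix_from_counts(X, "h3k27me3")
        out = score_region_enrichment(m, ["A"] * 200 + ["B"] * 200, "A")
        assert "g000" not in set(out["gene"])

    def test_planted_shift_retained_at_fdr(self):
        score_m, _, labels, truth = simulate_coprofiles(SimConfig(seed=53))
        out = score_region_enrichment(self._scored(score_m), labels, "R1")
        planted = truth[truth["score_sign"] != 0]
        assert planted["gene"].isin(set(out["gene"])).mean() >= 0.9
        assert (out["p_adj"] <= 0.05).all()
        assert (out["log2fc"].abs() >= 0.1).all()


class TestQuadrants:
    @pytest.mark.parametrize("rna,score,expected", [
        (1.2, 0.5, "I"),     # both up
        (-0.8, 0.3, "II"),   # high score (e.g. CSS), low RNA
        (-0.8, -0.3, "III"),
        (0.9, -0.2, "IV"),   # low score, high RNA
    ])
    def test_sign_convention(self, rna, score, expected):
        assert quadrant_assign(rna, score) == expected

    def test_axis_values_unassigned(self):
        assert quadrant_assign(0.0, 1.0) is None
        assert quadrant_assign(1.0, 0.0) is None
        assert quadrant_assign(np.nan, 1.0) is None

    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_partition_and_negation_symmetry(self, x, y):
        q = quadrant_assign(x, y)
        if x == 0 or y == 0:
            assert q is None
        else:
            assert q in {"I", "II", "III", "IV"}
            swap = {"I": "III", "III": "I", "II": "IV", "IV": "II"}
            assert quadrant_assign(-x, -y) == swap[q]

    def test_quadrant_table_recovers_planted_labels(self):
        """Full quadrant pipeline recovers >= 90% of planted labels at
        |log2FC| = 1, 200 pixels/region (repressive-mark layout: mostly
        II and IV, bivalent minority in I)."""
        score_m, rna_m, labels, truth = simulate_coprofiles(SimConfig(seed=54))
        markers = rank_sum_markers(rna_m, labels, "R1")
        markers = markers[markers["p_adj"] < 1e-5]
        scored = PixelMatrix(score_m.features, score_m.pixels, lognormalize(score_m.X),
                             score_m.modality, score_m.direction)
        enrich = score_region_enrichment(scored, labels, "R1", genes=markers["gene"])
        table = build_quadrant_table(markers, enrich, "R1")
        planted = truth[truth["expected_quadrant"].notna()].set_index("gene")
        assigned = table.set_index("gene")["quadrant"]
        hits = sum(
            1 for g, q in planted["expected_quadrant"].items()
            if g in assigned.index and assigned[g] == q
        )
        assert hits / len(planted) >= 0.9
        # no planted gene lands in the wrong quadrant
        wrong = [
            g for g, q in planted["expected_quadrant"].items()
            if g in assigned.index and assigned[g] != q
        ]
        assert wrong == []


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(seed=55)
    return simulate_peak_gene(cfg), cfg


class TestPeakGeneLinks:
    def test_planted_couplings_recovered(self, planted):
        (peak_m, gene_m, genes, peaks, truth), cfg = planted
        links = peak_gene_links(peak_m, gene_m, genes, peaks, seed=0)
        sig = links[links["significant"]]
        coupled = truth[truth["coupled"]]
        found = coupled.merge(sig, on=["peak", "gene"])
        assert len(found) / len(coupled) >= 0.9
        assert (found["r"] >= 0.9).all()
        assert (found["q"] <= 0.05).all()

    def test_distance_window_excludes_far_peak(self, planted):
        (peak_m, gene_m, genes, peaks, truth), cfg = planted
        links = peak_gene_links(peak_m, gene_m, genes, peaks, seed=0)
        assert "peak_far" not in set(links["peak"])  # 450 kb > 250 kb window

    def test_permuted_matrix_yields_fdr_consistent_links(self, planted):
        (peak_m, gene_m, genes, peaks, truth), cfg = planted
        rng = np.random.default_rng(99)
        perm = rng.permutation(len(gene_m.pixels))
        gene_perm = PixelMatrix(
            gene_m.features, gene_m.pixels, gene_m.dense()[:, perm], "rna"
        )
        links = peak_gene_links(peak_m, gene_perm, genes, peaks, seed=0)
        assert links["significant"].mean() <= 0.05

    def test_too_few_groups_rejected(self, planted):
        (peak_m, gene_m, genes, peaks, _), cfg = planted
        with pytest.raises(ValueError, match="groups"):
            peak_gene_links(peak_m, gene_m, genes, peaks, n_groups=2)

    def test_bh_adjustment_monotone_and_bounded(self, planted):
        (peak_m, gene_m, genes, peaks, _), cfg = planted
        links = peak_gene_links(peak_m, gene_m, genes, peaks, seed=0)
        assert links["q"].between(0, 1).all()
        ordered = links.sort_values("p")
        assert (np.diff(np.maximum.accumulate(ordered["q"].to_numpy())) >= -1e-12).all()
        same_p = links.groupby("p")["q"].nunique()
        assert (same_p == 1).all()


class TestMultimark:
    def test_pattern_construction_and_counts(self):
        tables = {
            "h3k27me3": pd.DataFrame({"gene": ["a", "b"], "log2fc": [-1.0, 0.5]}),
            "h3k27ac": pd.DataFrame({"gene": ["a", "c"], "log2fc": [0.7, 0.2]}),
            "h3k4me3": pd.DataFrame({"gene": ["a"], "log2fc": [1.1]}),
        }
        table, counts = multimark_pattern(tables, order=["h3k27me3", "h3k27ac", "h3k4me3"])
        row = table.set_index("gene")
        assert row.loc["a", "pattern"] == "-++"
        assert row.loc["a", "label"] == "h3k27me3-/h3k27ac+/h3k4me3+"
        assert row.loc["b", "pattern"] == "+.."
        assert counts["-++"] == 1

    def test_gene_absent_from_all_tables_excluded(self):
        tables = {"m1": pd.DataFrame({"gene": [], "log2fc": []})}
        table, counts = multimark_pattern(tables)
        assert len(table) == 0 and counts == {}

    def test_planted_anticorrelated_design_recovered_exactly(self):
        """Active genes come out H3K4me3+/H3K27ac+/H3K27me3-, repressed the
        mirror image, bivalent H3K4me3+/H3K27me3+; the pattern sets match
        the planted classes exactly after strict RNA preselection."""
        marks, rna, labels, truth = simulate_multimark(SimConfig(seed=56))
        rna_markers = rank_sum_markers(rna, labels, "R1")
        marker_genes = set(rna_markers[rna_markers["p_adj"] < 1e-5]["gene"])
        tables = {}
        for mark, m in marks.items():
            scored = PixelMatrix(m.features, m.pixels, lognormalize(m.X), m.modality, m.direction)
            tables[mark] = score_region_enrichment(scored, labels, "R1", genes=marker_genes)
        table, counts = multimark_pattern(tables, order=["h3k4me3", "h3k27ac", "h3k27me3"])
        patterns = dict(zip(table["gene"], table["pattern"]))
        expected = {"active": "++-", "repressed": "--+"}
        for cls, pattern in expected.items():
            genes = truth[truth["class"] == cls]["gene"]
            assert sorted(g for g, p in patterns.items() if p == pattern) == sorted(genes)
        # bivalent genes: planted slots (H3K4me3 and H3K27me3) both high; the
        # unplanted H3K27ac slot is unconstrained. Detection through the strict
        # RNA preselection has power >= 0.9, not 1.
        planted = list(truth[truth["class"] != "null"]["gene"])
        assert sum(g in patterns for g in planted) / len(planted) >= 0.9
        for g in truth[truth["class"] == "bivalent"]["gene"]:
            if g in patterns:
                assert patterns[g][0] == "+" and patterns[g][2] == "+"
        # null genes never enter the pattern table (blocked by RNA preselection)
        assert not set(truth[truth["class"] == "null"]["gene"]) & set(patterns)
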