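"""QC metrics against brute-force interval oracles and planted simulations."""

import numpy as np
import pytest

from coseq import (
    FragmentRecord,
    PixelGrid,
    PixelMatrix,
    SimConfig,
    build_fragments,
    count_umis,
    frip,
    insert_size_histogram,
    make_toy_genome,
    pixel_summary,
    pseudobulk_correlation,
    simulate_fragments,
    tss_fraction,
)
from coseq.qc import tss_windows


def _overlap_oracle(fragments, intervals):
    """Brute-force >=1 bp overlap fraction (independent double loop)."""
    if not fragments:
        return None
    hits = 0
    for f in fragments:
        for chrom, s, e in intervals:
            if f.chrom == chrom and f.start < e and s < f.end:
                hits += 1
                break
    return hits / len(fragments)


def _random_fixture(rng):
    frags = [
        FragmentRecord(
            f"chr{rng.integers(1, 3)}", int(s), int(s) + int(rng.integers(30, 400)),
            f"{rng.integers(1, 5)}x{rng.integers(1, 5)}",
        )
        for s in rng.integers(0, 50_000, int(rng.integers(1, 60)))
    ]
    peaks = [
        (f"chr{rng.integers(1, 3)}", int(s), int(s) + int(rng.integers(100, 2_000)))
        for s in rng.integers(0, 50_000, int(rng.integers(1, 12)))
    ]
    return frags, peaks


class TestFrip:
    def test_all_in_peaks(self):
        frags = [FragmentRecord("chr1", 100, 200, "1x1")] * 1  # single fragment inside
        assert frip(frags, [("chr1", 0, 1000)])[0] == 1.0

    def test_no_overlap(self):
        frags = [FragmentRecord("chr1", 100, 200, "1x1")]
        assert frip(frags, [("chr1", 500, 1000)])[0] == 0.0

    def test_empty_fragments_undefined(self):
        assert frip([], [("chr1", 0, 100)])[0] is None

    def test_matches_brute_force_on_random_fixtures(self):
        """100 random fixtures: exact agreement with the double-loop oracle."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            frags, peaks = _random_fixture(rng)
            measured, _ = frip(frags, peaks)
            assert measured == pytest.approx(_overlap_oracle(frags, peaks), abs=0)

    def test_planted_quarter_overlap(self):
        """13 of 50 fragments overlapping -> 0.26 (the real-data FRiP scale)."""
        frags = [FragmentRecord("chr1", 10_000 + 500 * i, 10_100 + 500 * i, "1x1") for i in range(37)]
        frags += [FragmentRecord("chr1", 100 * i, 100 * i + 50, "1x1") for i in range(13)]
        peaks = [("chr1", 0, 1400)]
        assert frip(frags, peaks)[0] == pytest.approx(0.26)
        assert _overlap_oracle(frags, peaks) == pytest.approx(0.26)

    def test_invariant_to_peak_order_and_split(self):
        rng = np.random.default_rng(5)
        frags, peaks = _random_fixture(rng)
        base = frip(frags, peaks)[0]
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        assert frip(frags, shuffled)[0] == base
        split = []
        for chrom, s, e in peaks:
            mid = (s + e) // 2
            split += [(chrom, s, mid), (chrom, mid, e)] if mid > s else [(chrom, s, e)]
        assert frip(frags, split)[0] == base

    def test_per_pixel_fractions_bounded(self):
        rng = np.random.default_rng(6)
        frags, peaks = _random_fixture(rng)
        _, per_pixel = frip(frags, peaks)
        assert all(0.0 <= v <= 1.0 for v in per_pixel.values())


class TestTssFraction:
    def test_fragment_on_tss_counted(self):
        frags = [FragmentRecord("chr1", 4_950, 5_050, "1x1")]
        assert tss_fraction(frags, [("chr1", 5_000)], window=2000)[0] == 1.0

    def test_fragment_beyond_window_not_counted(self):
        frags = [FragmentRecord("chr1", 10_000, 10_100, "1x1")]
        assert tss_fraction(frags, [("chr1", 5_000)], window=2000)[0] == 0.0

    def test_matches_oracle_via_windows(self):
        rng = np.random.default_rng(8)
        frags, _ = _random_fixture(rng)
        tss = [("chr1", int(p)) for p in rng.integers(0, 50_000, 5)]
        measured, _ = tss_fraction(frags, tss, window=1500)
        assert measured == pytest.approx(_overlap_oracle(frags, tss_windows(tss, 1500)))

    def test_planted_tss_fraction_recovered(self, toy_genome):
        """TSS mixture weight 0.2 recovered within 3 binomial sds (+ small
        background-in-window allowance)."""
        genes, peaks, length = toy_genome
        cfg = SimConfig(seed=31)
        templates, truth = simulate_fragments(
            cfg, PixelGrid(5, 5), genes, peaks, length, n_fragments=5000
        )
        frags = build_fragments(templates, shift=(0, 0))
        measured, _ = tss_fraction(frags, [(g.chrom, g.tss) for g in genes])
        p = cfg.mixture_weights["tss"]
        sd = (p * (1 - p) / 5000) ** 0.5
        # background fragments can also fall in TSS windows: one-sided slack
        window_coverage = len(genes) * 4001 / length
        assert p - 3 * sd <= measured <= p + 3 * sd + window_coverage + 0.01


class TestInsertSizes:
    def test_histogram_counts(self):
        frags = [
            FragmentRecord("chr1", 0, 100, "1x1"),
            FragmentRecord("chr1", 50, 150, "1x1"),
            FragmentRecord("chr1", 0, 200, "1x1"),
        ]
        assert insert_size_histogram(frags) == {100: 2, 200: 1}

    def test_empty_input(self):
        assert insert_size_histogram([]) == {}

    def test_total_equals_fragment_count_with_truncation(self):
        frags = [FragmentRecord("chr1", 0, 100, "1x1"), FragmentRecord("chr1", 0, 5000, "1x1")]
        hist = insert_size_histogram(frags, max_len=1000)
        assert sum(hist.values()) == 1  # the 5 kb fragment is truncated away

    def test_bimodal_nucleosomal_mixture(self, toy_genome):
        """Sub- and mono-nucleosomal planted modes land within 10 bp."""
        genes, peaks, length = toy_genome
        cfg = SimConfig(seed=32)
        templates, _ = simulate_fragments(
            cfg, PixelGrid(5, 5), genes, peaks, length, n_fragments=8000
        )
        frags = build_fragments(templates, shift=(0, 0))
        hist = insert_size_histogram(frags, max_len=500)
        dense = np.zeros(501)
        for size, n in hist.items():
            dense[size] = n
        smooth = np.convolve(dense, np.ones(11) / 11, mode="same")
        short_mode = np.argmax(smooth[:130])
        long_mode = 130 + np.argmax(smooth[130:])
        assert abs(short_mode - cfg.insert_means[0]) <= 10
        assert abs(long_mode - cfg.insert_means[1]) <= 10
        assert sum(hist.values()) == sum(1 for f in frags if f.end - f.start <= 500)


class TestPixelSummary:
    def test_median_of_planted_counts(self):
        frags = (
            [FragmentRecord("chr1", i * 10, i * 10 + 5, "1x1") for i in range(10)]
            + [FragmentRecord("chr1", i * 10, i * 10 + 5, "1x2") for i in range(20)]
            + [FragmentRecord("chr1", i * 10, i * 10 + 5, "1x3") for i in range(30)]
        )
        table, summary = pixel_summary(frags)
        assert summary["median_unique_fragments"] == 20

    def test_absent_pixel_reports_zero(self):
        frags = [FragmentRecord("chr1", 0, 100, "1x1")]
        table, _ = pixel_summary(frags, pixels=["1x1", "9x9"])
        assert table.set_index("pixel").loc["9x9", "unique_fragments"] == 0

    def test_gene_matrix_columns(self):
        m = count_umis([("g1", "1x1", "AAAA"), ("g2", "1x1", "CCCC"), ("g1", "2x1", "AAAA")])
        table, summary = pixel_summary([], gene_matrix=m)
        row = table.set_index("pixel")
        assert row.loc["1x1", "n_genes"] == 2 and row.loc["1x1", "n_umis"] == 2
        assert row.loc["2x1", "n_genes"] == 1
        assert summary["mean_umis_per_pixel"] == pytest.approx(1.5)

    def test_simulated_per_pixel_rates_within_5pct(self, toy_genome):
        genes, peaks, length = toy_genome
        cfg = SimConfig(seed=33, duplicate_rate=0.0)
        grid = PixelGrid(5, 5)
        templates, truth = simulate_fragments(cfg, grid, genes, peaks, length, n_fragments=20_000)
        frags = build_fragments(templates, shift=(0, 0))
        _, summary = pixel_summary(frags, pixels=grid.pixel_ids())
        planted_per_pixel = 20_000 / 25
        assert abs(summary["median_unique_fragments"] - planted_per_pixel) / planted_per_pixel < 0.05


class TestPseudobulkCorrelation:
    def _matrix(self, X):
        X = np.atleast_2d(np.asarray(X))
        return PixelMatrix(
            [f"g{i}" for i in range(X.shape[0])],
            [f"{j+1}x1" for j in range(X.shape[1])],
            X,
        )

    def test_identical_profiles(self):
        m = self._matrix(np.random.default_rng(0).integers(0, 50, (20, 4)))
        assert pseudobulk_correlation(m, m) == pytest.approx(1.0)

    def test_reversed_profile_anticorrelated(self):
        m1 = self._matrix(np.array([[1], [2], [3]]))
        m2 = self._matrix(np.array([[3], [2], [1]]))
        assert pseudobulk_correlation(m1, m2, transform="none") == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        m1 = self._matrix(np.ones((5, 2)))
        m2 = self._matrix(np.arange(10).reshape(5, 2))
        with pytest.raises(ValueError, match="variance"):
            pseudobulk_correlation(m1, m2)

    def test_multinomial_replicates_highly_correlated(self):
        """Two depth-1e6 multinomial resamples of one expression profile
        reproduce the replicate-concordance analysis (r >= 0.95)."""
        rng = np.random.default_rng(9)
        rates = rng.lognormal(0, 1.5, 500)
        rates /= rates.sum()
        rep1 = rng.multinomial(1_000_000, rates).reshape(-1, 1)
        rep2 = rng.multinomial(1_000_000, rates).reshape(-1, 1)
        r = pseudobulk_correlation(self._matrix(rep1), self._matrix(rep2))
        assert r >= 0.95
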