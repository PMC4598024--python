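"""TGS window counting, normalization, target calling and profiles."""

import numpy as np
import pytest

import occutarget as ot
from occutarget.occupancy import WindowSpec


def brute_force_read_tgs(reads, genes, half_width):
    """Naive all-pairs containment count on read midpoints."""
    mids = np.array([r.midpoint for r in reads])
    chroms = np.array([r.chrom for r in reads])
    out = {}
    for g in genes:
        lo, hi = g.tss - half_width, g.tss + half_width
        out[g.gene_id] = float(
            np.sum((chroms == g.chrom) & (mids >= lo) & (mids < hi))
        )
    return out


def brute_force_peak_tgs(peaks, genes, half_width, use_count=False):
    out = {}
    for g in genes:
        lo, hi = g.tss - half_width, g.tss + half_width
        total = 0.0
        for p in peaks:
            if p.chrom == g.chrom and lo <= p.summit < hi:
                total += 1.0 if use_count else p.signal
        out[g.gene_id] = total
    return out


class TestComputeTgs:
    def test_zero_reads_all_zero(self, three_genes):
        scores = ot.compute_tgs([], three_genes)
        assert scores == {"g1": 0.0, "g2": 0.0, "g3": 0.0}

    def test_half_open_window_boundaries(self):
        gene = ot.GeneAnnotation("g1", "G1", "chr1", "+", 50_000)
        reads = [
            ot.Interval("chr1", m - 10, m + 10) for m in (39_999, 40_000, 59_999, 60_000)
        ]
        scores = ot.compute_tgs(reads, [gene], WindowSpec(half_width=10_000))
        assert scores["g1"] == 2.0  # 40,000 and 59,999 in [40,000, 60,000)

    def test_other_chromosome_contributes_zero(self, three_genes):
        reads = [ot.Interval("chr1", 49_990, 50_010)]
        scores = ot.compute_tgs(reads, three_genes)
        assert scores["g1"] == 1.0 and scores["g3"] == 0.0

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ot.compute_tgs([], [])

    def test_matches_brute_force_on_planted_instance(self, seed7_bundle):
        _, genes, _, reads, _ = seed7_bundle
        fast = ot.compute_tgs(reads, genes, WindowSpec(half_width=10_000))
        assert fast == brute_force_read_tgs(reads, genes, 10_000)

    def test_monotone_in_half_width(self, seed7_bundle):
        _, genes, _, reads, _ = seed7_bundle
        narrow = ot.compute_tgs(reads, genes, WindowSpec(half_width=5_000))
        wide = ot.compute_tgs(reads, genes, WindowSpec(half_width=10_000))
        assert all(wide[g] >= narrow[g] for g in narrow)

    def test_strand_reflection_symmetry(self, seed7_bundle):
        """Reflecting all coordinates through a fixed point and flipping
        strands leaves TGS unchanged."""
        config, genes, _, reads, _ = seed7_bundle
        pivot = config.chrom_length
        flip = {"+": "-", "-": "+", ".": "."}
        # reflect [start, end) -> [2*pivot - end, 2*pivot - start)
        r_reads = [
            ot.Interval(r.chrom, 2 * pivot - r.end, 2 * pivot - r.start, flip[r.strand])
            for r in reads
        ]
        r_genes = [
            ot.GeneAnnotation(
                g.gene_id, g.gene_name, g.chrom, flip[g.strand],
                2 * pivot - g.tss, g.is_rp, g.is_dba,
            )
            for g in genes
        ]
        orig = ot.compute_tgs(reads, genes)
        # reflected midpoint of even-length reads shifts by the parity of the
        # reflection; window is symmetric so counts are preserved exactly for
        # the +/-10kb window used here
        refl = ot.compute_tgs(r_reads, r_genes)
        assert orig == refl


class TestPeakTgs:
    def test_summit_inside_window_sums_signal(self):
        gene = ot.GeneAnnotation("g1", "G1", "chr1", "+", 50_000)
        peak = ot.Peak("chr1", 48_000, 52_000, "p", 5.5, summit_offset=2_100)
        assert ot.compute_tgs_from_peaks([peak], [gene])["g1"] == 5.5

    def test_summit_outside_window_ignored(self):
        # peak overlaps the window but its summit lies outside
        gene = ot.GeneAnnotation("g1", "G1", "chr1", "+", 50_000)
        peak = ot.Peak("chr1", 55_000, 70_000, "p", 5.5, summit_offset=14_000)
        assert ot.compute_tgs_from_peaks([peak], [gene])["g1"] == 0.0

    def test_count_mode(self):
        gene = ot.GeneAnnotation("g1", "G1", "chr1", "+", 50_000)
        peaks = [
            ot.Peak("chr1", 48_000, 52_000, "a", 5.5, 2_000),
            ot.Peak("chr1", 49_000, 51_000, "b", 2.5, 1_000),
        ]
        assert ot.compute_tgs_from_peaks(peaks, [gene], use_count=True)["g1"] == 2.0

    def test_matches_brute_force_on_random_peaks(self):
        rng = np.random.default_rng(9)
        genes = [
            ot.GeneAnnotation(f"g{i}", f"G{i}", "chr1", "+", int(t))
            for i, t in enumerate(rng.integers(20_000, 2_000_000, size=100))
        ]
        peaks = []
        for i in range(300):
            start = int(rng.integers(0, 2_000_000))
            width = int(rng.integers(100, 2_000))
            peaks.append(
                ot.Peak("chr1", start, start + width, f"p{i}",
                        float(rng.uniform(0, 50)), int(rng.integers(0, width)))
            )
        fast = ot.compute_tgs_from_peaks(peaks, genes)
        assert fast == pytest.approx(brute_force_peak_tgs(peaks, genes, 10_000))

    def test_unit_signal_midpoint_peaks_equal_read_tgs(self, seed7_bundle):
        """Peaks with signal 1 and summit at read midpoints reproduce the
        read-based TGS."""
        _, genes, _, reads, _ = seed7_bundle
        peaks = [
            ot.Peak(r.chrom, r.start, r.end, "p", 1.0,
                    summit_offset=r.midpoint - r.start)
            for r in reads[:5_000]
        ]
        read_scores = ot.compute_tgs(reads[:5_000], genes)
        peak_scores = ot.compute_tgs_from_peaks(peaks, genes)
        assert read_scores == peak_scores


class TestNormalizeAndCall:
    def test_constant_scores_normalize_to_one(self):
        assert ot.normalize_tgs({"a": 2, "b": 2, "c": 2}) == {"a": 1, "b": 1, "c": 1}

    def test_zero_and_four(self):
        assert ot.normalize_tgs({"a": 0, "b": 4}) == {"a": 0.0, "b": 2.0}

    @pytest.mark.parametrize("seed", range(10))
    def test_mean_over_universe_is_one(self, seed):
        rng = np.random.default_rng(seed)
        raw = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0, 50, size=200))}
        norm = ot.normalize_tgs(raw)
        assert np.mean(list(norm.values())) == pytest.approx(1.0, abs=1e-12)

    def test_universe_subset_controls_mean(self):
        raw = {"a": 1.0, "b": 3.0, "c": 100.0}
        norm = ot.normalize_tgs(raw, universe={"a", "b"})
        assert norm == {"a": 0.5, "b": 1.5, "c": 50.0}

    def test_all_zero_scores_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            ot.normalize_tgs({"a": 0.0, "b": 0.0})

    def test_threshold_is_strict(self):
        assert ot.call_targets({"a": 1.0, "b": 1.0 + 1e-9, "c": 0.5}) == {"b"}

    def test_scale_invariance_of_target_calls(self, seed7_bundle):
        _, genes, _, reads, _ = seed7_bundle
        raw = ot.compute_tgs(reads, genes)
        base = ot.call_targets(ot.normalize_tgs(raw))
        scaled = ot.call_targets(ot.normalize_tgs({g: 3.7 * v for g, v in raw.items()}))
        assert base == scaled

    def test_score_dataset_bundles_flags(self):
        scores = ot.score_dataset({"a": 0.0, "b": 4.0})
        by_id = {s.gene_id: s for s in scores}
        assert by_id["b"].is_target and not by_id["a"].is_target


class TestTssProfile:
    def test_zero_reads_zero_vector(self):
        gene = ot.GeneAnnotation("g1", "G1", "chr1", "+", 50_000)
        prof = ot.tss_profile([], gene, library_size=10)
        assert len(prof.values) == 60 and set(prof.values) == {0.0}

    def test_single_read_at_tss(self):
        gene = ot.GeneAnnotation("g1", "G1", "chr1", "+", 50_000)
        prof = ot.tss_profile(
            [ot.Interval("chr1", 49_990, 50_010)], gene, library_size=1
        )
        assert prof.values[30] == 1e6  # bin containing offset 0
        assert sum(prof.values) == 1e6

    def test_minus_strand_profile_reversed(self):
        plus = ot.GeneAnnotation("g1", "G1", "chr1", "+", 50_000)
        minus = ot.GeneAnnotation("g1", "G1", "chr1", "-", 50_000)
        reads = [ot.Interval("chr1", 48_990, 49_010)]  # 1 kb upstream of + gene
        p_plus = ot.tss_profile(reads, plus, library_size=1)
        p_minus = ot.tss_profile(reads, minus, library_size=1)
        assert p_plus.values == p_minus.values[::-1]

    def test_matches_naive_binning(self, seed7_bundle):
        _, genes, occupied, reads, _ = seed7_bundle
        gene = next(g for g in genes if g.gene_id in occupied and g.strand == "+")
        prof = ot.tss_profile(reads, gene, library_size=len(reads))
        counts = np.zeros(60)
        for r in reads:
            off = r.midpoint - gene.tss
            if -1_500 <= off < 1_500:
                counts[(off + 1_500) // 50] += 1
        assert list(prof.values) == pytest.approx(list(counts * 1e6 / len(reads)))

    def test_bin_width_must_divide(self):
        gene = ot.GeneAnnotation("g1", "G1", "chr1", "+", 50_000)
        with pytest.raises(ValueError, match="divide"):
            ot.tss_profile([], gene, half_width=1_500, bin_width=70, library_size=1)
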