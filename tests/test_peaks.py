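"""Peak classification, binding-difference scoring, motif windows, profiles."""

import numpy as np
import pytest

import chipxpress as cx
from chipxpress.errors import (
    DegenerateNormalizationError,
    ValidationError,
)
from chipxpress.io import CoverageTrack
from chipxpress.peaks import COMMON, UNIQUE_MUT, UNIQUE_WT

from conftest import make_count_table, make_peak, random_peaks


def brute_force_overlap(peaks_wt, peaks_mut, min_overlap_bp=1):
    """All-pairs overlap oracle (numpy broadcasting over every wt/mut pair)."""
    labels_wt = {p.peak_id: UNIQUE_WT for p in peaks_wt}
    labels_mut = {p.peak_id: UNIQUE_MUT for p in peaks_mut}
    pairs = set()
    for p in peaks_wt:
        for q in peaks_mut:
            if p.chrom != q.chrom:
                continue
            if min(p.end, q.end) - max(p.start, q.start) >= min_overlap_bp:
                labels_wt[p.peak_id] = COMMON
                labels_mut[q.peak_id] = COMMON
                pairs.add((p.peak_id, q.peak_id))
    return labels_wt, labels_mut, pairs


class TestClassifyPeakOverlap:
    def test_empty_mut_set_makes_all_wt_unique(self):
        wt = [make_peak("chr1", 0, 100, "a"), make_peak("chr1", 200, 300, "b")]
        res = cx.classify_peak_overlap(wt, [])
        assert all(v == UNIQUE_WT for v in res.labels_wt.values())
        assert res.pairs == []

    def test_hand_worked_mixed_example(self):
        wt = [make_peak("chr1", 100, 200, "w1"), make_peak("chr1", 500, 600, "w2")]
        mut = [make_peak("chr1", 150, 250, "m1"), make_peak("chr1", 800, 900, "m2")]
        res = cx.classify_peak_overlap(wt, mut)
        assert res.labels_wt == {"w1": COMMON, "w2": UNIQUE_WT}
        assert res.labels_mut == {"m1": COMMON, "m2": UNIQUE_MUT}
        assert res.pairs == [("w1", "m1")]

    def test_min_overlap_threshold_applies(self):
        wt = [make_peak("chr1", 100, 200, "w1")]
        mut = [make_peak("chr1", 195, 300, "m1")]  # 5 bp overlap
        assert cx.classify_peak_overlap(wt, mut, 5).labels_wt["w1"] == COMMON
        assert cx.classify_peak_overlap(wt, mut, 6).labels_wt["w1"] == UNIQUE_WT

    def test_invalid_min_overlap_rejected(self):
        with pytest.raises(ValidationError):
            cx.classify_peak_overlap([], [], min_overlap_bp=0)

    def test_duplicate_ids_rejected(self):
        wt = [make_peak("chr1", 0, 10, "a"), make_peak("chr1", 20, 30, "a")]
        with pytest.raises(ValidationError, match="duplicate"):
            cx.classify_peak_overlap(wt, [])

    def test_matches_brute_force_on_random_instances(self, rng):
        for trial in range(30):
            wt = random_peaks(rng, int(rng.integers(0, 100)), prefix="w")
            mut = random_peaks(rng, int(rng.integers(0, 100)), prefix="m")
            min_ov = int(rng.integers(1, 50))
            res = cx.classify_peak_overlap(wt, mut, min_ov)
            lw, lm, pairs = brute_force_overlap(wt, mut, min_ov)
            assert res.labels_wt == lw
            assert res.labels_mut == lm
            assert set(res.pairs) == pairs


class TestSqrtScaledDifference:
    def test_identical_cpm_gives_zero(self):
        table = make_count_table([4, 16, 3], [4, 16, 3])
        assert all(s.d == pytest.approx(0.0) for s in cx.sqrt_scaled_difference(table))

    def test_hand_evaluated_two_peak_example(self):
        # means: wt 10, mut 1 -> d = (1 - sqrt(0.4), 1 - sqrt(1.6))
        table = make_count_table([4, 16], [1, 1])
        d = [s.d for s in cx.sqrt_scaled_difference(table)]
        assert d[0] == pytest.approx(1 - np.sqrt(0.4), abs=1e-12)
        assert d[1] == pytest.approx(1 - np.sqrt(1.6), abs=1e-12)

    def test_invariant_under_genotype_rescaling(self, rng):
        cpm_wt = rng.integers(1, 500, size=40).astype(float)
        cpm_mut = rng.integers(1, 500, size=40).astype(float)
        base = make_count_table(cpm_wt, cpm_mut, library_size=1_000_000)
        # rescale each genotype's CPM via its library size (k_wt=7, k_mut=3)
        scaled = cx.PeakCountTable(
            base.counts,
            {"wt_1": 7_000_000, "mut_1": 3_000_000},
            base.genotypes,
        )
        d0 = np.array([s.d for s in cx.sqrt_scaled_difference(base)])
        d1 = np.array([s.d for s in cx.sqrt_scaled_difference(scaled)])
        assert np.abs(d0 - d1).max() < 1e-9

    def test_genotype_exchange_negates_scores(self, rng):
        cpm_wt = rng.integers(0, 500, size=30).astype(float)
        cpm_mut = rng.integers(1, 500, size=30).astype(float)
        cpm_wt[0] = 1.0  # keep both genotype means nonzero
        fwd = make_count_table(cpm_wt, cpm_mut)
        rev = make_count_table(cpm_mut, cpm_wt)
        d_fwd = np.array([s.d for s in cx.sqrt_scaled_difference(fwd)])
        d_rev = np.array([s.d for s in cx.sqrt_scaled_difference(rev)])
        assert np.allclose(d_fwd, -d_rev, atol=1e-12)

    def test_sum_equals_sqrt_scaled_total_difference(self, rng):
        # sum d = sum sqrt(cpm_mut/mean_mut) - sum sqrt(cpm_wt/mean_wt)
        cpm_wt = rng.integers(1, 500, size=25).astype(float)
        cpm_mut = rng.integers(1, 500, size=25).astype(float)
        table = make_count_table(cpm_wt, cpm_mut)
        mean_cpm = table.genotype_mean_cpm()
        expected = (
            np.sqrt(mean_cpm["mut"] / mean_cpm["mut"].mean()).sum()
            - np.sqrt(mean_cpm["wt"] / mean_cpm["wt"].mean()).sum()
        )
        total = sum(s.d for s in cx.sqrt_scaled_difference(table))
        assert total == pytest.approx(expected, abs=1e-9)

    def test_all_zero_genotype_rejected(self):
        table = make_count_table([0, 0], [5, 5])
        with pytest.raises(DegenerateNormalizationError):
            cx.sqrt_scaled_difference(table)


class TestMotifRegions:
    genome = {"chrA": "ACGT" * 75, "chrB": "A" * 1000}  # chrA: 300 bp

    def test_exact_fit_returns_whole_contig(self):
        peak = make_peak("chrA", 0, 300, "p1", summit=150)
        score = cx.BindingDifferenceScore("p1", d=-1.0, peak_class=COMMON)
        regions = cx.select_motif_regions([peak], [score], self.genome, n_top=1)
        assert regions.common[0][1] == self.genome["chrA"]
        assert regions.dropped == []

    def test_clipped_window_dropped_with_all_sequences_full_length(self):
        peaks = [
            make_peak("chrB", 0, 120, "edge", summit=50),
            make_peak("chrB", 400, 600, "mid", summit=500),
        ]
        scores = [
            cx.BindingDifferenceScore("edge", d=-2.0, peak_class=COMMON),
            cx.BindingDifferenceScore("mid", d=-1.0, peak_class=COMMON),
        ]
        regions = cx.select_motif_regions(peaks, scores, self.genome, n_top=2)
        assert regions.dropped == ["edge", "edge"]  # dropped from both sets
        assert all(len(seq) == 300 for _, seq in regions.common)

    def test_common_ranked_by_caller_score(self):
        peaks = [
            make_peak("chrB", 300, 500, "lo", summit=400, score=9.0),
            make_peak("chrB", 500, 700, "hi", summit=600, score=12.0),
        ]
        scores = [
            cx.BindingDifferenceScore(p.peak_id, d=0.0, peak_class=COMMON)
            for p in peaks
        ]
        regions = cx.select_motif_regions(peaks, scores, self.genome, n_top=1)
        assert regions.common[0][0].startswith("hi|")

    def test_unique_set_takes_most_negative_d(self):
        peaks = [
            make_peak("chrB", 300, 500, "kept", summit=400),
            make_peak("chrB", 500, 700, "lost", summit=600),
        ]
        scores = [
            cx.BindingDifferenceScore("kept", d=-0.1, peak_class=COMMON),
            cx.BindingDifferenceScore("lost", d=-2.5, peak_class=UNIQUE_WT),
        ]
        regions = cx.select_motif_regions(peaks, scores, self.genome, n_top=1)
        assert regions.unique[0][0].startswith("lost|")


class TestSummitDensityProfile:
    def test_flat_coverage_gives_flat_profile(self):
        track = CoverageTrack({"chr1": np.full(10_000, 3.5)})
        peaks = [make_peak("chr1", 4900, 5100, "p1", summit=5000)]
        profile = cx.summit_density_profile(track, peaks, span=1500, bin_width=500)
        assert profile.matrix.shape == (1, 6)
        assert np.allclose(profile.matrix, 3.5)

    def test_hand_binned_step_function(self):
        # coverage 10 on [0,1000), 0 elsewhere; summit 1500, bin 500:
        # window [0,3000) -> bins (10, 10, 0, 0, 0, 0)
        arr = np.zeros(4000)
        arr[:1000] = 10.0
        track = CoverageTrack({"chr1": arr})
        peaks = [make_peak("chr1", 1400, 1600, "p1", summit=1500)]
        profile = cx.summit_density_profile(track, peaks, span=1500, bin_width=500)
        assert np.allclose(profile.matrix[0], [10, 10, 0, 0, 0, 0])

    def test_zero_coverage_gives_zero_profile(self):
        track = CoverageTrack({"chr1": np.zeros(4000)})
        peaks = [make_peak("chr1", 1900, 2100, "p1", summit=2000)]
        profile = cx.summit_density_profile(track, peaks, span=1500, bin_width=100)
        assert profile.matrix.sum() == 0.0

    def test_out_of_bounds_peak_dropped(self):
        track = CoverageTrack({"chr1": np.ones(2000)})
        peaks = [
            make_peak("chr1", 900, 1100, "in_bounds_fails_too", summit=1000),
            make_peak("chr1", 0, 100, "edge", summit=50),
        ]
        profile = cx.summit_density_profile(track, peaks, span=1500, bin_width=500)
        assert profile.peak_ids == []  # both windows exceed the 2-kb contig

    def test_bin_width_must_divide_span(self):
        track = CoverageTrack({"chr1": np.ones(10_000)})
        with pytest.raises(ValidationError):
            cx.summit_density_profile(track, [], span=1500, bin_width=7)

    def test_symmetric_coverage_yields_symmetric_profile(self):
        # triangular pileups centred on summits are mirror-symmetric; use
        # sparse distal peaks so neighbours cannot contaminate the window
        config = cx.SimulationConfig(
            n_genes=4, n_chroms=1, chrom_length_bp=2_000_000,
            frac_genes_with_tss_peak=0.0,
            n_distal_peaks=30, n_mut_only_peaks=0, seed=11,
        )
        landscape = cx.simulate_landscape(config, with_sequence=False)
        track = CoverageTrack(cx.simulate_coverage(landscape, "wt"))
        profile = cx.summit_density_profile(
            track, landscape.peaks_wt, span=1500, bin_width=100
        )
        mean = profile.mean_profile()
        assert profile.matrix.shape[0] > 0
        assert mean[mean.size // 2] > 10 * mean[0]  # signal concentrates centrally
        assert np.allclose(mean, mean[::-1], atol=0.05 * mean.max())
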