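"""TSS peak assignment, union-region ratios, group test, cumulative curve."""

import numpy as np
import pytest

import chipxpress as cx
from chipxpress.errors import (
    InsufficientDataError,
    LookupMissingError,
    ValidationError,
)
from chipxpress.tss import ACTIVATED, NONREGULATED

from conftest import make_count_table, make_gene, make_peak, random_peaks


def brute_force_assignment(peaks, genes, window):
    """All-pairs oracle: peak overlaps [tss - window, tss + window) by >= 1 bp."""
    assigned = {}
    for g in genes:
        hits = [
            p
            for p in peaks
            if p.chrom == g.chrom
            and min(p.end, g.tss + window) - max(p.start, g.tss - window) >= 1
        ]
        if hits:
            assigned[g.gene_id] = {p.peak_id for p in hits}
    return assigned


class TestAssignPeaksToTss:
    def test_containment_and_disjoint_cases(self):
        gene = make_gene("g1", "chr1", 1000)
        inside = make_peak("chr1", 900, 1100, "inside")
        outside = make_peak("chr1", 2000, 2100, "outside")
        edge = make_peak("chr1", 1490, 1600, "edge")  # overlaps [500,1500) by 10
        assigned = cx.assign_peaks_to_tss([inside, outside, edge], [gene], window=500)
        assert {p.peak_id for p in assigned["g1"]} == {"inside", "edge"}

    def test_peak_may_serve_multiple_genes(self):
        genes = [make_gene("g1", "chr1", 1000), make_gene("g2", "chr1", 1400)]
        peak = make_peak("chr1", 1100, 1300, "shared")
        assigned = cx.assign_peaks_to_tss([peak], genes, window=500)
        assert set(assigned) == {"g1", "g2"}

    def test_genes_without_peaks_absent(self):
        gene = make_gene("g1", "chr1", 1000)
        assert cx.assign_peaks_to_tss([], [gene], window=500) == {}

    def test_window_must_be_positive(self):
        with pytest.raises(ValidationError):
            cx.assign_peaks_to_tss([], [], window=0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for trial in range(30):
            peaks = random_peaks(rng, int(rng.integers(0, 120)))
            genes = [
                make_gene(
                    f"g{i}",
                    ("chr1", "chr2")[rng.integers(2)],
                    int(rng.integers(100, 9000)),
                    strand=("+", "-")[rng.integers(2)],
                    length=100,
                )
                for i in range(int(rng.integers(0, 60)))
            ]
            window = int(rng.integers(1, 800))
            assigned = cx.assign_peaks_to_tss(peaks, genes, window)
            got = {g: {p.peak_id for p in ps} for g, ps in assigned.items()}
            assert got == brute_force_assignment(peaks, genes, window)


class TestUnionRegionCpm:
    def test_singleton_union(self):
        table = make_count_table([8.0], [2.0], peak_ids=["p0"])
        peak = make_peak("chr1", 0, 100, "p0")
        assert cx.union_region_cpm([peak], table) == (8.0, 2.0)

    def test_duplicate_entries_counted_once(self):
        table = make_count_table([8.0], [2.0], peak_ids=["p0"])
        peak = make_peak("chr1", 0, 100, "p0")
        assert cx.union_region_cpm([peak, peak], table) == (8.0, 2.0)

    def test_disjoint_peaks_sum(self):
        table = make_count_table([3.0, 5.0], [1.0, 2.0], peak_ids=["a", "b"])
        peaks = [make_peak("chr1", 0, 100, "a"), make_peak("chr1", 200, 300, "b")]
        assert cx.union_region_cpm(peaks, table) == (8.0, 3.0)

    def test_missing_peak_raises_lookup_error(self):
        table = make_count_table([3.0], [1.0], peak_ids=["a"])
        with pytest.raises(LookupMissingError):
            cx.union_region_cpm([make_peak("chr1", 0, 10, "ghost")], table)


class TestTssLog2Ratio:
    def test_equal_cpm_gives_zero(self):
        assert cx.tss_log2_ratio(8.0, 8.0, 0.5) == 0.0
        assert cx.tss_log2_ratio(0.0, 0.0, 0.5) == 0.0

    def test_small_pseudocount_approaches_raw_ratio(self):
        assert cx.tss_log2_ratio(8.0, 2.0, 1e-9) == pytest.approx(-2.0, abs=1e-6)
        assert cx.tss_log2_ratio(8.0, 2.0, 0.01) == pytest.approx(
            np.log2(2.01 / 8.01)
        )

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            cx.tss_log2_ratio(-1.0, 2.0)
        with pytest.raises(ValidationError):
            cx.tss_log2_ratio(1.0, 2.0, pseudocount=0.0)


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t and its two-tailed p."""
    from scipy.stats import t as t_dist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t), na + nb - 2)
    return t, p


class TestGroupComparison:
    def test_identical_groups_give_t_zero_p_one(self):
        res = cx.group_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.median_difference == 0.0

    def test_hand_worked_example_matches_pooled_formula(self):
        a = [-2.0, -2.2, -1.8]
        b = [0.0, 0.1, -0.1]
        res = cx.group_comparison(a, b)
        t, p = pooled_t_oracle(a, b)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.median_activated == -2.0
        assert res.median_nonregulated == 0.0

    def test_matches_oracle_on_random_inputs(self, rng):
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 40))
            b = rng.normal(size=rng.integers(2, 40))
            res = cx.group_comparison(a, b)
            t, p = pooled_t_oracle(a, b)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_label_swap_negates_t_preserves_p(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=15)
        fwd = cx.group_comparison(a, b)
        rev = cx.group_comparison(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            cx.group_comparison([1.0], [1.0, 2.0])


def ratios_from(values, group=ACTIVATED):
    return [
        cx.TssBindingRatio(f"g{i}", 1.0, 1.0, r, group)
        for i, r in enumerate(values)
    ]


class TestCumulativeCurve:
    def test_zero_ratios_give_zero_curve(self):
        ratios = ratios_from([0.0, 0.0, 0.0])
        diffs = {f"g{i}": 3.0 - i for i in range(3)}
        curve = cx.cumulative_curve(ratios, diffs)
        assert np.all(curve.observed == 0.0)

    def test_hand_worked_running_sum(self):
        ratios = ratios_from([-1.0, -0.5, 0.25])
        diffs = {"g0": 3.0, "g1": 2.0, "g2": 1.0}
        curve = cx.cumulative_curve(ratios, diffs)
        assert curve.gene_ids == ["g0", "g1", "g2"]
        assert np.allclose(curve.observed, [-1.0, -1.5, -1.25])

    def test_ranking_is_descending_with_gene_id_ties(self):
        ratios = ratios_from([1.0, 2.0, 3.0])
        diffs = {"g0": 1.0, "g1": 5.0, "g2": 1.0}
        curve = cx.cumulative_curve(ratios, diffs)
        assert curve.gene_ids == ["g1", "g0", "g2"]

    def test_missing_ratio_rejected(self):
        with pytest.raises(LookupMissingError):
            cx.cumulative_curve(ratios_from([1.0]), {"g0": 1.0, "ghost": 2.0})

    def test_endpoint_is_permutation_invariant(self, rng):
        values = rng.normal(size=20)
        ratios = ratios_from(values)
        diffs = {f"g{i}": float(d) for i, d in enumerate(rng.normal(size=20))}
        curve = cx.cumulative_curve(ratios, diffs)
        assert curve.observed[-1] == pytest.approx(values.sum())


class TestShuffleNull:
    def test_single_gene_null_equals_observed(self):
        curve = cx.cumulative_curve(ratios_from([-2.0]), {"g0": 1.0})
        done = cx.shuffle_null(curve, n_shuffles=10, seed=1)
        assert np.all(done.null == done.observed)

    def test_deterministic_given_seed(self, rng):
        ratios = ratios_from(rng.normal(size=15))
        diffs = {f"g{i}": float(i) for i in range(15)}
        curve = cx.cumulative_curve(ratios, diffs)
        a = cx.shuffle_null(curve, n_shuffles=20, seed=42)
        b = cx.shuffle_null(curve, n_shuffles=20, seed=42)
        c = cx.shuffle_null(curve, n_shuffles=20, seed=43)
        assert np.array_equal(a.null, b.null)
        assert not np.array_equal(a.null, c.null)

    def test_every_null_curve_conserves_endpoint(self, rng):
        ratios = ratios_from(rng.normal(size=30))
        diffs = {f"g{i}": float(d) for i, d in enumerate(rng.normal(size=30))}
        curve = cx.shuffle_null(cx.cumulative_curve(ratios, diffs), 50, seed=0)
        assert np.abs(curve.null[:, -1] - curve.observed[-1]).max() < 1e-9

    def test_envelope_brackets_median(self, rng):
        ratios = ratios_from(rng.normal(size=25))
        diffs = {f"g{i}": float(d) for i, d in enumerate(rng.normal(size=25))}
        curve = cx.shuffle_null(cx.cumulative_curve(ratios, diffs), 200, seed=0)
        env = curve.envelope()
        assert np.all(env[2.5] <= env[50.0] + 1e-12)
        assert np.all(env[50.0] <= env[97.5] + 1e-12)
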