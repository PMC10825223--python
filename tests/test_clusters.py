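import numpy as np
import pytest

from rbekit import clusters as cl
from rbekit.editcall import EditSite

from conftest import toy_genes


def site(ref, pos, et="C2U", conf=0.99):
    return EditSite(
        ref=ref, pos0=pos, edit_type=et, ref_base="C" if et == "C2U" else "A",
        alt_base="T" if et == "C2U" else "G", coverage=50, alt_count=5,
        fraction=0.1, confidence=conf,
    )


def make_bin(start, end, editable, edited, ref="g", gid="g"):
    return cl.EditBin(
        ref=ref, start=start, end=end, gene_id=gid,
        editable_count=editable, edited_count=edited,
    )


class TestBinEdits:
    def test_single_edit_lands_in_expected_window(self):
        genes = toy_genes([("g", 0, 120, "g")])
        bins = cl.bin_edits([site("g", 35)], genes)
        assert len(bins) == 1
        assert (bins[0].start, bins[0].end) == (30, 60)
        assert bins[0].edited_count == 1

    def test_separated_edits_do_not_span(self):
        genes = toy_genes([("g", 0, 120, "g")])
        bins = cl.bin_edits([site("g", 10), site("g", 70)], genes)
        assert [(b.start, b.end) for b in bins] == [(0, 30), (60, 90)]

    def test_keep_empty_tiles_whole_gene(self):
        genes = toy_genes([("g", 0, 95, "g")])
        bins = cl.bin_edits([site("g", 10)], genes, keep_empty=True)
        assert [(b.start, b.end) for b in bins] == [(0, 30), (30, 60), (60, 90), (90, 95)]

    def test_gene_without_edits_not_tiled(self):
        genes = toy_genes([("g", 0, 90, "g"), ("h", 0, 90, "h")])
        bins = cl.bin_edits([site("g", 5)], genes, keep_empty=True)
        assert {b.ref for b in bins} == {"g"}

    def test_against_brute_force_loop(self):
        # oracle: per-position loop over a 500-bp toy gene
        rng = np.random.default_rng(3)
        genes = toy_genes([("g", 0, 500, "g")])
        positions = sorted(set(map(int, rng.integers(0, 500, 40))))
        sites = [site("g", p) for p in positions]
        bins = cl.bin_edits(sites, genes, keep_empty=True)
        expected = {}
        for p in positions:
            b0 = (p // 30) * 30
            expected[b0] = expected.get(b0, 0) + 1
        assert {b.start: b.edited_count for b in bins if b.edited_count} == expected
        assert len(bins) == int(np.ceil(500 / 30))

    def test_minus_strand_bins_tile_from_right(self):
        genes = toy_genes([("g", 0, 95, "g")])
        genes.loc[0, "strand"] = "-"
        bins = cl.bin_edits([site("g", 50)], genes, keep_empty=True)
        assert [(b.start, b.end) for b in bins] == [(0, 5), (5, 35), (35, 65), (65, 95)]

    def test_editable_counts_from_reference(self):
        genes = toy_genes([("g", 0, 30, "g")])
        ref = {"g": "C" * 10 + "A" * 20}
        bins = cl.bin_edits([site("g", 5)], genes, reference=ref)
        assert bins[0].editable_count == 10


class TestBackgroundRate:
    def test_mean_of_fractions(self):
        bins = [make_bin(0, 30, 10, 1), make_bin(30, 60, 10, 3)]
        assert cl.background_rate(bins) == pytest.approx(0.2)

    def test_all_zero(self):
        bins = [make_bin(0, 30, 10, 0)]
        assert cl.background_rate(bins) == 0.0

    def test_unweighted_differs_from_weighted_when_counts_unequal(self):
        bins = [make_bin(0, 30, 2, 1), make_bin(30, 60, 18, 1)]
        unweighted = cl.background_rate(bins)
        weighted = (1 + 1) / (2 + 18)
        assert unweighted == pytest.approx((0.5 + 1 / 18) / 2)
        assert unweighted != pytest.approx(weighted)
        equal = [make_bin(0, 30, 10, 1), make_bin(30, 60, 10, 3)]
        assert cl.background_rate(equal) == pytest.approx(4 / 20)

    def test_no_valid_bins(self):
        with pytest.raises(ValueError):
            cl.background_rate([make_bin(0, 30, 0, 0)])


class TestPoissonBinTest:
    def test_reference_value(self):
        # lambda = 0.05 * 20 = 1; P(X >= 4) = 1 - e^-1 (1 + 1 + 1/2 + 1/6)
        p = cl.poisson_bin_test(make_bin(0, 30, 20, 4), 0.05)
        assert p == pytest.approx(0.018988, abs=1e-6)

    def test_zero_count_gives_one(self):
        assert cl.poisson_bin_test(make_bin(0, 30, 20, 0), 0.05) == 1.0

    def test_zero_background_uses_lambda_floor(self):
        p = cl.poisson_bin_test(make_bin(0, 30, 20, 2), 0.0)
        assert 0.0 < p < 1e-9

    def test_matches_pmf_summation(self):
        # brute-force oracle over the pmf for k <= 25
        import math

        for lam in (0.1, 1.0, 5.0):
            editable = 20
            bg = lam / editable
            for k in range(26):
                tail = sum(
                    math.exp(-lam) * lam**j / math.factorial(j) for j in range(k)
                )
                expected = 1.0 - tail
                p = cl.poisson_bin_test(make_bin(0, 30, editable, k), bg)
                assert p == pytest.approx(expected, abs=1e-12)


class TestBhAdjust:
    def test_hand_computed_example(self):
        q = cl.bh_adjust([0.001, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.004, 0.02, 0.04, 0.04])

    def test_single_and_equal(self):
        assert cl.bh_adjust([0.07])[0] == pytest.approx(0.07)
        assert np.allclose(cl.bh_adjust([0.02] * 5), 0.02)

    def test_input_order_preserved(self):
        q = cl.bh_adjust([0.04, 0.001, 0.03, 0.01])
        assert np.allclose(q, [0.04, 0.004, 0.04, 0.02])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            cl.bh_adjust([0.5, 1.2])


class TestFilterAndMerge:
    def run(self, layout, fdr=0.1, gap=15):
        bins = [make_bin(s, e, 10, 2) for s, e in layout]
        q = [0.01] * len(bins)
        return cl.filter_and_merge(bins, q, q, fdr=fdr, merge_gap=gap)

    def test_gap_within_threshold_merges(self):
        (c,) = self.run([(100, 130), (140, 170)])
        assert (c.start, c.end, c.n_bins) == (100, 170, 2)

    def test_gap_beyond_threshold_splits(self):
        cs = self.run([(100, 130), (146, 176)])
        assert len(cs) == 2

    def test_q_filter_strict(self):
        bins = [make_bin(0, 30, 10, 2), make_bin(40, 70, 10, 2)]
        cs = cl.filter_and_merge(bins, [0.01, 0.01], [0.1, 0.05], fdr=0.1)
        assert len(cs) == 1 and cs[0].start == 40  # q == fdr is excluded

    def test_cluster_stats_are_minima_and_sums(self):
        bins = [make_bin(0, 30, 10, 2), make_bin(30, 60, 10, 5)]
        (c,) = cl.filter_and_merge(bins, [0.02, 0.001], [0.05, 0.004])
        assert c.p_value == 0.001 and c.q_value == 0.004 and c.edited_count == 7

    def test_matches_union_find_oracle(self):
        # oracle: transitive closure by repeated pairwise merging
        rng = np.random.default_rng(5)
        for trial in range(30):
            starts = np.sort(rng.choice(np.arange(0, 600, 10), 20, replace=False))
            bins = [make_bin(int(s), int(s) + 30, 10, 2) for s in starts]
            q = rng.uniform(0, 0.2, 20)
            got = cl.filter_and_merge(bins, q, q, fdr=0.1, merge_gap=15)
            kept = [(b, qq) for b, qq in zip(bins, q) if qq < 0.1]
            # union-find over every pair with gap <= 15 (transitive closure)
            parent = list(range(len(kept)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(kept)):
                for j in range(len(kept)):
                    a, b = kept[i][0], kept[j][0]
                    if b.start - a.end <= 15 and a.start - b.end <= 15:
                        parent[find(i)] = find(j)
            groups = {}
            for i, (b, qq) in enumerate(kept):
                groups.setdefault(find(i), []).append((b, qq))
            expected = sorted(
                (
                    min(b.start for b, _ in grp),
                    max(b.end for b, _ in grp),
                    min(qq for _, qq in grp),
                )
                for grp in groups.values()
            )
            assert [(c.start, c.end, c.q_value) for c in got] == expected

    def test_unsorted_input_sorted_internally(self):
        bins = [make_bin(140, 170, 10, 2), make_bin(100, 130, 10, 2)]
        (c,) = cl.filter_and_merge(bins, [0.01, 0.01], [0.01, 0.01])
        assert (c.start, c.end) == (100, 170)


class TestReplicateOps:
    def c(self, ref, s, e, q=0.01):
        return cl.EditCluster(
            ref=ref, start=s, end=e, gene_id=ref, n_bins=1,
            edited_count=3, p_value=q, q_value=q,
        )

    def test_identical_sets_idempotent(self):
        a = [self.c("g", 0, 30), self.c("g", 100, 130)]
        out = cl.replicate_intersect([a, list(a), list(a)])
        assert [(x.start, x.end) for x in out] == [(0, 30), (100, 130)]
        assert all(x.replicate_support == 3 for x in out)

    def test_one_empty_replicate_empties_output(self):
        a = [self.c("g", 0, 30)]
        assert cl.replicate_intersect([a, []]) == []

    def test_matches_quadratic_overlap_oracle(self):
        rng = np.random.default_rng(9)

        def random_set():
            return [
                self.c(f"g{rng.integers(3)}", int(s), int(s) + 30)
                for s in rng.integers(0, 300, 12)
            ]

        sets = [random_set() for _ in range(3)]
        got = cl.replicate_intersect(sets)
        expected = [
            c
            for c in sets[0]
            if all(
                any(c.ref == o.ref and c.start < o.end and o.start < c.end for o in s)
                for s in sets[1:]
            )
        ]
        assert [(c.ref, c.start) for c in got] == [(c.ref, c.start) for c in expected]

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            cl.replicate_intersect([[self.c("g", 0, 30)]])

    def test_subtract_background(self):
        rbp = [self.c("g", 0, 30), self.c("g", 100, 130)]
        free = [self.c("g", 120, 150)]
        out = cl.subtract_background(rbp, free)
        assert [(c.start, c.end) for c in out] == [(0, 30)]
        assert cl.subtract_background(rbp, []) == rbp
        assert cl.subtract_background(rbp, rbp) == []


def test_pipeline_invariant_to_site_order(small_transcriptome):
    seqs, genes, truth = small_transcriptome
    rng = np.random.default_rng(2)
    positions = rng.choice(len(seqs["g0001"]) - 2, 60, replace=False) + 1
    sites = [
        site("g0001", int(p))
        for p in positions
        if seqs["g0001"][int(p)] == "C"
    ]
    a = cl.call_clusters(sites, genes, reference=seqs)
    shuffled = list(sites)
    rng.shuffle(shuffled)
    b = cl.call_clusters(shuffled, genes, reference=seqs)
    assert [(c.start, c.end, c.q_value) for c in a] == [
        (c.start, c.end, c.q_value) for c in b
    ]
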