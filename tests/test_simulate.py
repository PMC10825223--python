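import numpy as np
import pandas as pd
import pytest

from rbekit.simdata import (
    EnzymeModel,
    TranscriptomeSpec,
    au_rich_weights,
    build_reporter,
    channel_edit_probs,
    default_treated_loads,
    plant_bound_sites,
    simulate_reads,
    simulate_transcriptome,
    simulate_translation,
    uniform_weights,
)


class TestTranscriptome:
    def test_top_fraction_exact(self):
        _, genes, _ = simulate_transcriptome(
            TranscriptomeSpec(n_genes=10, top_fraction=0.2, seed=0)
        )
        assert genes["top"].sum() == 2

    def test_feature_intervals_nested(self, small_transcriptome):
        seqs, genes, _ = small_transcriptome
        for _, g in genes.iterrows():
            assert g.start <= g.cds_start < g.cds_end <= g.utr3_start
            assert g.utr3_start < g.utr3_end <= g.end
            assert len(seqs[g.chrom]) == g.end - g.start

    def test_planted_motifs_found_by_rescan(self, small_transcriptome):
        # string-search oracle: the motif is present at every recorded start
        seqs, genes, truth = small_transcriptome
        motif = "GCATG"
        n = 0
        for gid, starts in truth.motif_sites.items():
            for s in starts:
                assert seqs[gid][s : s + len(motif)] == motif
                n += 1
        assert n > 0

    def test_bad_lengths_rejected(self):
        with pytest.raises(ValueError):
            TranscriptomeSpec(
                n_genes=5, length_model={"cds_mean": -10, "cds_sd": 1}
            )
        with pytest.raises(ValueError):
            TranscriptomeSpec(n_genes=0)


class TestSimulateReads:
    def test_no_enzyme_no_error_reads_match_reference(self, small_transcriptome):
        seqs, _, _ = small_transcriptome
        reads, _ = simulate_reads(seqs, {}, [], n_reads=200, seed=1, error_rate=0.0)
        for r in reads.reads:
            assert r.seq == seqs[r.ref][r.start : r.end]
            assert r.edits == ()

    def test_peak_rate_recovered_binomially(self):
        # 10,000 reads over one site; edited fraction at the kernel peak
        # should fall within 3 binomial SDs of peak_rate
        seq = "A" * 60 + "C" + "A" * 59  # lone substrate at the site midpoint
        enz = EnzymeModel(
            name="e",
            edit_type="C2U",
            peak_rate=0.3,
            kernel_halfwidth=20.0,
            background_rate=0.0,
            context_weights=uniform_weights(),
        )
        reads, _ = simulate_reads(
            {"r": seq},
            {"e": {"r": [(58, 63)]}},
            [enz],
            n_reads=10_000,
            read_length=120,
            seed=2,
            error_rate=0.0,
        )
        edited = sum(1 for r in reads.reads if r.edits)
        frac = edited / len(reads.reads)
        sd = np.sqrt(0.3 * 0.7 / len(reads.reads))
        assert abs(frac - 0.3) < 3 * sd

    def test_dual_enzyme_populates_both_channels(self):
        seq = ("ACGT" * 50)
        enz = EnzymeModel(
            name="d",
            edit_type="DUAL",
            peak_rate=0.4,
            kernel_halfwidth=50.0,
            background_rate=0.0,
            a2i_peak_rate=0.4,
        )
        reads, truth = simulate_reads(
            {"r": seq}, {"d": {"r": [(90, 110)]}}, [enz], n_reads=500, seed=3,
            read_length=100, error_rate=0.0,
        )
        channels = {c for r in reads.reads for _, c in r.edits}
        assert channels == {"C2U", "A2I"}
        assert truth.site_probs["r"]["C2U"].max() > 0
        assert truth.site_probs["r"]["A2I"].max() > 0

    def test_edit_conservation_against_truth(self, reporter_reads):
        # every non-reference base in an error-free read is a recorded edit
        reads, _ = reporter_reads
        ref = reads.reference
        mismatches = 0
        for r in reads.reads:
            expect = ref[r.ref][r.start : r.end]
            diff = {
                r.start + i for i, (a, b) in enumerate(zip(expect, r.seq)) if a != b
            }
            assert diff == {p for p, _ in r.edits}
            mismatches += len(diff)
        assert mismatches == reads.total_edits() > 0

    def test_determinism_bytes(self, tmp_path, small_transcriptome):
        seqs, _, _ = small_transcriptome
        enz = EnzymeModel(
            name="e", edit_type="C2U", peak_rate=0.1, kernel_halfwidth=10,
            background_rate=1e-3,
        )
        outs = []
        for run in range(2):
            reads, _ = simulate_reads(seqs, {"e": {}}, [enz], n_reads=300, seed=11)
            fq = tmp_path / f"r{run}.fastq"
            sam = tmp_path / f"r{run}.sam"
            reads.write_fastq(fq)
            reads.write_sam(sam)
            outs.append((fq.read_bytes(), sam.read_bytes()))
        assert outs[0] == outs[1]

    def test_context_weights_shape_emitted_edits(self):
        # A/U-favoring weights 10:1 -> edited substrates mostly have A/T flanks
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        enz = EnzymeModel(
            name="e", edit_type="C2U", peak_rate=0.0, kernel_halfwidth=10,
            background_rate=0.05, context_weights=au_rich_weights(10.0),
        )
        reads, _ = simulate_reads(
            {"r": seq}, {"e": {}}, [enz], n_reads=4000, seed=4, error_rate=0.0
        )
        au = gc = 0
        for r in reads.reads:
            for p, _ in r.edits:
                up, down = seq[p - 1], seq[p + 1]
                if up in "AT" and down in "AT":
                    au += 1
                elif up in "GC" and down in "GC":
                    gc += 1
        # expected ratio ~10x (modulated by context frequencies); demand >> 1
        assert au > 3 * max(gc, 1)

    def test_kernel_profile_monotone_decay(self):
        seq = "C" * 401
        enz = EnzymeModel(
            name="e", edit_type="C2U", peak_rate=0.5, kernel_halfwidth=30,
            background_rate=0.0,
        )
        probs = channel_edit_probs(seq, enz, [(198, 202)])["C2U"]
        mid = 200
        right = probs[mid : mid + 120]
        assert np.all(np.diff(right) <= 1e-12)
        assert probs[mid] == pytest.approx(0.5, abs=1e-6)
        assert probs[mid + 130] == 0.0  # truncated past 4 halfwidths

    def test_read_length_validation(self, small_transcriptome):
        seqs, _, _ = small_transcriptome
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads(seqs, {}, [], n_reads=10, read_length=10_000, seed=0)


class TestPlantBoundSites:
    def test_sites_inside_region_and_composition_applied(self):
        spec = TranscriptomeSpec(n_genes=6, seed=3)
        seqs, genes, _ = simulate_transcriptome(spec)
        rng = np.random.default_rng(1)
        sites = plant_bound_sites(
            seqs, genes, 6, rng, width=8, flank=40,
            composition={"A": 0.1, "C": 0.7, "G": 0.1, "T": 0.1},
        )
        meta = genes.set_index("chrom")
        n_checked = 0
        for g, ivs in sites.items():
            for s, e in ivs:
                assert meta.loc[g, "utr3_start"] <= s < e <= meta.loc[g, "utr3_end"]
                window = seqs[g][s - 40 : e + 40]
                assert window.count("C") / len(window) > 0.4
                n_checked += 1
        assert n_checked > 0


@pytest.fixture(scope="module")
def toy():
    spec = TranscriptomeSpec(
        n_genes=30,
        length_model={"cds_mean": 300, "cds_sd": 30, "utr3_mean": 300, "utr3_sd": 30},
        top_fraction=0.2,
        seed=5,
    )
    return simulate_transcriptome(spec)


class TestSimulateTranslation:
    def _truth_epr(self, reads):
        per_gene = {}
        for r in reads.reads:
            n, e = per_gene.get(r.ref, (0, 0))
            per_gene[r.ref] = (n + 1, e + len(r.edits))
        return {g: e / n for g, (n, e) in per_gene.items() if n > 0}

    def test_null_condition_epr_difference_near_zero(self, toy):
        seqs, genes, _ = toy
        loads = pd.Series(0.2, index=genes["gene_id"])
        ctrl, trt, _ = simulate_translation(
            seqs, genes, loads, loads, epr_scale=1.0, reads_per_gene=100,
            seed=8, error_rate=0.0,
        )
        a, b = self._truth_epr(ctrl), self._truth_epr(trt)
        diffs = np.array([a[g] - b[g] for g in a if g in b])
        sem = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < max(4 * sem, 0.005)

    def test_fourfold_reduction_gives_log2fc_near_minus_two(self, toy):
        # Poisson-thinning oracle: mean edits scale with load, so the TOP
        # log2 ratio across 3 replicate pairs should be about -2
        seqs, genes, _ = toy
        loads_c = pd.Series(0.3, index=genes["gene_id"])
        loads_t = default_treated_loads(genes, loads_c)
        top = set(genes.loc[genes["top"], "gene_id"])
        ratios = []
        for rep in range(3):
            ctrl, trt, _ = simulate_translation(
                seqs, genes, loads_c, loads_t, epr_scale=1.0,
                reads_per_gene=150, seed=100 + rep, error_rate=0.0,
            )
            a, b = self._truth_epr(ctrl), self._truth_epr(trt)
            for g in top:
                if a.get(g, 0) > 0 and b.get(g, 0) > 0:
                    ratios.append(np.log2(b[g] / a[g]))
        mean = np.mean(ratios)
        ci = 3 * np.std(ratios) / np.sqrt(len(ratios))
        assert abs(mean - (-2.0)) < max(ci, 0.2)

    def test_cds_bias_recovered_at_high_depth(self, toy):
        seqs, genes, _ = toy
        loads = pd.Series(0.3, index=genes["gene_id"])
        ctrl, _, _ = simulate_translation(
            seqs, genes, loads, loads, epr_scale=1.0, cds_bias=2.0,
            reads_per_gene=400, seed=9, error_rate=0.0,
        )
        meta = genes.set_index("chrom")
        cds = utr = 0
        cds_bases = utr_bases = 0
        for r in ctrl.reads:
            row = meta.loc[r.ref]
            for p, _ in r.edits:
                if row["cds_start"] <= p < row["cds_end"]:
                    cds += 1
                elif p >= row["utr3_start"]:
                    utr += 1
        for g in seqs:
            row = meta.loc[g]
            s = seqs[g]
            cds_bases += s[row["cds_start"] : row["cds_end"]].count("C")
            utr_bases += s[row["utr3_start"] : row["utr3_end"]].count("C")
        per_base_ratio = (cds / cds_bases) / (utr / utr_bases)
        assert per_base_ratio == pytest.approx(2.0, rel=0.15)

    def test_mismatched_gene_lists_rejected(self, toy):
        seqs, genes, _ = toy
        loads = pd.Series(0.2, index=genes["gene_id"])
        with pytest.raises(ValueError, match="does not match"):
            simulate_translation(seqs, genes, loads.iloc[:-1], loads, seed=0)
        with pytest.raises(ValueError, match="strictly positive"):
            simulate_translation(seqs, genes, loads * 0, loads, seed=0)
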