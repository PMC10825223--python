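import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbekit import translation as tr
from rbekit.editcall import EditSite
from rbekit.simdata import SimRead, SimReads

from conftest import toy_genes


def reads_on(ref, starts, length=50, refs=None):
    rs = [
        SimRead(name=f"r{i}", ref=ref, start=s, seq="A" * length, edits=())
        for i, s in enumerate(starts)
    ]
    return SimReads(reads=rs, reference=refs or {ref: "A" * 1000})


class TestGeneReadCounts:
    def test_reads_inside_single_gene(self):
        genes = toy_genes([("c", 0, 500, "A")])
        counts, amb = tr.gene_read_counts(reads_on("c", [10] * 100), genes)
        assert counts["A"] == 100 and amb == 0

    def test_ambiguous_reads_discarded(self):
        genes = toy_genes([("c", 0, 100, "A"), ("c", 80, 200, "B")])
        counts, amb = tr.gene_read_counts(reads_on("c", [70, 10, 150]), genes)
        assert counts["A"] == 1 and counts["B"] == 1 and amb == 1

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(1)
        genes = toy_genes(
            [("c", 0, 300, "A"), ("c", 250, 600, "B"), ("c", 650, 900, "C")]
        )
        starts = [int(s) for s in rng.integers(0, 850, 50)]
        reads = reads_on("c", starts)
        counts, amb = tr.gene_read_counts(reads, genes)
        oracle = {"A": 0, "B": 0, "C": 0}
        n_amb = 0
        for s in starts:
            hits = [
                g
                for g, (gs, ge) in {"A": (0, 300), "B": (250, 600), "C": (650, 900)}.items()
                if s < ge and gs < s + 50
            ]
            if len(hits) == 1:
                oracle[hits[0]] += 1
            elif len(hits) > 1:
                n_amb += 1
        assert counts.to_dict() == oracle and amb == n_amb

    def test_empty_gtf_rejected(self):
        with pytest.raises(ValueError):
            tr.gene_read_counts(reads_on("c", [0]), toy_genes([]).reindex(columns=toy_genes([("c",0,1,"x")]).columns))


class TestEditsPerRead:
    def test_simple_ratio(self):
        epr = tr.edits_per_read(
            pd.Series({"A": 30}), pd.Series({"A": 300}), min_reads=10
        )
        assert epr["A"] == pytest.approx(0.1)

    def test_zero_edits(self):
        epr = tr.edits_per_read(pd.Series({"A": 0}), pd.Series({"A": 50}))
        assert epr["A"] == 0.0

    def test_min_reads_filter(self):
        epr = tr.edits_per_read(
            pd.Series({"A": 5, "B": 5}), pd.Series({"A": 9, "B": 10}), min_reads=10
        )
        assert "A" not in epr.index and epr["B"] == 0.5


class TestFoldChange:
    def frame(self, eprs):
        rows = []
        for gene, (ctrl, trt) in eprs.items():
            for i, v in enumerate(ctrl):
                rows.append(
                    {"gene_id": gene, "condition": "control", "replicate": i + 1,
                     "read_count": 100, "edit_count": int(v * 100), "epr": v,
                     "epr_cds": np.nan, "epr_utr3": np.nan}
                )
            for i, v in enumerate(trt):
                rows.append(
                    {"gene_id": gene, "condition": "treated", "replicate": i + 1,
                     "read_count": 100, "edit_count": int(v * 100), "epr": v,
                     "epr_cds": np.nan, "epr_utr3": np.nan}
                )
        return pd.DataFrame(rows)

    def test_identical_conditions_ns(self):
        df = self.frame({"A": ([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])})
        out = tr.epr_fold_change(df)
        assert out.loc[0, "log2_fold_change"] == pytest.approx(0.0, abs=1e-6)
        assert out.loc[0, "call"] == "ns" and out.loc[0, "p_value"] == 1.0

    def test_halving_gives_log2fc_minus_one(self):
        df = self.frame(
            {"A": ([0.2, 0.201, 0.199], [0.1, 0.1005, 0.0995])}
        )
        out = tr.epr_fold_change(df)
        assert out.loc[0, "log2_fold_change"] == pytest.approx(-1.0, abs=0.01)

    def test_welch_t_matches_closed_form(self):
        ctrl, trt = [0.12, 0.15, 0.13], [0.08, 0.07, 0.09]
        df = self.frame({"A": (ctrl, trt)})
        out = tr.epr_fold_change(df)
        # closed-form Welch statistic
        m1, m2 = np.mean(trt), np.mean(ctrl)
        v1, v2 = np.var(trt, ddof=1), np.var(ctrl, ddof=1)
        t = (m1 - m2) / np.sqrt(v1 / 3 + v2 / 3)
        assert out.loc[0, "t_statistic"] == pytest.approx(t, abs=1e-10)
        ref_t, ref_p = stats.ttest_ind(trt, ctrl, equal_var=False)
        assert out.loc[0, "p_value"] == pytest.approx(ref_p, abs=1e-12)

    def test_requires_two_replicates(self):
        df = self.frame({"A": ([0.1], [0.2])})
        with pytest.raises(ValueError):
            tr.epr_fold_change(df)


class TestGroupContrast:
    def comparisons(self, group_lfc, other_lfc):
        genes = [f"g{i}" for i in range(len(group_lfc) + len(other_lfc))]
        lfc = list(group_lfc) + list(other_lfc)
        return (
            pd.DataFrame({"gene_id": genes, "log2_fold_change": lfc}),
            set(genes[: len(group_lfc)]),
        )

    def test_identical_groups_t_near_zero(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 0.1, 20)
        comp, group = self.comparisons(vals[:10], vals[10:])
        res = tr.group_contrast(comp, group)
        assert abs(res.t_statistic) < 2.5

    def test_shifted_group_large_positive_t(self):
        rng = np.random.default_rng(3)
        comp, group = self.comparisons(
            rng.normal(-2, 0.05, 10), rng.normal(0, 0.05, 10)
        )
        res = tr.group_contrast(comp, group)
        assert res.t_statistic > 20 and res.p_value < 1e-10

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        g, o = rng.normal(-1, 0.3, 10), rng.normal(0, 0.3, 10)
        comp, group = self.comparisons(g, o)
        res = tr.group_contrast(comp, group)
        # note the genes are sorted by id inside; order-invariant statistic
        ref_t, ref_p = stats.ttest_ind(o, g, equal_var=False)
        assert res.t_statistic == pytest.approx(ref_t, abs=1e-10)
        assert res.p_value == pytest.approx(ref_p, abs=1e-12)

    def test_invalid_group_rejected(self):
        comp, group = self.comparisons([0.1], [0.2])
        with pytest.raises(ValueError):
            tr.group_contrast(comp, set())
        with pytest.raises(ValueError):
            tr.group_contrast(comp, set(comp["gene_id"]))


class TestRegionRatio:
    def frame(self, rows):
        return pd.DataFrame(
            [
                {"gene_id": g, "condition": "control", "replicate": 1,
                 "read_count": 100, "edit_count": 10, "epr": 0.1,
                 "epr_cds": c, "epr_utr3": u}
                for g, c, u in rows
            ]
        )

    def test_equal_regions(self):
        ratio, per_gene = tr.region_epr_ratio(
            self.frame([("A", 0.1, 0.1), ("B", 0.3, 0.3)])
        )
        assert ratio == pytest.approx(1.0)
        assert np.allclose(per_gene, 1.0)

    def test_doubled_cds(self):
        ratio, _ = tr.region_epr_ratio(
            self.frame([("A", 0.2, 0.1), ("B", 0.6, 0.3)])
        )
        assert ratio == pytest.approx(2.0)

    def test_hand_computation_five_genes(self):
        rows = [("A", 0.2, 0.1), ("B", 0.1, 0.2), ("C", 0.3, 0.1),
                ("D", 0.0, 0.1), ("E", 0.4, 0.4)]
        ratio, per_gene = tr.region_epr_ratio(self.frame(rows))
        assert ratio == pytest.approx((0.2 + 0.1 + 0.3 + 0.0 + 0.4) / (0.1 + 0.2 + 0.1 + 0.1 + 0.4))
        assert per_gene["C"] == pytest.approx(3.0)

    def test_all_zero_utr_rejected(self):
        with pytest.raises(ValueError):
            tr.region_epr_ratio(self.frame([("A", 0.1, 0.0)]))


def test_epr_invariant_to_downsampling(small_transcriptome):
    # EPR is a per-read rate: halving depth leaves its expectation unchanged
    from rbekit.simdata import simulate_translation

    seqs, genes, _ = small_transcriptome
    loads = pd.Series(0.3, index=genes["gene_id"])
    eprs = []
    for depth in (400, 100):
        ctrl, _, _ = simulate_translation(
            seqs, genes, loads, loads, epr_scale=1.0, reads_per_gene=depth,
            seed=11, error_rate=0.0,
        )
        total_edits = ctrl.total_edits()
        eprs.append(total_edits / len(ctrl.reads))
    assert eprs[0] == pytest.approx(eprs[1], rel=0.1)
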