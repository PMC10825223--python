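"""Frozen simulation studies that characterize the pipeline's behaviour.

Each function here defines one self-contained in-silico experiment — the
study conditions (sample sizes, rates, depths) are part of the design and
are documented in docs/methods.md — and returns the summary statistics a
reviewer would ask for: false-positive rates, detection power, recovery of
planted effects, classifier performance, permutation-test calibration.
They are used by the analysis drivers, the test suite and the acceptance
script alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clusters as cl
from . import context as ctx
from . import editcall as ec
from . import overlaps as ov
from . import seqclf as sc
from . import translation as tr
from .simdata import (
    EnzymeModel,
    TranscriptomeSpec,
    au_rich_weights,
    default_treated_loads,
    gc_rich_weights,
    plant_bound_sites,
    simulate_reads,
    simulate_transcriptome,
    simulate_translation,
)

SMALL_GENE_MODEL = {"cds_mean": 300, "cds_sd": 30, "utr3_mean": 300, "utr3_sd": 30}
POWER_GENE_MODEL = {"cds_mean": 300, "cds_sd": 30, "utr3_mean": 400, "utr3_sd": 30}

#: bound-site neighbourhood compositions: an A/U-rich and a G/C-rich flavour
AU_NEIGHBOURHOOD = {"A": 0.40, "C": 0.10, "G": 0.10, "T": 0.40}
GC_NEIGHBOURHOOD = {"A": 0.10, "C": 0.40, "G": 0.40, "T": 0.10}
C_RICH_NEIGHBOURHOOD = {"A": 0.30, "C": 0.45, "G": 0.10, "T": 0.15}


def _call_all(mats, edit_type="C2U", min_coverage=5):
    sites = []
    for m in mats.values():
        sites.extend(ec.call_edits(m, edit_type, min_coverage=min_coverage))
    return sites


# ---------------------------------------------------------------------------
# cluster-caller calibration and power
# ---------------------------------------------------------------------------


def _background_only_run(seed: int, n_genes: int = 20, depth: float = 50.0,
                         background: float = 2e-3):
    spec = TranscriptomeSpec(
        n_genes=n_genes, motif_genes_fraction=0.0,
        length_model=SMALL_GENE_MODEL, seed=seed,
    )
    seqs, genes, _ = simulate_transcriptome(spec)
    enz = EnzymeModel(
        name="free", edit_type="C2U", peak_rate=0.0, kernel_halfwidth=30.0,
        background_rate=background,
    )
    total_len = sum(len(s) for s in seqs.values())
    reads, _ = simulate_reads(
        seqs, {"free": {}}, [enz], n_reads=int(depth * total_len / 100),
        seed=seed, error_rate=0.0,
    )
    mats = ec.count_simulated(reads)
    confident = [s for s in _call_all(mats) if s.confidence > 0.9]
    bins = cl.bin_edits(confident, genes, mats, keep_empty=True)
    bg = cl.background_rate(bins)
    p = np.array([cl.poisson_bin_test(b, bg) for b in bins])
    q = cl.bh_adjust(p)
    return bins, p, q


def cluster_null_calibration(seed: int = 0, n_triplicates: int = 4) -> dict:
    """Background-only editing: per-bin p-value calibration and replicate FPs.

    Runs ``n_triplicates`` replicate triplets of free-editor data, pools all
    per-bin Poisson p-values, and intersects each triplet's cluster calls.
    """
    all_p = []
    intersected = []
    for t in range(n_triplicates):
        reps = []
        for r in range(3):
            bins, p, q = _background_only_run(seed * 1000 + 10 * t + r)
            all_p.append(p)
            reps.append(cl.filter_and_merge(bins, p, q))
        intersected.append(len(cl.replicate_intersect(reps)))
    p = np.concatenate(all_p)
    return {
        "n_bins": int(p.size),
        "fp_rate_alpha_01": float(np.mean(p < 0.01)),
        "fp_rate_alpha_05": float(np.mean(p < 0.05)),
        "intersected_null_clusters": int(np.sum(intersected)),
        "n_triplicates": n_triplicates,
    }


def planted_site_power(
    seed: int = 0,
    n_sims: int = 100,
    depth: float = 50.0,
    background: float = 2e-3,
    fold: float = 20.0,
) -> dict:
    """Detection power for one bound site edited at ``fold`` x background.

    Each simulation plants a single site in a C-rich neighbourhood in the
    covered body of one transcript (among 10), with a flat recruitment
    kernel wide enough to span a full 30-bp bin, and asks whether a cluster
    with q < 0.1 covers the site midpoint.
    """
    hits = 0
    for i in range(n_sims):
        s = seed * 10_000 + i
        rng = np.random.default_rng(s)
        spec = TranscriptomeSpec(
            n_genes=10, motif_genes_fraction=0.0,
            length_model=POWER_GENE_MODEL, seed=s,
        )
        seqs, genes, _ = simulate_transcriptome(spec)
        sites = plant_bound_sites(
            seqs, genes.iloc[[0]], 1, rng, width=8, flank=40, margin=150,
            composition=C_RICH_NEIGHBOURHOOD,
        )
        if not sites:
            continue
        enz = EnzymeModel(
            name="e", edit_type="C2U", peak_rate=fold * background,
            kernel_halfwidth=30.0, background_rate=background,
            kernel_shape="flat",
        )
        total_len = sum(len(x) for x in seqs.values())
        reads, _ = simulate_reads(
            seqs, {"e": sites}, [enz], n_reads=int(depth * total_len / 100),
            seed=s + 77, error_rate=0.0,
        )
        mats = ec.count_simulated(reads)
        clusters = cl.call_clusters(_call_all(mats), genes, mats)
        ((g, ivs),) = sites.items()
        mid = (ivs[0][0] + ivs[0][1]) // 2
        if any(c.ref == g and c.start <= mid < c.end for c in clusters):
            hits += 1
    return {"n_sims": n_sims, "detected": hits, "power": hits / n_sims}


# ---------------------------------------------------------------------------
# edit-caller fidelity
# ---------------------------------------------------------------------------


def edit_caller_fidelity(seed: int = 0, depth: float = 100.0) -> dict:
    """False positives and recall on error-free reads with known edit truth.

    Truth positions with expected per-read edit rate >= 0.1 and observed
    coverage >= 5 count toward recall; any confident call at a position with
    zero true edit probability is a false positive.
    """
    rng = np.random.default_rng(seed)
    spec = TranscriptomeSpec(
        n_genes=20, motif_genes_fraction=0.0,
        length_model=POWER_GENE_MODEL, seed=seed,
    )
    seqs, genes, _ = simulate_transcriptome(spec)
    sites = plant_bound_sites(seqs, genes, 20, rng, width=8, margin=150)
    enz = EnzymeModel(
        name="e", edit_type="C2U", peak_rate=0.3, kernel_halfwidth=30.0,
        background_rate=1e-3,
    )
    total_len = sum(len(x) for x in seqs.values())
    reads, truth = simulate_reads(
        seqs, {"e": sites}, [enz], n_reads=int(depth * total_len / 100),
        seed=seed + 1, error_rate=0.0,
    )
    mats = ec.count_simulated(reads)
    n_fp = recall_hit = recall_tot = n_conf = 0
    for g, m in mats.items():
        called = ec.call_edits(m, "C2U")
        conf_pos = {s.pos0 for s in called if s.confidence > 0.9}
        n_conf += len(conf_pos)
        probs = truth.site_probs[g]["C2U"]
        n_fp += sum(1 for p in conf_pos if probs[p] == 0)
        qualifying = np.nonzero((probs >= 0.1) & (m.coverage >= 5))[0]
        recall_tot += qualifying.size
        recall_hit += sum(1 for p in qualifying if p in conf_pos)
    return {
        "confident_sites": n_conf,
        "false_positives": n_fp,
        "recall": recall_hit / recall_tot if recall_tot else np.nan,
        "n_truth_sites": recall_tot,
    }


# ---------------------------------------------------------------------------
# context-bias recovery
# ---------------------------------------------------------------------------


def context_bias_recovery(seed: int = 0, n_replicates: int = 3) -> dict:
    """Flanking-context PCA separation of A/U- versus G/C-preferring editors.

    Simulates free editors (background editing only) so the context signal
    comes purely from the enzymes' intrinsic preferences, three replicates
    each, and measures the PC1 gap between enzymes against the within-
    enzyme replicate spread, plus the loading-sign split of A/U versus G/C
    contexts on PC1.
    """
    spec = TranscriptomeSpec(
        n_genes=40, motif_genes_fraction=0.0,
        length_model=SMALL_GENE_MODEL, seed=seed,
    )
    seqs, genes, _ = simulate_transcriptome(spec)
    enzymes = [
        EnzymeModel(
            name="au", edit_type="C2U", peak_rate=0.0, kernel_halfwidth=10.0,
            background_rate=2e-3, context_weights=au_rich_weights(10.0),
        ),
        EnzymeModel(
            name="gc", edit_type="C2U", peak_rate=0.0, kernel_halfwidth=10.0,
            background_rate=2e-3, context_weights=gc_rich_weights(10.0),
        ),
    ]
    total_len = sum(len(x) for x in seqs.values())
    vectors = []
    for ei, enz in enumerate(enzymes):
        for r in range(n_replicates):
            reads, _ = simulate_reads(
                seqs, {enz.name: {}}, [enz],
                n_reads=int(30.0 * total_len / 100),
                seed=seed * 100 + 10 * ei + r, error_rate=0.0,
            )
            mats = ec.count_simulated(reads)
            called = _call_all(mats)
            vectors.append(
                ctx.flanking_contexts(
                    called, seqs, sample=f"{enz.name}_rep{r + 1}"
                )
            )
    pca = ctx.context_pca(vectors)
    pc1 = pca.coordinates[:, 0]
    a, g = pc1[:n_replicates], pc1[n_replicates:]
    gap = abs(a.mean() - g.mean())
    spread = max(a.max() - a.min(), g.max() - g.min())
    load = pca.loadings[0]
    au_loads = [
        load[i] for i, (u, d) in enumerate(ctx.CONTEXTS) if u in "AT" and d in "AT"
    ]
    gc_loads = [
        load[i] for i, (u, d) in enumerate(ctx.CONTEXTS) if u in "GC" and d in "GC"
    ]
    # orient so the A/U contexts load positively
    sign = 1.0 if np.mean(au_loads) >= 0 else -1.0
    return {
        "pc1_gap": float(gap),
        "within_spread": float(spread),
        "separation_ratio": float(gap / spread) if spread else np.inf,
        "au_loadings_positive": bool(min(sign * np.array(au_loads)) > 0),
        "gc_loadings_negative": bool(max(sign * np.array(gc_loads)) < 0),
        "variance_pc1": float(pca.variance_explained[0]),
    }


# ---------------------------------------------------------------------------
# classifier study
# ---------------------------------------------------------------------------


def classifier_windows(seed: int = 0, n_sites: int = 450):
    """Windows from two enzymes whose clusters live in distinct neighbourhoods."""
    rng = np.random.default_rng(seed)
    spec = TranscriptomeSpec(
        n_genes=80, motif_genes_fraction=0.0,
        length_model={"cds_mean": 600, "cds_sd": 60, "utr3_mean": 600, "utr3_sd": 60},
        seed=seed,
    )
    seqs, genes, _ = simulate_transcriptome(spec)
    kw = dict(width=8, flank=96, margin=130, region="whole")
    sites_a = plant_bound_sites(
        seqs, genes.iloc[::2], n_sites, rng, composition=AU_NEIGHBOURHOOD, **kw
    )
    sites_b = plant_bound_sites(
        seqs, genes.iloc[1::2], n_sites, rng, composition=GC_NEIGHBOURHOOD, **kw
    )

    class _IV:
        def __init__(self, ref, start, end):
            self.ref, self.start, self.end = ref, start, end

    def windows(site_map, label, sample):
        ivs = [_IV(g, s, e) for g, lst in site_map.items() for s, e in lst]
        return sc.make_windows(ivs, seqs, width=200, label=label, sample=sample)

    pos = windows(sites_a, 1, "enzyme_au")
    neg = sc.balance_negatives(pos, windows(sites_b, 0, "enzyme_gc"), seed=seed)
    return pos + neg


def classifier_study(seed: int = 0) -> dict:
    """Held-out AUC on context-divergent enzymes and on permuted labels."""
    wins = classifier_windows(seed)
    _, report = sc.train_classifier(wins, seed=seed)
    rng = np.random.default_rng(seed + 1)
    labels = np.array([w.label for w in wins])
    rng.shuffle(labels)
    permuted = [
        sc.OneHotWindow(w.matrix, int(l), w.origin) for w, l in zip(wins, labels)
    ]
    _, null_report = sc.train_classifier(permuted, seed=seed)
    return {
        "auc_heldout": report.test_auc,
        "auc_permuted": null_report.test_auc,
        "n_windows": len(wins),
        "epochs": report.n_epochs,
    }


# ---------------------------------------------------------------------------
# EPR study
# ---------------------------------------------------------------------------


def epr_study(
    seed: int = 0,
    n_genes: int = 200,
    n_replicates: int = 3,
    reads_per_gene: float = 40.0,
    null: bool = False,
) -> dict:
    """TOP-gene translation-repression recovery (or the matched null).

    Control loads are lognormal around 0.1 edits/read; the treated condition
    reduces TOP genes 4-fold and others 1.25-fold (``null=True`` keeps them
    equal).  Returns the TOP-versus-rest contrast on log2 EPR fold-changes
    and the per-gene call fractions.
    """
    spec = TranscriptomeSpec(
        n_genes=n_genes, length_model=SMALL_GENE_MODEL, seed=seed,
    )
    seqs, genes, _ = simulate_transcriptome(spec)
    rng = np.random.default_rng(seed + 1)
    loads_c = pd.Series(
        rng.lognormal(np.log(0.1), 0.3, n_genes), index=genes["gene_id"]
    )
    loads_t = loads_c if null else default_treated_loads(genes, loads_c)
    summaries = []
    for r in range(n_replicates):
        ctrl, trt, _ = simulate_translation(
            seqs, genes, loads_c, loads_t, epr_scale=1.0, cds_bias=1.5,
            reads_per_gene=reads_per_gene, seed=seed * 100 + r,
        )
        for cond, reads in (("control", ctrl), ("treated", trt)):
            mats = ec.count_simulated(reads)
            sites = _call_all(mats)
            summaries.append(
                tr.gene_edit_summary(
                    reads, sites, genes, condition=cond, replicate=r + 1
                )
            )
    summary = pd.concat(summaries, ignore_index=True)
    comparisons = tr.epr_fold_change(summary, fdr=0.05)
    top = set(genes.loc[genes["top"], "gene_id"])
    contrast = tr.group_contrast(comparisons, top)
    frac_called = float(np.mean(comparisons["q_value"] < 0.05))
    return {
        "t_statistic": contrast.t_statistic,
        "p_value": contrast.p_value,
        "n_genes_tested": len(comparisons),
        "fraction_q_below_05": frac_called,
        "n_decrease": int((comparisons["call"] == "decrease").sum()),
        "n_increase": int((comparisons["call"] == "increase").sum()),
    }


# ---------------------------------------------------------------------------
# permutation-test calibration
# ---------------------------------------------------------------------------


def permutation_calibration(
    seed: int = 0, n_trials: int = 100, n_perm: int = 200
) -> dict:
    """Uniformity of the empirical permutation p under the null.

    Query sets are drawn from the same placement process as the permutation
    null (120 intervals of 20 bp on 20 x 500 bp transcripts; a large query
    set keeps the overlap-fraction lattice fine enough for the add-one
    p-value to be close to uniform).  The subject set is 80 peaks of 60 bp
    placed once.  Also plants an enriched query set (clusters sitting on
    subject peaks) and reports its p-value.
    """
    from scipy.stats import kstest

    rng = np.random.default_rng(seed)
    domain = pd.DataFrame(
        {"chrom": [f"t{i}" for i in range(20)], "start": 0, "end": 500}
    )
    subject = pd.DataFrame(
        [
            {
                "chrom": f"t{rng.integers(20)}",
                "start": (s := int(rng.integers(0, 440))),
                "end": s + 60,
            }
            for _ in range(80)
        ]
    )

    def null_query(trial_rng):
        return pd.DataFrame(
            [
                {
                    "chrom": f"t{trial_rng.integers(20)}",
                    "start": (s := int(trial_rng.integers(0, 480))),
                    "end": s + 20,
                }
                for _ in range(120)
            ]
        )

    ps = []
    for t in range(n_trials):
        q = null_query(np.random.default_rng(seed * 10_000 + t))
        res = ov.permute_intervals(
            q, subject, domain, n_perm=n_perm, seed=seed * 20_000 + t
        )
        ps.append(res.p_value)
    ks = kstest(np.array(ps), "uniform").statistic
    planted = subject.sample(30, random_state=seed).reset_index(drop=True)
    enriched = ov.permute_intervals(
        planted[["chrom", "start", "end"]], subject, domain,
        n_perm=n_perm, seed=seed + 5,
    )
    return {
        "ks_statistic": float(ks),
        "n_trials": n_trials,
        "planted_p": enriched.p_value,
        "planted_enrichment": enriched.enrichment,
    }
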