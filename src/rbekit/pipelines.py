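"""End-to-end pipeline presets over simulated data.

Three presets mirror the standard tethered-editing study designs:

* ``reporter`` — stem-loop reporter screen: per-position editing profiles,
  spillover indices and on/off-target signal-to-noise per enzyme.
* ``fusion`` — RBP-fusion cluster analysis: replicate edit-cluster calling,
  free-editor background subtraction, motif statistics, flanking-context
  PCA and eCLIP-style overlap permutation tests.
* ``translation`` — ribosome-tethered editing: per-gene EPR fold-changes
  under a translation inhibitor, TOP-gene contrast and CDS/3'UTR ratios.

Every preset runs entirely from the synthetic-data generator, threads all
randomness from ``RunConfig.seed`` and writes byte-stable TSV/JSON bundles
plus the resolved configuration into the output directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as cl
from . import context as ctx
from . import editcall as ec
from . import overlaps as ov
from . import reporter as rep
from . import translation as tr
from .config import RunConfig
from .gtf import write_bed, write_fasta, write_gene_models
from .simdata import (
    A2I,
    C2U,
    EnzymeModel,
    TranscriptomeSpec,
    au_rich_weights,
    build_reporter,
    default_treated_loads,
    gc_rich_weights,
    plant_bound_sites,
    simulate_reads,
    simulate_translation,
    simulate_transcriptome,
)

log = logging.getLogger(__name__)

PRESETS = ("reporter", "fusion", "translation")

_TSV_KW = dict(sep="\t", index=False, float_format="%.6g")


def _sub_seed(seed: int, k: int) -> int:
    return (int(seed) * 1009 + k) % (2**31 - 1)


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _panel(cfg: RunConfig) -> list[EnzymeModel]:
    """The default simulated enzyme panel for the reporter screen."""
    return [
        EnzymeModel(
            name="c2u_precise",
            edit_type=C2U,
            peak_rate=0.30,
            kernel_halfwidth=15.0,
            background_rate=2e-4,
            context_weights=au_rich_weights(10.0),
        ),
        EnzymeModel(
            name="c2u_broad",
            edit_type=C2U,
            peak_rate=0.30,
            kernel_halfwidth=80.0,
            background_rate=1e-3,
            context_weights=au_rich_weights(10.0),
        ),
        EnzymeModel(
            name="a2i_precise",
            edit_type=A2I,
            peak_rate=0.25,
            kernel_halfwidth=15.0,
            background_rate=2e-4,
            context_weights=gc_rich_weights(10.0),
        ),
    ]


def _call_both_channels(mats, cfg: RunConfig):
    sites = []
    for mat in mats.values():
        for channel in (C2U, A2I):
            sites.extend(
                ec.call_edits(
                    mat,
                    channel,
                    min_coverage=cfg.min_coverage,
                    error_rate=cfg.call_error_rate,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# reporter preset
# ---------------------------------------------------------------------------


def preset_reporter(cfg: RunConfig, outdir: Path) -> dict:
    spec = build_reporter("MS2x12", seed=cfg.seed)
    off_spec = TranscriptomeSpec(
        n_genes=20,
        length_model={"cds_mean": 450, "cds_sd": 90, "utr3_mean": 300, "utr3_sd": 60},
        seed=_sub_seed(cfg.seed, 1),
    )
    off_seqs, off_genes, _ = simulate_transcriptome(off_spec)
    reference = {spec.name: spec.full_seq, **off_seqs}
    n_off_reads = int(cfg.reads_per_gene * len(off_seqs))
    n_rep_reads = int(cfg.reads_per_gene * 10)  # deep coverage on the reporter

    profiles, onoff_rows, spill_rows = [], [], []
    for ei, enz in enumerate(_panel(cfg)):
        sites = {enz.name: {spec.name: spec.loop_sites("MS2")}}
        for r in range(2):  # two replicates, the reporter-screen convention
            reads, _ = simulate_reads(
                reference,
                sites,
                [enz],
                n_reads=n_rep_reads + n_off_reads,
                read_length=cfg.read_length,
                seed=_sub_seed(cfg.seed, 10 + 10 * ei + r),
                error_rate=cfg.error_rate,
                ref_weights=np.array(
                    [n_rep_reads] + [n_off_reads / len(off_seqs)] * len(off_seqs)
                ),
            )
            mats = ec.count_simulated(reads, min_baseq=cfg.min_base_quality)
            called = {
                ref: ec.call_edits(
                    mats[ref],
                    enz.edit_type if enz.edit_type != "DUAL" else C2U,
                    min_coverage=cfg.min_coverage,
                    error_rate=cfg.call_error_rate,
                )
                for ref in reference
            }
            prof = rep.profile_reporter(mats[spec.name], spec)
            pf = prof.frame.copy()
            pf.insert(0, "enzyme", enz.name)
            pf.insert(1, "replicate", r + 1)
            profiles.append(pf)
            on = rep.edited_base_count(called[spec.name], cfg.min_confidence)
            off = sum(
                rep.edited_base_count(called[g], cfg.min_confidence)
                for g in off_seqs
            )
            report = rep.on_off_ratio(on, off, sample=f"{enz.name}_rep{r + 1}")
            onoff_rows.append(
                {
                    "enzyme": enz.name,
                    "replicate": r + 1,
                    "on_target_edits": report.on_target_edits,
                    "off_target_edits": report.off_target_edits,
                    "ratio": report.ratio,
                }
            )
            spill_rows.append(
                {
                    "enzyme": enz.name,
                    "replicate": r + 1,
                    "spillover_index": rep.spillover_index(prof),
                }
            )

    # dual-editing run on the alternating 4-site construct
    dual_spec = build_reporter("ALT4", seed=cfg.seed)
    mcp = _panel(cfg)[0]
    pp7 = _panel(cfg)[2]
    dual_sites = {
        mcp.name: {dual_spec.name: dual_spec.loop_sites("MS2")},
        pp7.name: {dual_spec.name: dual_spec.loop_sites("PP7")},
    }
    dual_reads, _ = simulate_reads(
        {dual_spec.name: dual_spec.full_seq},
        dual_sites,
        [mcp, pp7],
        n_reads=n_rep_reads,
        read_length=cfg.read_length,
        seed=_sub_seed(cfg.seed, 90),
        error_rate=cfg.error_rate,
    )
    dual_mat = ec.count_simulated(dual_reads, min_baseq=cfg.min_base_quality)
    dual_prof = rep.profile_reporter(dual_mat[dual_spec.name], dual_spec)
    dp = dual_prof.frame.copy()
    dp.insert(0, "enzyme", "dual_pair")
    dp.insert(1, "replicate", 1)

    prof_frame = pd.concat(profiles + [dp], ignore_index=True)
    onoff = pd.DataFrame(onoff_rows)
    spill = pd.DataFrame(spill_rows)
    prof_frame.to_csv(outdir / "reporter_profiles.tsv", **_TSV_KW)
    onoff.to_csv(outdir / "reporter_onoff.tsv", **_TSV_KW)
    spill.to_csv(outdir / "reporter_spillover.tsv", **_TSV_KW)
    write_bed(
        pd.DataFrame(
            [
                {"chrom": spec.name, "start": s, "end": e, "name": kind}
                for kind, s, e in spec.loop_intervals
            ]
        ),
        outdir / "reporter_loops.bed",
    )
    return {
        "profiles": prof_frame,
        "onoff": onoff,
        "spillover": spill,
        "dual_profile": dual_prof,
        "reporter": spec,
    }


# ---------------------------------------------------------------------------
# fusion preset
# ---------------------------------------------------------------------------


def _fusion_enzymes() -> tuple[EnzymeModel, EnzymeModel]:
    """Two context-divergent editors: A/U-preferring C2U, G/C-preferring A2I."""
    apo = EnzymeModel(
        name="c2u_au",
        edit_type=C2U,
        peak_rate=0.25,
        kernel_halfwidth=15.0,
        background_rate=5e-4,
        context_weights=au_rich_weights(10.0),
        kernel_shape="flat",
    )
    tad = EnzymeModel(
        name="a2i_gc",
        edit_type=A2I,
        peak_rate=0.25,
        kernel_halfwidth=15.0,
        background_rate=5e-4,
        context_weights=gc_rich_weights(10.0),
        kernel_shape="flat",
    )
    return apo, tad


def preset_fusion(cfg: RunConfig, outdir: Path) -> dict:
    spec = TranscriptomeSpec(
        n_genes=cfg.n_genes,
        length_model={"cds_mean": 360, "cds_sd": 60, "utr3_mean": 300, "utr3_sd": 60},
        seed=_sub_seed(cfg.seed, 1),
    )
    seqs, genes, truth = simulate_transcriptome(spec)
    rng = np.random.default_rng(_sub_seed(cfg.seed, 2))
    bound = {
        g: [(p, p + len(spec.motif)) for p in pos]
        for g, pos in truth.motif_sites.items()
        if pos
    }
    enzymes = _fusion_enzymes()
    n_reads = int(cfg.reads_per_gene * cfg.n_genes)

    cluster_sets: dict[str, list] = {}
    vectors = []
    for ei, enz in enumerate(enzymes):
        channel = enz.edit_type
        for fi, fused in enumerate((True, False)):
            label = f"{enz.name}_{'fusion' if fused else 'free'}"
            reps = []
            for r in range(cfg.n_replicates):
                sites_map = {enz.name: bound if fused else {}}
                reads, _ = simulate_reads(
                    seqs,
                    sites_map,
                    [enz],
                    n_reads=n_reads,
                    read_length=cfg.read_length,
                    seed=_sub_seed(cfg.seed, 100 + 20 * ei + 10 * fi + r),
                    error_rate=cfg.error_rate,
                )
                mats = ec.count_simulated(reads, min_baseq=cfg.min_base_quality)
                sites = []
                for mat in mats.values():
                    sites.extend(
                        ec.call_edits(
                            mat,
                            channel,
                            min_coverage=cfg.min_coverage,
                            error_rate=cfg.call_error_rate,
                        )
                    )
                reps.append(
                    cl.call_clusters(
                        sites,
                        genes,
                        mats,
                        edit_type=channel,
                        min_confidence=cfg.min_confidence,
                        bin_size=cfg.bin_size,
                        min_coverage=cfg.min_coverage,
                        fdr=cfg.fdr,
                        merge_gap=cfg.merge_gap,
                    )
                )
                vectors.append(
                    ctx.flanking_contexts(
                        sites,
                        seqs,
                        min_confidence=cfg.min_confidence,
                        sample=f"{label}_rep{r + 1}",
                    )
                )
            cluster_sets[label] = cl.replicate_intersect(reps)

    final: dict[str, list] = {}
    summary_rows = []
    for enz in enzymes:
        fused = cluster_sets[f"{enz.name}_fusion"]
        free = cluster_sets[f"{enz.name}_free"]
        kept = cl.subtract_background(fused, free)
        final[enz.name] = kept
        motif_sites = {g: list(p) for g, p in truth.motif_sites.items()}
        frac, _ = ctx.motif_presence(kept, seqs, motif=spec.motif) if kept else (0.0, [])
        dists, _ = (
            ctx.motif_distance_density(kept, motif_sites)
            if kept and any(motif_sites.values())
            else (np.array([]), 0)
        )
        summary_rows.append(
            {
                "enzyme": enz.name,
                "replicable_clusters": len(fused),
                "free_clusters": len(free),
                "clusters_after_subtraction": len(kept),
                "genes": len({c.gene_id for c in kept}),
                "motif_presence_fraction": frac,
                "median_abs_motif_distance": float(np.median(np.abs(dists)))
                if dists.size
                else np.nan,
            }
        )
        cl.write_clusters(kept, outdir / f"fusion_clusters_{enz.name}.tsv")

    pca = ctx.context_pca(vectors)
    coords = pd.DataFrame(
        {
            "sample": pca.samples,
            "pc1": pca.coordinates[:, 0],
            "pc2": pca.coordinates[:, 1],
        }
    )
    loadings = pd.DataFrame(
        pca.loadings.T, columns=["pc1", "pc2"], index=ctx.CONTEXT_LABELS
    ).reset_index(names="context")

    # overlap with eCLIP-like reference peaks (truth binding sites +- 30 bp)
    peaks = pd.DataFrame(
        [
            {"chrom": g, "start": max(0, s - 30), "end": e + 30}
            for g, ivs in bound.items()
            for s, e in ivs
        ]
    )
    domain = genes.rename(columns={"chrom": "chrom"})[["chrom", "start", "end"]]
    overlap_results = {}
    named_sets = {k: v for k, v in final.items() if v}
    for name, kept in named_sets.items():
        q = ov.intervals_from_clusters(kept)
        res = ov.permute_intervals(
            q, peaks, domain, n_perm=cfg.n_perm, seed=_sub_seed(cfg.seed, 7)
        )
        overlap_results[name] = {
            "observed": res.observed,
            "null_mean": float(np.mean(res.null_fractions)),
            "p_value": res.p_value,
            "enrichment": res.enrichment,
            "n_clusters": len(kept),
        }
    combined = None
    if len(named_sets) >= 2:
        sets = [ov.intervals_from_clusters(v) for v in named_sets.values()]
        union = ov.combined_set(sets)
        res = ov.permute_intervals(
            union[["chrom", "start", "end"]],
            peaks,
            domain,
            n_perm=cfg.n_perm,
            seed=_sub_seed(cfg.seed, 8),
        )
        overlap_results["combined"] = {
            "observed": res.observed,
            "null_mean": float(np.mean(res.null_fractions)),
            "p_value": res.p_value,
            "enrichment": res.enrichment,
            "n_clusters": int(len(union)),
        }
        patterns = ov.upset_counts(sets)
        combined = pd.DataFrame(
            [
                {
                    "pattern": "+".join(
                        list(named_sets)[i] for i in pat
                    ),
                    "count": n,
                }
                for pat, n in sorted(patterns.items())
            ]
        )
        combined.to_csv(outdir / "fusion_upset.tsv", **_TSV_KW)

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "fusion_summary.tsv", **_TSV_KW)
    coords.to_csv(outdir / "fusion_context_pca.tsv", **_TSV_KW)
    loadings.to_csv(outdir / "fusion_context_loadings.tsv", **_TSV_KW)
    _write_json(overlap_results, outdir / "fusion_overlap.json")
    write_fasta(seqs, outdir / "fusion_reference.fa")
    write_gene_models(genes, outdir / "fusion_genes.gtf")
    return {
        "summary": summary,
        "clusters": final,
        "pca": pca,
        "pca_coords": coords,
        "loadings": loadings,
        "overlap": overlap_results,
        "upset": combined,
        "genes": genes,
        "reference": seqs,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# translation preset
# ---------------------------------------------------------------------------


def preset_translation(cfg: RunConfig, outdir: Path) -> dict:
    spec = TranscriptomeSpec(
        n_genes=max(cfg.n_genes, 100),
        length_model={"cds_mean": 360, "cds_sd": 60, "utr3_mean": 300, "utr3_sd": 60},
        seed=_sub_seed(cfg.seed, 1),
    )
    seqs, genes, _ = simulate_transcriptome(spec)
    rng = np.random.default_rng(_sub_seed(cfg.seed, 2))
    loads_control = pd.Series(
        rng.lognormal(mean=np.log(0.1), sigma=0.3, size=len(genes)),
        index=genes["gene_id"],
    )
    loads_treated = default_treated_loads(genes, loads_control)

    summaries = []
    for r in range(cfg.n_replicates):
        ctrl, trt, _ = simulate_translation(
            seqs,
            genes,
            loads_control,
            loads_treated,
            epr_scale=cfg.epr_scale,
            cds_bias=cfg.cds_bias,
            reads_per_gene=cfg.reads_per_gene,
            read_length=cfg.read_length,
            seed=_sub_seed(cfg.seed, 200 + r),
            error_rate=cfg.error_rate,
        )
        for cond, reads in (("control", ctrl), ("treated", trt)):
            mats = ec.count_simulated(reads, min_baseq=cfg.min_base_quality)
            sites = []
            for mat in mats.values():
                sites.extend(
                    ec.call_edits(
                        mat,
                        C2U,
                        min_coverage=cfg.min_coverage,
                        error_rate=cfg.call_error_rate,
                    )
                )
            summaries.append(
                tr.gene_edit_summary(
                    reads,
                    sites,
                    genes,
                    condition=cond,
                    replicate=r + 1,
                    min_reads=cfg.min_reads,
                    min_confidence=cfg.min_confidence,
                )
            )
    summary = pd.concat(summaries, ignore_index=True)
    comparisons = tr.epr_fold_change(summary, fdr=cfg.epr_fdr)
    top_genes = set(genes.loc[genes["top"], "gene_id"])
    contrast = tr.group_contrast(comparisons, top_genes)
    ratio_all, _ = tr.region_epr_ratio(summary[summary["condition"] == "control"])
    ratio_top, _ = tr.region_epr_ratio(
        summary[summary["condition"] == "control"], top_genes
    )
    calls = comparisons["call"].value_counts().to_dict()
    result = {
        "top_t_statistic": contrast.t_statistic,
        "top_p_value": contrast.p_value,
        "n_top": contrast.n_group,
        "n_other": contrast.n_other,
        "n_decrease": int(calls.get("decrease", 0)),
        "n_increase": int(calls.get("increase", 0)),
        "n_ns": int(calls.get("ns", 0)),
        "cds_utr3_ratio_all": ratio_all,
        "cds_utr3_ratio_top": ratio_top,
    }
    summary.to_csv(outdir / "translation_summaries.tsv", **_TSV_KW)
    comparisons.to_csv(outdir / "translation_comparisons.tsv", **_TSV_KW)
    _write_json(result, outdir / "translation_contrast.json")
    return {
        "summary": summary,
        "comparisons": comparisons,
        "contrast": contrast,
        "result": result,
        "genes": genes,
    }


# ---------------------------------------------------------------------------


def run_pipeline(preset: str, config: RunConfig | dict | None = None) -> dict:
    """Run one preset end to end, writing its report bundle to config.outdir."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    if config is None:
        config = RunConfig()
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write(outdir / f"{preset}_config.yaml")
    log.info("running preset %s (seed %d)", preset, config.seed)
    fn = {
        "reporter": preset_reporter,
        "fusion": preset_fusion,
        "translation": preset_translation,
    }[preset]
    return fn(config, outdir)
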