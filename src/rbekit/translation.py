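"""Edits-per-read (EPR) quantification of translation.

When an editor rides along with a ribosomal protein, the number of edits it
deposits per sequencing read of a gene tracks how heavily ribosomes load
that gene's mRNA.  EPR = edited-base observations / gene-assigned reads, on
a per-gene, per-replicate basis; treated-versus-control contrasts use Welch
t-tests on replicate EPRs with Benjamini-Hochberg correction, and group
contrasts (e.g. TOP-like genes versus the rest) compare log2 fold-changes
between gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import bh_adjust
from .editcall import EditSite

LOG2_EPS = 1e-6
DEFAULT_MIN_READS = 10

SUMMARY_COLUMNS = [
    "gene_id",
    "condition",
    "replicate",
    "read_count",
    "edit_count",
    "epr",
    "epr_cds",
    "epr_utr3",
]


def _read_spans(alignments) -> list[tuple[str, int, int]]:
    """(ref, start, end) spans from a SimReads batch or a SAM/BAM path."""
    if hasattr(alignments, "reads"):  # SimReads
        return [(r.ref, r.start, r.end) for r in alignments.reads]
    import pysam

    spans = []
    with pysam.AlignmentFile(str(alignments)) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            spans.append(
                (read.reference_name, read.reference_start, read.reference_end)
            )
    return spans


def gene_read_counts(
    alignments, genes: pd.DataFrame
) -> tuple[pd.Series, int]:
    """Reads per gene; reads overlapping several genes are discarded.

    A read counts toward a gene iff its aligned span overlaps the gene's
    span (>= 1 bp) and no other gene's.  Returns (counts indexed by gene_id,
    number of ambiguous reads discarded).
    """
    if len(genes) == 0:
        raise ValueError("empty gene models")
    spans = _read_spans(alignments)
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for _, row in genes.iterrows():
        by_chrom.setdefault(row["chrom"], []).append(
            (int(row["start"]), int(row["end"]), row["gene_id"])
        )
    counts = pd.Series(0, index=genes["gene_id"], dtype=np.int64)
    ambiguous = 0
    for ref, s, e in spans:
        hits = [
            gid for gs, ge, gid in by_chrom.get(ref, []) if s < ge and gs < e
        ]
        if len(hits) == 1:
            counts[hits[0]] += 1
        elif len(hits) > 1:
            ambiguous += 1
    return counts, ambiguous


def gene_edit_counts(
    sites: list[EditSite],
    genes: pd.DataFrame,
    min_confidence: float = 0.9,
) -> pd.DataFrame:
    """Edited-base observations per gene, total and by region.

    Counts sum ``alt_count`` over confident sites falling in each gene's
    span; cds/utr3 columns restrict to sites inside those sub-intervals.
    """
    idx = genes.set_index("gene_id")
    out = pd.DataFrame(
        0,
        index=idx.index,
        columns=["edit_count", "edit_count_cds", "edit_count_utr3"],
        dtype=np.int64,
    )
    by_chrom = {
        row["chrom"]: gid for gid, row in idx.iterrows()
    }
    for s in sites:
        if s.confidence <= min_confidence:
            continue
        gid = by_chrom.get(s.ref)
        if gid is None:
            continue
        row = idx.loc[gid]
        if not (row["start"] <= s.pos0 < row["end"]):
            continue
        out.loc[gid, "edit_count"] += s.alt_count
        if row["cds_start"] <= s.pos0 < row["cds_end"]:
            out.loc[gid, "edit_count_cds"] += s.alt_count
        elif row["utr3_start"] <= s.pos0 < row["utr3_end"]:
            out.loc[gid, "edit_count_utr3"] += s.alt_count
    return out


def region_read_counts(alignments, genes: pd.DataFrame) -> pd.DataFrame:
    """Reads per gene assigned to CDS or 3'UTR by the midpoint rule."""
    idx = genes.set_index("gene_id")
    out = pd.DataFrame(
        0, index=idx.index, columns=["reads_cds", "reads_utr3"], dtype=np.int64
    )
    by_chrom = {row["chrom"]: gid for gid, row in idx.iterrows()}
    for ref, s, e in _read_spans(alignments):
        gid = by_chrom.get(ref)
        if gid is None:
            continue
        row = idx.loc[gid]
        mid = (s + e) // 2
        if row["cds_start"] <= mid < row["cds_end"]:
            out.loc[gid, "reads_cds"] += 1
        elif row["utr3_start"] <= mid < row["utr3_end"]:
            out.loc[gid, "reads_utr3"] += 1
    return out


def edits_per_read(
    edit_counts: pd.Series,
    read_counts: pd.Series,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.Series:
    """EPR per gene for genes with read_count >= min_reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    keep = read_counts[read_counts >= min_reads]
    return (edit_counts.reindex(keep.index).fillna(0) / keep).astype(float)


def gene_edit_summary(
    alignments,
    sites: list[EditSite],
    genes: pd.DataFrame,
    *,
    condition: str,
    replicate: int,
    min_reads: int = DEFAULT_MIN_READS,
    min_confidence: float = 0.9,
) -> pd.DataFrame:
    """Full per-gene summary for one library: reads, edits, EPR, region EPRs."""
    read_counts, _ = gene_read_counts(alignments, genes)
    edits = gene_edit_counts(sites, genes, min_confidence=min_confidence)
    region_reads = region_read_counts(alignments, genes)
    epr = edits_per_read(edits["edit_count"], read_counts, min_reads=min_reads)
    rows = []
    for gid in epr.index:
        rc_cds = region_reads.loc[gid, "reads_cds"]
        rc_utr = region_reads.loc[gid, "reads_utr3"]
        rows.append(
            {
                "gene_id": gid,
                "condition": condition,
                "replicate": replicate,
                "read_count": int(read_counts[gid]),
                "edit_count": int(edits.loc[gid, "edit_count"]),
                "epr": float(epr[gid]),
                "epr_cds": float(edits.loc[gid, "edit_count_cds"] / rc_cds)
                if rc_cds > 0
                else np.nan,
                "epr_utr3": float(edits.loc[gid, "edit_count_utr3"] / rc_utr)
                if rc_utr > 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


@dataclass
class GroupContrast:
    t_statistic: float
    p_value: float
    n_group: int
    n_other: int


def epr_fold_change(
    summaries: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-gene treated-versus-control EPR comparison.

    ``summaries`` stacks per-replicate gene summaries for both conditions.
    Genes quantified in every replicate of both conditions get a Welch
    two-sided t-test on replicate EPRs, log2FC with a small offset, BH
    q-values across genes and a decrease/increase/ns call at q < fdr.
    """
    piv = summaries.pivot_table(
        index="gene_id", columns=["condition", "replicate"], values="epr"
    )
    piv = piv.dropna()  # consistently quantifiable in all replicates
    ctrl = piv["control"].to_numpy()
    trt = piv["treated"].to_numpy()
    if ctrl.shape[1] < 2 or trt.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    log2fc = np.log2(mean_t + LOG2_EPS) - np.log2(mean_c + LOG2_EPS)
    t, p = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False)
    # degenerate: zero variance in both conditions with equal means
    degen = ~np.isfinite(p)
    p = np.where(degen, 1.0, p)
    t = np.where(degen, 0.0, t)
    q = bh_adjust(p)
    call = np.where(
        (q < fdr) & (log2fc < 0),
        "decrease",
        np.where((q < fdr) & (log2fc > 0), "increase", "ns"),
    )
    return pd.DataFrame(
        {
            "gene_id": piv.index,
            "mean_epr_control": mean_c,
            "mean_epr_treated": mean_t,
            "log2_fold_change": log2fc,
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "call": call,
        }
    ).reset_index(drop=True)


def group_contrast(
    comparisons: pd.DataFrame, group_members: set[str]
) -> GroupContrast:
    """Welch t-test of log2 fold-changes: group genes versus all others.

    The statistic is oriented so that a *positive* t means the group's EPR
    decreased more than the complement's (the usual direction for
    translation-inhibition contrasts on TOP-like genes).
    """
    genes = set(comparisons["gene_id"])
    group = group_members & genes
    other = genes - group
    if not group or not other:
        raise ValueError("group must be a non-empty proper subset of tested genes")
    lfc = comparisons.set_index("gene_id")["log2_fold_change"]
    g = lfc.loc[sorted(group)].to_numpy()
    o = lfc.loc[sorted(other)].to_numpy()
    t, p = stats.ttest_ind(o, g, equal_var=False)
    return GroupContrast(
        t_statistic=float(t), p_value=float(p), n_group=len(g), n_other=len(o)
    )


def region_epr_ratio(
    summaries: pd.DataFrame, group: set[str] | None = None
) -> tuple[float, pd.Series]:
    """CDS/3'UTR editing ratio for a gene group.

    Returns (ratio of means: mean(epr_cds)/mean(epr_utr3), per-gene ratio
    series).  Genes need epr_utr3 > 0 to enter the per-gene series.
    """
    df = summaries.copy()
    if group is not None:
        df = df[df["gene_id"].isin(group)]
    df = df.dropna(subset=["epr_cds", "epr_utr3"])
    per_gene = df.groupby("gene_id")[["epr_cds", "epr_utr3"]].mean()
    if (per_gene["epr_utr3"] <= 0).all():
        raise ValueError("no genes with positive 3'UTR EPR")
    ok = per_gene["epr_utr3"] > 0
    ratio_of_means = float(
        per_gene["epr_cds"].mean() / per_gene["epr_utr3"].mean()
    )
    per_gene_ratio = per_gene.loc[ok, "epr_cds"] / per_gene.loc[ok, "epr_utr3"]
    return ratio_of_means, per_gene_ratio
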