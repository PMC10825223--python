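"""Significant edit-cluster calling.

The procedure bins confident edit sites into fixed 30-bp windows tiled from
each gene's 5' end, estimates a background editing fraction as the
unweighted mean editing fraction across bins, tests each bin's edited-site
count against a Poisson null with lambda = background * editable positions
(one-sided upper tail), adjusts p-values by Benjamini-Hochberg, retains
bins with q strictly below the FDR threshold (default 0.1), merges retained
bins separated by at most 15 bp into clusters, intersects clusters across
replicates, and finally removes clusters that overlap clusters produced by
the free (unfused) editor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .editcall import BaseCountMatrix, EditSite, SUBSTRATES
from .simdata.enzymes import C2U

log = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 30
DEFAULT_MERGE_GAP = 15
DEFAULT_FDR = 0.1
DEFAULT_CONFIDENCE = 0.9
LAMBDA_FLOOR_PER_SITE = 1e-6  # guards p=0 artifacts when the background is 0


@dataclass
class EditBin:
    ref: str
    start: int
    end: int
    gene_id: str
    editable_count: int
    edited_count: int

    @property
    def editing_fraction(self) -> float:
        return self.edited_count / self.editable_count if self.editable_count else 0.0


@dataclass
class EditCluster:
    ref: str
    start: int
    end: int
    gene_id: str
    n_bins: int
    edited_count: int
    p_value: float
    q_value: float
    replicate_support: int = 1

    def overlaps(self, other: "EditCluster") -> bool:
        return self.ref == other.ref and self.start < other.end and other.start < self.end


def _gene_bins(row, bin_size: int) -> list[tuple[int, int]]:
    """Fixed tiling from the gene's 5' end; terminal partial bins retained."""
    start, end = int(row["start"]), int(row["end"])
    if row.get("strand", "+") == "-":
        # 5' end of a minus-strand gene is its right edge: tile right-to-left
        edges = np.arange(end, start, -bin_size)[::-1]
        lo = np.maximum(start, edges - bin_size)
        return [(int(a), int(b)) for a, b in zip(lo, edges)]
    edges = np.arange(start, end, bin_size)
    return [(int(e), int(min(end, e + bin_size))) for e in edges]


def bin_edits(
    sites: list[EditSite],
    genes: pd.DataFrame,
    coverage: dict[str, BaseCountMatrix] | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_coverage: int = 5,
    edit_type: str = C2U,
    keep_empty: bool = False,
    reference: dict[str, str] | None = None,
) -> list[EditBin]:
    """Tally confident edit sites into 30-bp bins along genes.

    Only genes exhibiting at least one edit are tiled.  With the default
    ``keep_empty=False`` only bins containing an edit are returned; with
    ``keep_empty=True`` every bin of an edited gene is returned (zero-count
    bins included), which keeps the background estimate free of the
    selection bias that conditioning on edited bins would introduce.

    ``editable_count`` is the number of substrate positions in the bin with
    coverage >= min_coverage (from ``coverage``).  Without a coverage matrix
    the sequence in ``reference`` is used and every substrate position
    counts as editable; with neither, the bin width is used.
    """
    sub = SUBSTRATES[(edit_type, "sense")][0]
    by_ref: dict[str, list[EditSite]] = {}
    for s in sites:
        if s.edit_type == edit_type:
            by_ref.setdefault(s.ref, []).append(s)
    n_orphan = 0
    bins: list[EditBin] = []
    for _, row in genes.iterrows():
        ref = row["chrom"]
        gsites = [
            s for s in by_ref.get(ref, []) if row["start"] <= s.pos0 < row["end"]
        ]
        if not gsites:
            continue
        positions = np.array(sorted(s.pos0 for s in gsites))
        mat = coverage.get(ref) if coverage else None
        for b0, b1 in _gene_bins(row, bin_size):
            edited = int(np.sum((positions >= b0) & (positions < b1)))
            if edited == 0 and not keep_empty:
                continue
            if mat is not None:
                seq = np.frombuffer(
                    mat.ref_seq[b0:b1].upper().encode(), dtype=np.uint8
                )
                editable = int(
                    np.sum((seq == ord(sub)) & (mat.coverage[b0:b1] >= min_coverage))
                )
            elif reference is not None and ref in reference:
                editable = reference[ref][b0:b1].upper().count(sub)
            else:
                editable = b1 - b0
            bins.append(
                EditBin(
                    ref=ref,
                    start=b0,
                    end=b1,
                    gene_id=row["gene_id"],
                    editable_count=editable,
                    edited_count=edited,
                )
            )
    for ref, ss in by_ref.items():
        covered = genes[genes["chrom"] == ref]
        for s in ss:
            if not ((covered["start"] <= s.pos0) & (s.pos0 < covered["end"])).any():
                n_orphan += 1
    if n_orphan:
        log.info("%d edit sites fell outside every gene and were dropped", n_orphan)
    return bins


def background_rate(bins: list[EditBin]) -> float:
    """Unweighted mean editing fraction over bins with editable positions."""
    fracs = [b.editing_fraction for b in bins if b.editable_count > 0]
    if not fracs:
        raise ValueError("no bins with editable positions")
    return float(np.mean(fracs))


def poisson_bin_test(bin_: EditBin, bg: float) -> float:
    """One-sided upper-tail Poisson p-value for elevated editing in a bin.

    lambda = bg * editable_count, floored at a tiny per-site rate when the
    background estimate is exactly zero so that p never degenerates to 0.
    """
    if bg < 0:
        raise ValueError("background rate must be >= 0")
    lam = bg * bin_.editable_count
    if lam == 0.0:
        lam = LAMBDA_FLOOR_PER_SITE * max(bin_.editable_count, 1)
    return float(poisson.sf(bin_.edited_count - 1, lam))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_and_merge(
    bins: list[EditBin],
    p_values,
    q_values,
    fdr: float = DEFAULT_FDR,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[EditCluster]:
    """Keep bins with q < fdr (strict) and merge near-adjacent ones.

    Consecutive kept bins on the same reference merge when the gap
    (next.start - prev.end) is at most ``merge_gap``.  Cluster p/q are the
    minima over member bins; coordinates are the union span.
    """
    kept = [
        (b, p, q)
        for b, p, q in zip(bins, p_values, q_values)
        if q < fdr
    ]
    order = sorted(range(len(kept)), key=lambda i: (kept[i][0].ref, kept[i][0].start))
    if order != list(range(len(kept))):
        log.info("filter_and_merge: input bins were not sorted; sorting internally")
    kept = [kept[i] for i in order]
    clusters: list[EditCluster] = []
    cur: list[tuple[EditBin, float, float]] = []

    def flush():
        if not cur:
            return
        bs = [c[0] for c in cur]
        clusters.append(
            EditCluster(
                ref=bs[0].ref,
                start=min(b.start for b in bs),
                end=max(b.end for b in bs),
                gene_id=bs[0].gene_id,
                n_bins=len(bs),
                edited_count=sum(b.edited_count for b in bs),
                p_value=min(c[1] for c in cur),
                q_value=min(c[2] for c in cur),
            )
        )

    for item in kept:
        b = item[0]
        if cur and b.ref == cur[-1][0].ref and b.start - cur[-1][0].end <= merge_gap:
            cur.append(item)
        else:
            flush()
            cur = [item]
    flush()
    return clusters


def replicate_intersect(cluster_sets: list[list[EditCluster]]) -> list[EditCluster]:
    """Clusters from set 1 that overlap (>= 1 bp) a cluster in every other set."""
    if len(cluster_sets) < 2:
        raise ValueError("need at least two replicate cluster sets")
    out = []
    for c in cluster_sets[0]:
        support = 1 + sum(
            any(c.overlaps(o) for o in other) for other in cluster_sets[1:]
        )
        if support == len(cluster_sets):
            out.append(
                EditCluster(
                    ref=c.ref,
                    start=c.start,
                    end=c.end,
                    gene_id=c.gene_id,
                    n_bins=c.n_bins,
                    edited_count=c.edited_count,
                    p_value=c.p_value,
                    q_value=c.q_value,
                    replicate_support=support,
                )
            )
    return out


def subtract_background(
    rbp_clusters: list[EditCluster], free_rbe_clusters: list[EditCluster]
) -> list[EditCluster]:
    """Drop RBP-fusion clusters overlapping any free-editor cluster."""
    return [
        c
        for c in rbp_clusters
        if not any(c.overlaps(f) for f in free_rbe_clusters)
    ]


def call_clusters(
    sites: list[EditSite],
    genes: pd.DataFrame,
    coverage: dict[str, BaseCountMatrix] | None = None,
    *,
    edit_type: str = C2U,
    min_confidence: float = DEFAULT_CONFIDENCE,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_coverage: int = 5,
    fdr: float = DEFAULT_FDR,
    merge_gap: int = DEFAULT_MERGE_GAP,
    reference: dict[str, str] | None = None,
) -> list[EditCluster]:
    """Single-replicate pipeline: confidence filter, bin, test, adjust, merge.

    Bins every bin of genes exhibiting edits (zero-count bins included) so
    the background mean is not conditioned on observing an edit.
    """
    confident = [s for s in sites if s.confidence > min_confidence]
    bins = bin_edits(
        confident,
        genes,
        coverage,
        bin_size=bin_size,
        min_coverage=min_coverage,
        edit_type=edit_type,
        keep_empty=True,
        reference=reference,
    )
    if not bins:
        return []
    bg = background_rate(bins)
    p = np.array([poisson_bin_test(b, bg) for b in bins])
    q = bh_adjust(p)
    return filter_and_merge(bins, p, q, fdr=fdr, merge_gap=merge_gap)


def clusters_to_frame(clusters: list[EditCluster]) -> pd.DataFrame:
    """BED6+ layout: chrom, start, end, name(gene), score(-log10 q), strand, p, q, edits."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "chrom": c.ref,
                "start": c.start,
                "end": c.end,
                "name": c.gene_id,
                "score": round(-np.log10(max(c.q_value, 1e-300)), 4),
                "strand": "+",
                "p_value": c.p_value,
                "q_value": c.q_value,
                "edited_count": c.edited_count,
                "replicate_support": c.replicate_support,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "name",
            "score",
            "strand",
            "p_value",
            "q_value",
            "edited_count",
            "replicate_support",
        ],
    )


def write_clusters(clusters: list[EditCluster], path) -> None:
    clusters_to_frame(clusters).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
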