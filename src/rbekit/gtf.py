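"""Gene-model I/O.

GTF files are 1-based inclusive on disk; everything in memory is 0-based
half-open.  The internal gene-model frame has one row per gene: chrom,
start, end, strand, gene_id, cds_start, cds_end, utr3_start, utr3_end, top.
"""

from __future__ import annotations

import pandas as pd

GENE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "gene_id",
    "cds_start",
    "cds_end",
    "utr3_start",
    "utr3_end",
    "top",
]


def write_gene_models(genes: pd.DataFrame, path) -> None:
    """Emit transcript/CDS/three_prime_utr GTF lines (1-based inclusive).

    The transcript line carries ``top "1"`` or ``top "0"``.
    """
    with open(path, "w") as fh:
        for _, r in genes.iterrows():
            attrs = (
                f'gene_id "{r.gene_id}"; transcript_id "{r.gene_id}.t1"; '
                f'top "{1 if r.top else 0}";'
            )
            base = [r.chrom, "rbekit", None, None, None, ".", r.strand, ".", attrs]
            for feature, s, e in (
                ("transcript", r.start, r.end),
                ("CDS", r.cds_start, r.cds_end),
                ("three_prime_utr", r.utr3_start, r.utr3_end),
            ):
                if e <= s:
                    continue
                row = list(base)
                row[2], row[3], row[4] = feature, int(s) + 1, int(e)
                fh.write("\t".join(str(x) for x in row) + "\n")


def read_gene_models(path) -> pd.DataFrame:
    """Parse a GTF into the internal 0-based half-open gene-model frame."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    required = {"Feature", "Start", "End", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GTF is missing mandatory fields: {sorted(missing)}")
    rows = []
    for gid, grp in df.groupby("gene_id", sort=True):
        tx = grp[grp["Feature"] == "transcript"]
        cds = grp[grp["Feature"] == "CDS"]
        utr = grp[grp["Feature"] == "three_prime_utr"]
        if tx.empty:
            raise ValueError(f"gene {gid} has no transcript feature")
        t = tx.iloc[0]
        top = False
        if "top" in tx.columns and not pd.isna(t.get("top")):
            top = str(t["top"]) in ("1", "True", "true")
        rows.append(
            {
                "chrom": t["Chromosome"],
                "start": int(t["Start"]),
                "end": int(t["End"]),
                "strand": t.get("Strand", "+"),
                "gene_id": gid,
                "cds_start": int(cds["Start"].min()) if not cds.empty else int(t["Start"]),
                "cds_end": int(cds["End"].max()) if not cds.empty else int(t["Start"]),
                "utr3_start": int(utr["Start"].min()) if not utr.empty else int(t["End"]),
                "utr3_end": int(utr["End"].max()) if not utr.empty else int(t["End"]),
                "top": top,
            }
        )
    out = pd.DataFrame(rows, columns=GENE_COLUMNS)
    bad = out[(out["cds_start"] < out["start"]) | (out["cds_end"] > out["end"])]
    if not bad.empty:
        raise ValueError("CDS intervals extend outside their transcript")
    return out


def write_fasta(seqs: dict[str, str], path, line_width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(intervals: pd.DataFrame, path) -> None:
    """BED (0-based half-open): chrom, start, end [, name, score, strand]."""
    cols = ["chrom", "start", "end"]
    for extra in ("name", "score", "strand"):
        if extra in intervals.columns:
            cols.append(extra)
        else:
            break
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df
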