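"""Per-position base counting and edit-site calling.

A :class:`BaseCountMatrix` tallies A/C/G/T observations at every reference
position from aligned reads (quality-filtered).  :func:`call_edits` turns a
matrix into candidate C-to-U or A-to-I sites with a Beta-posterior
confidence score: the posterior probability, under a flat Beta(1,1) prior
and a binomial likelihood, that the true editing fraction exceeds the
sequencing-error rate.  The confidence plays the role of a per-site edit
score with the conventional 0.9 high-confidence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .simdata.enzymes import A2I, C2U, DUAL

_ENC = {b: i for i, b in enumerate("ACGT")}

DEFAULT_MIN_BASEQ = 20
DEFAULT_MIN_COVERAGE = 5
DEFAULT_ERROR_RATE = 1e-3

#: (substrate base, alt base) in reference coordinates for each channel and
#: library orientation; "sense" means reads report the transcript strand.
SUBSTRATES = {
    (C2U, "sense"): ("C", "T"),
    (C2U, "antisense"): ("G", "A"),
    (A2I, "sense"): ("A", "G"),
    (A2I, "antisense"): ("T", "C"),
}

SITE_COLUMNS = [
    "ref",
    "pos0",
    "strand",
    "edit_type",
    "ref_base",
    "alt_base",
    "coverage",
    "alt_count",
    "fraction",
    "confidence",
]


@dataclass
class BaseCountMatrix:
    """Per-position A/C/G/T counts and coverage for one reference sequence.

    ``counts`` is (L, 4) in A,C,G,T order; ``coverage`` counts every aligned
    base that passed the quality filter (including N), so
    counts.sum(axis=1) <= coverage everywhere.
    """

    ref: str
    ref_seq: str
    counts: np.ndarray
    coverage: np.ndarray
    strandedness: str = "sense"

    def __post_init__(self) -> None:
        n = len(self.ref_seq)
        if self.counts.shape != (n, 4) or self.coverage.shape != (n,):
            raise ValueError("count matrix shape inconsistent with reference")

    @classmethod
    def zeros(cls, ref: str, ref_seq: str, strandedness: str = "sense"):
        n = len(ref_seq)
        return cls(
            ref=ref,
            ref_seq=ref_seq,
            counts=np.zeros((n, 4), dtype=np.int64),
            coverage=np.zeros(n, dtype=np.int64),
            strandedness=strandedness,
        )

    def add_read(self, start: int, seq: str, quals=None, min_baseq: int = 0) -> None:
        for j, ch in enumerate(seq):
            if quals is not None and quals[j] < min_baseq:
                continue
            pos = start + j
            self.coverage[pos] += 1
            code = _ENC.get(ch.upper())
            if code is not None:
                self.counts[pos, code] += 1


def count_simulated(
    sim_reads, min_baseq: int = DEFAULT_MIN_BASEQ
) -> dict[str, BaseCountMatrix]:
    """Base-count matrices straight from in-memory simulated reads."""
    out = {
        r: BaseCountMatrix.zeros(r, seq) for r, seq in sim_reads.reference.items()
    }
    for rd in sim_reads.reads:
        out[rd.ref].add_read(rd.start, rd.seq)
    return out


def pileup_counts(
    alignments,
    reference,
    min_base_quality: int = DEFAULT_MIN_BASEQ,
    region: tuple[str, int, int] | None = None,
) -> dict[str, BaseCountMatrix]:
    """Count bases per position from a SAM/BAM file.

    ``reference`` is a {name: sequence} mapping or a FASTA path (read via
    pyfaidx).  Unmapped, secondary, supplementary and duplicate reads are
    skipped; bases below ``min_base_quality`` are excluded.  With ``region``
    (ref, start, end) the file must be position-indexable (BAM + index).
    """
    import pysam

    if isinstance(reference, (str,)) or hasattr(reference, "__fspath__"):
        from pyfaidx import Fasta

        fa = Fasta(str(reference))
        reference = {name: str(fa[name][:]) for name in fa.keys()}
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        close = True
    try:
        for sn in alignments.references:
            if sn not in reference:
                raise ValueError(f"alignment reference {sn!r} missing from FASTA")
        out = {r: BaseCountMatrix.zeros(r, reference[r]) for r in alignments.references}
        it = (
            alignments.fetch(region[0], region[1], region[2])
            if region is not None
            else alignments.fetch(until_eof=True)
        )
        for read in it:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            mat = out[read.reference_name]
            quals = read.query_qualities
            seq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                if region is not None and not (region[1] <= rpos < region[2]):
                    continue
                mat.coverage[rpos] += 1
                code = _ENC.get(seq[qpos].upper())
                if code is not None:
                    mat.counts[rpos, code] += 1
    finally:
        if close:
            alignments.close()
    return out


@dataclass(frozen=True)
class EditSite:
    ref: str
    pos0: int
    edit_type: str
    ref_base: str
    alt_base: str
    coverage: int
    alt_count: int
    fraction: float
    confidence: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.alt_count <= self.coverage):
            raise ValueError("alt_count must be in [0, coverage]")


def edit_confidence(
    alt_count: np.ndarray, coverage: np.ndarray, error_rate: float
) -> np.ndarray:
    """P(true edit fraction > error_rate | counts) under a Beta(1,1) prior."""
    return beta_dist.sf(error_rate, alt_count + 1, coverage - alt_count + 1)


def call_edits(
    matrix: BaseCountMatrix,
    edit_type: str,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    error_rate: float = DEFAULT_ERROR_RATE,
    snv_mask=None,
) -> list[EditSite]:
    """Call candidate edit sites of one channel from a count matrix.

    A site is reported iff the reference base is the channel's substrate
    (on the matrix's library orientation), coverage >= min_coverage,
    at least one alt read is present, and the position is not masked.
    ``snv_mask`` is an iterable of (start, end) intervals or positions to
    exclude (e.g. known SNVs).
    """
    if edit_type == DUAL:
        raise ValueError("expand DUAL into separate C2U and A2I calls")
    if edit_type not in (C2U, A2I):
        raise ValueError(f"unknown edit_type {edit_type!r}")
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if not (0.0 < error_rate < 1.0):
        raise ValueError("error_rate must be in (0, 1)")
    sub, alt = SUBSTRATES[(edit_type, matrix.strandedness)]
    seq = np.frombuffer(matrix.ref_seq.upper().encode(), dtype=np.uint8)
    is_sub = seq == ord(sub)
    cov = matrix.coverage
    altc = matrix.counts[:, _ENC[alt]]
    masked = np.zeros(seq.size, dtype=bool)
    if snv_mask is not None:
        for iv in snv_mask:
            if np.isscalar(iv):
                masked[int(iv)] = True
            else:
                masked[int(iv[0]) : int(iv[1])] = True
    keep = is_sub & (cov >= min_coverage) & (altc >= 1) & ~masked
    pos = np.nonzero(keep)[0]
    conf = edit_confidence(altc[pos], cov[pos], error_rate)
    return [
        EditSite(
            ref=matrix.ref,
            pos0=int(p),
            edit_type=edit_type,
            ref_base=sub,
            alt_base=alt,
            coverage=int(cov[p]),
            alt_count=int(altc[p]),
            fraction=float(altc[p] / cov[p]),
            confidence=float(c),
        )
        for p, c in zip(pos, conf)
    ]


def combine_edit_channels(
    c2u_sites: list[EditSite], a2i_sites: list[EditSite]
) -> list[EditSite]:
    """Merge the two channels of a dual editor into one sorted site list."""
    merged = sorted(
        list(c2u_sites) + list(a2i_sites), key=lambda s: (s.ref, s.pos0, s.edit_type)
    )
    seen = set()
    for s in merged:
        key = (s.ref, s.pos0, s.edit_type)
        if key in seen:
            raise ValueError(f"duplicate edit site {key}")
        seen.add(key)
    return merged


def sites_to_frame(sites: list[EditSite]) -> pd.DataFrame:
    rows = [
        {
            "ref": s.ref,
            "pos0": s.pos0,
            "strand": s.strand,
            "edit_type": s.edit_type,
            "ref_base": s.ref_base,
            "alt_base": s.alt_base,
            "coverage": s.coverage,
            "alt_count": s.alt_count,
            "fraction": s.fraction,
            "confidence": s.confidence,
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def frame_to_sites(frame: pd.DataFrame) -> list[EditSite]:
    return [
        EditSite(
            ref=r.ref,
            pos0=int(r.pos0),
            edit_type=r.edit_type,
            ref_base=r.ref_base,
            alt_base=r.alt_base,
            coverage=int(r.coverage),
            alt_count=int(r.alt_count),
            fraction=float(r.fraction),
            confidence=float(r.confidence),
            strand=r.strand,
        )
        for r in frame.itertuples()
    ]


def write_sites(sites: list[EditSite], path) -> None:
    """EditSite TSV: 0-based positions (column pos0), stable column order."""
    sites_to_frame(sites).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_sites(path) -> list[EditSite]:
    return frame_to_sites(pd.read_csv(path, sep="\t"))
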