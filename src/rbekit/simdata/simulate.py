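"""Simulated transcriptomes and edited sequencing reads with full ground truth.

Everything downstream of alignment is testable against the truth records
produced here: per-position expected edit probabilities, bound-site
intervals, per-read lists of introduced edits, and per-gene ribosome loads.
Reads are single-end, sense-strand, ungapped (the emitted SAM records are
already placed on the reference, so no external aligner is involved).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enzymes import CHANNEL_BASES, EnzymeModel, weight_matrix

BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(BASES)}
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_ERROR_RATE = 1e-3
DEFAULT_READ_LENGTH = 100  # single-end short-read geometry
TOP_TRACT = "CTTTCCTTTC"  # pyrimidine-rich 5' tract planted on TOP-like genes


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3 (other characters -> 4)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for b, i in _ENC.items():
        out[arr == ord(b)] = i
    return out


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode()


@dataclass
class SimTruth:
    """Ground-truth record for a simulation run.

    site_probs[ref][channel] is the per-position expected per-read edit
    probability; bound_sites[enzyme][ref] lists (start, end) recruitment
    intervals; motif_sites[ref] lists planted motif start positions;
    loads[condition][gene] are per-gene ribosome loads (translation sims).
    """

    site_probs: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    bound_sites: dict[str, dict[str, list[tuple[int, int]]]] = field(
        default_factory=dict
    )
    motif_sites: dict[str, list[int]] = field(default_factory=dict)
    loads: dict[str, pd.Series] = field(default_factory=dict)


@dataclass(frozen=True)
class SimRead:
    name: str
    ref: str
    start: int
    seq: str
    edits: tuple[tuple[int, str], ...]  # (reference position, channel)
    errors: tuple[int, ...] = ()

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass
class SimReads:
    """A batch of simulated reads plus the reference they were drawn from."""

    reads: list[SimRead]
    reference: dict[str, str]

    def __len__(self) -> int:
        return len(self.reads)

    def total_edits(self) -> int:
        return sum(len(r.edits) for r in self.reads)

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.name}\n{r.seq}\n+\n{'F' * len(r.seq)}\n")

    def write_sam(self, path) -> None:
        """Ungapped sense-strand SAM (MAPQ 60, CIGAR <len>M, Phred 'F')."""
        import pysam

        names = list(self.reference)
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": len(self.reference[n])} for n in names],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            for r in self.reads:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = r.name
                a.query_sequence = r.seq
                a.flag = 0
                a.reference_id = names.index(r.ref)
                a.reference_start = r.start
                a.mapping_quality = 60
                a.cigarstring = f"{len(r.seq)}M"
                a.query_qualities = pysam.qualitystring_to_array("F" * len(r.seq))
                fh.write(a)


# ---------------------------------------------------------------------------
# toy transcriptome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptomeSpec:
    """Parameters of the toy transcriptome generator.

    One transcript per gene, laid out as a short 5' leader, a CDS and a
    3'UTR, each transcript on its own reference sequence (transcript space).
    ``length_model`` holds normal-distribution parameters for CDS and 3'UTR
    lengths; ``top_fraction`` of genes are flagged TOP-like and receive a
    pyrimidine tract at their 5' end.
    """

    n_genes: int
    length_model: dict = field(
        default_factory=lambda: {
            "cds_mean": 900,
            "cds_sd": 300,
            "utr3_mean": 500,
            "utr3_sd": 150,
        }
    )
    gc_content: float = 0.5
    motif: str = "GCATG"
    motif_genes_fraction: float = 0.6
    top_fraction: float = 0.2
    leader_len: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for k, v in self.length_model.items():
            if v <= 0:
                raise ValueError(f"length_model[{k!r}] must be positive")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")


def _draw_len(rng, mean, sd, lo):
    return max(lo, int(round(rng.normal(mean, sd))))


def simulate_transcriptome(
    spec: TranscriptomeSpec,
) -> tuple[dict[str, str], pd.DataFrame, SimTruth]:
    """Generate (reference sequences, gene models, truth).

    The gene-model frame has one row per gene with 0-based half-open
    transcript-space coordinates: chrom (== transcript id), start, end,
    strand, gene_id, cds_start, cds_end, utr3_start, utr3_end, top.
    """
    rng = np.random.default_rng(spec.seed)
    lm = spec.length_model
    n_top = int(round(spec.top_fraction * spec.n_genes))
    top_flags = np.zeros(spec.n_genes, dtype=bool)
    top_flags[:n_top] = True

    seqs: dict[str, str] = {}
    rows = []
    truth = SimTruth()
    p_gc = spec.gc_content / 2.0
    p_at = (1.0 - spec.gc_content) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]
    for i in range(spec.n_genes):
        gid = f"g{i + 1:04d}"
        cds_len = 3 * (_draw_len(rng, lm["cds_mean"], lm["cds_sd"], 150) // 3)
        utr3_len = _draw_len(rng, lm["utr3_mean"], lm["utr3_sd"], 100)
        total = spec.leader_len + cds_len + utr3_len
        arr = rng.choice(4, size=total, p=probs).astype(np.uint8)
        if top_flags[i]:
            tract = encode(TOP_TRACT)
            arr[: len(tract)] = tract
        # plant the RBP motif in some 3'UTRs
        motif_starts: list[int] = []
        if rng.random() < spec.motif_genes_fraction and spec.motif:
            m = encode(spec.motif)
            n_m = rng.integers(1, 4)
            lo = spec.leader_len + cds_len
            hi = total - len(m)
            for _ in range(n_m):
                s = int(rng.integers(lo, hi))
                arr[s : s + len(m)] = m
                motif_starts.append(s)
        seqs[gid] = decode(arr)
        truth.motif_sites[gid] = sorted(set(motif_starts))
        rows.append(
            {
                "chrom": gid,
                "start": 0,
                "end": total,
                "strand": "+",
                "gene_id": gid,
                "cds_start": spec.leader_len,
                "cds_end": spec.leader_len + cds_len,
                "utr3_start": spec.leader_len + cds_len,
                "utr3_end": total,
                "top": bool(top_flags[i]),
            }
        )
    genes = pd.DataFrame(rows)
    return seqs, genes, truth


def plant_bound_sites(
    seqs: dict[str, str],
    genes: pd.DataFrame,
    n_sites: int,
    rng: np.random.Generator,
    *,
    width: int = 8,
    region: str = "utr3",
    composition: dict[str, float] | None = None,
    flank: int = 30,
    margin: int | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Choose recruitment sites and optionally skew the local composition.

    Returns {ref: [(start, end), ...]} and, when ``composition`` is given
    (base -> probability), resamples ``flank`` bp on each side of every site
    from that distribution.  This emulates the empirical observation that
    different editors cluster in compositionally distinct neighbourhoods.
    ``margin`` keeps sites away from the region edges (defaults to
    ``flank``); a larger margin keeps sites inside the uniformly covered
    body of the transcript.  Mutates ``seqs`` in place when resampling.
    """
    if margin is None:
        margin = flank
    sites: dict[str, list[tuple[int, int]]] = {}
    order = list(genes.index)
    comp = None
    if composition is not None:
        comp = np.array([composition.get(b, 0.0) for b in BASES], dtype=float)
        comp = comp / comp.sum()
    for k in range(n_sites):
        row = genes.loc[order[k % len(order)]]
        gid = row["chrom"]
        lo, hi = (
            (row["utr3_start"], row["utr3_end"])
            if region == "utr3"
            else (row["start"], row["end"])
        )
        if hi - lo <= width + 2 * margin:
            continue
        s = int(rng.integers(lo + margin, hi - width - margin))
        sites.setdefault(gid, []).append((s, s + width))
        if comp is not None:
            arr = encode(seqs[gid])
            a, b = max(0, s - flank), min(len(arr), s + width + flank)
            arr[a:b] = rng.choice(4, size=b - a, p=comp).astype(np.uint8)
            seqs[gid] = decode(arr)
    return {g: sorted(v) for g, v in sites.items()}


# ---------------------------------------------------------------------------
# edit probability profiles and read simulation
# ---------------------------------------------------------------------------


def channel_edit_probs(
    refseq: str,
    enzyme: EnzymeModel,
    sites: list[tuple[int, int]] | None,
) -> dict[str, np.ndarray]:
    """Per-position per-read edit probability for each channel of an enzyme.

    Recruited editing decays with distance from the nearest bound-site
    midpoint; the intrinsic flanking-context weight multiplies both the
    recruited and the background term, and the two combine independently:
    p = 1 - (1 - peak*kernel*w) * (1 - background*w), which is always <= 1.
    """
    arr = encode(refseq)
    n = arr.size
    if sites:
        mids = np.array([(s + e) / 2.0 for s, e in sites])
        dist = np.min(np.abs(np.arange(n)[:, None] - mids[None, :]), axis=1)
    else:
        dist = None
    out: dict[str, np.ndarray] = {}
    for channel, peak, background, weights in enzyme.channels():
        sub = _ENC[CHANNEL_BASES[channel][0]]
        wmat = weight_matrix(weights)
        w = np.ones(n)
        valid = (arr[:-2] < 4) & (arr[2:] < 4)
        w[1:-1][valid] = wmat[arr[:-2][valid], arr[2:][valid]]
        p_rec = np.zeros(n)
        if dist is not None and peak > 0:
            p_rec = np.minimum(1.0, peak * enzyme.kernel(dist) * w)
        p_bg = np.minimum(1.0, background * w)
        p = 1.0 - (1.0 - p_rec) * (1.0 - p_bg)
        p[arr != sub] = 0.0
        out[channel] = p
    return out


def _combine_probs(per_enzyme: list[dict[str, np.ndarray]], n: int) -> dict[str, np.ndarray]:
    combined: dict[str, np.ndarray] = {}
    for probs in per_enzyme:
        for channel, p in probs.items():
            if channel not in combined:
                combined[channel] = np.zeros(n)
            combined[channel] = 1.0 - (1.0 - combined[channel]) * (1.0 - p)
    return combined


def _sample_reads(
    reference: dict[str, str],
    probs: dict[str, dict[str, np.ndarray]],
    n_reads: int,
    read_length: int,
    rng: np.random.Generator,
    error_rate: float,
    ref_weights: np.ndarray | None = None,
    name_prefix: str = "read",
) -> list[SimRead]:
    names = list(reference)
    arrs = {r: encode(reference[r]) for r in names}
    n_starts = np.array(
        [max(1, len(reference[r]) - read_length + 1) for r in names], dtype=float
    )
    if ref_weights is None:
        ref_weights = n_starts
    w = np.asarray(ref_weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("reference weights must have positive sum")
    ref_idx = rng.choice(len(names), size=n_reads, p=w / w.sum())
    reads: list[SimRead] = []
    alt_code = {c: _ENC[CHANNEL_BASES[c][1]] for c in ("C2U", "A2I")}
    for i in range(n_reads):
        ref = names[ref_idx[i]]
        arr = arrs[ref]
        L = min(read_length, arr.size)
        start = int(rng.integers(0, arr.size - L + 1))
        seg = arr[start : start + L].copy()
        edits: list[tuple[int, str]] = []
        for channel, p in probs.get(ref, {}).items():
            pp = p[start : start + L]
            hit = np.nonzero(rng.random(L) < pp)[0]
            for j in hit:
                seg[j] = alt_code[channel]
                edits.append((start + int(j), channel))
        errors: list[int] = []
        if error_rate > 0:
            err = np.nonzero(rng.random(L) < error_rate)[0]
            for j in err:
                seg[j] = (seg[j] + int(rng.integers(1, 4))) % 4
                errors.append(start + int(j))
        edits.sort()
        reads.append(
            SimRead(
                name=f"{name_prefix}{i:07d}",
                ref=ref,
                start=start,
                seq=decode(seg),
                edits=tuple(edits),
                errors=tuple(errors),
            )
        )
    return reads


def simulate_reads(
    reference: dict[str, str],
    truth_sites: dict[str, dict[str, list[tuple[int, int]]]],
    enzymes: list[EnzymeModel],
    n_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int = 0,
    *,
    error_rate: float = DEFAULT_ERROR_RATE,
    ref_weights: np.ndarray | None = None,
) -> tuple[SimReads, SimTruth]:
    """Simulate edited sequencing reads.

    ``truth_sites[enzyme.name][ref]`` lists the recruitment intervals of each
    enzyme (may be empty or missing for free editors).  An empty enzyme list
    gives an error-only control.  A substitution-only sequencing-error
    process runs after editing; with ``error_rate=0`` every non-reference
    base in the output is a recorded edit.
    """
    if read_length > min(len(s) for s in reference.values()):
        raise ValueError("read_length exceeds the shortest reference")
    rng = np.random.default_rng(seed)
    truth = SimTruth()
    per_ref: dict[str, list[dict[str, np.ndarray]]] = {r: [] for r in reference}
    for enz in enzymes:
        enz_sites = truth_sites.get(enz.name, {})
        truth.bound_sites[enz.name] = {r: list(v) for r, v in enz_sites.items()}
        for ref, seq in reference.items():
            per_ref[ref].append(
                channel_edit_probs(seq, enz, enz_sites.get(ref))
            )
    for ref, seq in reference.items():
        truth.site_probs[ref] = _combine_probs(per_ref[ref], len(seq))
    reads = _sample_reads(
        reference,
        truth.site_probs,
        n_reads,
        read_length,
        rng,
        error_rate,
        ref_weights=ref_weights,
    )
    return SimReads(reads=reads, reference=dict(reference)), truth


# ---------------------------------------------------------------------------
# translation (edits-per-read) simulation
# ---------------------------------------------------------------------------


def default_treated_loads(
    genes: pd.DataFrame, loads_control: pd.Series
) -> pd.Series:
    """Translation-inhibited condition: TOP genes 4-fold down, others 1.25-fold."""
    factor = np.where(genes.set_index("gene_id").loc[loads_control.index, "top"], 4.0, 1.25)
    return loads_control / factor


def _coverage_fraction(n: int, read_length: int) -> np.ndarray:
    """Fraction of uniform read placements covering each position."""
    L = min(read_length, n)
    n_starts = n - L + 1
    pos = np.arange(n)
    first = np.maximum(0, pos - L + 1)
    last = np.minimum(pos, n_starts - 1)
    return np.maximum(0, last - first + 1) / n_starts


def translation_edit_probs(
    refseq: str,
    load: float,
    *,
    epr_scale: float,
    cds_bias: float,
    cds_interval: tuple[int, int],
    read_length: int,
    substrate: str = "C",
) -> np.ndarray:
    """Per-position edit probabilities giving expected edits/read = load*epr_scale.

    Substrate positions inside the CDS are weighted ``cds_bias``-fold above
    3'UTR positions; the profile is normalized against the uniform read
    coverage profile so the per-read expectation is exact.
    """
    arr = encode(refseq)
    w = np.zeros(arr.size)
    w[arr == _ENC[substrate]] = 1.0
    c0, c1 = cds_interval
    w[c0:c1] *= cds_bias
    cov = _coverage_fraction(arr.size, read_length)
    denom = float((w * cov).sum())
    if denom == 0:
        return np.zeros(arr.size)
    p = load * epr_scale * w / denom
    return np.minimum(p, 0.9)


def simulate_translation(
    reference: dict[str, str],
    genes: pd.DataFrame,
    loads_control: pd.Series,
    loads_treated: pd.Series,
    *,
    epr_scale: float = 1.0,
    cds_bias: float = 1.0,
    reads_per_gene: float = 30.0,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int = 0,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> tuple[SimReads, SimReads, SimTruth]:
    """Simulate one replicate pair of ribosome-tethered editing experiments.

    Expected per-gene edits-per-read equals load * epr_scale in each
    condition; reads are allocated to genes multinomially with equal
    per-gene expectation (``reads_per_gene``).
    """
    gene_ids = list(genes["gene_id"])
    for loads, lab in ((loads_control, "control"), (loads_treated, "treated")):
        if set(loads.index) != set(gene_ids):
            raise ValueError(f"loads_{lab} index does not match gene models")
        if (loads <= 0).any():
            raise ValueError(f"loads_{lab} must be strictly positive")
    rng = np.random.default_rng(seed)
    truth = SimTruth()
    truth.loads = {"control": loads_control, "treated": loads_treated}
    gmeta = genes.set_index("gene_id")
    out = []
    for cond, loads in (("control", loads_control), ("treated", loads_treated)):
        probs: dict[str, dict[str, np.ndarray]] = {}
        for gid in gene_ids:
            row = gmeta.loc[gid]
            probs[gid] = {
                "C2U": translation_edit_probs(
                    reference[gid],
                    float(loads[gid]),
                    epr_scale=epr_scale,
                    cds_bias=cds_bias,
                    cds_interval=(int(row["cds_start"]), int(row["cds_end"])),
                    read_length=read_length,
                )
            }
        n_reads = int(round(reads_per_gene * len(gene_ids)))
        reads = _sample_reads(
            reference,
            probs,
            n_reads,
            read_length,
            rng,
            error_rate,
            ref_weights=np.ones(len(reference)),
            name_prefix=f"{cond}_",
        )
        if cond == "control":
            truth.site_probs = probs
        out.append(SimReads(reads=reads, reference=dict(reference)))
    return out[0], out[1], truth
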