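"""Reporter-mRNA analyses: editing profiles, spillover, on/off-target ratio.

The per-position profile reports, at every reference-C position, the
fraction of covered bases read as T (C-to-U), and at every reference-A
position the fraction read as G (A-to-I) — the standard way tethered-editing
reporter screens are displayed.  The spillover index quantifies editing that
leaked from the stem-loop region into the CDS, and the on/off-target ratio
is the screen's signal-to-noise metric: edited-base observations on the
reporter divided by edited-base observations on the rest of the
transcriptome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .editcall import BaseCountMatrix
from .simdata.constructs import ReporterSpec

_ENC = {b: i for i, b in enumerate("ACGT")}


@dataclass
class ReporterProfile:
    """Per-position editing fractions along a reporter construct.

    ``frame`` columns: pos0, region (CDS / UTR3 / loop kind), coverage,
    c2u_fraction (T/(C+T) at reference-C positions, 0 elsewhere),
    a2i_fraction (G/(A+G) at reference-A positions), c2u_edited, a2i_edited
    (edited-read counts).  Positions with zero coverage carry NaN fractions.
    """

    construct: str
    frame: pd.DataFrame

    def masked(self, min_coverage: int) -> pd.DataFrame:
        """Fractions with low-coverage positions masked to NaN (not zero)."""
        out = self.frame.copy()
        low = out["coverage"] < min_coverage
        out.loc[low, ["c2u_fraction", "a2i_fraction"]] = np.nan
        return out


@dataclass
class OnOffReport:
    sample: str
    on_target_edits: int
    off_target_edits: int

    @property
    def undefined(self) -> bool:
        return self.off_target_edits == 0

    @property
    def ratio(self) -> float:
        if self.undefined:
            return math.nan
        return self.on_target_edits / self.off_target_edits


def _annotate(spec: ReporterSpec, n: int) -> list[str]:
    region = ["UTR3"] * n
    c0, c1 = spec.cds_interval
    for i in range(c0, c1):
        region[i] = "CDS"
    for kind, s, e in spec.loop_intervals:
        for i in range(s, e):
            region[i] = kind
    return region


def profile_reporter(
    matrix: BaseCountMatrix,
    spec: ReporterSpec,
    edit_types: tuple[str, ...] = ("C2U", "A2I"),
) -> ReporterProfile:
    """Per-position edit-fraction tracks for a reporter count matrix."""
    if len(matrix.ref_seq) != len(spec.full_seq):
        raise ValueError("count matrix length does not match the construct")
    seq = np.frombuffer(spec.full_seq.upper().encode(), dtype=np.uint8)
    n = seq.size
    counts = matrix.counts
    c2u_frac = np.zeros(n)
    a2i_frac = np.zeros(n)
    c2u_edited = np.zeros(n, dtype=np.int64)
    a2i_edited = np.zeros(n, dtype=np.int64)
    if "C2U" in edit_types:
        is_c = seq == ord("C")
        denom = counts[:, _ENC["C"]] + counts[:, _ENC["T"]]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denom > 0, counts[:, _ENC["T"]] / denom, np.nan)
        c2u_frac = np.where(is_c, frac, 0.0)
        c2u_edited = np.where(is_c, counts[:, _ENC["T"]], 0)
    if "A2I" in edit_types:
        is_a = seq == ord("A")
        denom = counts[:, _ENC["A"]] + counts[:, _ENC["G"]]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denom > 0, counts[:, _ENC["G"]] / denom, np.nan)
        a2i_frac = np.where(is_a, frac, 0.0)
        a2i_edited = np.where(is_a, counts[:, _ENC["G"]], 0)
    cov = matrix.coverage.astype(np.int64)
    c2u_frac = np.where(cov > 0, c2u_frac, np.nan)
    a2i_frac = np.where(cov > 0, a2i_frac, np.nan)
    frame = pd.DataFrame(
        {
            "pos0": np.arange(n),
            "region": _annotate(spec, n),
            "coverage": cov,
            "c2u_fraction": c2u_frac,
            "a2i_fraction": a2i_frac,
            "c2u_edited": c2u_edited,
            "a2i_edited": a2i_edited,
        }
    )
    return ReporterProfile(construct=spec.name, frame=frame)


def spillover_index(profile: ReporterProfile) -> float:
    """Fraction of edited-read observations that fall in the CDS.

    Returns NaN (undefined, not zero) when the construct carries no edits.
    """
    f = profile.frame
    edited = f["c2u_edited"] + f["a2i_edited"]
    total = int(edited.sum())
    if total == 0:
        return math.nan
    return float(edited[f["region"] == "CDS"].sum() / total)


def on_off_ratio(
    construct_edit_count: int, genome_edit_count: int, sample: str = ""
) -> OnOffReport:
    """Signal-to-noise: on-target edited bases / off-target edited bases."""
    if construct_edit_count < 0 or genome_edit_count < 0:
        raise ValueError("edit counts must be non-negative")
    return OnOffReport(
        sample=sample,
        on_target_edits=construct_edit_count,
        off_target_edits=genome_edit_count,
    )


def combined_on_off(
    per_replicate: list[tuple[int, int]], mode: str = "pooled", sample: str = ""
):
    """Combine replicate (on, off) counts.

    ``mode="pooled"`` sums edits across replicates before forming one ratio;
    ``mode="per_replicate"`` returns one report per replicate (the boxplot
    contract, replicates kept separate).
    """
    if mode == "pooled":
        on = sum(a for a, _ in per_replicate)
        off = sum(b for _, b in per_replicate)
        return on_off_ratio(on, off, sample=sample)
    if mode == "per_replicate":
        return [
            on_off_ratio(a, b, sample=f"{sample}_rep{i + 1}")
            for i, (a, b) in enumerate(per_replicate)
        ]
    raise ValueError("mode must be 'pooled' or 'per_replicate'")


def edited_base_count(sites, min_confidence: float = 0.9) -> int:
    """Total edited-read observations over confident edit sites."""
    return int(sum(s.alt_count for s in sites if s.confidence > min_confidence))
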