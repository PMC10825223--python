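"""Reporter mRNA constructs for tethered-editing assays.

A reporter is a GFP-like coding sequence followed by a synthetic 3'UTR that
carries bacteriophage stem-loops (MS2 and/or PP7).  Coat-protein/editor
fusions are recruited to those loops, so downstream analyses only care about
the loop *coordinates*; the loop sequences bundled here are synthetic
stand-in hairpins of realistic length, not the published plasmid sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"

# Synthetic stand-in hairpins (8-bp stem, 6-nt loop, 8-bp stem complement).
# Only length and coordinates matter downstream; these are not the natural
# phage sequences.
MS2_LOOP = "GGCACGAGACATCACTCGTGCC"
PP7_LOOP = "CCTGCACGTTAGGACGTGCAGG"

LINKER_LEN = 50
CDS_LEN = 720  # sfGFP-sized stand-in

LAYOUTS = ("MS2x12", "PAIRED_350", "ALT12", "ALT4")


@dataclass(frozen=True)
class ReporterSpec:
    """A reporter construct with loop coordinates in construct space.

    ``loop_intervals`` are (kind, start, end) tuples, 0-based half-open, all
    inside the 3'UTR.  ``utr_layout`` lists the (kind, length) elements that
    make up the 3'UTR in order; kind is one of ``MS2``, ``PP7``, ``linker``.
    """

    name: str
    cds_seq: str
    utr_layout: tuple[tuple[str, int], ...]
    full_seq: str
    loop_intervals: tuple[tuple[str, int, int], ...] = field(default=())

    @property
    def cds_interval(self) -> tuple[int, int]:
        return (0, len(self.cds_seq))

    @property
    def utr_interval(self) -> tuple[int, int]:
        return (len(self.cds_seq), len(self.full_seq))

    def loop_sites(self, kind: str | None = None) -> list[tuple[int, int]]:
        """Loop intervals, optionally restricted to one loop kind."""
        return [
            (s, e) for k, s, e in self.loop_intervals if kind is None or k == kind
        ]

    def __post_init__(self) -> None:
        total = len(self.cds_seq) + sum(n for _, n in self.utr_layout)
        if len(self.full_seq) != total:
            raise ValueError("full_seq length inconsistent with layout")
        prev_end = len(self.cds_seq)
        for kind, s, e in self.loop_intervals:
            if not (prev_end <= s < e <= len(self.full_seq)):
                raise ValueError("loop intervals must be sorted, disjoint, in 3'UTR")
            prev_end = e


def _random_seq(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at])
    return "".join(BASES[i] for i in idx)


def _layout_elements(layout_name: str) -> list[tuple[str, int]]:
    link = ("linker", LINKER_LEN)
    ms2 = ("MS2", len(MS2_LOOP))
    pp7 = ("PP7", len(PP7_LOOP))
    if layout_name == "MS2x12":
        elems = [link]
        for _ in range(12):
            elems += [ms2, link]
    elif layout_name == "PAIRED_350":
        # MS2/PP7 pairs 50 bp apart, pairs separated by 350-bp spacers.
        elems = [link]
        for i in range(3):
            elems += [ms2, link, pp7]
            elems.append(("linker", 350) if i < 2 else link)
    elif layout_name in ("ALT12", "ALT4"):
        n = 12 if layout_name == "ALT12" else 4
        elems = [link]
        for i in range(n):
            elems += [ms2 if i % 2 == 0 else pp7, link]
    else:
        raise ValueError(
            f"unknown reporter layout {layout_name!r}; expected one of {LAYOUTS}"
        )
    return elems


def build_reporter(layout_name: str, seed: int = 0) -> ReporterSpec:
    """Assemble a reporter construct deterministically from a seed.

    The CDS and linkers are random sequence drawn from the seeded generator;
    the stem-loop elements use the fixed stand-in hairpins, so the same
    (layout, seed) pair always yields a byte-identical construct.
    """
    elems = _layout_elements(layout_name)
    rng = np.random.default_rng(seed)
    cds = "ATG" + _random_seq(CDS_LEN - 6, rng) + "TAA"
    parts: list[str] = []
    loops: list[tuple[str, int, int]] = []
    pos = len(cds)
    for kind, length in elems:
        if kind == "linker":
            parts.append(_random_seq(length, rng))
        else:
            loop_seq = MS2_LOOP if kind == "MS2" else PP7_LOOP
            loops.append((kind, pos, pos + length))
            parts.append(loop_seq)
        pos += length
    return ReporterSpec(
        name=layout_name,
        cds_seq=cds,
        utr_layout=tuple(elems),
        full_seq=cds + "".join(parts),
        loop_intervals=tuple(loops),
    )
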