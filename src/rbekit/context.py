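"""Sequence-context characterization of editing enzymes.

Each enzyme leaves a signature in the bases immediately flanking its edit
sites.  Counting the 16 possible (upstream base, downstream base) pairs over
high-confidence sites gives a 16-dimensional context vector per sample;
principal-component analysis of those vectors (as proportions, mean-
centered, no unit-variance scaling) separates enzymes by their A/U- versus
G/C-flank preference, with the loadings telling which contexts drive each
component.  Cluster-level summaries (base composition, motif presence,
distance to the nearest binding motif) complete the picture.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .editcall import EditSite

BASES = "ACGT"
CONTEXTS: tuple[tuple[str, str], ...] = tuple(product(BASES, BASES))
CONTEXT_LABELS = [f"{u}_{d}" for u, d in CONTEXTS]


@dataclass
class ContextVector:
    """Counts of flanking-base contexts at confident edit sites."""

    sample: str
    counts: np.ndarray  # length 16, CONTEXTS order
    n_skipped: int = 0

    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=CONTEXT_LABELS, name=self.sample)


@dataclass
class PcaResult:
    samples: list[str]
    coordinates: np.ndarray  # (n_samples, k)
    loadings: np.ndarray  # (k, 16)
    variance_explained: np.ndarray  # (k,)


@dataclass
class ClusterComposition:
    ref: str
    start: int
    end: int
    fractions: dict[str, float]  # A, C, G, T (U reported as T internally)

    @property
    def gc(self) -> float:
        return self.fractions["G"] + self.fractions["C"]


def flanking_contexts(
    sites: list[EditSite],
    reference: dict[str, str],
    min_confidence: float = 0.9,
    sample: str = "",
    window: int = 1,
) -> ContextVector:
    """Count (upstream, downstream) base pairs around confident edit sites.

    ``window=1`` gives the 16 single-flank contexts; ``window=2`` widens the
    context to two bases on each side (256 contexts, concatenated labels).
    Sites at sequence edges or with N neighbours are skipped and tallied.
    """
    if window == 1:
        contexts = CONTEXTS
    elif window == 2:
        contexts = tuple(
            ("".join(u), "".join(d))
            for u in product(BASES, repeat=2)
            for d in product(BASES, repeat=2)
        )
    else:
        raise ValueError("window must be 1 or 2")
    index = {c: i for i, c in enumerate(contexts)}
    counts = np.zeros(len(contexts), dtype=np.int64)
    skipped = 0
    for s in sites:
        if s.confidence <= min_confidence:
            continue
        seq = reference[s.ref]
        lo, hi = s.pos0 - window, s.pos0 + window
        if lo < 0 or hi >= len(seq):
            skipped += 1
            continue
        up = seq[lo : s.pos0].upper()
        down = seq[s.pos0 + 1 : hi + 1].upper()
        key = (up, down) if window > 1 else (up, down)
        if key not in index:
            skipped += 1
            continue
        counts[index[key]] += 1
    return ContextVector(sample=sample, counts=counts, n_skipped=skipped)


def context_pca(
    vectors: list[ContextVector],
    n_components: int = 2,
    use_proportions: bool = True,
) -> PcaResult:
    """PCA of per-sample context vectors via exact SVD.

    Vectors are normalized to proportions (compositional counts) and
    mean-centered; no unit-variance scaling, so the loadings keep the raw
    per-context contributions.
    """
    if len(vectors) < 3:
        raise ValueError("need at least 3 context vectors for a PCA")
    X = np.vstack(
        [v.proportions() if use_proportions else v.counts.astype(float) for v in vectors]
    )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, S.size)
    # deterministic sign: largest-magnitude loading positive
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    coords = U[:, :k] * S[:k]
    total_var = (Xc**2).sum()
    var_frac = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PcaResult(
        samples=[v.sample for v in vectors],
        coordinates=coords,
        loadings=Vt[:k],
        variance_explained=var_frac,
    )


def cluster_composition(
    clusters, reference: dict[str, str]
) -> list[ClusterComposition]:
    """Base composition of each cluster's sense-strand sequence (Ns ignored)."""
    out = []
    for c in clusters:
        seq = reference[c.ref][c.start : c.end].upper()
        if len(seq) == 0:
            raise ValueError(f"zero-length cluster {c.ref}:{c.start}-{c.end}")
        n_valid = sum(seq.count(b) for b in BASES)
        if n_valid == 0:
            raise ValueError("cluster sequence contains no A/C/G/T bases")
        out.append(
            ClusterComposition(
                ref=c.ref,
                start=c.start,
                end=c.end,
                fractions={b: seq.count(b) / n_valid for b in BASES},
            )
        )
    return out


def composition_summary(comps: list[ClusterComposition]) -> pd.DataFrame:
    """Mean and quartiles of per-cluster A and GC content."""
    a = np.array([c.fractions["A"] for c in comps])
    gc = np.array([c.gc for c in comps])
    rows = []
    for name, x in (("A", a), ("GC", gc)):
        rows.append(
            {
                "content": name,
                "mean": x.mean(),
                "q25": np.percentile(x, 25),
                "median": np.percentile(x, 50),
                "q75": np.percentile(x, 75),
            }
        )
    return pd.DataFrame(rows)


def motif_presence(
    clusters, reference: dict[str, str], motif: str = "GCATG"
) -> tuple[float, list[bool]]:
    """Fraction of clusters whose sense-strand sequence contains the motif."""
    if not motif:
        raise ValueError("motif must be non-empty")
    flags = [
        motif.upper() in reference[c.ref][c.start : c.end].upper() for c in clusters
    ]
    frac = float(np.mean(flags)) if flags else 0.0
    return frac, flags


def motif_distance_density(
    clusters,
    motif_sites: dict[str, list[int]],
    max_dist: int = 1000,
) -> tuple[np.ndarray, int]:
    """Signed distance from each cluster midpoint to the nearest motif start.

    Clusters with no motif within +-max_dist on their reference are excluded
    and tallied.  Positive distances mean the motif lies downstream of the
    cluster midpoint.
    """
    if not any(motif_sites.values()):
        raise ValueError("motif_sites is empty")
    dists = []
    excluded = 0
    for c in clusters:
        mids = np.asarray(motif_sites.get(c.ref, []), dtype=float)
        if mids.size == 0:
            excluded += 1
            continue
        mid = (c.start + c.end) // 2
        d = mids - mid
        best = d[np.argmin(np.abs(d))]
        if abs(best) > max_dist:
            excluded += 1
            continue
        dists.append(best)
    return np.array(dists), excluded
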