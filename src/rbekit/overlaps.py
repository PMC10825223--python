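"""Interval-set statistics: overlap fractions and permutation enrichment.

Intervals are pandas DataFrames with columns chrom, start, end and
optionally strand and name, 0-based half-open.  The permutation null
re-places each query interval, keeping its length, uniformly at random over
a placement domain (typically the transcribed regions), and the empirical
p-value uses the add-one rule p = (1 + #{null >= observed}) / (1 + n_perm)
so it can never degenerate to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def _check_intervals(df: pd.DataFrame, name: str) -> pd.DataFrame:
    for col in INTERVAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{name} is missing column {col!r}")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{name} has intervals with start >= end")
    return df


def intervals_from_clusters(clusters, strand: str = "+") -> pd.DataFrame:
    """IntervalSet frame from EditCluster-like objects (ref/start/end)."""
    return pd.DataFrame(
        {
            "chrom": [c.ref for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "strand": strand,
        }
    )


def _merge_sorted(starts: np.ndarray, ends: np.ndarray):
    """Flatten sorted intervals into maximal disjoint runs."""
    ms, me = [], []
    for s, e in zip(starts, ends):
        if ms and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms), np.asarray(me)


def _flatten_by_chrom(df: pd.DataFrame, stranded: bool):
    keys = ["chrom", "strand"] if stranded and "strand" in df.columns else ["chrom"]
    out = {}
    for key, grp in df.sort_values("start").groupby(keys, sort=True):
        if len(keys) == 1 and not isinstance(key, tuple):
            key = (key,)
        out[key] = _merge_sorted(grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


def _hits(flat, key, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean overlap (>=1 bp) of query intervals against flattened subject."""
    if key not in flat:
        return np.zeros(starts.shape, dtype=bool)
    ms, me = flat[key]
    idx = np.searchsorted(me, starts, side="right")
    ok = idx < ms.size
    hit = np.zeros(starts.shape, dtype=bool)
    hit[ok] = ms[idx[ok]] < ends[ok]
    return hit


def overlap_fraction(
    query: pd.DataFrame, subject: pd.DataFrame, stranded: bool = True
) -> float:
    """Fraction of query intervals overlapping (>= 1 bp) any subject interval."""
    _check_intervals(query, "query")
    _check_intervals(subject, "subject")
    if len(query) == 0:
        raise ValueError("query interval set is empty")
    stranded = (
        stranded and "strand" in query.columns and "strand" in subject.columns
    )
    flat = _flatten_by_chrom(subject, stranded)
    keys = ["chrom", "strand"] if stranded else ["chrom"]
    n_hit = 0
    for key, grp in query.groupby(keys, sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        n_hit += int(
            _hits(flat, key, grp["start"].to_numpy(), grp["end"].to_numpy()).sum()
        )
    return n_hit / len(query)


@dataclass
class PermutationResult:
    observed: float
    null_fractions: np.ndarray
    seed: int
    n_perm: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_perm = len(self.null_fractions)

    @property
    def p_value(self) -> float:
        return (1 + int(np.sum(self.null_fractions >= self.observed))) / (
            1 + self.n_perm
        )

    @property
    def enrichment(self) -> float:
        mean_null = float(np.mean(self.null_fractions))
        return self.observed / mean_null if mean_null > 0 else np.inf


def permute_intervals(
    query: pd.DataFrame,
    subject: pd.DataFrame,
    domain: pd.DataFrame,
    n_perm: int,
    seed: int = 0,
    stranded: bool = False,
) -> PermutationResult:
    """Permutation test of query/subject overlap against random placement.

    Each permutation re-places every query interval (same length) uniformly
    at random across the domain regions, then recomputes the overlap
    fraction against the subject set.
    """
    _check_intervals(query, "query")
    _check_intervals(domain, "domain")
    rng = np.random.default_rng(seed)
    observed = overlap_fraction(query, subject, stranded=stranded)
    flat_subject = _flatten_by_chrom(subject, stranded=False)
    dom = domain.reset_index(drop=True)
    dom_chroms = dom["chrom"].to_numpy()
    dom_len = (dom["end"] - dom["start"]).to_numpy()
    lengths = (query["end"] - query["start"]).to_numpy()
    null = np.zeros(n_perm)
    # per query interval: valid start slots in each domain region
    hits_per_perm = np.zeros((n_perm, len(query)), dtype=bool)
    for qi, L in enumerate(lengths):
        slots = np.maximum(0, dom_len - L + 1)
        total = slots.sum()
        if total <= 0:
            raise ValueError("a query interval is longer than every domain region")
        cum = np.cumsum(slots)
        draws = rng.integers(0, total, size=n_perm)
        region = np.searchsorted(cum, draws, side="right")
        offset = draws - (cum[region] - slots[region])
        starts = dom["start"].to_numpy()[region] + offset
        ends = starts + L
        for key in np.unique(dom_chroms[region]):
            m = dom_chroms[region] == key
            hits_per_perm[m, qi] = _hits(flat_subject, (key,), starts[m], ends[m])
    null = hits_per_perm.mean(axis=1)
    return PermutationResult(observed=observed, null_fractions=null, seed=seed)


def combined_set(cluster_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of several interval sets with overlapping runs flattened.

    Returns a frame with chrom, start, end and a ``sources`` column listing
    which input sets (0-based indices) contributed to each merged run.
    """
    if len(cluster_sets) < 2:
        raise ValueError("need at least two sets to combine")
    frames = []
    for i, df in enumerate(cluster_sets):
        _check_intervals(df, f"set {i}")
        f = df[INTERVAL_COLUMNS].copy()
        f["source"] = i
        frames.append(f)
    allint = pd.concat(frames, ignore_index=True).sort_values(["chrom", "start"])
    rows = []
    for chrom, grp in allint.groupby("chrom", sort=True):
        cur_s = cur_e = None
        cur_src: set[int] = set()
        for s, e, src in zip(grp["start"], grp["end"], grp["source"]):
            if cur_s is None or s > cur_e:
                if cur_s is not None:
                    rows.append((chrom, cur_s, cur_e, sorted(cur_src)))
                cur_s, cur_e, cur_src = s, e, {src}
            else:
                cur_e = max(cur_e, e)
                cur_src.add(src)
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, sorted(cur_src)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sources"])


def upset_counts(cluster_sets: list[pd.DataFrame]) -> dict[tuple[int, ...], int]:
    """Counts of flattened union regions per exact set-membership pattern.

    A region is a member of set i when it overlaps (>= 1 bp) any interval of
    that set; patterns are tuples of 0-based set indices.
    """
    union = combined_set(cluster_sets)
    flats = [_flatten_by_chrom(df, stranded=False) for df in cluster_sets]
    counts: dict[tuple[int, ...], int] = {}
    for chrom, grp in union.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        members = np.stack(
            [_hits(flat, (chrom,), starts, ends) for flat in flats], axis=1
        )
        for row in members:
            pattern = tuple(np.nonzero(row)[0])
            counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def coverage_bp(df: pd.DataFrame) -> int:
    """Total flattened base-pair coverage of an interval set."""
    flat = _flatten_by_chrom(_check_intervals(df, "set"), stranded=False)
    return int(sum((me - ms).sum() for ms, me in flat.values()))
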