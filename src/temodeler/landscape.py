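"""Chromosome-scale TE distribution statistics.

Sliding-window density/diversity profiles (default 10 Mb windows, 1 Mb
step), standard scores, exact least-squares segmentation of density
variation, correlation-based clustering of family distributions,
TE occupancy around genes, and TE-to-gene distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .model import COMPLETE, AnnotationSet, Gene, GenomicInterval

MEASURES = ("bp_fraction", "count", "family_count_N99")


@dataclass
class WindowProfile:
    seqid: str
    window_size: int
    step: int
    starts: np.ndarray
    values: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts)
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.starts)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{self.measure}"\n')
            for s, v in zip(self.starts, self.values):
                fh.write(f"{self.seqid}\t{s}\t{s + self.window_size}\t{v:g}\n")


def _selected_parts(
    annotation_set: AnnotationSet, seqid: str, family_filter: Optional[str]
) -> List[Tuple[int, int, str]]:
    out = []
    for f in annotation_set:
        if f.seqid != seqid:
            continue
        if family_filter and f.family_id != family_filter and f.superfamily != family_filter:
            continue
        for p in f.parts:
            out.append((p.qstart, p.qend, f.family_id))
    out.sort()
    return out


def window_profile(
    annotation_set: AnnotationSet,
    seqid: str,
    seq_length: int,
    window_size: int = 10_000_000,
    step: int = 1_000_000,
    measure: str = "bp_fraction",
    family_filter: Optional[str] = None,
) -> WindowProfile:
    """Sliding-window TE profile along one sequence.

    ``bp_fraction``: unique TE-covered bases / window size (optionally
    restricted to one family or superfamily); ``count``: features whose
    span midpoint falls in the window; ``family_count_N99``: N99 family
    diversity per window."""
    if step <= 0:
        raise ValueError("step must be positive")
    if seq_length < window_size:
        raise ValueError("seq_length must be >= window_size")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    starts = np.arange(0, seq_length - window_size + 1, step)
    if measure == "count":
        mids = np.sort(
            np.array(
                [
                    (f.span_start + f.span_end) // 2
                    for f in annotation_set
                    if f.seqid == seqid
                    and (
                        not family_filter
                        or f.family_id == family_filter
                        or f.superfamily == family_filter
                    )
                ],
                dtype=int,
            )
        )
        values = np.searchsorted(mids, starts + window_size, side="left") - np.searchsorted(
            mids, starts, side="left"
        )
        return WindowProfile(seqid, window_size, step, starts, values, measure)
    if measure == "family_count_N99":
        values = np.array(
            [
                n99_diversity(
                    annotation_set, GenomicInterval(seqid, int(s), int(s) + window_size)
                )
                for s in starts
            ],
            dtype=float,
        )
        return WindowProfile(seqid, window_size, step, starts, values, measure)
    # bp_fraction via a coverage difference array (parts are disjoint
    # within a valid set; overlapping inputs are unioned)
    diff = np.zeros(seq_length + 1, dtype=np.int32)
    last_end = -1
    for s, e, _ in _selected_parts(annotation_set, seqid, family_filter):
        s0, e0 = max(s, last_end), min(e, seq_length)
        if e0 > s0:
            diff[s0] += 1
            diff[e0] -= 1
            last_end = max(last_end, e0)
    cov = (np.cumsum(diff[:-1]) > 0).astype(np.int64)
    prefix = np.concatenate([[0], np.cumsum(cov)])
    values = (prefix[starts + window_size] - prefix[starts]) / window_size
    return WindowProfile(seqid, window_size, step, starts, values, measure)


def zscore_profile(profile: WindowProfile) -> WindowProfile:
    """Standard scores (population standard deviation) of a profile."""
    if len(profile) < 2:
        raise ValueError("need at least 2 windows for standard scores")
    sd = float(np.std(profile.values))
    if sd == 0.0:
        raise ValueError(
            f"zero variance in profile {profile.measure!r} on {profile.seqid}"
        )
    values = (profile.values - profile.values.mean()) / sd
    return WindowProfile(
        profile.seqid,
        profile.window_size,
        profile.step,
        profile.starts,
        values,
        f"{profile.measure}_zscore",
    )


def n99_diversity(annotation_set: AnnotationSet, window: GenomicInterval) -> int:
    """Number of most-abundant families jointly accounting for 99% of the
    TE nucleotides in a window (0 for a TE-free window)."""
    per_family: Dict[str, int] = {}
    for f in annotation_set:
        if f.seqid != window.seqid:
            continue
        for p in f.parts:
            ov = min(p.qend, window.end) - max(p.qstart, window.start)
            if ov > 0:
                per_family[f.family_id] = per_family.get(f.family_id, 0) + ov
    total = sum(per_family.values())
    if total == 0:
        return 0
    threshold = 0.99 * total
    acc = 0
    for i, bp in enumerate(sorted(per_family.values(), reverse=True), start=1):
        acc += bp
        if acc >= threshold:
            return i
    return len(per_family)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    breakpoints: List[int]  # indices into the profile; k segments -> k-1
    segment_means: List[float]

    def segments(self, n: int) -> List[Tuple[int, int]]:
        bounds = [0] + list(self.breakpoints) + [n]
        return list(zip(bounds[:-1], bounds[1:]))


def segment_profile(profile, k: int) -> SegmentationResult:
    """Exact least-squares segmentation into ``k`` segments.

    Dynamic program minimising the within-segment sum of squared
    deviations; deterministic, with ties broken toward the smallest
    breakpoint positions.  ``profile`` is a :class:`WindowProfile` or a
    value sequence."""
    values = np.asarray(
        profile.values if isinstance(profile, WindowProfile) else profile, dtype=float
    )
    n = len(values)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of windows ({n})")
    p1 = np.concatenate([[0.0], np.cumsum(values)])
    p2 = np.concatenate([[0.0], np.cumsum(values**2)])

    def sse(i: int, j: int) -> float:  # cost of segment values[i:j]
        s = p1[j] - p1[i]
        return (p2[j] - p2[i]) - s * s / (j - i)

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, arg = INF, m - 1
            for i in range(m - 1, j):
                c = cost[m - 1, i] + sse(i, j)
                if c < best - 1e-12:  # strict improvement keeps smallest i
                    best, arg = c, i
            cost[m, j] = best
            back[m, j] = arg
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = int(back[m, j])
        bounds.append(j)
    bounds.reverse()  # [0, b1, ..., n]
    breakpoints = bounds[1:-1]
    means = [float(values[i:j].mean()) for i, j in zip(bounds[:-1], bounds[1:])]
    return SegmentationResult(breakpoints=breakpoints, segment_means=means)


# ---------------------------------------------------------------------------
# clustering of family distributions
# ---------------------------------------------------------------------------

@dataclass
class FamilyClustering:
    labels: List[str]
    linkage: np.ndarray
    newick: str
    support: Optional[Dict[frozenset, float]] = None


def _corr_distance(mat: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    n = dist.shape[0]
    return dist[np.triu_indices(n, 1)]


def _leaf_sets(linkage: np.ndarray, n: int) -> List[frozenset]:
    members: Dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    sets = []
    for idx, (a, b, _, _) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + idx] = merged
        sets.append(merged)
    return sets


def _to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        return (
            f"({walk(node.left, node.dist)},{walk(node.right, node.dist)}):{length:.6f}"
        )

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def cluster_family_profiles(
    profiles: Mapping[str, Sequence[float]],
    min_abundance: float = 0.0001,
    n_boot: int = 1000,
    seed: int = 0,
) -> FamilyClustering:
    """Average-linkage clustering of family window distributions.

    Families whose profile never reaches ``min_abundance`` in any window
    are dropped; distance is 1 - Pearson correlation.  Bootstrap support
    (window-resampled, ``n_boot`` replicates) is the fraction of
    resampled dendrograms containing each internal node's leaf set."""
    labels = [f for f in profiles if max(profiles[f]) >= min_abundance]
    if len(labels) < 2:
        raise ValueError("fewer than 2 families pass the abundance filter")
    labels.sort()
    mat = np.array([np.asarray(profiles[f], dtype=float) for f in labels])
    link = hierarchy.linkage(_corr_distance(mat), method="average")
    support: Optional[Dict[frozenset, float]] = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        counts: Dict[frozenset, int] = {s: 0 for s in _leaf_sets(link, len(labels))}
        n_win = mat.shape[1]
        for _ in range(n_boot):
            cols = rng.integers(0, n_win, size=n_win)
            blink = hierarchy.linkage(_corr_distance(mat[:, cols]), method="average")
            bsets = set(_leaf_sets(blink, len(labels)))
            for s in counts:
                if s in bsets:
                    counts[s] += 1
        support = {s: c / n_boot for s, c in counts.items()}
    return FamilyClustering(
        labels=labels,
        linkage=link,
        newick=_to_newick(link, labels),
        support=support,
    )


# ---------------------------------------------------------------------------
# gene context
# ---------------------------------------------------------------------------

def gene_context_profile(
    annotation_set: AnnotationSet,
    genes: Sequence[Gene],
    seq_lengths: Mapping[str, int],
    flank: int = 20_000,
    family_filter: Optional[str] = None,
) -> np.ndarray:
    """Average TE occupancy at each position around genes.

    Returns a vector of length ``2*flank``: entries ``0..flank-1`` are
    the gene-oriented upstream positions ``-flank..-1`` relative to the
    gene start, entries ``flank..2*flank-1`` the downstream positions
    ``+1..+flank`` relative to the gene end (minus-strand genes flipped).
    Each entry is the fraction of genes whose context is TE-covered
    there; positions beyond the sequence ends are excluded from the
    denominator."""
    cov: Dict[str, np.ndarray] = {}
    for seqid, n in seq_lengths.items():
        arr = np.zeros(n, dtype=bool)
        for s, e, _ in _selected_parts(annotation_set, seqid, family_filter):
            arr[s:e] = True
        cov[seqid] = arr
    hits = np.zeros(2 * flank, dtype=float)
    denom = np.zeros(2 * flank, dtype=float)
    for g in genes:
        iv = g.interval
        arr = cov.get(iv.seqid)
        if arr is None:
            continue
        n = len(arr)
        if iv.strand == "+":
            up = (iv.start - flank, iv.start)
            down = (iv.end, iv.end + flank)
        else:
            up = (iv.end, iv.end + flank)
            down = (iv.start - flank, iv.start)
        for half, (lo, hi) in enumerate((up, down)):
            lo0, hi0 = max(lo, 0), min(hi, n)
            if hi0 <= lo0:
                continue
            window = arr[lo0:hi0].astype(float)
            pad_l, pad_r = lo0 - lo, hi - hi0
            vals = np.concatenate(
                [np.full(pad_l, np.nan), window, np.full(pad_r, np.nan)]
            )
            if iv.strand == "-":
                vals = vals[::-1]
            sl = slice(half * flank, (half + 1) * flank)
            ok = ~np.isnan(vals)
            hits[sl] += np.where(ok, np.nan_to_num(vals), 0.0)
            denom[sl] += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, hits / np.maximum(denom, 1), 0.0)
    return out


def nearest_gene_distance(
    annotation_set: AnnotationSet, genes: Sequence[Gene]
) -> pd.DataFrame:
    """Distance (kb) from each TE feature to its nearest gene, with the
    feature family's complete-copy-number class (1, 2-10, 11-100,
    101-1000, >1000)."""
    if not genes:
        raise ValueError("no genes provided")
    bounds: Dict[str, List[Tuple[int, int]]] = {}
    for g in genes:
        bounds.setdefault(g.interval.seqid, []).append(
            (g.interval.start, g.interval.end)
        )
    for ivs in bounds.values():
        ivs.sort()
    complete_copies: Dict[str, int] = {}
    for f in annotation_set:
        if f.status == COMPLETE:
            complete_copies[f.family_id] = complete_copies.get(f.family_id, 0) + 1

    def copy_class(n: int) -> str:
        if n <= 0:
            return "0"
        if n == 1:
            return "1"
        if n <= 10:
            return "2-10"
        if n <= 100:
            return "11-100"
        if n <= 1000:
            return "101-1000"
        return ">1000"

    rows = []
    for f in annotation_set:
        ivs = bounds.get(f.seqid)
        if not ivs:
            continue
        best = min(
            max(0, gs - f.span_end, f.span_start - ge) for gs, ge in ivs
        )
        rows.append(
            {
                "feature_id": f.feature_id,
                "family_id": f.family_id,
                "distance_kb": best / 1000.0,
                "copy_class": copy_class(complete_copies.get(f.family_id, 0)),
            }
        )
    return pd.DataFrame(rows, columns=["feature_id", "family_id", "distance_kb", "copy_class"])
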