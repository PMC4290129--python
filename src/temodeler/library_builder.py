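"""Building a classified TE family catalog from pairwise similarity data.

Families are defined by Markov clustering (MCL) of an all-by-all
similarity graph at low inflation (1.2, "very coarse grained"), named
``<superfamily>_famc<rank>`` by decreasing size, and reference elements
get their terminal repeats (LTR pairs) located by a seed-and-extend
self-comparison of the sequence extremities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .model import revcomp


# ---------------------------------------------------------------------------
# similarity graph
# ---------------------------------------------------------------------------

@dataclass
class SimilarityGraph:
    """Undirected weighted graph over library element ids (no self-loops)."""

    nodes: List[str]
    edges: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        self.edges[key] = max(self.edges.get(key, 0.0), weight)

    def weight(self, a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        return self.edges.get(key, 0.0)

    def n_edges(self) -> int:
        return len(self.edges)


def build_similarity_graph(
    pairwise_table: Union[pd.DataFrame, str],
    min_score: float = 0.0,
    min_coverage: float = 0.0,
    known_ids: Optional[Set[str]] = None,
) -> SimilarityGraph:
    """Filter an all-by-all alignment table into a similarity graph.

    Expects columns ``id_a, id_b, score, coverage_fraction``.  An edge is
    kept iff ``score >= min_score`` and ``coverage_fraction >=
    min_coverage``; asymmetric directed scores are symmetrised by their
    maximum.  With ``known_ids`` given, a row referencing an id outside
    that set is an error."""
    if not isinstance(pairwise_table, pd.DataFrame):
        pairwise_table = pd.read_csv(pairwise_table, sep="\t", dtype={0: str, 1: str})
    required = {"id_a", "id_b", "score", "coverage_fraction"}
    if not required.issubset(pairwise_table.columns):
        raise ValueError(f"pairwise table must have columns {sorted(required)}")
    ids = set(pairwise_table["id_a"]) | set(pairwise_table["id_b"])
    if known_ids is not None:
        unknown = ids - set(known_ids)
        if unknown:
            raise LookupError(f"unknown ids in pairwise table: {sorted(unknown)}")
        ids = set(known_ids)
    graph = SimilarityGraph(nodes=sorted(ids))
    for row in pairwise_table.itertuples(index=False):
        if row.score >= min_score and row.coverage_fraction >= min_coverage:
            graph.add_edge(str(row.id_a), str(row.id_b), float(row.score))
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def _column_normalize(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    colsum[colsum == 0.0] = 1.0
    return m / colsum


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 1.2,
    expansion: int = 2,
    max_iter: int = 200,
    convergence_tol: float = 1e-6,
    prune_below: float = 1e-6,
) -> List[Set[str]]:
    """Markov clustering of a similarity graph; returns a node partition.

    The column-stochastic matrix (self-loops added with weight equal to
    the node's maximum incident edge weight) is iterated through
    expansion (matrix power) and inflation (entrywise power followed by
    column renormalisation) until the change falls below
    ``convergence_tol``.  Attractor rows (positive diagonal mass) seed
    clusters; overlapping attractor systems are merged, so the result is
    always a partition of the node set."""
    if inflation <= 0:
        raise ValueError(f"inflation must be positive, got {inflation}")
    if not graph.nodes:
        raise ValueError("empty graph")
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for (a, b), w in graph.edges.items():
        i, j = index[a], index[b]
        m[i, j] = m[j, i] = w
    # self-loop regularisation: max incident weight (1.0 for isolated nodes)
    incident_max = m.max(axis=0)
    incident_max[incident_max == 0.0] = 1.0
    np.fill_diagonal(m, incident_max)
    m = _column_normalize(m)
    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = _column_normalize(expanded**inflation)
        inflated[inflated < prune_below] = 0.0
        inflated = _column_normalize(inflated)
        delta = np.abs(inflated - m).max()
        m = inflated
        if delta < convergence_tol:
            break
    # attractor interpretation: rows with positive diagonal mass seed
    # clusters; each cluster is the support of its attractor row
    attractors = [i for i in range(n) if m[i, i] > prune_below]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for a in attractors:
        for j in np.nonzero(m[a] > prune_below)[0]:
            union(a, int(j))
    # any node not reached by an attractor row: attach to its strongest column
    for j in range(n):
        if find(j) == j and j not in attractors:
            col = m[:, j]
            if col.max() > 0:
                union(int(col.argmax()), j)
    clusters: Dict[int, Set[str]] = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(nodes[i])
    return sorted(clusters.values(), key=lambda c: (-len(c), min(c)))


# ---------------------------------------------------------------------------
# family naming
# ---------------------------------------------------------------------------

@dataclass
class FamilyCatalog:
    """Named TE families partitioning the clustered element set."""

    families: Dict[str, List[str]]

    def family_of(self, element_id: str) -> str:
        for fam, members in self.families.items():
            if element_id in members:
                return fam
        raise LookupError(f"element {element_id!r} not in catalog")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"element_id": e, "family_id": fam}
            for fam, members in self.families.items()
            for e in members
        ]
        return pd.DataFrame(rows, columns=["element_id", "family_id"])


def assign_family_names(
    partition: Sequence[Set[str]],
    superfamily_of_element: Mapping[str, str],
) -> FamilyCatalog:
    """Name clusters ``<code>_famc<rank>``, ranked per superfamily code by
    decreasing member count (ties by lexicographically smallest member).

    A mixed-superfamily cluster takes the majority code (ties broken by
    lexicographically smallest code)."""
    if not partition:
        raise ValueError("empty partition")
    ordered = sorted(partition, key=lambda c: (-len(c), min(c)))
    counters: Dict[str, int] = {}
    families: Dict[str, List[str]] = {}
    for cluster in ordered:
        codes: Dict[str, int] = {}
        for e in cluster:
            if e not in superfamily_of_element:
                raise LookupError(f"no superfamily code for element {e!r}")
            codes[superfamily_of_element[e]] = codes.get(superfamily_of_element[e], 0) + 1
        code = min(codes, key=lambda c: (-codes[c], c))
        counters[code] = counters.get(code, 0) + 1
        families[f"{code}_famc{counters[code]}"] = sorted(cluster)
    return FamilyCatalog(families=families)


# ---------------------------------------------------------------------------
# terminal repeat (LTR) detection
# ---------------------------------------------------------------------------

def _kmer_positions(seq: str, k: int) -> Dict[str, List[int]]:
    out: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i : i + k], []).append(i)
    return out


def _extend(seq: str, i0: int, i1: int, j0: int, j1: int,
            xdrop: int = 12) -> Tuple[int, int, int, int]:
    """Greedy X-drop extension of an ungapped match block on both sides.

    ``[i0, i1)`` aligned with ``[j0, j1)`` on the same diagonal; returns
    the extended block trimmed back to its best-scoring extent."""
    # left
    score = best = 0
    best_off = 0
    off = 0
    while i0 - off > 0 and j0 - off > 0:
        off += 1
        score += 1 if seq[i0 - off] == seq[j0 - off] else -2
        if score > best:
            best, best_off = score, off
        if best - score > xdrop:
            break
    i0 -= best_off
    j0 -= best_off
    # right
    score = best = 0
    best_off = 0
    off = 0
    n = len(seq)
    while i1 + off < n and j1 + off < n:
        if seq[i1 + off] == seq[j1 + off]:
            score += 1
        else:
            score -= 2
        off += 1
        if score > best:
            best, best_off = score, off
        if best - score > xdrop:
            break
    return i0, i1 + best_off, j0, j1 + best_off


def detect_terminal_repeats(
    sequence: str,
    min_ltr_len: int = 100,
    min_identity: float = 0.80,
    extremity_range: int = 50,
    kmer: int = 12,
) -> Optional[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """Locate a 5'/3' terminal direct-repeat pair (LTRs) in ``sequence``.

    Seed-and-extend self-comparison of the first versus last 40% of the
    sequence: exact ``kmer`` seeds chained per diagonal, extended with an
    ungapped X-drop.  The best pair with length >= ``min_ltr_len`` and
    identity >= ``min_identity`` is returned as two 1-based inclusive
    intervals, or ``None`` -- in particular when either repeat copy
    starts/ends more than ``extremity_range`` bp from its sequence
    extremity.  Absence is a valid result, not an error."""
    sequence = sequence.upper()
    n = len(sequence)
    if n < 2 * min_ltr_len:
        return None
    head_end = max(int(0.4 * n), min_ltr_len)
    tail_start = min(int(0.6 * n), n - min_ltr_len)
    head_kmers = _kmer_positions(sequence[:head_end], kmer)
    # seed matches grouped by diagonal (j - i)
    diag_seeds: Dict[int, List[int]] = {}
    for j in range(tail_start, n - kmer + 1):
        for i in head_kmers.get(sequence[j : j + kmer], ()):
            diag_seeds.setdefault(j - i, []).append(i)
    best: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None
    best_key = (0.0, 0)
    for d, seeds in diag_seeds.items():
        seeds.sort()
        # chain seeds on this diagonal into runs (gap <= 2*kmer)
        run_start = seeds[0]
        prev = seeds[0]
        runs: List[Tuple[int, int]] = []
        for s in seeds[1:]:
            if s - prev > 2 * kmer:
                runs.append((run_start, prev + kmer))
                run_start = s
            prev = s
        runs.append((run_start, prev + kmer))
        for i0, i1 in runs:
            ei0, ei1, ej0, ej1 = _extend(sequence, i0, i1, i0 + d, i1 + d)
            length = ei1 - ei0
            if length < min_ltr_len:
                continue
            matches = sum(
                1 for a, b in zip(sequence[ei0:ei1], sequence[ej0:ej1]) if a == b
            )
            identity = matches / length
            if identity < min_identity:
                continue
            key = (identity * length, length)
            if key > best_key:
                best_key = key
                best = ((ei0, ei1), (ej0, ej1))
    if best is None:
        return None
    (i0, i1), (j0, j1) = best
    if i0 > extremity_range or (n - j1) > extremity_range:
        return None
    # 1-based inclusive, consensus-coordinate convention
    return (i0 + 1, i1), (j0 + 1, j1)


def annotate_terminal_repeats(sequence: str, **kwargs) -> Optional[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """Alias of :func:`detect_terminal_repeats` (kept for CLI symmetry)."""
    return detect_terminal_repeats(sequence, **kwargs)
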