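"""Detection of transposon-mediated gene capture and chimeric proteins.

A gene flanked on both sides by TE features of one family is a candidate
capture event (DNA transposons such as CACTAs move gene fragments this
way); an intact target-site duplication outside the flanking element
boundaries is the supporting evidence.  Chimeric (exon-shuffled) gene
products are proteins showing non-overlapping similarity segments to
two or more different reference proteins, none of which alone explains
most of the query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .formats import SequenceSource, get_sequence
from .model import AnnotationSet, Gene, TEFeature

logger = logging.getLogger(__name__)

# superfamily-characteristic target-site duplication lengths (bp)
DEFAULT_TSD_LEN: Dict[str, int] = {
    "DTC": 3,   # CACTA
    "RLG": 5,   # LTR retrotransposons
    "RLC": 5,
    "RLX": 5,
    "DTM": 9,   # Mutator
    "DTA": 8,   # hAT
}


@dataclass(frozen=True)
class CaptureEvent:
    gene_id: str
    family_id: str
    left_feature_id: str
    right_feature_id: str
    same_element: bool
    tsd_left: str
    tsd_right: str
    tsd_support: bool


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y) + abs(len(a) - len(b))


def detect_gene_capture(
    genes: Sequence[Gene],
    annotation_set: AnnotationSet,
    genome: SequenceSource,
    tsd_len_by_superfamily: Optional[Mapping[str, int]] = None,
    max_flank_dist: int = 5000,
    max_mismatch: int = 1,
) -> List[CaptureEvent]:
    """Genes flanked by two same-family TE features within
    ``max_flank_dist`` bp on each side.

    ``same_element`` marks flanks that are two parts of one reconstructed
    feature (the gene sits in its junction gap); ``tsd_support`` marks a
    target-site duplication (superfamily-specific length, <= 1 mismatch)
    found immediately outside the outer boundaries of the flanking
    element(s)."""
    tsd_lens = dict(DEFAULT_TSD_LEN)
    if tsd_len_by_superfamily:
        tsd_lens.update(tsd_len_by_superfamily)
    parts_by_seqid: Dict[str, List[Tuple[int, int, TEFeature]]] = {}
    for f in annotation_set:
        for p in f.parts:
            parts_by_seqid.setdefault(f.seqid, []).append((p.qstart, p.qend, f))
    for lst in parts_by_seqid.values():
        lst.sort(key=lambda t: (t[0], t[1]))
    events: List[CaptureEvent] = []
    for gene in genes:
        iv = gene.interval
        parts = parts_by_seqid.get(iv.seqid, [])
        left = None
        for s, e, f in parts:
            if e <= iv.start and (left is None or e > left[1]):
                left = (s, e, f)
        right = None
        for s, e, f in parts:
            if s >= iv.end:
                right = (s, e, f)
                break
        if left is None or right is None:
            logger.info("detect_gene_capture: %s lacks a TE flank", gene.gene_id)
            continue
        if iv.start - left[1] > max_flank_dist or right[0] - iv.end > max_flank_dist:
            continue
        lf, rf = left[2], right[2]
        if lf.family_id != rf.family_id:
            continue
        same_element = lf.feature_id == rf.feature_id
        tsd_len = tsd_lens.get(lf.superfamily, 5)
        outer_start = lf.span_start if not same_element else lf.span_start
        outer_end = rf.span_end
        seq = get_sequence(genome, iv.seqid)
        tsd_left = tsd_right = ""
        tsd_support = False
        if outer_start >= tsd_len and outer_end + tsd_len <= len(seq):
            tsd_left = seq[outer_start - tsd_len : outer_start]
            tsd_right = seq[outer_end : outer_end + tsd_len]
            tsd_support = _hamming(tsd_left, tsd_right) <= max_mismatch
        events.append(
            CaptureEvent(
                gene_id=gene.gene_id,
                family_id=lf.family_id,
                left_feature_id=lf.feature_id,
                right_feature_id=rf.feature_id,
                same_element=same_element,
                tsd_left=tsd_left,
                tsd_right=tsd_right,
                tsd_support=tsd_support,
            )
        )
    return events


# ---------------------------------------------------------------------------
# chimeric proteins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChimeraCall:
    protein_id: str
    protein_length: int
    segments: Tuple[Tuple[str, int, int], ...]  # (subject_id, q_start, q_end)


_CHIMERA_COLS = {"query_id", "subject_id", "q_start", "q_end", "score", "query_length"}


def detect_chimeras(
    alignment_table: pd.DataFrame,
    coverage_filter: float = 0.70,
    min_segment_len: int = 30,
    max_overlap_frac: float = 0.10,
    merge_gap: int = 5,
) -> List[ChimeraCall]:
    """Chimeric proteins from a tabular protein-similarity search.

    Queries where any single subject's hits cover more than
    ``coverage_filter`` of the query length are removed (explained by one
    parent).  Remaining hits are resolved greedily by descending score,
    keeping a hit iff its overlap with already-kept segments is at most
    ``max_overlap_frac`` of its own length; kept same-subject hits are
    merged when adjacent (gap <= ``merge_gap`` residues).  A call needs
    >= 2 kept segments of >= ``min_segment_len`` residues from >= 2
    distinct subjects.  Coordinates are 1-based inclusive residue
    positions."""
    missing = _CHIMERA_COLS - set(alignment_table.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    bad = alignment_table[alignment_table["q_end"] > alignment_table["query_length"]]
    if len(bad):
        raise ValueError(
            f"q_end beyond query_length for {bad['query_id'].iloc[0]!r}"
        )
    calls: List[ChimeraCall] = []
    for qid, grp in alignment_table.groupby("query_id", sort=True):
        qlen = int(grp["query_length"].iloc[0])
        # single-subject coverage filter
        explained = False
        for _, sub in grp.groupby("subject_id"):
            ivs = sorted(zip(sub["q_start"].astype(int), sub["q_end"].astype(int)))
            covered = 0
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s > cur_e + 1:
                    covered += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            covered += cur_e - cur_s + 1
            if covered > coverage_filter * qlen:
                explained = True
                break
        if explained:
            continue
        hits = sorted(
            (
                (float(r.score), int(r.q_end) - int(r.q_start) + 1, str(r.subject_id),
                 int(r.q_start), int(r.q_end))
                for r in grp.itertuples(index=False)
            ),
            key=lambda h: (-h[0], -h[1], h[2], h[3]),
        )
        kept: List[Tuple[str, int, int]] = []
        for _, hlen, subj, qs, qe in hits:
            overlap = sum(
                max(0, min(qe, ke) - max(qs, ks) + 1) for _, ks, ke in kept
            )
            if overlap <= max_overlap_frac * hlen:
                kept.append((subj, qs, qe))
        kept.sort(key=lambda t: (t[1], t[2]))
        merged: List[Tuple[str, int, int]] = []
        for subj, qs, qe in kept:
            if merged and merged[-1][0] == subj and qs - merged[-1][2] - 1 <= merge_gap:
                merged[-1] = (subj, merged[-1][1], max(merged[-1][2], qe))
            else:
                merged.append((subj, qs, qe))
        good = [s for s in merged if s[2] - s[1] + 1 >= min_segment_len]
        if len(good) >= 2 and len({s[0] for s in good}) >= 2:
            calls.append(
                ChimeraCall(
                    protein_id=str(qid),
                    protein_length=qlen,
                    segments=tuple(good),
                )
            )
    return calls
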