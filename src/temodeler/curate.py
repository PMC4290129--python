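"""Curation of raw repeat-similarity hits into whole-TE feature models.

Raw similarity searches over-fragment TE copies: one element is reported
as several overlapping or separated matches, and nested insertions split
old elements into pieces scattered along the sequence.  The curation
pipeline turns such a raw hit set into whole-element models in four
stages:

1. :func:`resolve_overlaps` -- make hits pairwise disjoint, giving
   priority to the hit covering a reference extremity, otherwise to the
   longer hit, and recomputing the trimmed hit's coordinates;
2. :func:`merge_collinear` -- merge neighbouring hits of the same family
   whose consensus coordinates advance collinearly into single features,
   with a special dispensation for matches falling inside an annotated
   LTR (a match to one LTR copy is interchangeable with the other);
3. :func:`reconstruct_nested` -- join same-family features separated by
   up to ``max_intervening`` whole predicted TEs when the junction is
   collinear, turning the intervening elements into nested children;
4. :func:`classify_completeness` -- call each model complete (both
   extremities found within tolerance and >= 90% of the reference
   covered) or fragmented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    COMPLETE,
    FRAGMENTED,
    AnnotationSet,
    GenomicInterval,
    Part,
    RawHit,
    TEFeature,
    TELibrary,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CurateConfig:
    """Tunable thresholds of the curation pipeline.

    extremity_tol: bp tolerance for "covers a reference extremity"
        (shared by overlap resolution and completeness calling).
    coverage_min: fraction of the reference that must be covered for a
        model to be called complete.
    max_gap: largest query gap (bp) bridged when merging neighbouring
        hits of one family (assembly gaps, diverged stretches).
    max_consensus_overlap: how far consensus coordinates may step
        backwards across a junction and still count as collinear
        (target-site duplications, fuzzy alignment ends).
    max_intervening: most predicted TEs allowed between two segments of
        one element when reconstructing nested insertions.
    min_hit_len: hits trimmed below this length are dropped as noise.
    """

    extremity_tol: int = 50
    coverage_min: float = 0.90
    max_gap: int = 200
    max_consensus_overlap: int = 50
    max_intervening: int = 10
    min_hit_len: int = 20


DEFAULT_CONFIG = CurateConfig()


# ---------------------------------------------------------------------------
# stage 1: overlap resolution
# ---------------------------------------------------------------------------

def _covers_extremity(hit: RawHit, library: TELibrary, tol: int) -> bool:
    ref = library.elements.get(hit.te_id)
    if ref is None:
        raise LookupError(f"hit {hit.hit_id}: unknown reference {hit.te_id!r}")
    return hit.te_start <= tol + 1 or hit.te_end >= ref.length - tol


def _trim_hit(
    hit: RawHit, d: int, side: str, min_hit_len: int
) -> Optional[RawHit]:
    """Remove ``d`` query bp from one side, shifting consensus coordinates
    by linear proportion; returns ``None`` when the remainder is too short."""
    qlen = hit.query.length
    if qlen - d < min_hit_len:
        return None
    te_len = hit.te_end - hit.te_start + 1
    td = round(d * te_len / qlen)
    te_start, te_end = hit.te_start, hit.te_end
    trim_start_of_consensus = (side == "left") == (hit.query.strand == "+")
    if trim_start_of_consensus:
        te_start = min(te_start + td, te_end)
    else:
        te_end = max(te_end - td, te_start)
    if side == "left":
        query = GenomicInterval(
            hit.query.seqid, hit.query.start + d, hit.query.end, hit.query.strand
        )
    else:
        query = GenomicInterval(
            hit.query.seqid, hit.query.start, hit.query.end - d, hit.query.strand
        )
    return dc_replace(hit, query=query, te_start=te_start, te_end=te_end)


def resolve_overlaps(
    hits: Sequence[RawHit],
    library: TELibrary,
    config: CurateConfig = DEFAULT_CONFIG,
) -> List[RawHit]:
    """Make a sorted single-seqid hit list pairwise disjoint.

    Between two overlapping hits, the one covering a reference extremity
    is kept intact and the other is trimmed; when none or both cover an
    extremity the longer one is kept (ties: higher score, then smaller
    query start).  Trimming recomputes both query and consensus
    coordinates; hits trimmed below ``min_hit_len`` are dropped."""
    for a, b in zip(hits, hits[1:]):
        if a.query.seqid != b.query.seqid:
            raise ValueError("resolve_overlaps expects hits on one seqid")
        if b.query.start < a.query.start:
            raise ValueError("hits must be sorted by query start")
    out: List[RawHit] = []
    for hit in hits:
        cur: Optional[RawHit] = hit
        while cur is not None and out and out[-1].query.end > cur.query.start:
            prev = out.pop()
            d = prev.query.end - cur.query.start  # overlap length
            ext_prev = _covers_extremity(prev, library, config.extremity_tol)
            ext_cur = _covers_extremity(cur, library, config.extremity_tol)
            if ext_prev != ext_cur:
                prev_wins = ext_prev
            else:
                key_prev = (prev.query.length, prev.score, -prev.query.start)
                key_cur = (cur.query.length, cur.score, -cur.query.start)
                prev_wins = key_prev >= key_cur
            if prev_wins:
                if prev is not None:
                    out.append(prev)
                cur = _trim_hit(cur, d, "left", config.min_hit_len)
            else:
                trimmed_prev = _trim_hit(prev, d, "right", config.min_hit_len)
                if trimmed_prev is not None:
                    out.append(trimmed_prev)
                # cur kept intact; loop again in case it still overlaps
                # an earlier kept hit (possible when prev shrank away)
        if cur is not None:
            out.append(cur)
    return out


# ---------------------------------------------------------------------------
# stage 2: collinear merging
# ---------------------------------------------------------------------------

def _ltr_alternatives(
    part: Part, ref, slack: int
) -> List[Part]:
    """Alternative consensus placements for a part lying inside an LTR.

    The two LTR copies of a reference element are near-identical, so a
    match reported inside one copy is equally consistent with the other;
    both placements are considered during merging/joining."""
    if ref is None or not ref.has_ltrs:
        return []
    (l5s, l5e), (l3s, l3e) = ref.ltr5, ref.ltr3
    alts: List[Part] = []
    if part.te_start >= l5s - slack and part.te_end <= l5e + slack:
        off = l3s - l5s
        alts.append(
            Part(part.qstart, part.qend,
                 min(part.te_start + off, ref.length),
                 min(part.te_end + off, ref.length))
        )
    if part.te_start >= l3s - slack and part.te_end <= l3e + slack:
        off = l3s - l5s
        alts.append(
            Part(part.qstart, part.qend,
                 max(part.te_start - off, 1),
                 max(part.te_end - off, 1))
        )
    return alts


def _collinear(prev: Part, nxt: Part, strand: str, max_overlap: int) -> bool:
    if strand == "+":
        return nxt.te_start >= prev.te_end - max_overlap
    return nxt.te_end <= prev.te_start + max_overlap


def _collinear_with_ltr(
    prev: Part,
    nxt: Part,
    strand: str,
    ref_prev,
    ref_next,
    config: CurateConfig,
    allow_replace_prev: bool,
) -> Optional[Tuple[Part, Part]]:
    """Collinearity test with the LTR dispensation.

    Returns the (possibly re-placed) part pair making the junction
    collinear, or ``None``.  The earlier part may only be re-placed when
    it is unconstrained on its left (``allow_replace_prev``)."""
    slack = config.extremity_tol
    # at most one side may be re-placed per junction: re-placing both
    # would let the tail of one element chain onto the head of the next
    pairs = [(prev, nxt)]
    pairs += [(prev, q) for q in _ltr_alternatives(nxt, ref_next, slack)]
    if allow_replace_prev:
        pairs += [(p, nxt) for p in _ltr_alternatives(prev, ref_prev, slack)]
    for p, q in pairs:
        if _collinear(p, q, strand, config.max_consensus_overlap):
            return p, q
    return None


def _hit_part(hit: RawHit) -> Part:
    return Part(hit.query.start, hit.query.end, hit.te_start, hit.te_end)


def merge_collinear(
    hits: Sequence[RawHit],
    library: TELibrary,
    config: CurateConfig = DEFAULT_CONFIG,
) -> List[TEFeature]:
    """Merge runs of neighbouring same-family, same-strand, collinear
    hits into single (multi-part) features.

    Adjacent merged parts with zero query gap coalesce into one part.
    Feature attributes (reference element, score) come from the longest
    constituent hit."""
    features: List[TEFeature] = []
    group: List[Tuple[RawHit, Part]] = []

    def flush() -> None:
        if not group:
            return
        parts: List[Part] = []
        for _, p in group:
            if parts and p.qstart == parts[-1].qend:
                last = parts[-1]
                parts[-1] = Part(
                    last.qstart,
                    p.qend,
                    min(last.te_start, p.te_start),
                    max(last.te_end, p.te_end),
                )
            else:
                parts.append(p)
        longest = max(group, key=lambda hp: hp[1].qlen)[0]
        features.append(
            TEFeature(
                feature_id=f"tmp{len(features)}",
                seqid=longest.query.seqid,
                strand=longest.query.strand,
                family_id=library.family_of(longest.te_id),
                parts=parts,
                superfamily=library.superfamily_of(longest.te_id),
                te_id=longest.te_id,
                score=max(h.score for h, _ in group),
            )
        )
        group.clear()

    for hit in hits:
        if hit.te_id not in library:
            raise LookupError(f"hit {hit.hit_id}: unknown reference {hit.te_id!r}")
        part = _hit_part(hit)
        if group:
            prev_hit, prev_part = group[-1]
            gap = part.qstart - prev_part.qend
            compatible = (
                hit.query.seqid == prev_hit.query.seqid
                and hit.query.strand == prev_hit.query.strand
                and library.family_of(hit.te_id) == library.family_of(prev_hit.te_id)
                and 0 <= gap <= config.max_gap
            )
            if compatible:
                placed = _collinear_with_ltr(
                    prev_part,
                    part,
                    hit.query.strand,
                    library.elements.get(prev_hit.te_id),
                    library.elements.get(hit.te_id),
                    config,
                    allow_replace_prev=len(group) == 1,
                )
                if placed is not None:
                    group[-1] = (prev_hit, placed[0])
                    group.append((hit, placed[1]))
                    continue
            flush()
        group.append((hit, part))
    flush()
    return features


# ---------------------------------------------------------------------------
# stage 3: nested reconstruction
# ---------------------------------------------------------------------------

def _junction_collinear(
    a: TEFeature, b: TEFeature, library: TELibrary, config: CurateConfig
) -> Optional[Tuple[Part, Part]]:
    return _collinear_with_ltr(
        a.parts[-1],
        b.parts[0],
        a.strand,
        library.elements.get(a.te_id) if a.te_id else None,
        library.elements.get(b.te_id) if b.te_id else None,
        config,
        allow_replace_prev=a.n_parts == 1,
    )


def reconstruct_nested(
    features: Sequence[TEFeature],
    library: TELibrary,
    config: CurateConfig = DEFAULT_CONFIG,
) -> AnnotationSet:
    """Join split same-family features across nested insertions.

    Two features of one family joined iff separated by 1..``max_intervening``
    whole predicted TEs all lying wholly inside the junction gap, with a
    collinear consensus junction (LTR dispensation included).  Joins are
    applied greedily, innermost (smallest) gaps first, iterating until no
    join applies; features spanning a closed gap become children of the
    joined feature.  Input feature ids are preserved."""
    out = AnnotationSet()
    for f in features:
        out.add(f)
    from bisect import bisect_left

    for seqid in out.seqids():
        while True:
            top = [f for f in out.by_seqid(seqid) if f.parent is None]
            starts = [f.span_start for f in top]
            candidates: List[Tuple[int, int, TEFeature, TEFeature, List[TEFeature]]] = []
            for a in top:
                # features wholly right of a's last part, in span order;
                # a candidate partner at walk position k has exactly the
                # k walked features as intervening TEs, all of which must
                # end before the partner starts (else the gap is blocked)
                j0 = bisect_left(starts, a.span_end)
                walked: List[TEFeature] = []
                max_end = -1
                for b in top[j0:]:
                    k = len(walked)
                    if k > config.max_intervening:
                        break
                    if (
                        b.family_id == a.family_id
                        and b.strand == a.strand
                        and max_end <= b.span_start
                        and 1 <= k <= config.max_intervening
                    ):
                        placed = _junction_collinear(a, b, library, config)
                        if placed is not None:
                            # forward consensus discontinuity across the
                            # junction; a true split has ~none (the copies
                            # overlap by the target-site duplication),
                            # while chaining two distinct copies leaves a
                            # large unexplained skip
                            p, q = placed
                            if a.strand == "+":
                                jump = q.te_start - p.te_end
                            else:
                                jump = p.te_start - q.te_end
                            gap = b.span_start - a.span_end
                            candidates.append(
                                (max(jump, 0), gap, a.span_end, a, b, walked.copy())
                            )
                    walked.append(b)
                    max_end = max(max_end, b.span_end)
            if not candidates:
                break
            candidates.sort(key=lambda c: (c[0], c[1], c[2]))
            _, _, _, a, b, inner = candidates[0]
            placed = _junction_collinear(a, b, library, config)
            assert placed is not None
            a.parts[-1], b.parts[0] = placed
            a.parts.extend(b.parts)
            a.check_parts()
            a.score = max(a.score, b.score)
            if b.te_id is not None:
                a_long = max(a.parts, key=lambda p: p.qlen)
                if a_long in b.parts:
                    a.te_id = b.te_id
            for child in b.children:
                out[child].parent = a.feature_id
                a.children.append(child)
            for f in inner:
                f.parent = a.feature_id
                a.children.append(f.feature_id)
            del out.features[b.feature_id]
    out.normalize()
    out.validate()
    return out


# ---------------------------------------------------------------------------
# stage 4: completeness
# ---------------------------------------------------------------------------

def classify_completeness(
    feature: TEFeature,
    library: TELibrary,
    coverage_min: float = 0.90,
    extremity_tol: int = 50,
) -> str:
    """Call a model intact/complete or fragmented.

    Complete iff the union of consensus positions covered by its parts is
    >= ``coverage_min`` of the reference length AND both reference
    extremities are reached within ``extremity_tol``.  A feature whose
    reference is not flagged complete is fragmented by definition."""
    ref = library.elements.get(feature.te_id) if feature.te_id else None
    if ref is None or not ref.is_complete:
        return FRAGMENTED
    ivs = sorted((p.te_start, p.te_end) for p in feature.parts)
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e + 1:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s + 1
    if covered < coverage_min * ref.length:
        return FRAGMENTED
    if min(p.te_start for p in feature.parts) > extremity_tol + 1:
        return FRAGMENTED
    if max(p.te_end for p in feature.parts) < ref.length - extremity_tol:
        return FRAGMENTED
    return COMPLETE


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def curate(
    raw_hits: Sequence[RawHit],
    library: TELibrary,
    config: CurateConfig = DEFAULT_CONFIG,
) -> AnnotationSet:
    """Full curation pipeline: overlap resolution, collinear merging,
    nested reconstruction, completeness calling.  Deterministic for a
    fixed input and configuration."""
    by_seqid: Dict[str, List[RawHit]] = {}
    for h in raw_hits:
        by_seqid.setdefault(h.query.seqid, []).append(h)
    all_features: List[TEFeature] = []
    n_resolved = 0
    for seqid in sorted(by_seqid):
        hits = sorted(by_seqid[seqid], key=lambda h: (h.query.start, h.query.end))
        resolved = resolve_overlaps(hits, library, config)
        n_resolved += len(resolved)
        all_features.extend(merge_collinear(resolved, library, config))
    logger.info(
        "curate: %d hits in, %d after overlap resolution, %d merged features",
        len(raw_hits),
        n_resolved,
        len(all_features),
    )
    for i, f in enumerate(all_features, start=1):
        f.feature_id = f"F{i:05d}"
    annotations = reconstruct_nested(all_features, library, config)
    n_joined = sum(1 for f in annotations if f.n_parts > 1)
    for f in annotations:
        f.status = classify_completeness(
            f, library, config.coverage_min, config.extremity_tol
        )
    n_complete = sum(1 for f in annotations if f.status == COMPLETE)
    logger.info(
        "curate: %d features out (%d multi-part, %d complete)",
        len(annotations),
        n_joined,
        n_complete,
    )
    return annotations


def hits_as_features(raw_hits: Sequence[RawHit], library: TELibrary) -> AnnotationSet:
    """Interpret each raw hit as a stand-alone single-part feature
    (the uncurated baseline an evaluation compares against)."""
    out = AnnotationSet()
    for i, h in enumerate(sorted(raw_hits, key=lambda h: (h.query.seqid, h.query.start)), 1):
        out.add(
            TEFeature(
                feature_id=f"R{i:05d}",
                seqid=h.query.seqid,
                strand=h.query.strand,
                family_id=library.family_of(h.te_id) if h.te_id in library else h.te_id,
                parts=[_hit_part(h)],
                superfamily=library.superfamily_of(h.te_id) if h.te_id in library else "",
                te_id=h.te_id,
                score=h.score,
            )
        )
    return out
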