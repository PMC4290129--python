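"""LTR retrotransposon insertion dating, family amplification dynamics,
and solo-LTR detection.

At insertion time the two LTRs of an LTR-RT are identical; they then
accumulate substitutions independently, so the divergence K between them
dates the insertion as ``T = K / (2 r)`` with a substitution rate r
(default 1.3e-8 substitutions/site/year).  Per family, the burst date is
the mode of the insertion-date distribution (0.1 MY bins) and the
activity period is the shortest interval containing more than 80% of the
dated insertions.

Solo-LTRs -- single LTRs left behind by unequal intrachromosomal
recombination -- are recognised among LTR-library hits by near-complete
coverage of their source LTR, absence of overlap with any intact
element, and an intact 5 bp target-site duplication (at most one
mismatch) flanking the match.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .formats import SequenceSource, fetch_sequence, get_sequence
from .library_builder import detect_terminal_repeats
from .model import (
    COMPLETE,
    AnnotationSet,
    GenomicInterval,
    Part,
    RawHit,
    TEFeature,
    TELibrary,
)

logger = logging.getLogger(__name__)

MUTATION_RATE = 1.3e-8  # substitutions / site / year

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


# ---------------------------------------------------------------------------
# divergence between an LTR pair
# ---------------------------------------------------------------------------

def _aligned_columns(a: str, b: str) -> Iterable[Tuple[str, str]]:
    """Columns of a global pairwise alignment of ``a`` and ``b``
    (match +2, mismatch -3, gap open -5, gap extend -2), gap columns
    excluded."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-3,
        open_gap_score=-5,
        extend_gap_score=-2,
    )
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for x, y in zip(a[a0:a1], b[b0:b1]):
            yield x, y


def ltr_divergence(ltr5_seq: str, ltr3_seq: str, model: str = "raw") -> float:
    """Substitutions per site between the two LTR copies of one element.

    ``model='raw'`` returns the observed mismatch proportion;
    ``model='K2P'`` applies the Kimura two-parameter correction
    ``K = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`` with transition/transversion
    proportions P and Q."""
    if not ltr5_seq or not ltr3_seq:
        raise ValueError("empty LTR sequence")
    if model not in ("raw", "K2P"):
        raise ValueError(f"unknown divergence model {model!r}")
    a, b = ltr5_seq.upper(), ltr3_seq.upper()
    sites = transitions = transversions = 0
    for x, y in _aligned_columns(a, b):
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("alignment with zero compared sites")
    if model == "raw":
        return (transitions + transversions) / sites
    p = transitions / sites
    q = transversions / sites
    if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
        raise ValueError("K2P correction undefined (saturated divergence)")
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


# ---------------------------------------------------------------------------
# dating one insertion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatedInsertion:
    feature_id: str
    family_id: str
    K: float
    age_years: float
    model: str = "raw"


def _query_pos(part: Part, t: int, strand: str) -> int:
    """Genome position of consensus coordinate ``t`` inside a part,
    by linear proportion (exact when the part aligns 1:1)."""
    if strand == "+":
        off = t - part.te_start
    else:
        off = part.te_end - t
    return part.qstart + round(off * part.qlen / part.te_span)

def _consensus_to_query(
    feature: TEFeature, interval: Tuple[int, int]
) -> Optional[GenomicInterval]:
    """Map a consensus interval onto the genome through a single part of
    the feature; ``None`` when no part contains it entirely."""
    s, e = interval
    for part in feature.parts:
        if part.te_start <= s and e <= part.te_end:
            q1 = _query_pos(part, s, feature.strand)
            q2 = _query_pos(part, e, feature.strand)
            lo, hi = min(q1, q2), max(q1, q2) + 1
            return GenomicInterval(feature.seqid, lo, hi, feature.strand)
    return None


def extract_ltr_sequences(
    feature: TEFeature,
    genome: SequenceSource,
    library: TELibrary,
    extremity_tol: int = 50,
) -> Optional[Tuple[str, str]]:
    """The genomic sequences of a complete element's two LTRs.

    Uses the LTR intervals annotated on the reference element when
    available; otherwise falls back to de novo terminal-repeat detection
    on the feature sequence, accepting only repeats within
    ``extremity_tol`` bp of the feature extremities.  ``None`` when the
    LTRs cannot be located (the caller skips the feature)."""
    ref = library.elements.get(feature.te_id) if feature.te_id else None
    if ref is not None and ref.has_ltrs:
        iv5 = _consensus_to_query(feature, ref.ltr5)
        iv3 = _consensus_to_query(feature, ref.ltr3)
        if iv5 is not None and iv3 is not None:
            s5 = fetch_sequence(genome, iv5)
            s3 = fetch_sequence(genome, iv3)
            return (s3, s5) if feature.strand == "-" else (s5, s3)
    # fall back: locate terminal repeats on the feature sequence itself
    span = GenomicInterval(
        feature.seqid, feature.span_start, feature.span_end, feature.strand
    )
    seq = fetch_sequence(genome, span)
    pair = detect_terminal_repeats(seq, extremity_range=extremity_tol)
    if pair is None:
        return None
    (s1, e1), (s2, e2) = pair
    return seq[s1 - 1 : e1], seq[s2 - 1 : e2]


def date_insertion(
    feature: TEFeature,
    genome: SequenceSource,
    library: TELibrary,
    r: float = MUTATION_RATE,
    model: str = "raw",
) -> Optional[DatedInsertion]:
    """Insertion age of a complete LTR-RT feature, ``T = K/(2 r)``.

    Returns ``None`` (with a logged reason) when the LTR pair cannot be
    located at the element extremities."""
    ltrs = extract_ltr_sequences(feature, genome, library)
    if ltrs is None:
        logger.info("date_insertion: %s skipped (LTRs not locatable)", feature.feature_id)
        return None
    k = ltr_divergence(ltrs[0], ltrs[1], model=model)
    return DatedInsertion(
        feature_id=feature.feature_id,
        family_id=feature.family_id,
        K=k,
        age_years=k / (2 * r),
        model=model,
    )


def date_annotation(
    annotation_set: AnnotationSet,
    genome: SequenceSource,
    library: TELibrary,
    r: float = MUTATION_RATE,
    model: str = "raw",
) -> List[DatedInsertion]:
    """Date every complete LTR-RT feature of an annotation set."""
    out = []
    for f in annotation_set:
        if f.status != COMPLETE or not f.superfamily.startswith("RL"):
            continue
        d = date_insertion(f, genome, library, r=r, model=model)
        if d is not None:
            out.append(d)
    return out


# ---------------------------------------------------------------------------
# family activity profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyActivity:
    family_id: str
    n_dated: int
    burst_date_years: float
    activity_start: float
    activity_end: float

    @property
    def activity_span(self) -> float:
        return self.activity_end - self.activity_start


def shortest_activity_window(
    ages: Sequence[float], fraction: float = 0.8
) -> Tuple[float, float]:
    """Shortest interval between two order statistics containing strictly
    more than ``fraction`` of the points (smallest qualifying count is
    ``floor(fraction*n) + 1``)."""
    xs = sorted(ages)
    n = len(xs)
    m = min(int(math.floor(fraction * n + 1e-9)) + 1, n)
    best = (math.inf, 0.0, 0.0)
    for i in range(0, n - m + 1):
        span = xs[i + m - 1] - xs[i]
        if span < best[0]:
            best = (span, xs[i], xs[i + m - 1])
    return best[1], best[2]


def family_activity_profile(
    dated_insertions: Iterable[DatedInsertion],
    min_copies: int = 20,
    bin_width: float = 100_000.0,
    fraction: float = 0.8,
) -> Dict[str, FamilyActivity]:
    """Burst date and activity period per family.

    Families with fewer than ``min_copies`` dated insertions are omitted.
    The burst is the midpoint of the maximal-count histogram bin
    (``bin_width`` years, bins anchored at 0) among insertions inside the
    activity window, so it always lies within the window."""
    by_family: Dict[str, List[float]] = {}
    for d in dated_insertions:
        by_family.setdefault(d.family_id, []).append(d.age_years)
    out: Dict[str, FamilyActivity] = {}
    for fam in sorted(by_family):
        ages = by_family[fam]
        if len(ages) < min_copies:
            continue
        start, end = shortest_activity_window(ages, fraction)
        inside = [a for a in ages if start <= a <= end]
        counts: Dict[int, int] = {}
        for a in inside:
            counts[int(a // bin_width)] = counts.get(int(a // bin_width), 0) + 1
        peak_bin = min(counts, key=lambda b: (-counts[b], b))
        burst = min(max((peak_bin + 0.5) * bin_width, start), end)
        out[fam] = FamilyActivity(
            family_id=fam,
            n_dated=len(ages),
            burst_date_years=burst,
            activity_start=start,
            activity_end=end,
        )
    return out


# ---------------------------------------------------------------------------
# solo-LTR detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SoloLTRCall:
    interval: GenomicInterval
    family_id: str
    source_id: str
    tsd_left: str
    tsd_right: str
    n_mismatches: int


def collect_solo_ltr_library(
    annotation_set: AnnotationSet,
    genome: SequenceSource,
    library: TELibrary,
) -> Dict[str, str]:
    """LTR sequences of all complete LTR-RT features, kept iff flanked by
    the canonical 5'-TG ... CA-3' dinucleotides (strand-aware).  Keys are
    ``<feature_id>_LTR5`` / ``<feature_id>_LTR3``."""
    out: Dict[str, str] = {}
    for f in annotation_set:
        if f.status != COMPLETE or not f.superfamily.startswith("RL"):
            continue
        ltrs = extract_ltr_sequences(f, genome, library)
        if ltrs is None:
            continue
        for tag, seq in zip(("LTR5", "LTR3"), ltrs):
            s = seq.upper()
            if s.startswith("TG") and s.endswith("CA"):
                out[f"{f.feature_id}_{tag}"] = s
    return out


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y) + abs(len(a) - len(b))


def call_solo_ltrs(
    ltr_hits: Sequence[RawHit],
    genome: SequenceSource,
    annotation_set: AnnotationSet,
    ltr_library: Mapping[str, str],
    tsd_len: int = 5,
    max_mismatch: int = 1,
    min_source_coverage: float = 0.90,
) -> List[SoloLTRCall]:
    """Solo-LTR calls among hits of an LTR library against the genome.

    A hit is a solo-LTR iff it covers >= ``min_source_coverage`` of its
    source LTR, does not overlap any part of a complete LTR-RT feature,
    and the ``tsd_len``-mers immediately flanking it differ at <=
    ``max_mismatch`` positions (an intact target-site duplication).
    Hits at a sequence edge lacking a full flank are skipped."""
    complete_parts: Dict[str, List[Tuple[int, int]]] = {}
    fam_of_source: Dict[str, str] = {}
    for f in annotation_set:
        if f.status == COMPLETE and f.superfamily.startswith("RL"):
            for p in f.parts:
                complete_parts.setdefault(f.seqid, []).append((p.qstart, p.qend))
        for tag in ("LTR5", "LTR3"):
            fam_of_source[f"{f.feature_id}_{tag}"] = f.family_id
    for ivs in complete_parts.values():
        ivs.sort()
    calls: List[SoloLTRCall] = []
    for hit in ltr_hits:
        if hit.te_id not in ltr_library:
            raise LookupError(f"hit {hit.hit_id}: unknown LTR source {hit.te_id!r}")
        src_len = len(ltr_library[hit.te_id])
        if (hit.te_end - hit.te_start + 1) < min_source_coverage * src_len:
            continue
        overlap = False
        for s, e in complete_parts.get(hit.query.seqid, ()):
            if s < hit.query.end and hit.query.start < e:
                overlap = True
                break
            if s >= hit.query.end:
                break
        if overlap:
            continue
        seq = get_sequence(genome, hit.query.seqid)
        if hit.query.start < tsd_len or hit.query.end + tsd_len > len(seq):
            logger.info(
                "call_solo_ltrs: %s skipped (insufficient flank)", hit.hit_id
            )
            continue
        left = seq[hit.query.start - tsd_len : hit.query.start]
        right = seq[hit.query.end : hit.query.end + tsd_len]
        nm = _hamming(left, right)
        if nm <= max_mismatch:
            calls.append(
                SoloLTRCall(
                    interval=hit.query,
                    family_id=fam_of_source.get(hit.te_id, hit.te_id),
                    source_id=hit.te_id,
                    tsd_left=left,
                    tsd_right=right,
                    n_mismatches=nm,
                )
            )
    return calls
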