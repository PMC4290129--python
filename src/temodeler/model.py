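"""Domain types shared across the toolkit.

Coordinate conventions
----------------------
Two conventions coexist and are kept strictly apart:

* **Genome coordinates** (everything positioned on an assembled sequence)
  are 0-based half-open intervals, the arithmetic-safe convention.
  External formats (RepeatMasker ``.out``, GFF3) are 1-based inclusive and
  are converted at the I/O boundary only (:mod:`temodeler.formats`).
* **Reference/consensus coordinates** (positions on a TE reference
  element: ``te_start``/``te_end`` of hits and feature parts, annotated
  LTR intervals) are 1-based inclusive throughout, matching how repeat
  libraries and RepeatMasker report them.  They are normalised so that
  ``te_start <= te_end`` regardless of strand; orientation is carried by
  a single strand flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Tuple

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTRYKMacgtrykmN n", "TGCAYRMKtgcayrmkN n")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-light)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genome interval, 0-based half-open."""

    seqid: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seqid!r}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RawHit:
    """One similarity-search match between the genome and a reference element.

    ``te_start``/``te_end`` are 1-based inclusive on the reference
    consensus, normalised so ``te_start <= te_end`` for both strands.
    """

    query: GenomicInterval
    te_id: str
    te_start: int
    te_end: int
    score: float
    divergence_pct: float = 0.0
    hit_id: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.te_start <= self.te_end):
            raise ValueError(
                f"invalid consensus interval [{self.te_start}, {self.te_end}]"
            )


@dataclass(frozen=True)
class TEReference:
    """A classified reference element of the TE library."""

    id: str
    family_id: str
    superfamily: str
    length: int
    is_complete: bool = False
    ltr5: Optional[Tuple[int, int]] = None  # 1-based inclusive on consensus
    ltr3: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.id}: non-positive length {self.length}")
        for name, iv in (("ltr5", self.ltr5), ("ltr3", self.ltr3)):
            if iv is not None:
                s, e = iv
                if not (1 <= s <= e <= self.length):
                    raise ValueError(
                        f"{self.id}: {name} interval {iv} outside [1, {self.length}]"
                    )
        if self.ltr5 is not None and self.ltr3 is not None:
            if not self.ltr5[1] < self.ltr3[0]:
                raise ValueError(f"{self.id}: ltr5 must precede ltr3")

    @property
    def has_ltrs(self) -> bool:
        return self.ltr5 is not None and self.ltr3 is not None


class TELibrary:
    """Classified TE reference library: elements, family index and sequences."""

    def __init__(
        self,
        elements: Mapping[str, TEReference],
        sequences: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.elements: Dict[str, TEReference] = dict(elements)
        self.sequences: Dict[str, str] = dict(sequences or {})
        self.families: Dict[str, List[str]] = {}
        for eid, el in self.elements.items():
            if eid != el.id:
                raise ValueError(f"element key {eid!r} != element id {el.id!r}")
            self.families.setdefault(el.family_id, []).append(eid)
        for fam in self.families.values():
            fam.sort()
        for eid, seq in self.sequences.items():
            if eid not in self.elements:
                raise ValueError(f"sequence for unknown element {eid!r}")
            if len(seq) != self.elements[eid].length:
                raise ValueError(
                    f"{eid}: sequence length {len(seq)} != declared "
                    f"{self.elements[eid].length}"
                )

    def __contains__(self, te_id: str) -> bool:
        return te_id in self.elements

    def __len__(self) -> int:
        return len(self.elements)

    def family_of(self, te_id: str) -> str:
        try:
            return self.elements[te_id].family_id
        except KeyError:
            raise LookupError(f"unknown reference element {te_id!r}") from None

    def superfamily_of(self, te_id: str) -> str:
        try:
            return self.elements[te_id].superfamily
        except KeyError:
            raise LookupError(f"unknown reference element {te_id!r}") from None


@dataclass
class Part:
    """One contiguous aligned segment of a TE feature.

    ``qstart``/``qend`` in genome coordinates (0-based half-open),
    ``te_start``/``te_end`` on the consensus (1-based inclusive).
    """

    qstart: int
    qend: int
    te_start: int
    te_end: int

    def __post_init__(self) -> None:
        if self.qstart >= self.qend:
            raise ValueError(f"empty part [{self.qstart}, {self.qend})")
        if not (1 <= self.te_start <= self.te_end):
            raise ValueError(
                f"invalid consensus interval [{self.te_start}, {self.te_end}]"
            )

    @property
    def qlen(self) -> int:
        return self.qend - self.qstart

    @property
    def te_span(self) -> int:
        return self.te_end - self.te_start + 1


COMPLETE = "complete"
FRAGMENTED = "fragmented"


@dataclass
class TEFeature:
    """A curated, possibly multi-part TE model.

    Multi-part features arise when nested insertions split one element
    into separated segments; ``children`` lists the features reconstructed
    inside this element's junction gaps.
    """

    feature_id: str
    seqid: str
    strand: str
    family_id: str
    parts: List[Part]
    superfamily: str = ""
    te_id: Optional[str] = None
    status: str = FRAGMENTED
    parent: Optional[str] = None
    children: List[str] = field(default_factory=list)
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.parts:
            raise ValueError(f"{self.feature_id}: feature with no parts")
        self.check_parts()

    def check_parts(self) -> None:
        for a, b in zip(self.parts, self.parts[1:]):
            if b.qstart < a.qend:
                raise ValueError(
                    f"{self.feature_id}: parts unsorted or overlapping "
                    f"([{a.qstart},{a.qend}) then [{b.qstart},{b.qend}))"
                )

    @property
    def span_start(self) -> int:
        return self.parts[0].qstart

    @property
    def span_end(self) -> int:
        return self.parts[-1].qend

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    @property
    def aligned_bp(self) -> int:
        return sum(p.qlen for p in self.parts)


class AnnotationSet:
    """A set of TE features with a per-seqid index and a nesting forest."""

    def __init__(self, features: Optional[Mapping[str, TEFeature]] = None) -> None:
        self.features: Dict[str, TEFeature] = {}
        if features:
            for f in features.values():
                self.add(f)

    def add(self, feature: TEFeature) -> None:
        if feature.feature_id in self.features:
            raise ValueError(f"duplicate feature id {feature.feature_id!r}")
        self.features[feature.feature_id] = feature

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[TEFeature]:
        return iter(self.features.values())

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.features

    def __getitem__(self, feature_id: str) -> TEFeature:
        return self.features[feature_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.features == other.features

    def seqids(self) -> List[str]:
        return sorted({f.seqid for f in self})

    def by_seqid(self, seqid: str) -> List[TEFeature]:
        """Features on one sequence, sorted by span start."""
        feats = [f for f in self if f.seqid == seqid]
        feats.sort(key=lambda f: (f.span_start, f.span_end, f.feature_id))
        return feats

    def parts_by_seqid(self, seqid: str) -> List[Tuple[int, int, TEFeature, Part]]:
        """All (qstart, qend, feature, part) on one sequence, sorted."""
        out = [
            (p.qstart, p.qend, f, p)
            for f in self
            if f.seqid == seqid
            for p in f.parts
        ]
        out.sort(key=lambda t: (t[0], t[1]))
        return out

    def top_level(self) -> List[TEFeature]:
        return [f for f in self if f.parent is None]

    def normalize(self) -> "AnnotationSet":
        """Sort children lists in place (canonical form for comparisons)."""
        for f in self:
            f.children.sort()
        return self

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        for seqid in self.seqids():
            parts = self.parts_by_seqid(seqid)
            for (s1, e1, f1, _), (s2, e2, f2, _) in zip(parts, parts[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping parts on {seqid}: "
                        f"{f1.feature_id}[{s1},{e1}) and {f2.feature_id}[{s2},{e2})"
                    )
        for f in self:
            if f.parent is not None:
                if f.parent not in self.features:
                    raise ValueError(
                        f"{f.feature_id}: unknown parent {f.parent!r}"
                    )
                if f.feature_id not in self.features[f.parent].children:
                    raise ValueError(
                        f"{f.feature_id}: parent {f.parent} does not list it"
                    )
            for c in f.children:
                if c not in self.features or self.features[c].parent != f.feature_id:
                    raise ValueError(
                        f"{f.feature_id}: inconsistent child link {c!r}"
                    )
        # acyclicity / finite depth
        for f in self:
            seen = set()
            cur: Optional[str] = f.feature_id
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"parent cycle involving {cur!r}")
                seen.add(cur)
                cur = self.features[cur].parent

    def nesting_depth(self, feature_id: str) -> int:
        depth = 1
        cur = self.features[feature_id].parent
        while cur is not None:
            depth += 1
            cur = self.features[cur].parent
        return depth


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene locus (for TE-context analyses)."""

    gene_id: str
    interval: GenomicInterval
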