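"""Synthetic genomes with a known TE insertion history.

The generator produces (a) a classified reference library with annotated
terminal repeats, (b) a genome built by sequential element insertions --
uniform positions, optional nesting inside existing elements (splitting
the host into separated parts and recording the parent link), target
site duplications written at every insertion boundary, and LTR pairs
mutated to a known age -- and (c) noisy raw-hit sets emulating
similarity-search output (border jitter, over-fragmentation, false
hits, mis-placed LTR matches).  With all noise parameters at zero the
hit set reconstructs the truth exactly under curation.

Substitutions are drawn uniformly across sites with equal base exchange
probabilities, so the expected pairwise LTR divergence of an element of
age T is 2*r*T to first order and the dating oracle stays analytic.

Nested insertions choose a host of a *different* family than the
inserting element: a same-family zero-gap junction is collinear by
construction and therefore unidentifiable from hit coordinates, so no
curation method could reconstruct it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import (
    COMPLETE,
    AnnotationSet,
    Gene,
    GenomicInterval,
    Part,
    RawHit,
    TEFeature,
    TELibrary,
    TEReference,
    revcomp,
)

BASES = "ACGT"

# superfamily-characteristic target-site duplication lengths
TSD_LEN: Dict[str, int] = {"RLG": 5, "RLC": 5, "RLX": 5, "DTC": 3, "DTM": 9, "DTA": 8}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated genome.

    Defaults describe a wheat-like, TE-dense sequence: ~1 Mb once ~200
    elements of 2-6 kb have been inserted into 200 kb of background
    (GC 0.46), 40% of insertions nested, ages uniform over the last 3 MY
    at the standard grass substitution rate."""

    seed: int = 0
    n_families: int = 8
    superfamily_weights: Mapping[str, float] = field(
        default_factory=lambda: {"RLG": 0.4, "RLC": 0.25, "DTC": 0.35}
    )
    element_len_range: Tuple[int, int] = (2000, 6000)
    ltr_len_range: Tuple[int, int] = (200, 400)
    background_len: int = 200_000
    n_insertions: int = 200
    nesting_prob: float = 0.4
    age_range_years: Tuple[float, float] = (0.0, 3.0e6)
    rate: float = 1.3e-8
    gc: float = 0.46
    min_split_margin: int = 50  # keep splits away from part boundaries
    # hit noise
    frag_prob: float = 0.0
    jitter_sd: float = 0.0
    false_hit_rate: float = 0.0
    ltr_confusion_prob: float = 0.0
    # extra planted structures
    n_solo_ltrs: int = 0
    n_truncated_ltrs: int = 0
    n_gene_captures: int = 0
    n_background_genes: int = 0
    gene_len_range: Tuple[int, int] = (1000, 2000)
    seqid: str = "chr1"

    def __post_init__(self) -> None:
        for name in ("element_len_range", "ltr_len_range", "gene_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} inverted: {lo} > {hi}")
        for name in ("nesting_prob", "frag_prob", "false_hit_rate", "ltr_confusion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class PlantedSolo:
    interval: GenomicInterval
    family_id: str
    source_id: str


@dataclass(frozen=True)
class PlantedFragment:
    interval: GenomicInterval
    family_id: str
    source_id: str
    fraction: float


@dataclass(frozen=True)
class PlantedCapture:
    gene_id: str
    host_feature_id: str
    family_id: str


@dataclass
class SimTruth:
    """A simulated genome plus its complete ground truth."""

    genome: Dict[str, str]
    annotations: AnnotationSet
    ages: Dict[str, float]
    genes: List[Gene]
    solo_ltrs: List[PlantedSolo]
    truncated_ltrs: List[PlantedFragment]
    captures: List[PlantedCapture]
    config: SimConfig


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.46) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def mutate_sequence(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``p`` by a uniformly chosen
    different base (Jukes-Cantor-like, at most one hit per site)."""
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hit:
        old = arr[i].decode()
        choices = [b for b in BASES if b != old]
        arr[i] = choices[rng.integers(3)].encode()
    return arr.tobytes().decode()


def simulate_ltr_pair(
    length: int, age_years: float, rate: float, rng: np.random.Generator,
    gc: float = 0.46,
) -> Tuple[str, str]:
    """Two LTR copies of one element of the given age: a common ancestor
    mutated independently with per-site probability ``rate * age``."""
    anc = random_sequence(rng, length, gc)
    p = rate * age_years
    return mutate_sequence(anc, p, rng), mutate_sequence(anc, p, rng)


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

def simulate_library(config: SimConfig) -> TELibrary:
    """A classified reference library, deterministic per seed.

    LTR-RT families get identical 5'/3' LTRs starting TG and ending CA
    with annotated coordinates; CACTA-like (DTC) families get terminal
    inverted repeats."""
    if config.n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(config.seed)
    codes = sorted(config.superfamily_weights)
    weights = np.array([config.superfamily_weights[c] for c in codes], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * config.n_families).astype(int)
    while counts.sum() < config.n_families:
        counts[int(np.argmax(weights * config.n_families - counts))] += 1
    elements: Dict[str, TEReference] = {}
    sequences: Dict[str, str] = {}
    per_code: Dict[str, int] = {}
    for code, k in zip(codes, counts):
        for _ in range(int(k)):
            per_code[code] = per_code.get(code, 0) + 1
            family_id = f"{code}_famc{per_code[code]}"
            eid = f"{family_id}_cons"
            total = int(rng.integers(config.element_len_range[0],
                                     config.element_len_range[1] + 1))
            if code.startswith("RL"):
                ltr_len = int(rng.integers(config.ltr_len_range[0],
                                           config.ltr_len_range[1] + 1))
                ltr_len = min(ltr_len, (total - 100) // 2)
                ltr = "TG" + random_sequence(rng, ltr_len - 4, config.gc) + "CA"
                internal = random_sequence(rng, total - 2 * ltr_len, config.gc)
                seq = ltr + internal + ltr
                ref = TEReference(
                    id=eid, family_id=family_id, superfamily=code,
                    length=len(seq), is_complete=True,
                    ltr5=(1, ltr_len), ltr3=(len(seq) - ltr_len + 1, len(seq)),
                )
            else:
                tir = "CACTA" + random_sequence(rng, 10, config.gc)
                internal = random_sequence(rng, total - 2 * len(tir), config.gc)
                seq = tir + internal + revcomp(tir)
                ref = TEReference(
                    id=eid, family_id=family_id, superfamily=code,
                    length=len(seq), is_complete=True,
                )
            elements[eid] = ref
            sequences[eid] = seq
    return TELibrary(elements, sequences)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

class _GenomeBuilder:
    """Insertion engine: maintains the growing sequence and shifts all
    tracked coordinates consistently at each insertion."""

    def __init__(self, background: str, seqid: str) -> None:
        self.seq = background
        self.seqid = seqid
        self.features: Dict[str, TEFeature] = {}
        self.genes: List[Gene] = []
        self.solo_intervals: List[Tuple[int, int, str, str]] = []
        self.trunc_intervals: List[Tuple[int, int, str, str, float]] = []
        self._n = 0

    def new_id(self) -> str:
        self._n += 1
        return f"T{self._n:05d}"

    # -- coordinate bookkeeping ------------------------------------------

    def _shift_all(self, p: int, s: int, skip_part: Optional[Tuple[str, int]]) -> None:
        def sh_start(c: int) -> int:
            return c + s if c >= p else c

        def sh_end(c: int) -> int:
            return c + s if c > p else c

        for fid, f in self.features.items():
            for i, part in enumerate(f.parts):
                if skip_part is not None and (fid, i) == skip_part:
                    continue
                part.qstart = sh_start(part.qstart)
                part.qend = sh_end(part.qend)
        self.genes = [
            Gene(
                g.gene_id,
                GenomicInterval(
                    g.interval.seqid,
                    sh_start(g.interval.start),
                    sh_end(g.interval.end),
                    g.interval.strand,
                ),
            )
            for g in self.genes
        ]
        self.solo_intervals = [
            (sh_start(a), sh_end(b), fam, src) for a, b, fam, src in self.solo_intervals
        ]
        self.trunc_intervals = [
            (sh_start(a), sh_end(b), fam, src, fr)
            for a, b, fam, src, fr in self.trunc_intervals
        ]

    def part_gaps(self, min_len: int) -> List[Tuple[int, int]]:
        """Maximal intervals not covered by any feature part (background)."""
        ivs = sorted(
            (p.qstart, p.qend) for f in self.features.values() for p in f.parts
        )
        for g in self.genes:
            ivs.append((g.interval.start, g.interval.end))
        for t in self.trunc_intervals:
            ivs.append((t[0], t[1]))
        for t in self.solo_intervals:
            ivs.append((t[0], t[1]))
        ivs.sort()
        gaps = []
        cur = 0
        for s, e in ivs:
            if s - cur >= min_len:
                gaps.append((cur, s))
            cur = max(cur, e)
        if len(self.seq) - cur >= min_len:
            gaps.append((cur, len(self.seq)))
        return gaps

    def insert(
        self,
        p: int,
        insert_seq: str,
        tsd_len: int,
        split: Optional[Tuple[str, int]] = None,
    ) -> Tuple[int, int]:
        """Insert ``insert_seq`` at position ``p``, duplicating the
        ``tsd_len``-mer at the target site; returns the inserted
        element's genome interval.  ``split`` names (feature_id,
        part_index) of the host part being split."""
        elem_len = len(insert_seq)
        shift = tsd_len + elem_len
        if split is not None:
            fid, idx = split
            host = self.features[fid]
            part = host.parts[idx]
            a, b = part.qstart, part.qend
            assert a < p and p + tsd_len < b
            if host.strand == "+":
                te_mid_end = part.te_start + (p + tsd_len - a) - 1
                te_mid_start = part.te_start + (p - a)
                piece1 = Part(a, p + tsd_len, part.te_start, te_mid_end)
                piece2 = Part(p + tsd_len + elem_len, b + shift, te_mid_start, part.te_end)
            else:
                te_mid_start = part.te_end - (p + tsd_len - a) + 1
                te_mid_end = part.te_end - (p - a)
                piece1 = Part(a, p + tsd_len, te_mid_start, part.te_end)
                piece2 = Part(p + tsd_len + elem_len, b + shift, part.te_start, te_mid_end)
            self._shift_all(p, shift, skip_part=(fid, idx))
            host.parts[idx : idx + 1] = [piece1, piece2]
            host.parts.sort(key=lambda q: q.qstart)
        else:
            self._shift_all(p, shift, skip_part=None)
        self.seq = self.seq[: p + tsd_len] + insert_seq + self.seq[p:]
        return p + tsd_len, p + tsd_len + elem_len


def _choose_split_target(
    builder: _GenomeBuilder,
    rng: np.random.Generator,
    exclude_family: Optional[str],
    window: int,
    margin: int,
    superfamily_prefix: Optional[str] = None,
) -> Optional[Tuple[str, int, int]]:
    """(feature_id, part_index, position) for a nesting insertion, or
    ``None`` when no part is large enough."""
    cands = []
    for fid, f in builder.features.items():
        if exclude_family is not None and f.family_id == exclude_family:
            continue
        if superfamily_prefix and not f.superfamily.startswith(superfamily_prefix):
            continue
        for i, part in enumerate(f.parts):
            if part.qlen >= 2 * margin + window + 2:
                cands.append((fid, i))
    if not cands:
        return None
    fid, i = cands[int(rng.integers(len(cands)))]
    part = builder.features[fid].parts[i]
    p = int(rng.integers(part.qstart + margin + 1, part.qend - margin - window))
    return fid, i, p


def simulate_genome(library: TELibrary, config: SimConfig) -> SimTruth:
    """Build a genome by sequential insertions with full ground truth."""
    if not library.elements:
        raise ValueError("empty library")
    rng = np.random.default_rng(config.seed + 1)
    builder = _GenomeBuilder(
        random_sequence(rng, config.background_len, config.gc), config.seqid
    )
    eids = sorted(library.elements)
    margin = config.min_split_margin

    # plan insertions, oldest first so hosts predate their nested guests
    plans = []
    for _ in range(config.n_insertions):
        eid = eids[int(rng.integers(len(eids)))]
        age = float(rng.uniform(*config.age_range_years))
        strand = "+" if rng.random() < 0.5 else "-"
        plans.append((age, eid, strand))
    plans.sort(key=lambda t: -t[0])

    if config.background_len < 1000:
        raise ValueError("genome too small for requested insertions")

    ages: Dict[str, float] = {}
    for age, eid, strand in plans:
        ref = library.elements[eid]
        seq = library.sequences[eid]
        if ref.has_ltrs:
            p_sub = config.rate * age
            (l5s, l5e), (l3s, l3e) = ref.ltr5, ref.ltr3
            seq = (
                mutate_sequence(seq[: l5e], p_sub, rng)
                + seq[l5e : l3s - 1]
                + mutate_sequence(seq[l3s - 1 :], p_sub, rng)
            )
        tsd = TSD_LEN.get(ref.superfamily, 5)
        ins_seq = revcomp(seq) if strand == "-" else seq
        split = None
        if rng.random() < config.nesting_prob:
            split = _choose_split_target(
                builder, rng, exclude_family=ref.family_id, window=tsd, margin=margin
            )
        if split is not None:
            fid, idx, p = split
            qs, qe = builder.insert(p, ins_seq, tsd, split=(fid, idx))
            parent = fid
        else:
            gaps = builder.part_gaps(min_len=tsd + 2)
            weightsum = sum(e - s - tsd for s, e in gaps)
            if weightsum <= 0:
                raise ValueError("genome too small for requested insertions")
            pick = int(rng.integers(weightsum))
            for s, e in gaps:
                w = e - s - tsd
                if pick < w:
                    p = s + pick
                    break
                pick -= w
            qs, qe = builder.insert(p, ins_seq, tsd, split=None)
            parent = None
        fid_new = builder.new_id()
        feature = TEFeature(
            feature_id=fid_new,
            seqid=config.seqid,
            strand=strand,
            family_id=ref.family_id,
            parts=[Part(qs, qe, 1, ref.length)],
            superfamily=ref.superfamily,
            te_id=eid,
            status=COMPLETE,
            parent=parent,
            score=2.0 * ref.length,
        )
        builder.features[fid_new] = feature
        if parent is not None:
            builder.features[parent].children.append(fid_new)
        ages[fid_new] = age

    # planted gene captures: a gene inserted inside a DNA-transposon
    captures: List[PlantedCapture] = []
    for i in range(config.n_gene_captures):
        target = _choose_split_target(
            builder, rng, exclude_family=None,
            window=max(config.gene_len_range) + 1, margin=margin,
            superfamily_prefix="DT",
        )
        if target is None:
            break
        fid, idx, p = target
        glen = int(rng.integers(config.gene_len_range[0], config.gene_len_range[1] + 1))
        gseq = random_sequence(rng, glen, config.gc)
        qs, qe = builder.insert(p, gseq, tsd_len=0, split=(fid, idx))
        gid = f"G{i + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        builder.genes.append(
            Gene(gid, GenomicInterval(config.seqid, qs, qe, strand))
        )
        captures.append(
            PlantedCapture(
                gene_id=gid,
                host_feature_id=fid,
                family_id=builder.features[fid].family_id,
            )
        )

    # planted solo-LTRs (TSD present) and truncated fragments (TSD absent)
    ltr_refs = [e for e in eids if library.elements[e].has_ltrs]
    for _ in range(config.n_solo_ltrs):
        if not ltr_refs:
            break
        eid = ltr_refs[int(rng.integers(len(ltr_refs)))]
        ref = library.elements[eid]
        ltr_seq = library.sequences[eid][ref.ltr5[0] - 1 : ref.ltr5[1]]
        gaps = builder.part_gaps(min_len=len(ltr_seq) + 200)
        if not gaps:
            break
        s, e = gaps[int(rng.integers(len(gaps)))]
        p = int(rng.integers(s + 20, e - len(ltr_seq) - 20))
        qs, qe = builder.insert(p, ltr_seq, tsd_len=5, split=None)
        builder.solo_intervals.append((qs, qe, ref.family_id, f"{eid}_LTR"))
    for _ in range(config.n_truncated_ltrs):
        if not ltr_refs:
            break
        eid = ltr_refs[int(rng.integers(len(ltr_refs)))]
        ref = library.elements[eid]
        full = library.sequences[eid][ref.ltr5[0] - 1 : ref.ltr5[1]]
        frac = float(rng.uniform(0.4, 0.7))
        frag = full[: max(20, int(len(full) * frac))]
        gaps = builder.part_gaps(min_len=len(frag) + 200)
        if not gaps:
            break
        s, e = gaps[int(rng.integers(len(gaps)))]
        p = int(rng.integers(s + 20, e - len(frag) - 20))
        qs, qe = builder.insert(p, frag, tsd_len=0, split=None)
        builder.trunc_intervals.append(
            (qs, qe, ref.family_id, f"{eid}_LTR", len(frag) / len(full))
        )

    # background genes (not captured)
    for i in range(config.n_background_genes):
        glen = int(rng.integers(config.gene_len_range[0], config.gene_len_range[1] + 1))
        gaps = builder.part_gaps(min_len=glen + 200)
        if not gaps:
            break
        s, e = gaps[int(rng.integers(len(gaps)))]
        p = int(rng.integers(s + 20, e - glen - 20))
        qs, qe = builder.insert(p, random_sequence(rng, glen, config.gc), 0, None)
        strand = "+" if rng.random() < 0.5 else "-"
        builder.genes.append(
            Gene(f"BG{i + 1:03d}", GenomicInterval(config.seqid, qs, qe, strand))
        )

    annotations = AnnotationSet()
    for f in builder.features.values():
        annotations.add(f)
    annotations.normalize()
    annotations.validate()
    return SimTruth(
        genome={config.seqid: builder.seq},
        annotations=annotations,
        ages=ages,
        genes=builder.genes,
        solo_ltrs=[
            PlantedSolo(GenomicInterval(config.seqid, a, b), fam, src)
            for a, b, fam, src in builder.solo_intervals
        ],
        truncated_ltrs=[
            PlantedFragment(GenomicInterval(config.seqid, a, b), fam, src, fr)
            for a, b, fam, src, fr in builder.trunc_intervals
        ],
        captures=captures,
        config=config,
    )


# ---------------------------------------------------------------------------
# noisy raw hits
# ---------------------------------------------------------------------------

def _jitter_part(
    q0: int, q1: int, t0: int, t1: int, strand: str,
    sd: float, seq_len: int, ref_len: int, rng: np.random.Generator,
) -> Tuple[int, int, int, int]:
    """Apply rounded Gaussian border noise consistently to query and
    consensus coordinates, truncated to keep the hit valid."""
    for side in (0, 1):
        d = int(round(rng.normal(0.0, sd)))
        if d == 0:
            continue
        if side == 0:
            nq0 = min(max(q0 + d, 0), q1 - 20)
            d = nq0 - q0
            q0 = nq0
            if strand == "+":
                t0 = min(max(t0 + d, 1), t1)
            else:
                t1 = max(min(t1 - d, ref_len), t0)
        else:
            nq1 = max(min(q1 + d, seq_len), q0 + 20)
            d = nq1 - q1
            q1 = nq1
            if strand == "+":
                t1 = max(min(t1 + d, ref_len), t0)
            else:
                t0 = min(max(t0 - d, 1), t1)
    return q0, q1, t0, t1


def simulate_raw_hits(truth: SimTruth, config: Optional[SimConfig] = None) -> List[RawHit]:
    """Raw similarity hits for a simulated genome.

    Each truth part yields one hit (two, split at a uniform internal
    point, with probability ``frag_prob``); borders get rounded Gaussian
    jitter (``jitter_sd``); false hits to random families are added at
    ``false_hit_rate`` per true hit.  Mis-assignment between the two
    identical LTR copies is added separately by :func:`confuse_ltr_hits`.
    With all noise at zero the hits are exactly the truth parts."""
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 2)
    seq_len = len(truth.genome[config.seqid])
    hits: List[RawHit] = []
    lib_ages = truth.ages

    def emit(f: TEFeature, q0: int, q1: int, t0: int, t1: int, ref_len: int) -> None:
        if config.jitter_sd > 0:
            q0, q1, t0, t1 = _jitter_part(
                q0, q1, t0, t1, f.strand, config.jitter_sd, seq_len, ref_len, rng
            )
        hits.append(
            RawHit(
                query=GenomicInterval(f.seqid, q0, q1, f.strand),
                te_id=f.te_id,
                te_start=t0,
                te_end=t1,
                score=2.0 * (q1 - q0),
                divergence_pct=min(
                    50.0, 100.0 * 2 * config.rate * lib_ages.get(f.feature_id, 0.0)
                ),
                hit_id=f"h{len(hits) + 1}",
            )
        )

    # truth parts carry full elements, so max te_end equals reference length
    ref_len_of: Dict[str, int] = {}
    for f in truth.annotations:
        if f.te_id is not None and f.te_id not in ref_len_of:
            ref_len_of[f.te_id] = max(p.te_end for p in f.parts)

    for f in truth.annotations:
        ref_len = ref_len_of.get(f.te_id, max(p.te_end for p in f.parts))
        for part in f.parts:
            pieces = [(part.qstart, part.qend, part.te_start, part.te_end)]
            if part.qlen >= 80 and rng.random() < config.frag_prob:
                cut = int(rng.integers(30, part.qlen - 30))
                q0, q1, t0, t1 = pieces[0]
                if f.strand == "+":
                    tcut = t0 + round(cut * part.te_span / part.qlen)
                    pieces = [
                        (q0, q0 + cut, t0, max(t0, tcut - 1)),
                        (q0 + cut, q1, min(tcut, t1), t1),
                    ]
                else:
                    tcut = t1 - round(cut * part.te_span / part.qlen)
                    pieces = [
                        (q0, q0 + cut, min(tcut + 1, t1), t1),
                        (q0 + cut, q1, t0, max(t0, tcut)),
                    ]
            for q0, q1, t0, t1 in pieces:
                emit(f, q0, q1, t0, t1, ref_len)

    if config.false_hit_rate > 0 and hits:
        te_ids = sorted(ref_len_of)
        n_false = int(round(config.false_hit_rate * len(hits)))
        for _ in range(n_false):
            te_id = te_ids[int(rng.integers(len(te_ids)))]
            ref_len = ref_len_of[te_id]
            length = int(rng.integers(100, 800))
            q0 = int(rng.integers(0, max(1, seq_len - length)))
            t0 = int(rng.integers(1, max(2, ref_len - length)))
            hits.append(
                RawHit(
                    query=GenomicInterval(
                        config.seqid, q0, q0 + length,
                        "+" if rng.random() < 0.5 else "-",
                    ),
                    te_id=te_id,
                    te_start=t0,
                    te_end=min(t0 + length - 1, ref_len),
                    score=1.0 * length,
                    divergence_pct=float(rng.uniform(10, 30)),
                    hit_id=f"h{len(hits) + 1}",
                )
            )
    hits.sort(key=lambda h: (h.query.seqid, h.query.start, h.query.end))
    return hits


def confuse_ltr_hits(
    hits: Sequence[RawHit],
    library: TELibrary,
    prob: float,
    seed: int,
) -> List[RawHit]:
    """Re-code hits lying inside an annotated 3' LTR with the equivalent
    5'-LTR consensus coordinates with probability ``prob`` (the two LTR
    copies are identical at insertion, so a similarity search assigns
    such matches arbitrarily)."""
    rng = np.random.default_rng(seed)
    out: List[RawHit] = []
    for h in hits:
        ref = library.elements.get(h.te_id)
        if (
            ref is not None
            and ref.has_ltrs
            and h.te_start >= ref.ltr3[0]
            and h.te_end <= ref.ltr3[1]
            and rng.random() < prob
        ):
            off = ref.ltr3[0] - ref.ltr5[0]
            h = dc_replace(h, te_start=h.te_start - off, te_end=h.te_end - off)
        out.append(h)
    return out


def simulate_ltr_hits(
    truth: SimTruth, library: TELibrary
) -> Tuple[List[RawHit], Dict[str, str]]:
    """Hits of the LTR library against the genome, for solo-LTR calling.

    Emits full-coverage hits over planted solo-LTRs, partial hits over
    planted truncated fragments, and hits over the LTR regions of intact
    elements (which a solo-LTR caller must reject).  Returns the hits
    and the LTR source-sequence dict they refer to."""
    ltr_lib: Dict[str, str] = {}
    for eid in sorted(library.elements):
        ref = library.elements[eid]
        if ref.has_ltrs:
            ltr_lib[f"{eid}_LTR"] = library.sequences[eid][ref.ltr5[0] - 1 : ref.ltr5[1]]
    hits: List[RawHit] = []

    def add(iv: GenomicInterval, src: str, t0: int, t1: int) -> None:
        hits.append(
            RawHit(
                query=iv, te_id=src, te_start=t0, te_end=t1,
                score=2.0 * iv.length, hit_id=f"L{len(hits) + 1}",
            )
        )

    for solo in truth.solo_ltrs:
        add(solo.interval, solo.source_id, 1, len(ltr_lib[solo.source_id]))
    for frag in truth.truncated_ltrs:
        add(
            frag.interval, frag.source_id, 1,
            max(1, int(len(ltr_lib[frag.source_id]) * frag.fraction)),
        )
    for f in truth.annotations:
        ref = library.elements.get(f.te_id)
        if ref is None or not ref.has_ltrs or f.status != COMPLETE:
            continue
        src = f"{f.te_id}_LTR"
        ltr_len = ref.ltr5[1] - ref.ltr5[0] + 1
        first, last = f.parts[0], f.parts[-1]
        if first.qlen >= ltr_len:
            add(
                GenomicInterval(f.seqid, first.qstart, first.qstart + ltr_len, f.strand),
                src, 1, ltr_len,
            )
        if last.qlen >= ltr_len:
            add(
                GenomicInterval(f.seqid, last.qend - ltr_len, last.qend, f.strand),
                src, 1, ltr_len,
            )
    hits.sort(key=lambda h: (h.query.seqid, h.query.start))
    return hits, ltr_lib


def write_fixture(truth: SimTruth, library: TELibrary, outdir) -> None:
    """Write a simulated data set (genome FASTA, truth GFF3, ages TSV,
    hits .out, library FASTA+TSV, genes GFF3) to a directory."""
    import os

    import pandas as pd

    from . import formats

    os.makedirs(outdir, exist_ok=True)
    formats.write_fasta(truth.genome, os.path.join(outdir, "genome.fa"))
    formats.write_annotations_gff3(
        truth.annotations, os.path.join(outdir, "truth.gff3")
    )
    pd.DataFrame(
        [{"feature_id": k, "age_years": v} for k, v in sorted(truth.ages.items())]
    ).to_csv(os.path.join(outdir, "ages.tsv"), sep="\t", index=False)
    formats.write_repeatmasker_out(
        simulate_raw_hits(truth), os.path.join(outdir, "hits.out")
    )
    formats.write_te_library(
        library,
        os.path.join(outdir, "library.fa"),
        os.path.join(outdir, "library.tsv"),
    )
    formats.write_genes_gff3(truth.genes, os.path.join(outdir, "genes.gff3"))
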