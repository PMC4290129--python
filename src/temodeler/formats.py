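"""Readers and writers for the external formats the toolkit touches.

All conversion between external 1-based inclusive coordinates and the
internal 0-based half-open genome convention happens here and nowhere
else.  Reference/consensus coordinates stay 1-based inclusive on both
sides of the boundary (see :mod:`temodeler.model`).
"""

from __future__ import annotations

import io
import os
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .model import (
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

PathLike = Union[str, os.PathLike]
SequenceSource = Union[PathLike, Mapping[str, str]]


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def to_external(start: int, end: int) -> Tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def to_internal(start1: int, end1: int) -> Tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# RepeatMasker .out dialect
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW   perc perc perc  query       position in query    "
    "         matching          repeat         position in repeat\n"
    "score   div. del. ins.  sequence    begin  end    (left) "
    "  repeat            class/family  begin  end   (left)  ID\n"
    "\n"
)


def _num(token: str, line_no: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"line {line_no}: non-numeric {what} {token!r}"
        ) from None


def read_repeatmasker_out(path: PathLike) -> List[RawHit]:
    """Parse a RepeatMasker ``.out`` table into :class:`RawHit` records.

    The dialect has 3 header lines and whitespace-separated columns
    (score, div, del, ins, query, qbegin, qend, (qleft), strand, repeat,
    class/family, and three consensus-position columns of which the
    parenthesised one is the remaining length).  Strand ``C`` means minus;
    consensus coordinates are normalised so ``te_start <= te_end``.
    """
    hits: List[RawHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            # skip header lines (first token of a data line is the score)
            try:
                float(fields[0])
            except ValueError:
                continue
            if len(fields) < 14:
                raise ParseError(
                    f"line {line_no}: expected >= 14 columns, got {len(fields)}"
                )
            score = _num(fields[0], line_no, "score")
            div = _num(fields[1], line_no, "divergence")
            seqid = fields[4]
            qbegin = int(_num(fields[5], line_no, "query begin"))
            qend = int(_num(fields[6], line_no, "query end"))
            strand = "-" if fields[8] in ("C", "-") else "+"
            te_id = fields[9]
            cons = fields[11:14]
            cons_pos: List[int] = []
            for tok in cons:
                if tok.startswith("("):
                    continue  # remaining length, position varies with strand
                cons_pos.append(int(_num(tok, line_no, "consensus coordinate")))
            if len(cons_pos) != 2:
                raise ParseError(
                    f"line {line_no}: expected 2 plain consensus coordinates "
                    f"in {cons!r}"
                )
            te_start, te_end = sorted(cons_pos)
            hit_id = fields[14] if len(fields) > 14 else f"hit{len(hits) + 1}"
            start, end = to_internal(qbegin, qend)
            hits.append(
                RawHit(
                    query=GenomicInterval(seqid, start, end, strand),
                    te_id=te_id,
                    te_start=te_start,
                    te_end=te_end,
                    score=score,
                    divergence_pct=div,
                    hit_id=hit_id,
                )
            )
    return hits


def write_repeatmasker_out(hits: Sequence[RawHit], path: PathLike) -> None:
    """Write hits in the RepeatMasker ``.out`` dialect read by
    :func:`read_repeatmasker_out` (round-trips; remaining-length columns
    are written as ``(0)`` placeholders)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for h in hits:
            qb, qe = to_external(h.query.start, h.query.end)
            if h.query.strand == "+":
                strand = "+"
                cons = f"{h.te_start} {h.te_end} (0)"
            else:
                strand = "C"
                cons = f"(0) {h.te_start} {h.te_end}"
            fh.write(
                f"{h.score!s} {h.divergence_pct!s} 0.0 0.0 "
                f"{h.query.seqid} {qb} {qe} (0) {strand} "
                f"{h.te_id} Unknown {cons} {h.hit_id}\n"
            )


# ---------------------------------------------------------------------------
# TE library: FASTA + sidecar metadata TSV
# ---------------------------------------------------------------------------

_META_COLS = [
    "id",
    "family_id",
    "superfamily",
    "is_complete",
    "ltr5_start",
    "ltr5_end",
    "ltr3_start",
    "ltr3_end",
]

_TRUE_STRINGS = {"1", "true", "yes", "y", "t"}


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a FASTA file into an id -> sequence dict (Biopython)."""
    from Bio import SeqIO

    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(sequences: Mapping[str, str], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _opt_interval(row: pd.Series, pre: str) -> Optional[Tuple[int, int]]:
    s, e = row[f"{pre}_start"], row[f"{pre}_end"]
    if pd.isna(s) or pd.isna(e) or str(s).strip() == "" or str(e).strip() == "":
        return None
    return int(s), int(e)


def load_te_library(fasta_path: PathLike, metadata_path: PathLike) -> TELibrary:
    """Load a classified TE library from FASTA + tab-separated metadata.

    The metadata table must carry the columns ``id, family_id, superfamily,
    is_complete, ltr5_start, ltr5_end, ltr3_start, ltr3_end`` (LTR columns
    may be empty)."""
    sequences = read_fasta(fasta_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing = set(_META_COLS) - set(meta.columns)
    if missing:
        raise ParseError(f"metadata missing columns: {sorted(missing)}")
    elements: Dict[str, TEReference] = {}
    for _, row in meta.iterrows():
        eid = row["id"]
        if eid in elements:
            raise ParseError(f"duplicate library id {eid!r}")
        if eid not in sequences:
            raise ParseError(f"id {eid!r} present in metadata but not in FASTA")
        elements[eid] = TEReference(
            id=eid,
            family_id=row["family_id"],
            superfamily=row["superfamily"],
            length=len(sequences[eid]),
            is_complete=str(row["is_complete"]).strip().lower() in _TRUE_STRINGS,
            ltr5=_opt_interval(row, "ltr5"),
            ltr3=_opt_interval(row, "ltr3"),
        )
    return TELibrary(elements, {k: sequences[k] for k in elements})


def write_te_library(
    library: TELibrary, fasta_path: PathLike, metadata_path: PathLike
) -> None:
    write_fasta(library.sequences, fasta_path)
    rows = []
    for el in library.elements.values():
        rows.append(
            {
                "id": el.id,
                "family_id": el.family_id,
                "superfamily": el.superfamily,
                "is_complete": int(el.is_complete),
                "ltr5_start": el.ltr5[0] if el.ltr5 else "",
                "ltr5_end": el.ltr5[1] if el.ltr5 else "",
                "ltr3_start": el.ltr3[0] if el.ltr3 else "",
                "ltr3_end": el.ltr3[1] if el.ltr3 else "",
            }
        )
    pd.DataFrame(rows, columns=_META_COLS).to_csv(
        metadata_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# annotation GFF3 (discontinuous features, Parent-encoded nesting)
# ---------------------------------------------------------------------------

def _fmt_attrs(attrs: Mapping[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v != "")


def _parse_attrs(col: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def write_annotations_gff3(annotation_set: AnnotationSet, path: PathLike) -> None:
    """Write an :class:`AnnotationSet` as GFF3 ``repeat_region`` features.

    A multi-part feature is emitted as several lines sharing one ID (the
    GFF3 discontinuous-feature convention); nesting is encoded with a
    ``Parent`` attribute on the nested element."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    feats = sorted(
        annotation_set,
        key=lambda f: (f.seqid, f.span_start, f.span_end, f.feature_id),
    )
    for f in feats:
        f.check_parts()  # unsorted/overlapping parts -> error on write
        for p in f.parts:
            start1, end1 = to_external(p.qstart, p.qend)
            attrs = {
                "ID": f.feature_id,
                "family": f.family_id,
                "superfamily": f.superfamily,
                "status": f.status,
                "te_start": str(p.te_start),
                "te_end": str(p.te_end),
            }
            if f.te_id:
                attrs["te_id"] = f.te_id
            if f.parent:
                attrs["Parent"] = f.parent
            buf.write(
                "\t".join(
                    [
                        f.seqid,
                        "temodeler",
                        "repeat_region",
                        str(start1),
                        str(end1),
                        f"{f.score:g}",
                        f.strand,
                        ".",
                        _fmt_attrs(attrs),
                    ]
                )
                + "\n"
            )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_annotations_gff3(path: PathLike) -> AnnotationSet:
    """Inverse of :func:`write_annotations_gff3` (round-trips)."""
    pending: Dict[str, TEFeature] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ParseError(f"line {line_no}: expected 9 columns")
            seqid, _, ftype, start1, end1, score, strand, _, attr_col = cols
            if ftype != "repeat_region":
                continue
            attrs = _parse_attrs(attr_col)
            fid = attrs.get("ID")
            if fid is None:
                raise ParseError(f"line {line_no}: repeat_region without ID")
            start, end = to_internal(int(start1), int(end1))
            part = Part(
                qstart=start,
                qend=end,
                te_start=int(attrs.get("te_start", 1)),
                te_end=int(attrs.get("te_end", max(1, end - start))),
            )
            if fid in pending:
                pending[fid].parts.append(part)
            else:
                pending[fid] = TEFeature(
                    feature_id=fid,
                    seqid=seqid,
                    strand=strand,
                    family_id=attrs.get("family", ""),
                    parts=[part],
                    superfamily=attrs.get("superfamily", ""),
                    te_id=attrs.get("te_id"),
                    status=attrs.get("status", "fragmented"),
                    parent=attrs.get("Parent"),
                    score=float(score) if score != "." else 0.0,
                )
    out = AnnotationSet()
    for f in pending.values():
        f.parts.sort(key=lambda p: p.qstart)
        f.check_parts()
        out.add(f)
    for f in out:
        if f.parent is not None:
            if f.parent not in out:
                raise ParseError(f"{f.feature_id}: unknown Parent {f.parent!r}")
            out[f.parent].children.append(f.feature_id)
    out.normalize()
    return out


# ---------------------------------------------------------------------------
# gene GFF3
# ---------------------------------------------------------------------------

def read_genes_gff3(path: PathLike) -> List[Gene]:
    """Read ``gene`` features (ID + strand) from a GFF3 file."""
    genes: List[Gene] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ParseError(f"line {line_no}: expected 9 columns")
            if cols[2] != "gene":
                continue
            attrs = _parse_attrs(cols[8])
            start, end = to_internal(int(cols[3]), int(cols[4]))
            strand = cols[6] if cols[6] in ("+", "-") else "+"
            genes.append(
                Gene(
                    gene_id=attrs.get("ID", f"gene{len(genes) + 1}"),
                    interval=GenomicInterval(cols[0], start, end, strand),
                )
            )
    return genes


def write_genes_gff3(genes: Sequence[Gene], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start1, end1 = to_external(g.interval.start, g.interval.end)
            fh.write(
                f"{g.interval.seqid}\ttemodeler\tgene\t{start1}\t{end1}\t."
                f"\t{g.interval.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# sequence access
# ---------------------------------------------------------------------------

def get_sequence(source: SequenceSource, seqid: str) -> str:
    """Full sequence for ``seqid`` from a FASTA path or an in-memory dict."""
    if isinstance(source, Mapping):
        if seqid not in source:
            raise LookupError(f"unknown seqid {seqid!r}")
        return source[seqid]
    from pyfaidx import Fasta

    fa = Fasta(str(source))
    if seqid not in fa:
        raise LookupError(f"unknown seqid {seqid!r}")
    return str(fa[seqid][:]).upper()


def sequence_length(source: SequenceSource, seqid: str) -> int:
    if isinstance(source, Mapping):
        if seqid not in source:
            raise LookupError(f"unknown seqid {seqid!r}")
        return len(source[seqid])
    from pyfaidx import Fasta

    fa = Fasta(str(source))
    if seqid not in fa:
        raise LookupError(f"unknown seqid {seqid!r}")
    return len(fa[seqid])


def fetch_sequence(source: SequenceSource, interval: GenomicInterval) -> str:
    """Sequence of ``interval``; minus strand returns the reverse complement.

    ``source`` may be a FASTA path (indexed via pyfaidx) or an in-memory
    ``{seqid: sequence}`` mapping.  Out-of-bounds intervals are errors."""
    if isinstance(source, Mapping):
        if interval.seqid not in source:
            raise LookupError(f"unknown seqid {interval.seqid!r}")
        seq = source[interval.seqid]
        if interval.end > len(seq):
            raise ValueError(
                f"interval [{interval.start},{interval.end}) beyond "
                f"{interval.seqid} length {len(seq)}"
            )
        sub = seq[interval.start : interval.end]
    else:
        from pyfaidx import Fasta

        fa = Fasta(str(source))
        if interval.seqid not in fa:
            raise LookupError(f"unknown seqid {interval.seqid!r}")
        if interval.end > len(fa[interval.seqid]):
            raise ValueError(
                f"interval [{interval.start},{interval.end}) beyond "
                f"{interval.seqid} length {len(fa[interval.seqid])}"
            )
        sub = str(fa[interval.seqid][interval.start : interval.end]).upper()
    return revcomp(sub) if interval.strand == "-" else sub
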