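"""Scoring a predicted annotation against a reference annotation.

Sensitivity (Sn = TP/(TP+FN)) and specificity (Sp = TP/(TP+FP)) are
computed at three levels:

* **nucleotide** -- every base covered by both sets is a TP, bases
  covered only by the prediction are FP, only by the reference FN;
* **feature** -- every contiguous part (segments of TEs split by nested
  insertions count individually) is matched to at most one predicted
  part whose both borders lie within a tolerance (default 10 bp),
  greedily by smallest total border distance;
* **nested feature** -- the same border rule applied to the outer borders
  of multi-part (nested-host) features only, additionally requiring an
  identical number of reconstructed children.

Sn is undefined (``None``, printed NA) when the reference level is
empty, Sp when the prediction level is empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .model import AnnotationSet, TEFeature

LEVELS = ("nucleotide", "feature", "nested_feature")


@dataclass
class LevelScores:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None


@dataclass
class EvalReport:
    levels: Dict[str, LevelScores]
    n_predictions: int
    coverage_fraction: Optional[float] = None

    def __getitem__(self, level: str) -> LevelScores:
        return self.levels[level]

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_predictions", self.n_predictions)]
        rows.append(
            (
                "coverage",
                "NA" if self.coverage_fraction is None else f"{self.coverage_fraction:.4f}",
            )
        )
        for level in LEVELS:
            s = self.levels[level]
            for name, v in (("Sn", s.sensitivity), ("Sp", s.specificity)):
                rows.append(
                    (f"{name}_{level}", "NA" if v is None else f"{v:.4f}")
                )
        return pd.DataFrame(rows, columns=["metric", "value"])


def _merged_intervals(aset: AnnotationSet, seqid: str) -> List[Tuple[int, int]]:
    ivs = sorted((p.qstart, p.qend) for f in aset if f.seqid == seqid for p in f.parts)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _intersection_bp(a: List[Tuple[int, int]], b: List[Tuple[int, int]]) -> int:
    i = j = total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _greedy_border_match(
    pred_items: Sequence[Tuple],
    ref_items: Sequence[Tuple],
    tol: int,
) -> int:
    """Greedy one-to-one matching of (start, end, group) items whose both
    borders agree within ``tol``; ``group`` must be equal (used for seqid
    bundling and child-count constraints).  Returns the match count."""
    cands: List[Tuple[int, int, int]] = []
    for ri, (rs, re, rg) in enumerate(ref_items):
        for pi, (ps, pe, pg) in enumerate(pred_items):
            if rg == pg and abs(ps - rs) <= tol and abs(pe - re) <= tol:
                cands.append((abs(ps - rs) + abs(pe - re), ri, pi))
    cands.sort()
    used_r: set = set()
    used_p: set = set()
    tp = 0
    for _, ri, pi in cands:
        if ri in used_r or pi in used_p:
            continue
        used_r.add(ri)
        used_p.add(pi)
        tp += 1
    return tp


def _feature_items(
    aset: AnnotationSet, strict_family: bool
) -> List[Tuple]:
    items = []
    for f in aset:
        for p in f.parts:
            g = (f.seqid, f.family_id) if strict_family else (f.seqid,)
            items.append((p.qstart, p.qend, g))
    return items


def _nested_items(
    aset: AnnotationSet, strict_family: bool
) -> List[Tuple]:
    """Multi-part (nested-host) features as (span_start, span_end, group)
    where the group also encodes the child count."""
    items = []
    for f in aset:
        if f.n_parts < 2:
            continue
        key: Tuple = (f.seqid, len(f.children))
        if strict_family:
            key = key + (f.family_id,)
        items.append((f.span_start, f.span_end, key))
    return items


def compare_annotations(
    predicted: AnnotationSet,
    reference: AnnotationSet,
    border_tol: int = 10,
    strict_family: bool = False,
    seq_lengths: Optional[Mapping[str, int]] = None,
) -> EvalReport:
    """Score ``predicted`` against ``reference`` at all three levels.

    ``strict_family`` additionally requires family identity for feature
    and nested-feature matches (coordinates only by default).  With
    ``seq_lengths`` the prediction's coverage fraction of the sequence
    universe is reported."""
    if border_tol < 0:
        raise ValueError("border_tol must be >= 0")
    seqids = sorted(set(predicted.seqids()) | set(reference.seqids()))

    # nucleotide level
    tp = pred_bp = ref_bp = 0
    for s in seqids:
        pm = _merged_intervals(predicted, s)
        rm = _merged_intervals(reference, s)
        tp += _intersection_bp(pm, rm)
        pred_bp += sum(e - b for b, e in pm)
        ref_bp += sum(e - b for b, e in rm)
    nuc = LevelScores(tp=tp, fp=pred_bp - tp, fn=ref_bp - tp)

    # feature level
    p_items = _feature_items(predicted, strict_family)
    r_items = _feature_items(reference, strict_family)
    ftp = _greedy_border_match(p_items, r_items, border_tol)
    feat = LevelScores(tp=ftp, fp=len(p_items) - ftp, fn=len(r_items) - ftp)

    # nested-feature level: groups must agree on child count, but FP/FN
    # counts span all multi-part features regardless of grouping
    pn_items = _nested_items(predicted, strict_family)
    rn_items = _nested_items(reference, strict_family)
    ntp = _greedy_border_match(pn_items, rn_items, border_tol)
    nested = LevelScores(tp=ntp, fp=len(pn_items) - ntp, fn=len(rn_items) - ntp)

    coverage: Optional[float] = None
    if seq_lengths is not None:
        total = sum(seq_lengths.values())
        if total > 0:
            coverage = pred_bp / total
    return EvalReport(
        levels={"nucleotide": nuc, "feature": feat, "nested_feature": nested},
        n_predictions=len(predicted),
        coverage_fraction=coverage,
    )
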