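"""Curation pipeline: overlap resolution, merging, nested reconstruction,
completeness calling."""

import pytest

from temodeler import (
    COMPLETE,
    FRAGMENTED,
    AnnotationSet,
    CurateConfig,
    GenomicInterval,
    Part,
    RawHit,
    TEFeature,
    classify_completeness,
    compare_annotations,
    curate,
    merge_collinear,
    reconstruct_nested,
    resolve_overlaps,
    simulate_raw_hits,
)


def _hit(start, end, te_start, te_end, te_id="RLG_famc1_cons", strand="+",
         score=None, seqid="chr1", hid=""):
    return RawHit(
        query=GenomicInterval(seqid, start, end, strand),
        te_id=te_id,
        te_start=te_start,
        te_end=te_end,
        score=score if score is not None else 2.0 * (end - start),
        hit_id=hid or f"h{start}",
    )


def _annotation_to_hits(aset):
    hits = []
    for f in sorted(aset, key=lambda f: (f.seqid, f.span_start)):
        for p in f.parts:
            hits.append(
                _hit(p.qstart, p.qend, p.te_start, p.te_end,
                     te_id=f.te_id, strand=f.strand, seqid=f.seqid)
            )
    hits.sort(key=lambda h: (h.query.seqid, h.query.start, h.query.end))
    return hits


class TestResolveOverlaps:
    def test_extremity_hit_kept_intact(self, toy_library):
        a = _hit(100, 500, 1, 400)          # covers the 5' extremity
        b = _hit(450, 900, 1000, 1450)      # mid-element
        out = resolve_overlaps([a, b], toy_library)
        assert out[0] == a
        assert (out[1].query.start, out[1].query.end) == (500, 900)
        assert out[1].te_start == 1050  # trimmed proportionally

    def test_disjoint_hits_unchanged(self, toy_library):
        a = _hit(0, 400, 1, 400)
        b = _hit(500, 900, 500, 900)
        assert resolve_overlaps([a, b], toy_library) == [a, b]

    def test_both_extremities_longer_wins(self, toy_library):
        a = _hit(100, 500, 1, 400)          # 400 bp, 5' extremity
        b = _hit(450, 900, 7850, 8300)      # 450 bp, 3' extremity
        out = resolve_overlaps([a, b], toy_library)
        assert out[1] == b
        assert (out[0].query.start, out[0].query.end) == (100, 450)
        assert out[0].te_end == 350

    def test_unsorted_input_is_error(self, toy_library):
        with pytest.raises(ValueError, match="sorted"):
            resolve_overlaps(
                [_hit(500, 900, 500, 900), _hit(0, 400, 1, 400)], toy_library
            )

    def test_sub_minimum_remainder_dropped(self, toy_library):
        a = _hit(0, 500, 1, 500)
        b = _hit(485, 515, 2000, 2030)      # 30 bp, trimmed to 15 < 20
        out = resolve_overlaps([a, b], toy_library)
        assert out == [a]

    def test_output_pairwise_disjoint(self, toy_library):
        hits = [
            _hit(0, 600, 1, 600),
            _hit(100, 400, 2000, 2300),
            _hit(550, 1200, 3000, 3650),
            _hit(1100, 1300, 7000, 7200),
        ]
        out = resolve_overlaps(hits, toy_library)
        for x, y in zip(out, out[1:]):
            assert x.query.end <= y.query.start


class TestMergeCollinear:
    def test_collinear_same_family_merged(self, toy_library):
        a = _hit(0, 500, 1, 500)
        b = _hit(530, 1050, 480, 1000)  # 30 bp gap, 20 bp consensus overlap
        (feat,) = merge_collinear([a, b], toy_library)
        assert feat.n_parts == 2
        assert (feat.parts[0].te_start, feat.parts[-1].te_end) == (1, 1000)

    def test_different_families_not_merged(self, toy_library):
        a = _hit(0, 500, 1, 500)
        b = _hit(530, 1050, 480, 1000, te_id="DTC_famc1_cons")
        assert len(merge_collinear([a, b], toy_library)) == 2

    def test_ltr_match_reassigned_to_three_prime_copy(self, toy_library):
        # element end reached, then a 5'-LTR-coded match: the LTR copies
        # are interchangeable, so it is re-placed onto the 3' LTR
        a = _hit(0, 3000, 5000, 8000)
        b = _hit(3030, 3330, 1, 300)
        (feat,) = merge_collinear([a, b], toy_library)
        assert feat.n_parts == 2
        assert (feat.parts[1].te_start, feat.parts[1].te_end) == (8001, 8300)

    def test_non_collinear_not_merged(self, toy_library):
        a = _hit(0, 500, 5000, 5500)
        b = _hit(530, 930, 1000, 1400)  # consensus steps backwards
        assert len(merge_collinear([a, b], toy_library)) == 2

    def test_zero_gap_parts_coalesce(self, toy_library):
        a = _hit(0, 500, 1, 500)
        b = _hit(500, 1000, 501, 1000)
        (feat,) = merge_collinear([a, b], toy_library)
        assert feat.n_parts == 1
        assert (feat.parts[0].te_start, feat.parts[0].te_end) == (1, 1000)

    def test_unknown_reference_is_error(self, toy_library):
        with pytest.raises(LookupError):
            merge_collinear([_hit(0, 500, 1, 500, te_id="nope")], toy_library)


def _feature(fid, parts, family="RLG_famc1", te_id="RLG_famc1_cons",
             strand="+", seqid="chr1"):
    sf = family.split("_")[0]
    return TEFeature(
        feature_id=fid, seqid=seqid, strand=strand, family_id=family,
        superfamily=sf, te_id=te_id, parts=[Part(*p) for p in parts],
    )


class TestReconstructNested:
    def test_split_host_rejoined_around_nested_element(self, toy_library):
        host_a = _feature("F1", [(0, 4000, 1, 4000)])
        inner = _feature("F2", [(4000, 13000, 1, 5000)],
                         family="DTC_famc1", te_id="DTC_famc1_cons")
        host_b = _feature("F3", [(13000, 17300, 4001, 8300)])
        aset = reconstruct_nested([host_a, inner, host_b], toy_library)
        assert len(aset) == 2
        joined = aset["F1"]
        assert joined.n_parts == 2
        assert joined.children == ["F2"]
        assert aset["F2"].parent == "F1"
        assert aset.nesting_depth("F2") == 2

    def test_more_than_max_intervening_not_joined(self, toy_library):
        feats = [_feature("A", [(0, 4000, 1, 4000)])]
        for i in range(11):
            s = 4100 + i * 120
            feats.append(
                _feature(f"I{i}", [(s, s + 100, 1, 100)],
                         family="DTC_famc1", te_id="DTC_famc1_cons")
            )
        feats.append(_feature("B", [(6000, 10300, 4001, 8300)]))
        aset = reconstruct_nested(feats, toy_library)
        assert aset["A"].n_parts == 1 and "B" in aset

    def test_reversed_consensus_order_not_joined(self, toy_library):
        f1 = _feature("A", [(0, 3300, 5000, 8300)])
        mid = _feature("I", [(4000, 9000, 1, 5000)],
                       family="DTC_famc1", te_id="DTC_famc1_cons")
        f2 = _feature("B", [(13000, 13400, 1, 400)])
        aset = reconstruct_nested([f1, mid, f2], toy_library)
        assert aset["A"].n_parts == 1 and aset["B"].n_parts == 1

    def test_empty_gap_not_joined(self, toy_library):
        # no intervening predicted TE: bridging plain gaps is the merge
        # stage's job, bounded by max_gap
        f1 = _feature("A", [(0, 4000, 1, 4000)])
        f2 = _feature("B", [(9000, 13300, 4001, 8300)])
        aset = reconstruct_nested([f1, f2], toy_library)
        assert aset["A"].n_parts == 1 and aset["B"].n_parts == 1


class TestClassifyCompleteness:
    def test_full_coverage_both_extremities(self, toy_library):
        f = _feature("F", [(0, 4980, 10, 4990)],
                     family="DTC_famc1", te_id="DTC_famc1_cons")
        assert classify_completeness(f, toy_library) == COMPLETE

    def test_low_coverage_fragmented(self, toy_library):
        f = _feature("F", [(0, 4251, 40, 4290)],
                     family="DTC_famc1", te_id="DTC_famc1_cons")
        assert classify_completeness(f, toy_library) == FRAGMENTED

    def test_missing_extremity_fragmented(self, toy_library):
        f = _feature("F", [(0, 4751, 200, 4950)],
                     family="DTC_famc1", te_id="DTC_famc1_cons")
        assert classify_completeness(f, toy_library) == FRAGMENTED

    def test_incomplete_reference_forces_fragmented(self, toy_library):
        from temodeler import TELibrary, TEReference

        ref = TEReference(id="x", family_id="f", superfamily="DTX",
                          length=1000, is_complete=False)
        lib = TELibrary({"x": ref})
        f = _feature("F", [(0, 1000, 1, 1000)], family="f", te_id="x")
        assert classify_completeness(f, lib) == FRAGMENTED


class TestCuratePipeline:
    def test_empty_hit_set(self, toy_library):
        assert len(curate([], toy_library)) == 0

    def test_noise_free_round_trip(self, sim_bundle):
        _, lib, truth = sim_bundle(seed=2)
        result = curate(simulate_raw_hits(truth), lib)
        report = compare_annotations(result, truth.annotations)
        for level in ("nucleotide", "feature", "nested_feature"):
            assert report[level].sensitivity == 1.0
            assert report[level].specificity == 1.0
        # completeness status also matches: every truth element is intact
        assert all(f.status == COMPLETE for f in result)

    def test_idempotence(self, sim_bundle):
        _, lib, truth = sim_bundle(seed=4, frag_prob=0.5, jitter_sd=3.0)
        first = curate(simulate_raw_hits(truth), lib)
        second = curate(_annotation_to_hits(first), lib)
        report = compare_annotations(second, first)
        for level in ("nucleotide", "feature", "nested_feature"):
            assert report[level].sensitivity == 1.0
            assert report[level].specificity == 1.0

    def test_annotated_bp_never_exceeds_hit_bp(self, sim_bundle):
        _, lib, truth = sim_bundle(seed=5, frag_prob=0.8, jitter_sd=5.0,
                                   false_hit_rate=0.1)
        hits = simulate_raw_hits(truth)
        result = curate(hits, lib)
        hit_bp = sum(h.query.length for h in hits)
        annotated_bp = sum(f.aligned_bp for f in result)
        assert annotated_bp <= hit_bp

    def test_output_parts_disjoint(self, sim_bundle):
        _, lib, truth = sim_bundle(seed=6, frag_prob=0.8, jitter_sd=5.0,
                                   false_hit_rate=0.2)
        curate(simulate_raw_hits(truth), lib).validate()

    def test_max_intervening_monotonicity(self, sim_bundle):
        _, lib, truth = sim_bundle(seed=7, nesting_prob=0.5)
        hits = simulate_raw_hits(truth)
        joined_counts = []
        for mi in (10, 5, 2, 1, 0):
            result = curate(hits, lib, CurateConfig(max_intervening=mi))
            joined_counts.append(sum(1 for f in result if f.n_parts > 1))
        assert joined_counts == sorted(joined_counts, reverse=True)
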