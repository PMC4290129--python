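"""Window profiles, segmentation, family clustering, gene context."""

import itertools

import numpy as np
import pytest

from temodeler import (
    AnnotationSet,
    Gene,
    GenomicInterval,
    Part,
    TEFeature,
    cluster_family_profiles,
    gene_context_profile,
    n99_diversity,
    nearest_gene_distance,
    segment_profile,
    window_profile,
    zscore_profile,
)


def _single(fid, start, end, family="famA", seqid="c", status="fragmented"):
    return TEFeature(
        feature_id=fid, seqid=seqid, strand="+", family_id=family,
        parts=[Part(start, end, 1, end - start)], status=status,
    )


def _aset(features):
    out = AnnotationSet()
    for f in features:
        out.add(f)
    return out


class TestWindowProfile:
    def test_full_window_fraction_one(self):
        aset = _aset([_single("f", 0, 10_000)])
        prof = window_profile(aset, "c", 30_000, window_size=10_000, step=10_000)
        assert prof.values[0] == 1.0

    def test_partial_window_fraction(self):
        aset = _aset([_single("a", 0, 4_000), _single("b", 5_000, 7_000)])
        prof = window_profile(aset, "c", 30_000, window_size=10_000, step=10_000)
        assert prof.values[0] == pytest.approx(0.6)

    def test_empty_annotation_all_zero(self):
        prof = window_profile(AnnotationSet(), "c", 30_000, 10_000, 1_000)
        assert np.all(prof.values == 0)

    def test_non_positive_step_is_error(self):
        with pytest.raises(ValueError):
            window_profile(AnnotationSet(), "c", 30_000, 10_000, 0)

    def test_count_measure_uses_midpoints(self):
        aset = _aset([_single("a", 9_500, 10_500), _single("b", 10_600, 11_000)])
        prof = window_profile(aset, "c", 30_000, 10_000, 10_000, measure="count")
        # midpoints 10000 and 10800 both fall in the second window
        assert list(prof.values) == [0, 2, 0]

    def test_bp_conservation_non_overlapping_windows(self, sim_bundle):
        _, _, truth = sim_bundle(seed=8, n_insertions=30, background_len=50_000)
        n = len(truth.genome["chr1"])
        w = 10_000
        usable = (n // w) * w
        prof = window_profile(truth.annotations, "chr1", usable, w, w)
        covered = sum(
            min(p.qend, usable) - p.qstart
            for f in truth.annotations
            for p in f.parts
            if p.qstart < usable
        )
        assert int(round(prof.values.sum() * w)) == covered


class TestZScores:
    def test_hand_arithmetic(self):
        prof = window_profile(AnnotationSet(), "c", 30_000, 10_000, 10_000)
        prof.values = np.array([1.0, 2.0, 3.0])
        z = zscore_profile(prof)
        assert z.values == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_constant_profile_is_error(self):
        prof = window_profile(AnnotationSet(), "c", 30_000, 10_000, 10_000)
        with pytest.raises(ValueError, match="variance"):
            zscore_profile(prof)

    def test_idempotence(self):
        prof = window_profile(AnnotationSet(), "c", 60_000, 10_000, 10_000)
        prof.values = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 2.0])
        z1 = zscore_profile(prof)
        z2 = zscore_profile(z1)
        assert z2.values == pytest.approx(z1.values)


class TestN99:
    def test_majority_families(self):
        aset = _aset(
            [
                _single("a", 0, 9_000, family="f1"),
                _single("b", 9_000, 9_900, family="f2"),
                _single("c", 9_900, 10_000, family="f3"),
            ]
        )
        assert n99_diversity(aset, GenomicInterval("c", 0, 10_000)) == 2

    def test_single_family(self):
        aset = _aset([_single("a", 0, 5_000)])
        assert n99_diversity(aset, GenomicInterval("c", 0, 10_000)) == 1

    def test_hundred_equal_families(self):
        aset = _aset(
            [_single(f"e{i}", i * 10, i * 10 + 10, family=f"f{i}") for i in range(100)]
        )
        assert n99_diversity(aset, GenomicInterval("c", 0, 10_000)) == 99

    def test_empty_window_is_zero(self):
        assert n99_diversity(AnnotationSet(), GenomicInterval("c", 0, 1_000)) == 0


def segmentation_oracle(values, k):
    """Brute-force enumeration of all breakpoint placements."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    best = None
    for bps in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *bps, n]
        cost = sum(
            ((values[i:j] - values[i:j].mean()) ** 2).sum()
            for i, j in zip(bounds[:-1], bounds[1:])
        )
        if best is None or cost < best[0] - 1e-12:
            best = (cost, list(bps))
    return best


class TestSegmentation:
    def test_noiseless_plateaus_recovered_exactly(self):
        values = [1.0] * 8 + [5.0] * 8 + [2.0] * 8 + [7.0] * 8 + [3.0] * 8
        seg = segment_profile(values, 5)
        assert seg.breakpoints == [8, 16, 24, 32]
        assert seg.segment_means == [1.0, 5.0, 2.0, 7.0, 3.0]

    def test_k1_global_mean(self):
        seg = segment_profile([1.0, 2.0, 6.0], 1)
        assert seg.breakpoints == []
        assert seg.segment_means == [pytest.approx(3.0)]

    def test_constant_profile_smallest_breakpoint(self):
        seg = segment_profile([2.0] * 6, 2)
        assert seg.breakpoints == [1]

    def test_k_exceeding_windows_is_error(self):
        with pytest.raises(ValueError):
            segment_profile([1.0, 2.0], 3)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n = int(rng.integers(5, 20))
            values = rng.uniform(0, 10, n)
            for k in range(1, min(5, n) + 1):
                seg = segment_profile(values, k)
                cost_oracle, _ = segmentation_oracle(values, k)
                bounds = [0, *seg.breakpoints, n]
                cost = sum(
                    ((values[i:j] - values[i:j].mean()) ** 2).sum()
                    for i, j in zip(bounds[:-1], bounds[1:])
                )
                assert cost == pytest.approx(cost_oracle, abs=1e-9)


class TestFamilyClustering:
    def test_identical_profiles_merge_first(self):
        base = [1.0, 2.0, 3.0, 4.0, 2.0]
        profiles = {
            "a": base,
            "b": base,
            "c": [4.0, 1.0, 0.5, 9.0, 2.0],
        }
        result = cluster_family_profiles(profiles, n_boot=0)
        first = {result.labels[int(result.linkage[0, 0])],
                 result.labels[int(result.linkage[0, 1])]}
        assert first == {"a", "b"}
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_groups_split_at_top(self):
        up = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        rng = np.random.default_rng(18)
        profiles = {}
        for i in range(3):
            profiles[f"u{i}"] = up + rng.normal(0, 0.01, 6)
            profiles[f"d{i}"] = -up + rng.normal(0, 0.01, 6)
        result = cluster_family_profiles(profiles, min_abundance=-10, n_boot=50, seed=1)
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(result.linkage, 2, criterion="maxclust")
        groups = {}
        for lbl, cl in zip(result.labels, two):
            groups.setdefault(cl, set()).add(lbl[0])
        assert sorted(map(sorted, groups.values())) == [["d"], ["u"]]
        assert result.newick.count("(") == 5  # binary tree over 6 leaves

    def test_abundance_filter_drops_family(self):
        profiles = {
            "rich1": [0.1, 0.2, 0.1, 0.3],
            "rich2": [0.3, 0.1, 0.2, 0.1],
            "sparse": [0.00005, 0.00004, 0.00005, 0.00003],
        }
        result = cluster_family_profiles(profiles, min_abundance=0.0001, n_boot=0)
        assert result.labels == ["rich1", "rich2"]

    def test_fewer_than_two_retained_is_error(self):
        with pytest.raises(ValueError):
            cluster_family_profiles({"only": [0.5, 0.6]}, n_boot=0)


class TestGeneContext:
    def test_upstream_te_occupancy(self):
        flank = 6_000
        aset = _aset([_single("te", 5_000, 10_000)])
        gene = Gene("g1", GenomicInterval("c", 10_000, 12_000, "+"))
        prof = gene_context_profile(aset, [gene], {"c": 40_000}, flank=flank)
        # TE covers exactly upstream positions -5000..-1
        assert np.all(prof[flank - 5_000 : flank] == 1.0)
        assert np.all(prof[: flank - 5_000] == 0.0)
        assert np.all(prof[flank:] == 0.0)

    def test_minus_strand_gene_flipped(self):
        flank = 6_000
        plus = gene_context_profile(
            _aset([_single("te", 5_000, 10_000)]),
            [Gene("g", GenomicInterval("c", 10_000, 12_000, "+"))],
            {"c": 40_000}, flank=flank,
        )
        minus = gene_context_profile(
            _aset([_single("te", 22_000, 27_000)]),
            [Gene("g", GenomicInterval("c", 20_000, 22_000, "-"))],
            {"c": 40_000}, flank=flank,
        )
        assert np.array_equal(plus, minus)

    def test_no_tes_all_zero(self):
        prof = gene_context_profile(
            AnnotationSet(),
            [Gene("g", GenomicInterval("c", 10_000, 12_000, "+"))],
            {"c": 40_000}, flank=1_000,
        )
        assert np.all(prof == 0.0)


class TestNearestGeneDistance:
    def test_gap_in_kb(self):
        aset = _aset([_single("te", 10_000, 12_000)])
        genes = [Gene("g", GenomicInterval("c", 15_000, 16_000, "+"))]
        df = nearest_gene_distance(aset, genes)
        assert df["distance_kb"].iloc[0] == pytest.approx(3.0)

    def test_overlap_is_zero(self):
        aset = _aset([_single("te", 10_000, 12_000)])
        genes = [Gene("g", GenomicInterval("c", 11_000, 13_000, "+"))]
        assert nearest_gene_distance(aset, genes)["distance_kb"].iloc[0] == 0.0

    def test_no_genes_is_error(self):
        with pytest.raises(ValueError):
            nearest_gene_distance(_aset([_single("te", 0, 100)]), [])

    def test_copy_number_class(self):
        feats = [_single(f"t{i}", i * 1_000, i * 1_000 + 500, family="famX",
                         status="complete") for i in range(5)]
        genes = [Gene("g", GenomicInterval("c", 50_000, 51_000, "+"))]
        df = nearest_gene_distance(_aset(feats), genes)
        assert set(df["copy_class"]) == {"2-10"}
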