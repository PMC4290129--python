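"""LTR dating, family activity windows, and solo-LTR calling."""

import math

import numpy as np
import pytest

from temodeler import (
    COMPLETE,
    DatedInsertion,
    GenomicInterval,
    RawHit,
    call_solo_ltrs,
    collect_solo_ltr_library,
    date_annotation,
    family_activity_profile,
    ltr_divergence,
    shortest_activity_window,
    simulate_genome,
    simulate_library,
    simulate_ltr_hits,
    simulate_ltr_pair,
)
from temodeler.dynamics import MUTATION_RATE
from temodeler.simulate import SimConfig, random_sequence

RNG = np.random.default_rng(0)


def _pair_with_changes(n, transitions=0, transversions=0):
    """An A-homopolymer pair with exact numbers of substitution types."""
    a = "A" * n
    b = list(a)
    for i in range(transitions):
        b[i] = "G"  # A->G transition
    for i in range(transitions, transitions + transversions):
        b[i] = "C"  # A->C transversion
    return a, "".join(b)


class TestLtrDivergence:
    def test_identical_sequences(self):
        seq = random_sequence(RNG, 300)
        assert ltr_divergence(seq, seq) == 0.0

    def test_raw_proportion(self):
        a, b = _pair_with_changes(1000, transitions=20, transversions=6)
        assert ltr_divergence(a, b, "raw") == pytest.approx(0.026)

    def test_k2p_matches_textbook_formula(self):
        a, b = _pair_with_changes(1000, transitions=20, transversions=6)
        p, q = 20 / 1000, 6 / 1000
        expected = -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)
        assert ltr_divergence(a, b, "K2P") == pytest.approx(expected)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            ltr_divergence("", "ACGT")

    def test_unknown_model_is_error(self):
        with pytest.raises(ValueError):
            ltr_divergence("ACGT", "ACGT", model="JC99")


class TestDating:
    def test_age_formula(self):
        # K = 0.026 at the standard rate is exactly 1.0 MY
        assert 0.026 / (2 * MUTATION_RATE) == pytest.approx(1.0e6)

    def test_age_linear_in_k_and_inverse_in_rate(self):
        a, b = _pair_with_changes(1000, transitions=13)
        k = ltr_divergence(a, b)
        for r in (1e-8, 1.3e-8, 2.6e-8):
            assert k / (2 * r) == pytest.approx(0.013 / (2 * r))

    def test_simulated_annotation_ages_recovered(self, sim_bundle):
        _, lib, truth = sim_bundle(
            seed=9, n_insertions=40, background_len=60_000,
            nesting_prob=0.0, age_range_years=(2.0e6, 2.0e6),
        )
        dated = date_annotation(truth.annotations, truth.genome, lib)
        assert len(dated) >= 10
        mean_age = np.mean([d.age_years for d in dated])
        # 3 binomial standard errors on the pooled estimate
        n_sites = sum(300 for _ in dated)  # LTRs are >= 200 bp; conservative
        p = 2 * MUTATION_RATE * 2.0e6
        se = math.sqrt(p * (1 - p) / n_sites) / (2 * MUTATION_RATE)
        assert abs(mean_age - 2.0e6) < 3 * se + 1e5

    def test_age_zero_gives_identical_ltrs(self, sim_bundle):
        _, lib, truth = sim_bundle(
            seed=10, n_insertions=20, background_len=50_000,
            nesting_prob=0.0, age_range_years=(0.0, 0.0),
        )
        dated = date_annotation(truth.annotations, truth.genome, lib)
        assert dated and all(d.K == 0.0 and d.age_years == 0.0 for d in dated)


def activity_window_oracle(ages, fraction=0.8):
    """Exhaustive search over all order-statistic interval pairs."""
    xs = sorted(ages)
    n = len(xs)
    need = math.floor(fraction * n) + 1
    best = None
    for i in range(n):
        for j in range(i, n):
            count = sum(1 for x in xs if xs[i] <= x <= xs[j])
            if count >= min(need, n):
                span = xs[j] - xs[i]
                if best is None or span < best[0]:
                    best = (span, xs[i], xs[j])
    return best[1], best[2]


class TestFamilyActivity:
    def _dated(self, ages, fam="RLG_famc1"):
        return [
            DatedInsertion(f"F{i}", fam, a * 2 * MUTATION_RATE, a)
            for i, a in enumerate(ages)
        ]

    def test_degenerate_single_date(self):
        prof = family_activity_profile(self._dated([1.0e6] * 25))
        fa = prof["RLG_famc1"]
        assert (fa.activity_start, fa.activity_end) == (1.0e6, 1.0e6)
        assert fa.activity_span == 0.0
        assert fa.burst_date_years == pytest.approx(1.0e6)  # clamped to window

    def test_outliers_force_wide_window(self):
        ages = list(np.linspace(1.0e6, 1.5e6, 8)) + [4.0e6, 5.0e6]
        start, end = shortest_activity_window(ages)
        assert (start, end) == activity_window_oracle(ages)
        assert end == 4.0e6  # 9 of 10 points needed

    def test_below_min_copies_omitted(self):
        assert family_activity_profile(self._dated([1e6] * 19)) == {}

    def test_burst_within_activity_window(self):
        rng = np.random.default_rng(12)
        ages = list(rng.uniform(0.5e6, 3e6, 40))
        fa = family_activity_profile(self._dated(ages))["RLG_famc1"]
        assert fa.activity_start <= fa.burst_date_years <= fa.activity_end

    def test_window_matches_exhaustive_search(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(1, 51))
            ages = list(rng.uniform(0, 4e6, n))
            got = shortest_activity_window(ages)
            exp = activity_window_oracle(ages)
            assert got[1] - got[0] == pytest.approx(exp[1] - exp[0])


class TestSoloLTRs:
    def _genome_with_solos(self, seed=20):
        config = SimConfig(
            seed=seed, n_insertions=40, background_len=120_000,
            nesting_prob=0.2, n_solo_ltrs=10, n_truncated_ltrs=10,
        )
        lib = simulate_library(config)
        truth = simulate_genome(lib, config)
        return lib, truth

    def test_tgca_filter(self, sim_bundle):
        _, lib, truth = sim_bundle(
            seed=21, n_insertions=30, background_len=50_000,
            nesting_prob=0.0, age_range_years=(0.0, 0.0),
        )
        ltrs = collect_solo_ltr_library(truth.annotations, truth.genome, lib)
        # unmutated LTRs all carry canonical TG...CA ends, both strands
        n_rl = sum(
            1 for f in truth.annotations
            if f.superfamily.startswith("RL") and f.status == COMPLETE
        )
        assert len(ltrs) == 2 * n_rl
        assert all(s.startswith("TG") and s.endswith("CA") for s in ltrs.values())

    def test_planted_solos_called_fragments_rejected(self):
        lib, truth = self._genome_with_solos()
        hits, ltr_lib = simulate_ltr_hits(truth, lib)
        calls = call_solo_ltrs(hits, truth.genome, truth.annotations, ltr_lib)
        planted = {(s.interval.start, s.interval.end) for s in truth.solo_ltrs}
        called = {(c.interval.start, c.interval.end) for c in calls}
        assert called == planted
        assert all(c.n_mismatches == 0 for c in calls)

    def test_one_tsd_mismatch_tolerated_two_rejected(self):
        genome = {"c": "T" * 50 + "GATTC" + "TG" + "A" * 196 + "CA" + "GACTC" + "T" * 50}
        ltr = "TG" + "A" * 196 + "CA"
        hit = RawHit(
            query=GenomicInterval("c", 55, 55 + 200), te_id="src",
            te_start=1, te_end=200, score=400.0, hit_id="h1",
        )
        from temodeler import AnnotationSet

        calls = call_solo_ltrs([hit], genome, AnnotationSet(), {"src": ltr})
        assert len(calls) == 1 and calls[0].n_mismatches == 1  # GATTC vs GACTC
        genome2 = {"c": "T" * 50 + "GGGTC" + ltr + "GACTC" + "T" * 50}
        assert call_solo_ltrs([hit], genome2, AnnotationSet(), {"src": ltr}) == []

    def test_low_source_coverage_rejected(self):
        genome = {"c": "T" * 50 + "GATTC" + "TG" + "A" * 96 + "GATTC" + "T" * 50}
        hit = RawHit(
            query=GenomicInterval("c", 55, 55 + 98), te_id="src",
            te_start=1, te_end=98, score=100.0, hit_id="h1",
        )
        from temodeler import AnnotationSet

        ltr = "TG" + "A" * 196 + "CA"  # hit covers only half of it
        assert call_solo_ltrs([hit], genome, AnnotationSet(), {"src": ltr}) == []


class TestSimulatedDivergence:
    def test_expected_divergence_is_2rt(self):
        rng = np.random.default_rng(30)
        age, length, reps = 2.0e6, 400, 100
        ks = []
        for _ in range(reps):
            a, b = simulate_ltr_pair(length, age, MUTATION_RATE, rng)
            ks.append(sum(1 for x, y in zip(a, b) if x != y) / length)
        expected = 2 * MUTATION_RATE * age
        se = math.sqrt(expected * (1 - expected) / (reps * length))
        assert abs(np.mean(ks) - expected) < 4 * se + 1e-4
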