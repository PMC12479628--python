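"""Signature statistics against definitions and brute-force oracles."""
from __future__ import annotations

import math

import numpy as np
import pytest

from srnasig import signatures as sig
from srnasig import simulate
from srnasig.errors import ConfigurationError, DataError
from srnasig.model import AlignedRead, Library

from _oracles import (
    brute_dicer_pair_count,
    brute_overlap_hist,
    brute_phasing_hist,
    random_reads,
)


def _lib(reads, chrom_len=5000):
    chroms = {r.chrom for r in reads}
    return Library("t", sorted(reads), {c: chrom_len for c in chroms})


class TestOverlapHistogram:
    @pytest.mark.parametrize(
        "plus,minus,k",
        [((2000, 2028), (1982, 2010), 10), ((100, 122), (78, 110), 10)],
    )
    def test_definition(self, plus, minus, k):
        reads = [
            AlignedRead("c", *plus, "+"),
            AlignedRead("c", *minus, "-"),
        ]
        hist = sig.overlap_histogram(reads)
        assert hist[k] == 1 and hist.sum() == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        reads = random_reads(rng, 150, with_copies=seed % 3 == 0)
        assert np.array_equal(
            sig.overlap_histogram(reads, 25), brute_overlap_hist(reads, 25)
        )

    def test_invalid_k_max(self):
        with pytest.raises(ConfigurationError):
            sig.overlap_histogram([], k_max=0)


class TestZScores:
    def test_all_background_zero_is_undefined(self):
        hist = np.zeros(26)
        hist[10] = 100
        assert math.isnan(sig.pingpong_zscore(hist))

    def test_uniform_histogram_undefined(self):
        assert math.isnan(sig.pingpong_zscore(np.full(26, 7.0)))

    def test_matches_direct_arithmetic(self, rng):
        hist = np.zeros(26)
        hist[1:] = rng.poisson(5, size=25)
        hist[10] = 50.0
        background = np.delete(hist[1:], 9)
        expected = (50.0 - background.mean()) / background.std(ddof=1)
        assert sig.pingpong_zscore(hist) == pytest.approx(expected)

    def test_phasing_zscore_same_contract(self, rng):
        hist = np.zeros(10)
        hist[1] = 80.0
        hist[2:] = rng.poisson(4, size=8)
        background = hist[2:]
        if background.std(ddof=1) == 0:
            assert math.isnan(sig.phasing_zscore(hist))
        else:
            expected = (80.0 - background.mean()) / background.std(ddof=1)
            assert sig.phasing_zscore(hist) == pytest.approx(expected)

    def test_all_zero_phasing_undefined(self):
        assert math.isnan(sig.phasing_zscore(np.zeros(10)))


class TestDicerPairs:
    def test_canonical_duplex_found(self):
        reads = [
            AlignedRead("c", 1000, 1022, "+"),
            AlignedRead("c", 998, 1020, "-"),
        ]
        assert len(sig.find_dicer_pairs(reads)) == 1

    def test_one_nt_overhang_rejected(self):
        reads = [
            AlignedRead("c", 1000, 1022, "+"),
            AlignedRead("c", 999, 1021, "-"),
        ]
        assert sig.find_dicer_pairs(reads) == []

    def test_simulated_duplexes_recovered_exactly(self, rng):
        seq = bytearray(b"A" * 20_000)
        tuples = simulate.simulate_sirna_locus(seq, 1000, 7, (20, 24), rng)
        reads = [AlignedRead("c", s, e, st) for s, e, st in tuples]
        assert len(sig.find_dicer_pairs(reads)) == 7

    def test_pirna_locus_has_no_pairs(self, rng):
        seq = bytearray(b"A" * 20_000)
        tuples = simulate.simulate_pingpong_locus(seq, 100, 40, (26, 30), 0.9, rng)
        reads = [AlignedRead("c", s, e, st) for s, e, st in tuples]
        assert sig.find_dicer_pairs(reads) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        reads = random_reads(rng, 200, len_range=(19, 26))
        assert len(sig.find_dicer_pairs(reads)) == brute_dicer_pair_count(reads)

    def test_inverted_size_range(self):
        with pytest.raises(ConfigurationError):
            sig.find_dicer_pairs([], size_range=(24, 20))


class TestPercentDicerPairs:
    def test_arithmetic(self):
        reads = [
            AlignedRead("c", 1000, 1022, "+"),
            AlignedRead("c", 998, 1020, "-"),
            AlignedRead("c", 3000, 3022, "+"),
            AlignedRead("c", 2998, 3020, "-"),
        ] + [AlignedRead("c", 100 + 40 * i, 128 + 40 * i, "+") for i in range(6)]
        result = sig.percent_dicer_pairs(_lib(reads))
        assert result["n_pairs"] == 2
        assert result["percent_dicer_pairs"] == pytest.approx(20.0)

    def test_no_opposite_overlaps_zero(self):
        reads = [AlignedRead("c", 100 * i, 100 * i + 22, "+") for i in range(1, 10)]
        assert sig.percent_dicer_pairs(_lib(reads))["percent_dicer_pairs"] == 0.0

    def test_empty_library_rejected(self):
        with pytest.raises(DataError):
            sig.percent_dicer_pairs(Library("e", [], {"c": 1000}))


class TestPhasingHistogram:
    def test_plus_strand_adjacency(self):
        reads = [
            AlignedRead("c", 5000, 5027, "+", "A"),
            AlignedRead("c", 5027, 5055, "+", "U"),
        ]
        hist = sig.phasing_histogram(reads)
        assert hist[1] == 1 and hist.sum() == 1

    def test_minus_strand_symmetry(self):
        reads = [
            AlignedRead("c", 5027, 5055, "-", "A"),  # upstream in minus orientation
            AlignedRead("c", 5000, 5027, "-", "U"),
        ]
        hist = sig.phasing_histogram(reads)
        assert hist[1] == 1 and hist.sum() == 1

    def test_1u_filter(self):
        reads = [
            AlignedRead("c", 5000, 5027, "+", "U"),
            AlignedRead("c", 5027, 5055, "+", "A"),
        ]
        assert sig.phasing_histogram(reads, require_1u=True).sum() == 0
        assert sig.phasing_histogram(reads, require_1u=False)[1] == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(200 + seed)
        reads = random_reads(rng, 150, with_copies=seed % 4 == 0)
        for require in (True, False):
            assert np.array_equal(
                sig.phasing_histogram(reads, 9, require),
                brute_phasing_hist(reads, 9, require),
            )

    def test_simulated_phased_locus_modal_at_one(self, rng):
        seq = bytearray(b"A" * 40_000)
        tuples = simulate.simulate_phased_locus(seq, 100, 200, (26, 30), 1.0, rng)
        genome_str = bytes(seq).decode()
        reads = [
            AlignedRead("c", s, e, st, "U" if genome_str[s] == "T" else "A")
            for s, e, st in tuples
        ]
        hist = sig.phasing_histogram(reads)
        assert hist.argmax() == 1

    def test_shuffled_positions_lose_phasing(self, rng):
        starts = rng.integers(0, 10_000, size=200)
        reads = [
            AlignedRead("c", int(s), int(s) + 27, "+", "U") for s in set(starts)
        ]
        hist = sig.phasing_histogram(reads)
        z = sig.phasing_zscore(hist)
        assert math.isnan(z) or abs(z) < 3


class TestStrandSymmetry:
    def test_mirrored_library_same_histograms(self, rng):
        span = 3000
        reads = random_reads(rng, 250, chroms=("c",), span=span)
        flip = {"+": "-", "-": "+"}
        mirrored = [
            AlignedRead("c", span - r.end, span - r.start, flip[r.strand], r.first_nt, r.copy)
            for r in reads
        ]
        assert np.array_equal(
            sig.overlap_histogram(reads), sig.overlap_histogram(mirrored)
        )
        assert np.array_equal(
            sig.phasing_histogram(reads), sig.phasing_histogram(mirrored)
        )
        assert len(sig.find_dicer_pairs(reads)) == len(sig.find_dicer_pairs(mirrored))


class TestFirstNtFraction:
    def test_fraction(self):
        reads = [AlignedRead("c", i * 50, i * 50 + 27, "+", "U") for i in range(9)]
        reads.append(AlignedRead("c", 900, 927, "+", "A"))
        assert sig.first_nt_fraction(reads) == pytest.approx(0.9)

    def test_absent_nucleotide_zero(self):
        reads = [AlignedRead("c", 0, 27, "+", "A")]
        assert sig.first_nt_fraction(reads, "G") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            sig.first_nt_fraction([])
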