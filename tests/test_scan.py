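"""Mismatch-tolerant scanning, orientation calls, conservation profiles."""

import numpy as np
import pytest

from conftest import naive_scan, random_genome
from palcore import (
    PALINDROME_CORE,
    REX_CONSENSUS,
    GenomeRecord,
    central_dinucleotide,
    classify_orientation,
    consensus_site_search,
    conservation_profile,
    parse_pattern,
    scan_genome,
)
from palcore.motif import revcomp
from palcore.scan import SiteHit


def _plant(seq: str, word: str, pos0: int) -> str:
    return seq[:pos0] + word + seq[pos0 + len(word):]


class TestScanGenome:
    def test_single_planted_exact_site(self, rng):
        g = random_genome(rng, 200, gid="t")
        word = "AAACCGTTGAAACGGTTT"
        seq = _plant(g.sequence, word, 90)
        # re-roll until the planted word is the unique exact hit (brute force)
        while len(naive_scan(seq, PALINDROME_CORE, 0)) != 1:
            g = random_genome(rng, 200, gid="t")
            seq = _plant(g.sequence, word, 90)
        hits = scan_genome(GenomeRecord(id="t", sequence=seq), PALINDROME_CORE, 0)
        assert [(h.start, h.mismatches) for h in hits] == [(91, 0)]
        assert hits[0].matched_seq == word
        assert hits[0].end == 108

    def test_pattern_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            scan_genome(GenomeRecord(id="t", sequence="ACGT"), "ACGTA", 0)

    def test_wraparound_hit_on_circular_genome(self, rng):
        g = random_genome(rng, 300)
        word = "AAACCGTTGAAACGGTTT"
        # plant straddling the origin: last 8 bases + first 10 bases
        seq = g.sequence[:-8] + word[:8]
        seq = word[8:] + seq[10:]
        g2 = GenomeRecord(id="t", sequence=seq, circular=True)
        starts = [h.start for h in scan_genome(g2, PALINDROME_CORE, 0)]
        assert 293 in starts
        linear = [h.start for h in scan_genome(g2, PALINDROME_CORE, 0, circular=False)]
        assert 293 not in linear

    def test_matches_naive_enumeration(self, rng):
        for _ in range(25):
            L = int(rng.integers(50, 1500))
            w = int(rng.integers(4, 11))
            pat = "".join(rng.choice(list("ACGTN"), size=w, p=[0.22] * 4 + [0.12]))
            budget = int(rng.integers(0, 4))
            g = random_genome(rng, L)
            got = [(h.start, h.mismatches) for h in scan_genome(g, pat, budget)]
            assert got == naive_scan(g.sequence, pat, budget)

    def test_budget_monotonicity(self, rng):
        g = random_genome(rng, 3000)
        prev: set[int] = set()
        for k in range(4):
            starts = {h.start for h in scan_genome(g, "ACGNNCGT", k)}
            assert prev <= starts
            prev = starts

    def test_mirror_positions_on_revcomp_genome(self, rng):
        core = parse_pattern("ACNNGT")
        g = random_genome(rng, 2000)
        rc = GenomeRecord(id="rc", sequence=revcomp(g.sequence), circular=True)
        fwd = {h.start for h in scan_genome(g, core, 1)}
        mirrored = {g.length - h.end + 1 for h in scan_genome(rc, core, 1)}
        # wrap-around ends fold back onto the circle
        mirrored = {((s - 1) % g.length) + 1 for s in mirrored}
        fwd = {((s - 1) % g.length) + 1 for s in fwd}
        assert fwd == mirrored


class TestConsensusSearch:
    def test_rex_site_found_at_two_deviations(self, rng):
        site = "CTGTGAATCAATTCACAT"
        g = random_genome(rng, 400)
        seq = _plant(g.sequence, site, 200)
        while naive_scan(seq, REX_CONSENSUS, 2) != [(201, 2)]:
            g = random_genome(rng, 400)
            seq = _plant(g.sequence, site, 200)
        gen = GenomeRecord(id="t", sequence=seq)
        hits = consensus_site_search(gen, REX_CONSENSUS, 2)
        assert [(h.start, h.mismatches) for h in hits] == [(201, 2)]
        assert consensus_site_search(gen, REX_CONSENSUS, 1) == []

    def test_reverse_strand_hit_reported(self, rng):
        consensus = parse_pattern("AACCGGTA")  # not self-rc
        instance_rc = revcomp("AACCGGTA")
        g = random_genome(rng, 300)
        seq = _plant(g.sequence, instance_rc, 150)
        while naive_scan(seq, "AACCGGTA", 0) or naive_scan(seq, instance_rc, 0) != [(151, 0)]:
            g = random_genome(rng, 300)
            seq = _plant(g.sequence, instance_rc, 150)
        hits = consensus_site_search(GenomeRecord(id="t", sequence=seq), consensus, 0)
        assert [(h.start, h.strand) for h in hits] == [(151, "-")]

    def test_self_rc_consensus_single_pass(self, rng):
        g = random_genome(rng, 2000)
        both = consensus_site_search(g, REX_CONSENSUS, 4)
        fwd = scan_genome(g, REX_CONSENSUS, 4)
        assert [(h.start, h.mismatches) for h in both] == [
            (h.start, h.mismatches) for h in fwd
        ]


class TestCentralDinucleotide:
    def test_read_off_positions_9_10(self):
        core = parse_pattern(PALINDROME_CORE)
        assert central_dinucleotide("AAACCGTTGAAACGGTTT", core) == "GA"
        assert central_dinucleotide("AAACCGTTTCAACGGTTT", core) == "TC"

    def test_odd_length_core_rejected(self):
        with pytest.raises(ValueError):
            central_dinucleotide("A" * 17, parse_pattern("N" * 17))


class TestClassifyOrientation:
    @pytest.mark.parametrize(
        "dinuc,expect",
        [("GA", "forward"), ("TC", "reverse"), ("AA", "forward"),
         ("TT", "reverse"), ("TA", "ambiguous"), ("NA", "ambiguous")],
    )
    def test_examples(self, dinuc, expect):
        assert classify_orientation(dinuc) == expect

    def test_agrees_with_distance_enumeration(self):
        def dist(a, b):
            return sum(x != y for x, y in zip(a, b))

        for a in "ACGT":
            for b in "ACGT":
                d = a + b
                df, dr = dist(d, "GA"), dist(d, "TC")
                expect = "forward" if df < dr else "reverse" if dr < df else "ambiguous"
                assert classify_orientation(d) == expect


def _hit(seq: str, mm: int) -> SiteHit:
    return SiteHit(
        start=1, end=len(seq), mismatches=mm, matched_seq=seq,
        central_dinuc="", orientation="ambiguous",
    )


class TestConservationProfile:
    def test_identical_sites_fully_conserved(self):
        hits = [_hit("AAACCGTTGAAACGGTTT", 0)] * 10
        prof = conservation_profile(hits, 0)
        assert prof.n_sites == 10
        assert np.allclose(prof.modal_freq, 1.0)
        assert prof.conserved_positions == list(range(1, 19))

    def test_position_conserved_only_in_low_mismatch_stratum(self, rng):
        # position 1 fixed to A among exact sites, random among 2-4 mm sites
        exact = [_hit("A" + "ACGT" * 4 + "C", 0) for _ in range(20)]
        noisy = [
            _hit("ACGT"[int(rng.integers(4))] + "ACGT" * 4 + "C", int(rng.integers(2, 5)))
            for _ in range(60)
        ]
        low = conservation_profile(exact + noisy, 1)
        high = conservation_profile(exact + noisy, 4)
        assert 1 in low.conserved_positions
        assert 1 not in high.conserved_positions

    def test_columns_sum_to_n_sites(self, rng):
        hits = [
            _hit("".join(rng.choice(list("ACGT"), size=8)), int(rng.integers(0, 3)))
            for _ in range(30)
        ]
        prof = conservation_profile(hits, (0, 2))
        assert (prof.counts.sum(axis=0) == prof.n_sites).all()

    def test_empty_input(self):
        prof = conservation_profile([], 4)
        assert prof.n_sites == 0 and prof.conserved_positions == []
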