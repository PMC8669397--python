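"""Motif scanning, GC skew, family ranking and global identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from muklock import (
    CircularGenome,
    ScanParameters,
    circular_distance,
    cumulative_gc_skew,
    edit_distance,
    global_identity,
    rank_site_families,
    scan_motifs,
)
from muklock.errors import DataError
from muklock.genome import reverse_complement
from muklock.motif import MotifHit

dna = st.text(alphabet="ACGT", min_size=0, max_size=30)


class TestEditDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("GTGAC", "GTGAC", 0),
        ("ACGT", "", 4),
        ("", "ACGT", 4),
        ("GTGACATTGTCAC", "GTTACATTGTAAC", 2),
    ])
    def test_known_distances(self, a, b, expected):
        assert edit_distance(a, b) == expected
        assert oracles.dp_edit_distance(a, b) == expected

    def test_rejects_invalid_characters(self):
        with pytest.raises(DataError):
            edit_distance("ACGN", "ACGT")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(dna, dna, dna)
    def test_metric_axioms_and_dp_agreement(self, a, b, c):
        dab = edit_distance(a, b)
        assert dab == oracles.dp_edit_distance(a, b)
        assert dab == edit_distance(b, a)
        assert (dab == 0) == (a == b)
        assert dab <= edit_distance(a, c) + edit_distance(c, b)


class TestScanMotifs:
    def test_degenerate_pattern_single_hit(self):
        g = CircularGenome("g", "AAGTTACATTGTAACAA", circular=False)
        hits = scan_motifs(g, ScanParameters("GTTACNNNGTAAC", max_edit=0))
        assert [(h.start, h.edit_distance) for h in hits] == [(2, 0)]
        assert hits[0].matched_seq == "GTTACATTGTAAC"

    def test_edit_mode_reports_minimum_distance(self):
        g = CircularGenome("g", "AAGTTACATTGTAACAA", circular=False)
        hits = scan_motifs(g, ScanParameters("GTGACATTGTCAC", max_edit=2))
        assert len(hits) == 1
        assert hits[0].start == 2 and hits[0].edit_distance == 2

    def test_absent_pattern_yields_no_hits(self):
        g = CircularGenome("g", "A" * 200 + "C" * 200, circular=False)
        assert scan_motifs(g, ScanParameters("GTGACATTGTCAC", 0)) == []

    def test_pattern_longer_than_genome_rejected(self):
        g = CircularGenome("g", "ACGTACG", circular=False)
        with pytest.raises(DataError):
            scan_motifs(g, ScanParameters("A" * 10, 0))

    def test_circular_scan_finds_origin_spanning_site(self):
        site = "GTTACATTGTAAC"
        seq = site[6:] + "A" * 200 + site[:6]
        g = CircularGenome("g", seq, circular=True)
        hits = scan_motifs(g, ScanParameters(site, max_edit=0))
        assert [h.start for h in hits] == [207]
        g_lin = CircularGenome("g", seq, circular=False)
        assert scan_motifs(g_lin, ScanParameters(site, max_edit=0)) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        pattern = "GTTACATTGTAAC"
        g = CircularGenome("g", seq, circular=False)
        hits = scan_motifs(g, ScanParameters(pattern, max_edit=k,
                                             both_strands=False))
        expected = oracles.collapse_starts(
            oracles.brute_force_scan(seq, pattern, k), len(pattern))
        assert {h.start: h.edit_distance for h in hits} == expected

    def test_exact_mode_equals_substring_search(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4],
                                 size=1500))
        pattern = "ACGTAC"
        g = CircularGenome("g", seq, circular=False)
        hits = scan_motifs(g, ScanParameters(pattern, 0, both_strands=False,
                                             collapse_overlaps=False))
        expected, s = [], seq.find(pattern)
        while s != -1:
            expected.append(s)
            s = seq.find(pattern, s + 1)
        assert [h.start for h in hits] == expected

    def test_palindrome_reported_once_per_locus(self):
        # GTTACATTGTAAC is not a strict palindrome; GTTACGTAAC is
        pal = "GTTACGTAAC"
        assert reverse_complement(pal) == pal
        g = CircularGenome("g", "AA" + pal + "TT", circular=False)
        hits = scan_motifs(g, ScanParameters(pal, 0, both_strands=True))
        assert len(hits) == 1 and hits[0].strand == "+"

    def test_reverse_complement_genome_gives_mapped_loci(self):
        truth_pattern = "GTTACNNNGTAAC"
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=800))
        seq = seq[:100] + "GTTACGGGGTAAC" + seq[113:]
        g = CircularGenome("g", seq, circular=False)
        hits_fwd = scan_motifs(g, ScanParameters(truth_pattern, 0))
        g_rc = g.reverse_complement()
        hits_rc = scan_motifs(g_rc, ScanParameters(truth_pattern, 0))
        n = len(seq)
        mapped = sorted(n - h.start - h.length for h in hits_rc)
        assert mapped == sorted(h.start for h in hits_fwd)

    def test_planted_site_recovery(self, planted_genome):
        g = planted_genome
        hits = scan_motifs(g.genome, ScanParameters("GTTACATTGTAAC",
                                                    max_edit=2))
        starts = {h.start for h in hits}
        for site in g.planted_sites:
            assert site.position in starts


class TestGCSkew:
    def test_hand_summed_cumulative_series(self):
        g = CircularGenome("s", "GGGGGCCCCC", circular=True)
        prof = cumulative_gc_skew(g, window=1, step=1)
        assert np.allclose(prof.cumulative,
                           [1, 2, 3, 4, 5, 4, 3, 2, 1, 0])
        assert prof.ter_pos == 5
        assert prof.ori_pos == 0

    def test_gc_free_genome_has_undefined_calls(self):
        g = CircularGenome("a", "A" * 2000, circular=True)
        prof = cumulative_gc_skew(g, window=100)
        assert prof.ori_pos is None and prof.ter_pos is None

    def test_window_larger_than_genome_rejected(self):
        g = CircularGenome("g", "ACGT" * 10, circular=True)
        with pytest.raises(DataError):
            cumulative_gc_skew(g, window=100)

    def test_ter_recovered_on_synthetic_genome(self, planted_genome):
        g = planted_genome
        prof = cumulative_gc_skew(g.genome, window=1000)
        n = len(g.genome)
        tol = max(prof.window, int(0.05 * n))
        assert circular_distance(prof.ter_pos, g.ter_pos, n) <= tol
        assert circular_distance(prof.ori_pos, g.ori_pos, n) <= tol

    def test_rotation_covariance(self, planted_genome):
        g = planted_genome.genome
        n = len(g)
        shift = 7000  # a multiple of the window/step
        rotated = CircularGenome(g.name, g.seq[shift:] + g.seq[:shift], True)
        p0 = cumulative_gc_skew(g, window=1000)
        p1 = cumulative_gc_skew(rotated, window=1000)
        assert (p0.ter_pos - shift) % n == p1.ter_pos % n
        assert (p0.ori_pos - shift) % n == p1.ori_pos % n


class TestCircularDistance:
    @pytest.mark.parametrize("i,j,length,expected", [
        (0, 5, 10, 5), (1, 9, 10, 2), (3, 3, 10, 0), (0, 9, 10, 1),
    ])
    def test_known_values(self, i, j, length, expected):
        assert circular_distance(i, j, length) == expected

    def test_invalid_length_rejected(self):
        with pytest.raises(DataError):
            circular_distance(0, 0, 0)


class TestRankFamilies:
    @staticmethod
    def _hits(positions):
        return [MotifHit(p, 13, "+", 0, "GTTACATTGTAAC") for p in positions]

    def test_median_distance_ordering(self):
        ter, n = 0, 100000
        fams = {"X": self._hits([100, 300, 500]),
                "Y": self._hits([50000])}
        ranking = rank_site_families(fams, ter_pos=ter, genome_length=n)
        by_name = {e[0]: e for e in ranking.entries}
        assert by_name["X"][2] == pytest.approx(306)  # midpoints at +6
        assert by_name["Y"][3] == 2 and by_name["X"][3] == 1

    def test_single_family_gets_rank_one(self):
        ranking = rank_site_families({"Z": self._hits([10])}, 0, 1000)
        assert ranking.entries[0][3] == 1

    def test_ties_break_lexicographically(self):
        fams = {"B": self._hits([100]), "A": self._hits([100])}
        ranking = rank_site_families(fams, 0, 1000)
        assert [e[0] for e in ranking.entries] == ["A", "B"]

    def test_empty_family_rejected(self):
        with pytest.raises(DataError):
            rank_site_families({"X": []}, 0, 1000)

    def test_planted_family_ranks_first(self, planted_genome):
        g = planted_genome
        near = scan_motifs(g.genome, ScanParameters("GTTACNNNGTAAC", 0))
        # a decoy family planted nowhere near ter: use ori-proximal A-runs
        decoy = [MotifHit((g.ori_pos + d) % len(g.genome), 13, "+", 0, "N" * 13)
                 for d in (-200, 0, 200)]
        ranking = rank_site_families({"GTTACNNNGTAAC": near, "DECOY": decoy},
                                     cumulative_gc_skew(g.genome, 1000).ter_pos,
                                     len(g.genome))
        assert ranking.entries[0][0] == "GTTACNNNGTAAC"


class TestGlobalIdentity:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGT", 100.0),
        ("ACGT", "ACGA", 75.0),
        ("ACGTT", "ACGT", 80.0),
    ])
    def test_known_identities(self, a, b, expected):
        assert global_identity(a, b) == pytest.approx(expected)
        assert oracles.needleman_wunsch_identity(a, b) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(DataError):
            global_identity("", "ACGT")

    def test_amino_acid_sequences_supported(self):
        assert global_identity("MSTIEER", "MSTIEER") == 100.0
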