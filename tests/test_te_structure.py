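import numpy as np
import pytest

from httscan import _seq
from httscan.synthetic_data import evolve_seq, insert_te, make_te_consensus
from httscan.te_structure import (classify_copy, find_tirs, find_tsd,
                                  longest_orf_aa)


def _brute_force_tir(seq, lo, hi, frac):
    """Independent oracle: check every candidate arm length directly."""
    best = None
    for L in range(lo, min(hi, len(seq) // 2) + 1):
        mm = sum(1 for a, b in zip(seq[:L], _seq.revcomp(seq[-L:]))
                 if a != b or a == "N" or b == "N")
        if mm <= int(frac * L):
            best = (L, mm)
    return best


class TestFindTirs:
    def test_planted_tir_recovered(self):
        s = make_te_consensus(2000, tir_length=15, seed=3)
        rep = find_tirs(s)
        assert rep.found and rep.length >= 15
        # reported arms really are inverted repeats up to the reported mismatches
        mm = sum(1 for a, b in zip(rep.left_arm, _seq.revcomp(rep.right_arm))
                 if a != b)
        assert mm == rep.mismatches <= int(0.2 * rep.length)

    @pytest.mark.parametrize("seed", range(100))
    def test_random_sequence_has_no_exact_tir(self, seed):
        rng = np.random.default_rng(10_000 + seed)
        s = _seq.random_seq(rng, 1000)
        rep = find_tirs(s, min_tir_len=10, max_mismatch_frac=0.0)
        assert not rep.found

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(777 + seed)
        s = make_te_consensus(400, tir_length=12, seed=rng)
        rep = find_tirs(s, 10, 30, 0.2)
        oracle = _brute_force_tir(s, 10, 30, 0.2)
        assert rep.found == (oracle is not None)
        if oracle:
            assert (rep.length, rep.mismatches) == oracle

    def test_palindrome_found_at_max_length(self):
        left = "ACGTTGCAACGTACGTACGTTGCAACGTAC"      # 30 bp
        s = left + "TTTT" + _seq.revcomp(left)
        rep = find_tirs(s, 10, 30, 0.0)
        assert rep.found and rep.length == 30 and rep.mismatches == 0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_tirs("ACGTACGT", min_tir_len=10)

    @pytest.mark.parametrize("seed", range(10))
    def test_strand_symmetry(self, seed):
        s = make_te_consensus(600, tir_length=14, seed=seed)
        a = find_tirs(s)
        b = find_tirs(_seq.revcomp(s))
        assert (a.found, a.length, a.mismatches) == (b.found, b.length, b.mismatches)


class TestFindTsd:
    def test_simulated_insertion_recovers_tsd(self, rng):
        host = _seq.random_seq(rng, 400)
        g, iv, tsd = insert_te(host, _seq.random_seq(rng, 100), 200, tsd_length=8)
        rep = find_tsd(g[iv.start - 30:iv.start], g[iv.end:iv.end + 30])
        assert rep.found and rep.length >= 8
        assert rep.left_site == rep.right_site

    def test_unrelated_flanks_not_found(self):
        rep = find_tsd("G" * 20 + "AAAA", "CCCC" + "G" * 20, tsd_min=4)
        assert not rep.found

    def test_longest_k_wins(self):
        # suffix/prefix agree for k=10 (hence also k=8): the 10-mer is reported
        core = "ACGTACGTAC"
        rep = find_tsd("TTTTTT" + core, core + "GGGGGG", tsd_min=4, tsd_max=12)
        assert rep.found and rep.length == 10 and rep.left_site == core

    def test_short_flank_rejected(self):
        with pytest.raises(ValueError):
            find_tsd("ACGT", "ACGTACGTACGTACGT", tsd_max=12)

    @pytest.mark.parametrize("seed", range(10))
    def test_orientation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        left, right = _seq.random_seq(rng, 40), _seq.random_seq(rng, 40)
        a = find_tsd(left, right)
        b = find_tsd(_seq.revcomp(right), _seq.revcomp(left))
        assert (a.found, a.length) == (b.found, b.length)

    def test_recovery_on_200_intact_copies(self):
        """Every planted 8 bp TSD is recovered; the longest-k rule may extend
        it when the neighbouring host base happens to match."""
        te = make_te_consensus(300, tir_length=15, seed=0)
        lengths = []
        for i in range(200):
            rng = np.random.default_rng(50_000 + i)
            host = _seq.random_seq(rng, 300)
            copy = evolve_seq(te, rng.uniform(0.0, 0.05), seed=rng)
            g, iv, _ = insert_te(host, copy, 150, tsd_length=8)
            rep = find_tsd(g[iv.start - 30:iv.start], g[iv.end:iv.end + 30])
            assert rep.found
            lengths.append(rep.length)
        assert min(lengths) == 8
        assert np.bincount(lengths).argmax() == 8     # modal length = planted


@pytest.fixture(scope="module")
def consensus():
    return make_te_consensus(1500, tir_length=15, seed=11)


class TestClassifyCopy:
    def _locus(self, consensus, divergence, rng):
        host = _seq.random_seq(rng, 600)
        copy = evolve_seq(consensus, divergence, seed=rng)
        g, iv, _ = insert_te(host, copy, 300)
        return g[iv.start:iv.end], g[iv.start - 30:iv.start], g[iv.end:iv.end + 30]

    def test_intact_copy_full_length(self, consensus, rng):
        copy, l, r = self._locus(consensus, 0.02, rng)
        cls = classify_copy(copy, l, r, consensus)
        assert cls.status == "full_length" and cls.consensus_coverage >= 0.9

    def test_truncated_copy_is_fragment(self, consensus, rng):
        copy, l, r = self._locus(consensus, 0.02, rng)
        cls = classify_copy(copy[:len(copy) // 2], l, r, consensus)
        assert cls.status == "fragment" and cls.consensus_coverage < 0.9

    def test_shuffled_flanks_break_full_length(self, consensus, rng):
        copy, l, r = self._locus(consensus, 0.02, rng)
        shuffled = _seq.random_seq(rng, 30)
        cls = classify_copy(copy, shuffled, _seq.random_seq(rng, 30), consensus)
        assert cls.consensus_coverage >= 0.9 and cls.status == "fragment"

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError):
            classify_copy("ACGT" * 50, "A" * 20, "A" * 20, "")


class TestLongestOrf:
    def test_counting_convention(self):
        assert longest_orf_aa("ATGAAATAA") == 2          # Met-Lys, stop excluded

    def test_no_atg_means_no_orf(self):
        assert longest_orf_aa("AAAAAATAA") == 0
        assert longest_orf_aa("AAATAAAAA", require_atg=False) > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_six_frame_oracle(self, seed):
        rng = np.random.default_rng(31_000 + seed)
        s = _seq.random_seq(rng, 500)
        assert longest_orf_aa(s) == _orf_oracle(s)

    def test_planted_long_orf_flagged(self):
        s = make_te_consensus(3000, tir_length=15, seed=1, orf_aa=610)
        assert longest_orf_aa(s) >= 610


def _orf_oracle(s):
    """Exhaustive oracle: try every ATG in all six frames."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for seq in (s, _seq.revcomp(s)):
        for start in range(len(seq) - 2):
            if seq[start:start + 3] != "ATG":
                continue
            n = 0
            for pos in range(start, len(seq) - 2, 3):
                if seq[pos:pos + 3] in stops:
                    break
                n += 1
            best = max(best, n)
    return best
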