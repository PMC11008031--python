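import numpy as np
import pytest
from Bio import Align

from httscan import _seq
from httscan.homology_search import (Hit, clean_short_hits, filter_candidates,
                                     local_search, pairwise_identity_matrix)
from httscan.io_core import Interval, ScanConfig
from httscan.synthetic_data import evolve_seq


def _sw_oracle():
    """Exhaustive Smith-Waterman with the pipeline scoring (independent engine)."""
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 4
    al.mismatch_score = -5
    al.open_gap_score = -10       # our convention: gap of length L costs 8 + 2L
    al.extend_gap_score = -2
    return al


class TestLocalSearch:
    def test_verbatim_plant_full_identity(self, rng):
        host = _seq.random_seq(rng, 2000)
        q = _seq.random_seq(rng, 150)
        genome = host[:1000] + q + host[1000:]
        hits = local_search(q, genome)
        assert len(hits) == 1
        h = hits[0]
        assert (h.interval.start, h.interval.end, h.strand) == (1000, 1150, "+")
        assert h.identity == 1.0 and (h.qstart, h.qend) == (0, 150)

    def test_reverse_complement_plant_minus_strand(self, rng):
        host = _seq.random_seq(rng, 2000)
        q = _seq.random_seq(rng, 150)
        genome = host[:1000] + _seq.revcomp(q) + host[1000:]
        hits = local_search(q, genome)
        assert len(hits) == 1
        h = hits[0]
        assert (h.interval.start, h.interval.end, h.strand) == (1000, 1150, "-")
        assert h.identity == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_top_score_equals_smith_waterman(self, seed):
        rng = np.random.default_rng(900 + seed)
        host = _seq.random_seq(rng, 300)
        q = _seq.random_seq(rng, 100)
        qm = evolve_seq(q, 0.10, seed=int(rng.integers(2**31)))
        genome = host[:150] + qm + host[150:]
        hits = local_search(q, genome, ScanConfig(min_score=30))
        oracle = int(_sw_oracle().score(q, genome))
        assert hits and max(h.score for h in hits) == oracle

    def test_strand_invariance(self, rng):
        host = _seq.random_seq(rng, 3000)
        q = _seq.random_seq(rng, 200)
        qm = evolve_seq(q, 0.05, seed=5)
        genome = host[:1500] + qm + host[1500:]
        fwd = local_search(q, genome)
        rev = local_search(q, _seq.revcomp(genome))
        assert sorted(h.score for h in fwd) == sorted(h.score for h in rev)
        assert sorted(h.strand for h in fwd) != sorted(h.strand for h in rev) or \
            len(fwd) == 0

    def test_query_shorter_than_word_rejected(self):
        with pytest.raises(ValueError):
            local_search("ACG", "ACGT" * 100)


def _mk_hit(start, end, identity, qspan, score=500):
    return Hit(Interval("c", start, end), qspan[0], qspan[1], score, identity,
               end - start)


class TestFilters:
    def test_identity_threshold_edges(self):
        hits = [_mk_hit(0, 900, 0.74, (0, 900)),
                _mk_hit(1000, 1950, 0.80, (0, 950))]
        kept = filter_candidates(hits, query_length=1000)
        assert len(kept) == 1 and kept[0].identity == 0.80

    def test_coverage_threshold(self):
        hits = [_mk_hit(0, 800, 0.95, (0, 800)),       # 80% coverage: dropped
                _mk_hit(0, 950, 0.95, (0, 950))]       # 95% coverage: kept
        assert filter_candidates(hits, query_length=1000) == [hits[1]]

    def test_divergent_copy_passes_until_identity_saturates(self, rng):
        """A full-length copy at K~0.10 survives the 75% cutoff; at K~0.35
        (p-distance ~0.27) it is removed."""
        q = _seq.random_seq(rng, 1000)
        host = _seq.random_seq(rng, 3000)
        for d, survives in ((0.10, True), (0.35, False)):
            genome = host[:1500] + evolve_seq(q, d, seed=17) + host[1500:]
            hits = local_search(q, genome, ScanConfig(min_score=50))
            kept = filter_candidates(hits, len(q))
            assert bool(kept) == survives, f"distance {d}"

    def test_short_hit_boundary_at_100(self):
        hits = [_mk_hit(0, 99, 1.0, (0, 99)), _mk_hit(200, 300, 1.0, (0, 100))]
        kept = clean_short_hits(hits)
        assert len(kept) == 1 and len(kept[0].interval) == 100

    def test_clean_counts(self):
        hits = [_mk_hit(i * 1000, i * 1000 + L, 1.0, (0, L))
                for i, L in enumerate([50, 99, 100, 150, 400])]
        assert len(clean_short_hits(hits)) == 3
        assert clean_short_hits([]) == []

    def test_threshold_monotonicity(self, rng):
        hits = [_mk_hit(i * 1000, i * 1000 + int(L), float(p), (0, int(L)))
                for i, (L, p) in enumerate(
                    zip(rng.integers(50, 1000, 30), rng.uniform(0.5, 1.0, 30)))]
        prev = len(hits) + 1
        for ident in (0.5, 0.7, 0.75, 0.9, 0.99):
            n = len(filter_candidates(hits, 1000, min_identity=ident,
                                      min_coverage=0.0))
            assert n <= prev
            prev = n


class TestPim:
    def test_identical_pair(self, rng):
        s = _seq.random_seq(rng, 500)
        p = pairwise_identity_matrix([s, s], ["a", "b"])
        assert p.identity("a", "b") == 1.0

    def test_symmetry_and_unit_diagonal(self, rng):
        seqs = [_seq.random_seq(rng, 400) for _ in range(3)]
        seqs.append(evolve_seq(seqs[0], 0.05, seed=2))
        p = pairwise_identity_matrix(seqs)
        assert np.allclose(p.matrix, p.matrix.T)
        assert np.allclose(np.diag(p.matrix), 1.0)

    def test_pair_at_known_distance(self, rng):
        s = _seq.random_seq(rng, 2000)
        p = pairwise_identity_matrix([s, evolve_seq(s, 0.05, seed=3)])
        # K=0.05 corresponds to ~95.2% identity; allow 3 binomial SE at 2 kb
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(p.matrix[0, 1] - 0.952) < 3 * se + 0.005

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            pairwise_identity_matrix(["ACGTACGTACGT"])
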