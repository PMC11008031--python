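import numpy as np
import pytest

from httscan import _seq
from httscan.divergence import k2p_distance
from httscan.synthetic_data import (InsertionEvent, SimConfig, evolve_seq,
                                    htt_scenario, insert_te, make_te_consensus,
                                    presence_absence_scenario,
                                    simulate_scenario, vertical_scenario)


class TestConsensus:
    def test_terminal_inverted_repeat_by_construction(self):
        s = make_te_consensus(3000, tir_length=15, seed=1)
        assert _seq.revcomp(s[:15]) == s[-15:]

    def test_zero_tir_length_allowed(self):
        s = make_te_consensus(500, tir_length=0, seed=1)
        assert len(s) == 500

    def test_deterministic_given_seed(self):
        assert make_te_consensus(800, 15, seed=9) == make_te_consensus(800, 15, seed=9)

    def test_length_violation_rejected(self):
        with pytest.raises(ValueError):
            make_te_consensus(30, tir_length=15)


class TestInsertTe:
    def test_target_site_duplicated(self):
        g, iv, tsd = insert_te("AAAATTTTGGGG", "CCCC", 4, tsd_length=2)
        assert tsd == "TT"
        assert g == "AAAATTCCCCTTTTGGGG"
        assert len(g) == 12 + 4 + 2
        # flanks of the TE interval both read the TSD
        assert g[iv.start - 2:iv.start] == g[iv.end:iv.end + 2] == "TT"

    def test_zero_tsd_no_duplication(self):
        g, iv, _ = insert_te("AAAATTTT", "CC", 4, tsd_length=0)
        assert g == "AAAACCTTTT" and len(g) == 10

    def test_default_8bp_tsd(self, rng):
        host = _seq.random_seq(rng, 200)
        g, iv, tsd = insert_te(host, "C" * 40, 100)
        assert len(tsd) == 8
        assert g[iv.start - 8:iv.start] == g[iv.end:iv.end + 8] == tsd

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            insert_te("ACGT", "CC", 3, tsd_length=8)


class TestEvolve:
    def test_zero_distance_is_identity(self, rng):
        s = _seq.random_seq(rng, 5000)
        assert evolve_seq(s, 0.0, seed=3) == s

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            evolve_seq("ACGT", -0.1)

    def test_deterministic_given_seed(self):
        s = "ACGT" * 500
        assert evolve_seq(s, 0.1, seed=5) == evolve_seq(s, 0.1, seed=5)

    def test_large_kappa_suppresses_transversions(self, rng):
        s = _seq.random_seq(rng, 10000)
        total_q = 0
        for i in range(20):
            e = evolve_seq(s, 0.2, kappa=500.0, seed=i)
            total_q += k2p_distance(s, e).Q * 10000
        # 20 replicates x 10 kb at kappa=500: expected transversions ~ 0.2/501 per site
        assert total_q < 0.2 / 501 * 200000 * 3 + 10

    def test_n_sites_left_untouched(self):
        assert evolve_seq("N" * 100, 0.5, seed=1) == "N" * 100


class TestScenario:
    def test_genome_length_conservation(self):
        sc = vertical_scenario(seed=2, genome_length=60_000, copies=3,
                               min_locus_spacing=3500)
        for sp, rec in sc.genomes.items():
            rows = sc.truth.copies[sc.truth.copies.species == sp]
            grown = sum(int(r.end - r.start) for r in rows.itertuples())
            tsds = sum(8 for r in rows.itertuples() if not r.fragment)
            assert len(rec.sequence) == 60_000 + grown + tsds

    def test_deterministic_given_config(self):
        a = vertical_scenario(seed=8, genome_length=50_000, copies=2)
        b = vertical_scenario(seed=8, genome_length=50_000, copies=2)
        assert a.genomes["A"].sequence == b.genomes["A"].sequence
        assert a.truth.copies.equals(b.truth.copies)

    def test_vertical_copies_are_orthologous(self):
        sc = vertical_scenario(seed=3, genome_length=60_000, copies=3)
        by_copy = sc.truth.copies.groupby("copy_id")
        for _, grp in by_copy:
            assert set(grp.species) == {"A", "B", "C", "D"}
            assert grp.anchor.nunique() == 1      # same ancestral position
            assert grp.start.nunique() == 1       # no cross-lineage indels

    def test_htt_cross_species_divergence_is_twice_transfer_age(self):
        # transfer at 2 MY x 0.002 subs/site/MY -> pairwise K ~ 0.008
        sc = htt_scenario(seed=4, genome_length=60_000, copies=3, fragment_prob=0.0)
        rows_a = sc.truth.copies[sc.truth.copies.species == "A"]
        rows_c = sc.truth.copies[sc.truth.copies.species == "C"]
        ks = []
        for ra in rows_a.itertuples():
            for rc in rows_c.itertuples():
                ks.append(k2p_distance(sc.copy_sequence(ra), sc.copy_sequence(rc)).K)
        mean_k = np.mean(ks)
        se = 3 * np.sqrt(0.008 / 3000)            # binomial-scale error at 3 kb
        assert abs(mean_k - 0.008) < 3 * se + 0.002
        # while the hosts themselves are ~0.2 apart
        assert sc.rate_scale * 2 * 50 == pytest.approx(0.2)

    def test_full_fragmentation_destroys_hallmarks(self):
        from httscan.te_structure import classify_copy
        sc = vertical_scenario(seed=5, genome_length=60_000, copies=3,
                               fragment_prob=1.0)
        rows = sc.truth.copies[sc.truth.copies.species == "A"]
        assert rows.fragment.all()
        for r in rows.itertuples():
            left, right = sc.copy_flanks(r, 30)
            cls = classify_copy(sc.copy_sequence(r), left, right, sc.consensus)
            assert cls.status == "fragment"

    def test_truth_shared_counts(self):
        sc = presence_absence_scenario(seed=1, n_ancestral=4, n_independent=3,
                                       genome_length=120_000)
        assert sc.truth.shared_count("A", "B") == 4
        assert len(sc.truth.copies[sc.truth.copies.species == "A"]) == 7

    def test_event_on_unknown_branch_rejected(self):
        cfg = SimConfig(
            species_tree="((A:1,B:1):1,C:2);",
            events=[InsertionEvent("vertical", 1.5, clade=("A", "C"))],
            genome_length=30_000, min_locus_spacing=2000)
        with pytest.raises(ValueError, match="no branch"):
            simulate_scenario(cfg)

    def test_event_age_must_sit_on_branch(self):
        cfg = SimConfig(
            species_tree="((A:1,B:1):1,C:2);",
            events=[InsertionEvent("vertical", 1.5, clade=("A", "B"))],
            genome_length=30_000, min_locus_spacing=2000)
        simulate_scenario(cfg)          # age 1.5 lies on the (A,B) branch: fine
        below = SimConfig(
            species_tree="((A:1,B:1):1,C:2);",
            events=[InsertionEvent("vertical", 0.5, clade=("A", "B"))],
            genome_length=30_000, min_locus_spacing=2000)
        with pytest.raises(ValueError, match="not on the branch"):
            simulate_scenario(below)    # age 0.5 is below the clade's MRCA
        bad = SimConfig(
            species_tree="((A:1,B:1):1,C:2);",
            events=[InsertionEvent("horizontal", 1.5, recipients=("A",))],
            genome_length=30_000, min_locus_spacing=2000)
        with pytest.raises(ValueError, match="beyond"):
            simulate_scenario(bad)

    def test_mya_tree_requires_rate(self):
        with pytest.raises(ValueError, match="rate"):
            SimConfig(species_tree="(A:1,B:1);", events=[], units="mya")
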