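"""End-to-end orchestration: genomes + consensus + species tree -> HTT calls.

The stages mirror the analysis a practitioner would run by hand: scan each
genome for TE copies, classify their structure, pick a representative copy
per species, measure cross-species identity and K2P divergence, build the
TE tree and test discordance, run the orthologous presence/absence test for
each focal pair, and integrate everything in the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from . import _seq
from ._align import global_align
from .divergence import DIVERGENCE_GAP_EXTEND, DIVERGENCE_GAP_OPEN, k2p_distance
from .homology_search import (Hit, clean_short_hits, filter_candidates,
                              local_search)
from .htt_caller import HTTCall, HTTEvidence, call_htt, patchiness
from .io_core import (GenomeRecord, Interval, RunConfig, divergence_time,
                      read_newick)
from .phylogeny import nj_tree, rf_distance, te_distance_matrix
from .presence_absence import extract_loci, shared_insertion_count
from .te_structure import CopyClassification, classify_copy

__all__ = ["SpeciesScan", "PairResult", "scan_species", "run_htt_analysis"]


@dataclass
class SpeciesScan:
    """Per-species scan result with the chosen representative copy."""

    species: str
    hits: list[Hit]
    candidates: list[Hit]               # identity/coverage-filtered full-length set
    representative: str | None
    representative_hit: Hit | None
    representative_class: CopyClassification | None
    present: bool


def _hit_sequence(genome: GenomeRecord, hit: Hit) -> str:
    s = genome.sequence[hit.interval.start:hit.interval.end]
    return _seq.revcomp(s) if hit.strand == "-" else s


def _refine_interval(hit: Hit, query_len: int, contig_len: int):
    """Extend a hit to the full query extent.

    Local alignment trims mutated terminal bases, but the structural
    hallmarks (TIR/TSD) live exactly at the termini, so the copy interval is
    widened by the unaligned query overhangs before classification.
    """
    lead, trail = hit.qstart, query_len - hit.qend
    if hit.strand == "-":
        lead, trail = trail, lead
    start = max(0, hit.interval.start - lead)
    end = min(contig_len, hit.interval.end + trail)
    return Interval(hit.interval.seq_id, start, end, hit.interval.strand)


def scan_species(
    consensus: str,
    genome: GenomeRecord,
    config: RunConfig | None = None,
    flank_pad: int = 30,
) -> SpeciesScan:
    """Scan one genome; presence means any clean hit at the identity cutoff."""
    cfg = config or RunConfig()
    hits = local_search(consensus, genome, cfg.scan)
    clean = [h for h in clean_short_hits(hits, cfg.scan.min_hit_len)
             if h.identity >= cfg.scan.min_identity]
    candidates = filter_candidates(
        hits, len(consensus), cfg.scan.min_identity, cfg.scan.min_coverage)
    pool = candidates or clean
    rep_hit = max(pool, key=lambda h: h.score) if pool else None
    rep_seq = None
    rep_cls = None
    if rep_hit is not None:
        iv = _refine_interval(rep_hit, len(consensus), len(genome.sequence))
        rep_seq = genome.sequence[iv.start:iv.end]
        if rep_hit.strand == "-":
            rep_seq = _seq.revcomp(rep_seq)
        left = genome.sequence[max(0, iv.start - flank_pad):iv.start]
        right = genome.sequence[iv.end:iv.end + flank_pad]
        if rep_hit.strand == "-":
            left, right = _seq.revcomp(right), _seq.revcomp(left)
        rep_cls = classify_copy(rep_seq, left, right, consensus, cfg.structure)
    return SpeciesScan(genome.species_id, hits, candidates, rep_seq, rep_hit,
                       rep_cls, bool(clean))


@dataclass
class PairResult:
    evidence: HTTEvidence
    call: HTTCall
    shared_table: pd.DataFrame | None = None


def run_htt_analysis(
    genomes: dict[str, GenomeRecord],
    consensus: str,
    species_tree,
    rate: float | None = None,
    focal_pairs: list[tuple[str, str]] | None = None,
    config: RunConfig | None = None,
) -> tuple[dict[tuple[str, str], PairResult], dict]:
    """Run the full pipeline and call HTT for the requested species pairs.

    ``species_tree`` is the host tree (newick or dendropy) with branch
    lengths in MY when ``rate`` (subs/site/MY) is supplied; without a rate
    the identity criterion is skipped.  Returns per-pair results plus a
    summary dict (scans, TE tree, discordance report).
    """
    cfg = config or RunConfig()
    tree = species_tree if isinstance(species_tree, dendropy.Tree) \
        else read_newick(species_tree)

    scans = {sp: scan_species(consensus, g, cfg) for sp, g in genomes.items()}
    presence = {sp: s.present for sp, s in scans.items()}
    reps = {sp: s.representative for sp, s in scans.items()
            if s.representative is not None}

    # prune the species tree to the genomes actually provided (patchiness is
    # judged among surveyed species only)
    surveyed = sorted(genomes)
    tree_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(surveyed) - tree_labels)
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    pruned = dendropy.Tree(tree)
    drop = sorted(tree_labels - set(surveyed))
    if drop:
        pruned.prune_taxa_with_labels(drop)

    # TE tree discordance (needs >= 4 species with a representative)
    te_tree = None
    discord = None
    if len(reps) >= 4:
        dm = te_distance_matrix(reps)
        te_tree = nj_tree(dm)
        sp_sub = dendropy.Tree(pruned)
        drop2 = sorted(set(surveyed) - set(reps))
        if drop2:
            sp_sub.prune_taxa_with_labels(drop2)
        discord = rf_distance(te_tree, sp_sub)

    if focal_pairs is None:
        rs = sorted(reps)
        focal_pairs = [(a, b) for i, a in enumerate(rs) for b in rs[i + 1:]]

    results: dict[tuple[str, str], PairResult] = {}
    for a, b in focal_pairs:
        te_ident = te_k2p = None
        if a in reps and b in reps:
            pair_hits = local_search(reps[a], reps[b], cfg.scan)
            if pair_hits:
                te_ident = max(pair_hits, key=lambda h: h.score).identity
            ga, gb = global_align(reps[a], reps[b],
                                  gap_open=DIVERGENCE_GAP_OPEN,
                                  gap_extend=DIVERGENCE_GAP_EXTEND)
            res = k2p_distance(ga, gb)
            te_k2p = res.K if res.defined else None

        shared = None
        table = None
        if a in reps and b in reps:
            shared, table = _shared_count_bidirectional(
                genomes[a], genomes[b], scans[a], scans[b], cfg)

        patchy = patchiness(pruned, presence, (a, b)) \
            if a in presence and b in presence else None

        T = divergence_time(tree, a, b) if rate is not None else None
        ev = HTTEvidence(
            species_a=a, species_b=b, te_identity=te_ident, te_k2p=te_k2p,
            species_T=T, rate=rate,
            discordant=discord.discordant if discord else None,
            patchy=patchy, shared_count=shared)
        results[(a, b)] = PairResult(ev, call_htt(ev, cfg.caller), table)

    summary = {
        "scans": scans, "presence": presence, "te_tree": te_tree,
        "discordance": discord, "config_manifest": cfg.manifest(),
    }
    return results, summary


def _shared_count_bidirectional(ga, gb, scan_a, scan_b, cfg) -> tuple[int, pd.DataFrame]:
    """Shared-insertion count for a pair; tries the reverse direction when the
    forward one finds nothing shared (loci can be lost to fragmentation)."""
    loci_a = extract_loci(
        ga, [h.interval for h in clean_short_hits(scan_a.hits, cfg.scan.min_hit_len)],
        cfg.locus.pad)
    shared, table = shared_insertion_count(loci_a, gb, cfg.scan, cfg.locus)
    if shared == 0:
        loci_b = extract_loci(
            gb, [h.interval for h in clean_short_hits(scan_b.hits, cfg.scan.min_hit_len)],
            cfg.locus.pad)
        shared_rev, table_rev = shared_insertion_count(loci_b, ga, cfg.scan, cfg.locus)
        if shared_rev > shared:
            return shared_rev, table_rev
    return shared, table
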