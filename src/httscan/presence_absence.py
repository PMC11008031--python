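"""Orthologous-locus presence/absence test.

For each TE insertion, the flanking host sequence (1.5 kb on each side by
default) is searched in a second species' genome.  If both flanks land
co-linearly with roughly a TE-length of sequence between them, the second
species shares the insertion (it predates the split: vertical descent).
If the flanks land directly adjacent — an *empty orthologous site*, with at
most a TSD-sized remnant between them — the insertion postdates the split
and was acquired independently, the signature expected after horizontal
transfer.  Anything else (missing, rearranged or ambiguous flanks) is
unresolved and supports neither call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .homology_search import Hit, clean_short_hits, local_search
from .io_core import GenomeRecord, Interval, LocusConfig, ScanConfig

__all__ = [
    "InsertionLocus", "LocusCall", "extract_loci", "classify_locus",
    "shared_insertion_count",
]


@dataclass(frozen=True)
class InsertionLocus:
    """A TE insertion with its immediately adjacent flanks."""

    locus_id: str
    species: str
    te_interval: Interval
    left_flank: str
    right_flank: str
    pad: int
    left_clipped: bool = False
    right_clipped: bool = False


@dataclass(frozen=True)
class LocusCall:
    locus_id: str
    status: str                       # shared | absent_empty_site | unresolved
    reason: str = ""
    target_contig: str | None = None
    left_hit: Hit | None = None
    right_hit: Hit | None = None
    inter_flank_gap: int | None = None


def extract_loci(
    genome: GenomeRecord,
    te_intervals: Sequence[Interval],
    pad: int = 1500,
    species: str | None = None,
) -> list[InsertionLocus]:
    """One locus per interval, flanks clipped (and flagged) at contig edges."""
    if pad <= 0:
        raise ValueError("pad must be positive")
    out = []
    L = len(genome.sequence)
    for i, iv in enumerate(te_intervals):
        if iv.end > L:
            raise ValueError(
                f"interval [{iv.start},{iv.end}) beyond contig of length {L}")
        ls = max(0, iv.start - pad)
        re_ = min(L, iv.end + pad)
        out.append(InsertionLocus(
            locus_id=f"{genome.species_id}:{iv.seq_id}:{iv.start}-{iv.end}",
            species=species or genome.species_id,
            te_interval=iv,
            left_flank=genome.sequence[ls:iv.start],
            right_flank=genome.sequence[iv.end:re_],
            pad=pad,
            left_clipped=ls > iv.start - pad,
            right_clipped=re_ < iv.end + pad,
        ))
    return out


def _flank_hits(flank: str, target: GenomeRecord, scan_cfg: ScanConfig,
                locus_cfg: LocusConfig) -> list[Hit]:
    hits = clean_short_hits(local_search(flank, target, scan_cfg),
                            locus_cfg.min_flank_hit)
    return [h for h in hits if h.identity >= locus_cfg.min_flank_identity]


def classify_locus(
    locus: InsertionLocus,
    target: GenomeRecord,
    scan_config: ScanConfig | None = None,
    locus_config: LocusConfig | None = None,
) -> LocusCall:
    """Decide shared / absent-empty-site / unresolved for one locus.

    Both flanks are searched in the target; the best-scoring co-linear pair
    (same contig, same strand, correct order) sets the inter-flank gap.  The
    call is *shared* when the gap is within ``[0.5, 1.5] * |TE|``, and
    *absent_empty_site* when the gap is at most ``empty_gap_max`` bp (small
    negative gaps arise from the TSD remnant overlapping both flanks).
    """
    scan_cfg = scan_config or ScanConfig()
    cfg = locus_config or LocusConfig()
    te_len = len(locus.te_interval)

    if min(len(locus.left_flank), len(locus.right_flank)) < cfg.min_flank_len:
        return LocusCall(locus.locus_id, "unresolved", "flank_too_short")

    lhits = _flank_hits(locus.left_flank, target, scan_cfg, cfg)
    rhits = _flank_hits(locus.right_flank, target, scan_cfg, cfg)
    if not lhits or not rhits:
        return LocusCall(locus.locus_id, "unresolved", "flank_not_found")

    max_pair_gap = int(3 * te_len)
    best = None
    for hl in lhits:
        for hr in rhits:
            if (hl.interval.seq_id != hr.interval.seq_id
                    or hl.strand != hr.strand):
                continue
            if hl.strand == "+":
                gap = hr.interval.start - hl.interval.end
            else:
                gap = hl.interval.start - hr.interval.end
            if gap < -cfg.pair_gap_slack or gap > max_pair_gap:
                continue
            score = hl.score + hr.score
            if best is None or score > best[0]:
                best = (score, hl, hr, gap)
    if best is None:
        return LocusCall(locus.locus_id, "unresolved", "no_colinear_pair")

    _, hl, hr, gap = best
    if cfg.shared_gap_lo * te_len <= gap <= cfg.shared_gap_hi * te_len:
        status, reason = "shared", ""
    elif gap <= cfg.empty_gap_max:
        status, reason = "absent_empty_site", ""
    else:
        status, reason = "unresolved", "gap_ambiguous"
    return LocusCall(locus.locus_id, status, reason, hl.interval.seq_id,
                     hl, hr, gap)


def shared_insertion_count(
    loci: Sequence[InsertionLocus],
    target: GenomeRecord,
    scan_config: ScanConfig | None = None,
    locus_config: LocusConfig | None = None,
) -> tuple[int, pd.DataFrame]:
    """Count loci of one species shared by another genome, with a call table."""
    rows = []
    shared = 0
    for locus in loci:
        call = classify_locus(locus, target, scan_config, locus_config)
        shared += call.status == "shared"
        rows.append({
            "locus_id": locus.locus_id,
            "status": call.status,
            "reason": call.reason,
            "target_contig": call.target_contig,
            "left_start": call.left_hit.interval.start if call.left_hit else None,
            "left_end": call.left_hit.interval.end if call.left_hit else None,
            "right_start": call.right_hit.interval.start if call.right_hit else None,
            "right_end": call.right_hit.interval.end if call.right_hit else None,
            "gap": call.inter_flank_gap,
        })
    table = pd.DataFrame(rows, columns=[
        "locus_id", "status", "reason", "target_contig", "left_start",
        "left_end", "right_start", "right_end", "gap"])
    return shared, table
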