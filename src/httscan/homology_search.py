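"""Seed-and-extend local nucleotide homology search.

Finds copies of a TE query in a genome with the sensitive word size the
pipeline standardises on (exact 7-mer seeds, match/mismatch +4/-5), then
extends seeds in two stages: an ungapped X-drop extension that must reach a
trigger score to open a window, followed by a full affine-gap Smith-Waterman
over the window.  On desk-scale windows the reported top-hit score is exactly
the exhaustive Smith-Waterman optimum with the same scoring scheme, which is
what the test suite asserts against an independent aligner.

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(BLAST-style).  Identity is matches over aligned columns excluding gap
columns; ``aligned_length`` counts all columns including gaps.  E-values are
not computed; a raw score threshold stands in for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from . import _seq
from .io_core import GenomeRecord, Interval, ScanConfig

__all__ = [
    "Hit", "PIM", "local_search", "filter_candidates", "clean_short_hits",
    "pairwise_identity_matrix",
]


@dataclass(frozen=True)
class Hit:
    """One local alignment of the query against a genome."""

    interval: Interval
    qstart: int
    qend: int
    score: int
    identity: float
    aligned_length: int          # alignment columns, gaps included
    matches: int = 0

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def genome_span(self) -> int:
        return len(self.interval)

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart


@dataclass
class PIM:
    """Symmetric pairwise-identity matrix over a set of sequences."""

    labels: list[str]
    matrix: np.ndarray

    def identity(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

_NEG = -1_000_000_000


@njit(cache=True)
def _sw_fill(q, g, match, mismatch, go, ge):
    """Affine local DP; returns best score, end cell, and pointer matrices."""
    m = q.shape[0]
    n = g.shape[0]
    Hprev = np.zeros(n + 1, np.int32)
    Hcur = np.zeros(n + 1, np.int32)
    Fprev = np.full(n + 1, _NEG, np.int32)
    Fcur = np.full(n + 1, _NEG, np.int32)
    pH = np.zeros((m + 1, n + 1), np.uint8)
    pE = np.zeros((m + 1, n + 1), np.uint8)
    pF = np.zeros((m + 1, n + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        Hcur[0] = 0
        e = _NEG
        qi = q[i - 1]
        for j in range(1, n + 1):
            eh = Hcur[j - 1] + go + ge
            ee = e + ge
            if ee > eh:
                e = ee
                pE[i, j] = 1
            else:
                e = eh
                pE[i, j] = 0
            fh = Hprev[j] + go + ge
            ff = Fprev[j] + ge
            if ff > fh:
                f = ff
                pF[i, j] = 1
            else:
                f = fh
                pF[i, j] = 0
            Fcur[j] = f
            gj = g[j - 1]
            if qi == gj and qi < 4:
                s = match
            else:
                s = mismatch
            d = Hprev[j - 1] + s
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            Hcur[j] = h
            pH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = Hprev
        Hprev = Hcur
        Hcur = tmp
        tmpf = Fprev
        Fprev = Fcur
        Fcur = tmpf
    return best, bi, bj, pH, pE, pF


@njit(cache=True)
def _sw_score(q, g, match, mismatch, go, ge):
    """Score-only affine local DP (rolling rows); returns best score and end cell."""
    m = q.shape[0]
    n = g.shape[0]
    Hprev = np.zeros(n + 1, np.int32)
    Hcur = np.zeros(n + 1, np.int32)
    Fprev = np.full(n + 1, _NEG, np.int32)
    Fcur = np.full(n + 1, _NEG, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        Hcur[0] = 0
        e = _NEG
        qi = q[i - 1]
        for j in range(1, n + 1):
            eh = Hcur[j - 1] + go + ge
            ee = e + ge
            e = ee if ee > eh else eh
            fh = Hprev[j] + go + ge
            ff = Fprev[j] + ge
            f = ff if ff > fh else fh
            Fcur[j] = f
            gj = g[j - 1]
            if qi == gj and qi < 4:
                s = match
            else:
                s = mismatch
            d = Hprev[j - 1] + s
            h = 0
            if d > h:
                h = d
            if e > h:
                h = e
            if f > h:
                h = f
            Hcur[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = Hprev
        Hprev = Hcur
        Hcur = tmp
        tmpf = Fprev
        Fprev = Fcur
        Fcur = tmpf
    return best, bi, bj


@njit(cache=True)
def _sw_traceback(pH, pE, pF, q, g, bi, bj):
    """Walk pointers from the best cell; returns start cell and column counts."""
    i = bi
    j = bj
    matches = 0
    mismatches = 0
    gapcols = 0
    while True:
        p = pH[i, j]
        if p == 0:
            break
        if p == 1:
            if q[i - 1] == g[j - 1] and q[i - 1] < 4:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif p == 2:
            while True:
                gapcols += 1
                frome = pE[i, j]
                j -= 1
                if frome == 0:
                    break
        else:
            while True:
                gapcols += 1
                fromf = pF[i, j]
                i -= 1
                if fromf == 0:
                    break
    return i, j, matches, mismatches, gapcols


@njit(cache=True)
def _ungapped_extend(q, g, qp, gp, k, match, mismatch, xdrop):
    """X-drop ungapped extension around an exact k-mer seed.

    Returns (best score, genome start examined, genome end examined) so the
    caller can avoid re-extending later seeds on the same diagonal.
    """
    score = k * match
    # right
    best_r = 0
    cur = 0
    i = qp + k
    j = gp + k
    nq = q.shape[0]
    ng = g.shape[0]
    while i < nq and j < ng:
        if q[i] == g[j] and q[i] < 4:
            cur += match
        else:
            cur += mismatch
        if cur > best_r:
            best_r = cur
        if best_r - cur > xdrop:
            break
        i += 1
        j += 1
    gend = j
    # left
    best_l = 0
    cur = 0
    i = qp - 1
    j = gp - 1
    while i >= 0 and j >= 0:
        if q[i] == g[j] and q[i] < 4:
            cur += match
        else:
            cur += mismatch
        if cur > best_l:
            best_l = cur
        if best_l - cur > xdrop:
            break
        i -= 1
        j -= 1
    gstart = j + 1
    return score + best_r + best_l, gstart, gend


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer code per k-mer start; positions containing N get code -1."""
    n = arr.shape[0]
    if n < k:
        return np.empty(0, np.int64)
    m = n - k + 1
    codes = np.zeros(m, np.int64)
    valid = np.ones(m, bool)
    for j in range(k):
        col = arr[j:m + j]
        codes = codes * 4 + col
        valid &= col < 4
    codes[~valid] = -1
    return codes


def _seed_windows(qarr: np.ndarray, garr: np.ndarray, cfg: ScanConfig) -> list[tuple[int, int]]:
    """Genome windows worth a gapped alignment, from triggered seed extensions."""
    k = cfg.word_size
    qcodes = _kmer_codes(qarr, k)
    gcodes = _kmer_codes(garr, k)
    if qcodes.size == 0 or gcodes.size == 0:
        return []
    order = np.argsort(qcodes, kind="stable")
    sq = qcodes[order]
    lo = np.searchsorted(sq, gcodes, "left")
    hi = np.searchsorted(sq, gcodes, "right")
    hits_at = np.nonzero((hi > lo) & (gcodes >= 0))[0]

    qlen = qarr.shape[0]
    covered: dict[int, int] = {}       # diagonal -> genome pos already examined up to
    regions: list[tuple[int, int]] = []
    for gp in hits_at:
        for t in range(lo[gp], hi[gp]):
            qp = int(order[t])
            diag = gp - qp
            if covered.get(diag, -1) >= gp:
                continue
            score, gs, ge = _ungapped_extend(
                qarr, garr, qp, int(gp), k, cfg.match, cfg.mismatch, cfg.xdrop)
            covered[diag] = max(int(gp) + k, ge)
            if score >= cfg.ungapped_trigger:
                # pad by the query not yet consumed by the ungapped extension,
                # plus slack for gapped wobble
                qs = qp - (int(gp) - gs)
                qe = qp + (ge - int(gp))
                regions.append((gs - qs - 150, ge + (qlen - qe) + 150))

    if not regions:
        return []
    glen = garr.shape[0]
    regions = [(max(0, s), min(glen, e)) for s, e in regions]
    regions.sort()
    merged = [list(regions[0])]
    for s, e in regions[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# search driver
# ---------------------------------------------------------------------------

_TRACE_SLACK = 400   # genome slack beyond query length when re-filling for traceback


def _extract_hits_in_window(
    qarr: np.ndarray, warr: np.ndarray, woff: int, cfg: ScanConfig,
) -> list[dict]:
    """Repeatedly pull the best local alignment out of a window (then split).

    A fast score-only DP locates the optimum; the pointer-matrix DP is then
    re-run on a tight rectangle around it for the traceback.
    """
    out: list[dict] = []
    stack: list[tuple[int, int]] = [(0, warr.shape[0])]
    min_len = max(cfg.word_size, 20)
    while stack:
        s, e = stack.pop()
        if e - s < min_len:
            continue
        best, bi, bj = _sw_score(
            qarr, warr[s:e], cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend)
        if best < cfg.min_score:
            continue
        g_lo = max(0, bj - bi - _TRACE_SLACK)
        sub = warr[s + g_lo:s + bj]
        best2, bi2, bj2, pH, pE, pF = _sw_fill(
            qarr[:bi], sub, cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend)
        if best2 != best:     # rectangle clipped the optimum; fall back to full window
            g_lo = 0
            sub = warr[s:e]
            best2, bi2, bj2, pH, pE, pF = _sw_fill(
                qarr, sub, cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend)
        i0, j0, matches, mismatches, gapcols = _sw_traceback(
            pH, pE, pF, qarr, sub, bi2, bj2)
        out.append({
            "score": int(best2),
            "qstart": i0, "qend": bi2,
            "gstart": woff + s + g_lo + j0, "gend": woff + s + g_lo + bj2,
            "matches": matches, "mismatches": mismatches, "gapcols": gapcols,
        })
        stack.append((s, s + g_lo + j0))
        stack.append((s + g_lo + bj2, e))
    return out


def merge_hits(hits: list[Hit], overlap_frac: float = 0.5) -> list[Hit]:
    """Drop a hit when it overlaps a better same-strand hit by >= overlap_frac."""
    kept: list[Hit] = []
    for h in sorted(hits, key=lambda x: (-x.score, x.interval.start)):
        redundant = False
        for k in kept:
            if k.interval.seq_id != h.interval.seq_id or k.strand != h.strand:
                continue
            ov = min(k.interval.end, h.interval.end) - max(k.interval.start, h.interval.start)
            if ov > 0 and ov >= overlap_frac * min(len(k.interval), len(h.interval)):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda x: (x.interval.seq_id, x.interval.start))
    return kept


def local_search(
    query: str,
    genome: GenomeRecord | str,
    config: ScanConfig | None = None,
    seq_id: str = "seq",
) -> list[Hit]:
    """Search both strands of a genome for local alignments to ``query``.

    Returns hits sorted by genomic position; overlapping same-strand hits are
    merged to the best-scoring one.  Minus-strand hits carry genome (plus
    strand) coordinates with ``strand == '-'``; query spans are always in
    query coordinates.
    """
    cfg = config or ScanConfig()
    if isinstance(genome, GenomeRecord):
        gseq, seq_id = genome.sequence, genome.seq_id
    else:
        gseq = genome
    if len(query) < cfg.word_size:
        raise ValueError(
            f"query length {len(query)} < word size {cfg.word_size}")

    qarr = _seq.encode(query)
    hits: list[Hit] = []
    for strand in "+-":
        garr = _seq.encode(gseq) if strand == "+" else _seq.revcomp_arr(_seq.encode(gseq))
        glen = garr.shape[0]
        for ws, we in _seed_windows(qarr, garr, cfg):
            for raw in _extract_hits_in_window(qarr, garr[ws:we], ws, cfg):
                gstart, gend = raw["gstart"], raw["gend"]
                if strand == "-":
                    gstart, gend = glen - raw["gend"], glen - raw["gstart"]
                cols = raw["matches"] + raw["mismatches"]
                ident = raw["matches"] / cols if cols else 0.0
                hits.append(Hit(
                    interval=Interval(seq_id, gstart, gend, strand),
                    qstart=raw["qstart"], qend=raw["qend"],
                    score=raw["score"], identity=ident,
                    aligned_length=cols + raw["gapcols"],
                    matches=raw["matches"],
                ))
    return merge_hits(hits, cfg.overlap_merge_frac)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_candidates(
    hits: Sequence[Hit],
    query_length: int,
    min_identity: float = 0.75,
    min_coverage: float = 0.90,
) -> list[Hit]:
    """Retain hits passing the identity and query-coverage cutoffs."""
    return [
        h for h in hits
        if h.identity >= min_identity
        and (h.qend - h.qstart) / query_length >= min_coverage
    ]


def clean_short_hits(hits: Sequence[Hit], min_len: int = 100) -> list[Hit]:
    """Remove hits whose aligned genomic span is under ``min_len`` bp."""
    return [h for h in hits if len(h.interval) >= min_len]


# ---------------------------------------------------------------------------
# pairwise identity matrix
# ---------------------------------------------------------------------------

def pairwise_identity_matrix(
    seqs: Sequence[str],
    labels: Sequence[str] | None = None,
    config: ScanConfig | None = None,
) -> PIM:
    """Best-local-alignment identity for every sequence pair.

    Identity is matches over aligned columns with gap columns excluded from
    the denominator; pairs with no alignment above threshold get 0.  The
    matrix is symmetric with unit diagonal.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for a PIM")
    cfg = config or ScanConfig()
    if labels is None:
        labels = [f"seq{i}" for i in range(len(seqs))]
    n = len(seqs)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            hits = local_search(seqs[i], seqs[j], cfg, seq_id=str(labels[j]))
            ident = max(hits, key=lambda h: h.score).identity if hits else 0.0
            mat[i, j] = mat[j, i] = ident
    return PIM(list(labels), mat)
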