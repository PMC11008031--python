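"""Structural hallmarks of hAT-style DNA transposons.

A full-length hAT copy ends in ~15 bp terminal inverted repeats (the 5'
terminus matches the reverse complement of the 3' terminus) and sits between
two identical copies of an ~8 bp target site duplication created by the
integration machinery.  Copies lacking either hallmark, or covering less
than 90% of the family consensus, are classified as fragments.  A 6-frame
ORF screen flags copies that could still encode a transposase (>= 600 aa).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _seq
from ._align import global_align_linear
from .io_core import StructureConfig

__all__ = [
    "TIRReport", "TSDReport", "CopyClassification",
    "find_tirs", "find_tsd", "classify_copy", "longest_orf_aa",
]


@dataclass(frozen=True)
class TIRReport:
    found: bool
    length: int = 0
    mismatches: int = 0
    left_arm: str = ""
    right_arm: str = ""


@dataclass(frozen=True)
class TSDReport:
    found: bool
    length: int = 0
    left_site: str = ""
    right_site: str = ""


@dataclass(frozen=True)
class CopyClassification:
    status: str                      # "full_length" | "fragment"
    consensus_coverage: float
    tir: TIRReport
    tsd: TSDReport
    orf_aa: int = 0

    @property
    def coding_capable(self) -> bool:
        return self.orf_aa >= 600


def find_tirs(
    copy_seq: str,
    min_tir_len: int = 10,
    max_tir_len: int = 30,
    max_mismatch_frac: float = 0.2,
) -> TIRReport:
    """Longest terminal inverted repeat within the length window.

    Reports the largest L in ``[min_tir_len, max_tir_len]`` for which the
    first L bases match the reverse complement of the last L bases with at
    most ``floor(max_mismatch_frac * L)`` mismatches.  Positions involving N
    always count as mismatches.
    """
    if len(copy_seq) <= 2 * min_tir_len:
        raise ValueError(
            f"sequence of {len(copy_seq)} bp too short for TIR search "
            f"(need > {2 * min_tir_len})")
    arr = _seq.encode(copy_seq)
    hi = min(max_tir_len, len(copy_seq) // 2)
    for L in range(hi, min_tir_len - 1, -1):
        left = arr[:L]
        right_rc = _seq.revcomp_arr(arr[-L:])
        mm = int(((left != right_rc) | (left >= 4) | (right_rc >= 4)).sum())
        if mm <= int(max_mismatch_frac * L):
            return TIRReport(
                True, L, mm, _seq.decode(left), _seq.decode(arr[-L:]))
    return TIRReport(False)


def find_tsd(
    left_flank: str,
    right_flank: str,
    tsd_min: int = 4,
    tsd_max: int = 12,
) -> TSDReport:
    """Longest exact target-site duplication flanking an insertion.

    The TSD is the longest k in ``[tsd_min, tsd_max]`` such that the last k
    bases of the left flank equal the first k bases of the right flank
    exactly (longest k wins ties).
    """
    if len(left_flank) < tsd_max or len(right_flank) < tsd_max:
        raise ValueError(
            f"flanks must be at least tsd_max={tsd_max} bp "
            f"(got {len(left_flank)} and {len(right_flank)})")
    for k in range(tsd_max, tsd_min - 1, -1):
        if left_flank[-k:] == right_flank[:k]:
            return TSDReport(True, k, left_flank[-k:], right_flank[:k])
    return TSDReport(False)


def consensus_coverage(copy_seq: str, consensus: str,
                       config: StructureConfig | None = None) -> float:
    """Fraction of consensus positions aligned to copy bases in a global
    alignment (columns where both sequences contribute a base)."""
    cfg = config or StructureConfig()
    a, b = global_align_linear(copy_seq, consensus, gap=cfg.gap_linear)
    aligned = sum(1 for ca, cb in zip(a, b) if ca != "-" and cb != "-")
    return aligned / len(consensus)


def classify_copy(
    copy_seq: str,
    left_flank: str,
    right_flank: str,
    consensus: str,
    config: StructureConfig | None = None,
) -> CopyClassification:
    """Classify a detected copy as full-length or fragment.

    Full length requires a TIR, an exact TSD, and >= 90% consensus coverage
    (by default).  Flanks too short for the TSD window simply yield a
    not-found TSD rather than an error, since clipped contig-edge loci are
    legitimate fragments.
    """
    if not consensus:
        raise ValueError("empty consensus")
    cfg = config or StructureConfig()
    cov = consensus_coverage(copy_seq, consensus, cfg)
    try:
        tir = find_tirs(copy_seq, cfg.min_tir_len, cfg.max_tir_len,
                        cfg.max_mismatch_frac)
    except ValueError:
        tir = TIRReport(False)
    try:
        tsd = find_tsd(left_flank, right_flank, cfg.tsd_min, cfg.tsd_max)
    except ValueError:
        tsd = TSDReport(False)
    orf = longest_orf_aa(copy_seq, require_atg=cfg.require_atg)
    full = tir.found and tsd.found and cov >= cfg.full_length_coverage
    return CopyClassification(
        "full_length" if full else "fragment", cov, tir, tsd, orf)


_STOP = {"TAA", "TAG", "TGA"}


def longest_orf_aa(copy_seq: str, require_atg: bool = True) -> int:
    """Longest open reading frame, in residues, over all 6 frames.

    Counts codons from the first ATG of a stop-free stretch (or from the
    stretch start when ``require_atg`` is false) up to the codon before the
    stop; unterminated trailing stretches count too.  ``"ATGAAATAA"`` scores
    2 (Met-Lys).
    """
    best = 0
    for seq in (copy_seq, _seq.revcomp(copy_seq)):
        for frame in range(3):
            start = None          # codon index opening the current ORF
            idx = 0
            for pos in range(frame, len(seq) - 2, 3):
                codon = seq[pos:pos + 3]
                if codon in _STOP:
                    if start is not None:
                        best = max(best, idx - start)
                    start = None
                elif start is None and (codon == "ATG" or not require_atg):
                    start = idx
                idx += 1
            if start is not None:
                best = max(best, idx - start)
    return best
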