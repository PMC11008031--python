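"""Global pairwise alignment helper (Bio.Align backed).

One scoring scheme is used pipeline-wide: match +4, mismatch -5 (the same
scores as the local search), with either the affine gap cost of the local
search or the linear gap used for consensus-coverage measurement.  The cost
of a gap of length L is ``gap_open + L * gap_extend``; Bio.Align's
open/extend convention differs by one extension, which is adjusted here.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align


@lru_cache(maxsize=8)
def _aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open + gap_extend
    al.extend_gap_score = gap_extend
    return al


def global_align(
    a: str,
    b: str,
    match: int = 4,
    mismatch: int = -5,
    gap_open: int = -8,
    gap_extend: int = -2,
) -> tuple[str, str]:
    """Best global alignment of two sequences as a pair of gapped strings."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _aligner(match, mismatch, gap_open, gap_extend).align(a, b)[0]
    return str(aln[0]), str(aln[1])


def global_align_linear(a: str, b: str, match: int = 4, mismatch: int = -5,
                        gap: int = -6) -> tuple[str, str]:
    """Global alignment with a linear gap cost (used for coverage measurement)."""
    return global_align(a, b, match, mismatch, gap_open=0, gap_extend=gap)
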