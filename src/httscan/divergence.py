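"""Kimura 2-parameter divergence and repeat landscapes.

The K2P distance separates transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q) among comparable aligned columns and estimates

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

in expected substitutions per site.  The estimate saturates: when
``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0`` the distance is undefined and the
result is flagged rather than silently dropped.

A divergence landscape is the bp-weighted histogram of copy-to-consensus
divergence for a TE family: each copy contributes its comparable aligned
columns to the bin of its K (as a percentage, CpG-naive).  Young bursts of
activity — including recent horizontal arrivals — appear as mass near 0%,
old vertically inherited families as broad peaks at high divergence.
Copies dominated by short tandem repeats can be excluded, and saturated
copies are routed to the top bin so that total bp is conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from . import _seq
from ._align import global_align
from .io_core import LandscapeConfig

# Gap scores for divergence-measurement alignments.  The K2P model has no
# indels; permissive gaps let the aligner pair identical letters across true
# substitutions ("gap attraction"), deflating old divergences, so gaps are
# penalised much harder here than in homology search.
DIVERGENCE_GAP_OPEN = -16
DIVERGENCE_GAP_EXTEND = -4


def _divergence_align(a: str, b: str) -> tuple[str, str]:
    return global_align(a, b, gap_open=DIVERGENCE_GAP_OPEN,
                        gap_extend=DIVERGENCE_GAP_EXTEND)

__all__ = [
    "K2PResult", "DivergenceLandscape", "k2p_distance", "is_simple_repeat",
    "build_landscape", "detect_peaks", "copy_divergences",
]


@dataclass(frozen=True)
class K2PResult:
    P: float                 # transition proportion
    Q: float                 # transversion proportion
    K: float                 # K2P distance (nan when undefined)
    sites: int               # comparable columns (no gap, no N)
    defined: bool = True


def k2p_distance(aligned_a: str, aligned_b: str) -> K2PResult:
    """K2P distance from two equal-length aligned strings.

    Columns with a gap or N in either sequence are excluded from the
    comparable-site count; zero comparable sites is an error.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned strings differ in length ({len(aligned_a)} vs {len(aligned_b)})")
    a = _seq.encode(aligned_a.replace("-", "N"))
    b = _seq.encode(aligned_b.replace("-", "N"))
    ok = (a < 4) & (b < 4)
    sites = int(ok.sum())
    if sites == 0:
        raise ValueError("no comparable sites (all columns gapped or ambiguous)")
    diff = ok & (a != b)
    ts = diff & ((a ^ b) == 2)          # A<->G or C<->T
    P = float(ts.sum()) / sites
    Q = float(diff.sum() - ts.sum()) / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(P, Q, float("nan"), sites, defined=False)
    return K2PResult(P, Q, -0.5 * math.log(w1 * math.sqrt(w2)), sites)


def is_simple_repeat(seq: str, max_period: int = 6, cov_frac: float = 0.8) -> bool:
    """True when > ``cov_frac`` of the sequence lies in tandem repeats of
    period <= ``max_period`` (found by a direct autocorrelation scan)."""
    arr = _seq.encode(seq)
    n = arr.shape[0]
    if n == 0:
        return False
    covered = np.zeros(n, bool)
    for p in range(1, max_period + 1):
        if n <= p:
            break
        m = (arr[:-p] == arr[p:]) & (arr[:-p] < 4)
        # runs of True of length >= p cover [start, end + p)
        idx = np.flatnonzero(np.diff(np.concatenate(([False], m, [False])).astype(np.int8)))
        for s, e in zip(idx[::2], idx[1::2]):
            if e - s >= p:
                covered[s:e + p] = True
    return covered.mean() > cov_frac


@dataclass
class DivergenceLandscape:
    """bp-weighted histogram of divergence (percent bins) for one family."""

    bin_width: float
    bins: np.ndarray                      # aligned bp per bin; last bin = saturation
    family: str = "TE"
    n_copies: int = 0
    n_excluded_simple: int = 0
    n_undefined: int = 0

    @property
    def total_bp(self) -> float:
        return float(self.bins.sum())

    def bin_edges(self) -> np.ndarray:
        return np.arange(len(self.bins) + 1) * self.bin_width

    def mode_bin(self) -> tuple[float, float]:
        """(lower percent edge, bp) of the heaviest bin."""
        i = int(np.argmax(self.bins))
        return i * self.bin_width, float(self.bins[i])

    def to_rows(self) -> list[tuple[float, float, float]]:
        e = self.bin_edges()
        return [(float(e[i]), float(e[i + 1]), float(b))
                for i, b in enumerate(self.bins)]


def copy_divergences(
    copies: Sequence[str], consensus: str,
) -> list[K2PResult]:
    """K2P of each copy against the family consensus via global alignment."""
    out = []
    for c in copies:
        a, b = _divergence_align(c, consensus)
        out.append(k2p_distance(a, b))
    return out


def build_landscape(
    copies: Sequence[str],
    consensus: str,
    config: LandscapeConfig | None = None,
    family: str = "TE",
) -> DivergenceLandscape:
    """Bin each copy's aligned bp by its divergence to the consensus.

    Simple-repeat-dominated copies are excluded when the config says so;
    copies with an undefined (saturated) K2P go to the top bin so that the
    binned total equals the total comparable bp of included copies exactly.
    """
    cfg = config or LandscapeConfig()
    n_bins = int(round(cfg.max_percent / cfg.bin_width))
    bins = np.zeros(n_bins)
    n_simple = n_undef = n_used = 0
    for c in copies:
        if cfg.exclude_simple and is_simple_repeat(
                c, cfg.simple_max_period, cfg.simple_cov_frac):
            n_simple += 1
            continue
        a, b = _divergence_align(c, consensus)
        res = k2p_distance(a, b)
        n_used += 1
        if not res.defined:
            bins[-1] += res.sites
            n_undef += 1
            continue
        idx = min(int(res.K * 100.0 / cfg.bin_width), n_bins - 1)
        bins[idx] += res.sites
    return DivergenceLandscape(cfg.bin_width, bins, family, n_used, n_simple, n_undef)


def detect_peaks(
    landscape: DivergenceLandscape,
    min_prominence_bp: float | None = None,
) -> list[tuple[float, float]]:
    """Local maxima of the binned series with at least the given prominence.

    Returns (bin lower edge in percent, bp) sorted by bin.  The series is
    zero-padded so peaks in the first and last bin are detectable.
    """
    if landscape.bins.size == 0:
        raise ValueError("empty landscape")
    prom = (min_prominence_bp if min_prominence_bp is not None
            else LandscapeConfig().min_peak_prominence_bp)
    padded = np.concatenate(([0.0], landscape.bins, [0.0]))
    idx, _ = find_peaks(padded, prominence=prom)
    return [(float((i - 1) * landscape.bin_width), float(padded[i])) for i in idx]
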