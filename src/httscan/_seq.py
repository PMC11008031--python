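"""Low-level DNA sequence utilities shared across the package.

Sequences cross module boundaries as plain uppercase strings over
``{A, C, G, T, N}``; hot loops work on ``numpy.uint8`` code arrays with
A=0, C=1, G=2, T=3 and N=4.  Transitions are A<->G and C<->T, i.e. codes
differing by 2 (mod 4); anything involving N is never counted as a match.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

_COMP_STR = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (any non-ACGT letter becomes N)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def clean(seq: str) -> str:
    """Uppercase and collapse every non-ACGT IUPAC letter to N."""
    return decode(encode(seq))


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr][::-1]


def random_seq_arr(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    """Random i.i.d. sequence at the given GC fraction (no Ns)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    return decode(random_seq_arr(rng, length, gc))


def is_transition(a: int, b: int) -> bool:
    """A<->G or C<->T (codes differ by exactly 2)."""
    return a != b and a < 4 and b < 4 and abs(a - b) == 2
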