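"""Vectorized 2-bit k-mer encoding shared by the mapper, assembler, and
TNF computation.

K-mers are packed big-endian into int64 (k <= 31); the canonical form
of a k-mer is the numeric minimum of its forward and reverse-complement
codes. Positions whose window contains a non-ACGT base are masked out.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_ALPHABET = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 array with A,C,G,T -> 0..3 and anything else 4."""
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_table(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All k-mers of an encoded sequence.

    Returns (canonical codes int64, forward-is-canonical bool, valid
    bool), each of length len(arr) - k + 1 (empty when too short).
    """
    n = len(arr) - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, np.empty(0, dtype=bool), np.empty(0, dtype=bool)
    W = sliding_window_view(arr, k)
    valid = (W != 4).all(axis=1)
    Wl = W.astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = Wl @ powers
    rc = (3 - Wl[:, ::-1]) @ powers
    canon = np.minimum(fwd, rc)
    forward = fwd <= rc
    return canon, forward, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed k-mer codes."""
    out = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (c & 3))
        c >>= 2
    return out


def decode(code: int, k: int) -> str:
    """Packed code -> k-mer string."""
    chars = []
    for _ in range(k):
        chars.append(_ALPHABET[code & 3])
        code >>= 2
    return "".join(reversed(chars))
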