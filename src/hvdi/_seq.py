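"""Low-level nucleotide sequence helpers shared across modules.

Sequences are plain Python strings over {A,C,G,T} (ambiguity codes are only
tolerated where a module explicitly allows them).  For inner loops, sequences
are 2-bit encoded into ``uint8`` numpy arrays (A=0, C=1, G=2, T=3) and k-mers
are packed into ``uint64`` codes.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCATGCA")


def encode(seq: str) -> np.ndarray:
    """2-bit encode a sequence; raises on characters outside {A,C,G,T}."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = chr(np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[arr > 3][0])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def has_ambiguous(seq: str) -> bool:
    """True if the sequence contains any character outside {A,C,G,T}."""
    arr = _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    return bool(arr.size and arr.max() > 3)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of identical characters."""
    if not seq:
        return 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if arr.size == 1:
        return 1
    breaks = np.flatnonzero(arr[1:] != arr[:-1])
    edges = np.concatenate(([-1], breaks, [arr.size - 1]))
    return int(np.diff(edges).max())


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed uint64 codes of all k-mers of a 2-bit encoded sequence.

    Returns an array of length ``len(codes) - k + 1`` (empty if shorter).
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    for j in range(k):
        out <<= np.uint64(2)
        out |= c64[j : j + n]
    return out


def rc_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed codes of the reverse complement of each k-mer window."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    three = np.uint64(3)
    for j in range(k - 1, -1, -1):
        out <<= np.uint64(2)
        out |= three - c64[j : j + n]
    return out
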