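"""Vectorized 2-bit k-mer encoding shared by the aligner and the sex-contig scan.

k-mers up to k=31 are packed into uint64 codes (2 bits per base). Windows
containing any non-ACGT character are marked invalid and never emitted.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Map a DNA string to uint8 base codes (A=0..T=3, anything else 4)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def kmer_codes(base_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mer codes for every window plus a validity mask.

    Returns (codes, valid) of length ``len(base_codes) - k + 1``; windows
    overlapping a non-ACGT base are invalid (their code is meaningless).
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    n = base_codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    c = base_codes.astype(np.uint64)
    ok = base_codes < 4
    code = np.zeros(n, np.uint64)
    valid = np.ones(n, bool)
    two = np.uint64(2)
    for j in range(k):
        code = (code << two) | (c[j:j + n] & np.uint64(3))
        valid &= ok[j:j + n]
    return code, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mer codes."""
    rc = np.zeros_like(codes)
    c = codes.copy()
    two, three = np.uint64(2), np.uint64(3)
    for _ in range(k):
        rc = (rc << two) | ((~c) & three)
        c = c >> two
    return rc


def canonical_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-collapsed) codes and a forward-is-canonical mask."""
    rc = revcomp_codes(codes, k)
    fwd = codes <= rc
    return np.where(fwd, codes, rc), fwd


def decode(code: int, k: int) -> str:
    """Unpack one k-mer code back to its DNA string (test/debug helper)."""
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = _BASES[code & 3]
        code >>= 2
    return out.decode()


def sequence_kmers(seq: str, k: int, canonical: bool = True):
    """All valid k-mer codes of one sequence with their start positions.

    Returns (codes, positions, fwd_mask); with ``canonical`` the codes are
    strand-collapsed and fwd_mask says whether the forward orientation was
    the canonical one.
    """
    codes, valid = kmer_codes(encode(seq), k)
    pos = np.flatnonzero(valid)
    codes = codes[pos]
    if canonical:
        codes, fwd = canonical_codes(codes, k)
    else:
        fwd = np.ones(codes.size, bool)
    return codes, pos.astype(np.int64), fwd
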