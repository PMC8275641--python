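"""Canonical k-mer primitives.

k-mers over the ACGT alphabet are packed two bits per base into a Python /
numpy 64-bit integer (A=0, C=1, G=2, T=3), so unsigned comparison of the
packed form is identical to lexicographic comparison of the sequence.  The
canonical form of a k-mer is the smaller of the k-mer and its reverse
complement; canonical k-mers make every operation downstream (graph
construction, read threading) strand-symmetric.  k is limited to 31.
"""

from __future__ import annotations

import numpy as np

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = "ACGT"

COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


def encode_kmer(seq: str) -> int:
    """Pack a k-mer (k <= 31, ACGT only) into an integer."""
    if len(seq) > 31:
        raise ValueError("k-mer longer than 31 bases")
    code = 0
    for ch in seq:
        b = _ENC[ord(ch)]
        if b == 255:
            raise ValueError(f"non-ACGT base {ch!r} in k-mer {seq!r}")
        code = (code << 2) | int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    out = []
    for i in range(k):
        out.append(_DEC[(code >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Reverse complement of a packed k-mer."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def canonical_code(code: int, k: int) -> int:
    """Canonical (min of self and reverse complement) packed form."""
    return min(code, revcomp_code(code, k))


def canonical_kmer(seq: str) -> str:
    """Return the lexicographically smaller of a k-mer and its reverse
    complement.

    >>> canonical_kmer("CGT")
    'ACG'
    >>> canonical_kmer("TTT")
    'AAA'
    """
    code = encode_kmer(seq)  # validates the alphabet
    k = len(seq)
    return decode_kmer(canonical_code(code, k), k)


# 4^j weights; float64 is exact below 2^53, ample for 2*(31+1) = 64... bits
# of a (k<=26)-mer; larger k falls back to the shift loop
_POWERS = {k: (4.0 ** np.arange(k - 1, -1, -1)) for k in range(1, 27)}


def seq_to_codes(seq: str, k: int) -> np.ndarray:
    """All packed k-mers of ``seq`` in order, as a uint64 array.

    Empty array when the sequence is shorter than k.
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    b = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (b == 255).any():
        bad = seq[int(np.argmax(b == 255))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    if k in _POWERS:  # windowed dot product: one BLAS call, exact in float64
        w = np.lib.stride_tricks.sliding_window_view(b, k)
        return (w @ _POWERS[k]).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        codes = (codes << np.uint64(2)) | b[i : i + n].astype(np.uint64)
    return codes


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed k-mers."""
    rc = np.zeros_like(codes)
    tmp = codes ^ np.uint64((1 << (2 * k)) - 1)  # complement every base
    for _ in range(k):
        rc = (rc << np.uint64(2)) | (tmp & np.uint64(3))
        tmp = tmp >> np.uint64(2)
    return rc


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized canonical form of packed k-mers."""
    return np.minimum(codes, revcomp_codes(codes, k))


def seq_to_canonical_codes(seq: str, k: int) -> np.ndarray:
    """Canonical packed k-mers of ``seq`` in positional order.

    The reverse-complement codes are derived by encoding the
    reverse-complemented string (C-speed) rather than bit-twiddling each
    packed code.
    """
    f = seq_to_codes(seq, k)
    if len(f) == 0:
        return f
    r = seq_to_codes(revcomp(seq), k)[::-1]
    return np.minimum(f, r)
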