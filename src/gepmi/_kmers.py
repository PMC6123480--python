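"""Vectorised canonical k-mer encoding and 64-bit hashing.

A k-mer over {A,C,G,T} is packed into a ``uint64`` using two bits per base
(A=0, C=1, G=2, T=3, most significant base first).  Because the encoding
preserves lexicographic order, the canonical form (the lexicographic minimum
of a k-mer and its reverse complement) is simply the numeric minimum of the
two packed values.  The packing is injective for k <= 31, so hashing the
packed integer is equivalent to hashing the k-mer string itself.

Hashing uses the MurmurHash3 64-bit finaliser (fmix64), a published
avalanche mixer, seeded by XOR-ing a splitmix64-scrambled seed into the
input.  All operations are numpy-vectorised over arrays of packed k-mers.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

# 256-entry base -> 2-bit code table; 4 marks any non-ACGT byte.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_M1 = np.uint64(0xFF51AFD7ED558CCD)
_M2 = np.uint64(0xC4CEB9FE1A85EC53)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to an array of 2-bit codes (4 = invalid)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def _pack_windows(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement packed values for every window.

    Returns (fwd, rcv) uint64 arrays of length ``len(codes) - k + 1``;
    windows containing invalid codes hold garbage and must be masked out
    by the caller.
    """
    m = codes.size - k + 1
    c64 = codes.astype(np.uint64)
    four = np.uint64(4)
    three = np.uint64(3)
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = fwd * four + c64[j : j + m]
    rcv = np.zeros(m, dtype=np.uint64)
    for j in range(k - 1, -1, -1):
        rcv = rcv * four + (three - c64[j : j + m])
    return fwd, rcv


def canonical_window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed canonical k-mers of all valid (ACGT-only) windows, in order."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    if codes.size < k:
        return np.empty(0, dtype=np.uint64)
    invalid = (codes >= 4).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(invalid)))
    valid = (cum[k:] - cum[:-k]) == 0
    fwd, rcv = _pack_windows(codes, k)
    return np.minimum(fwd[valid], rcv[valid])


def hash_kmers(packed: np.ndarray, seed: int = 42) -> np.ndarray:
    """Seeded 64-bit hash (MurmurHash3 fmix64) of packed canonical k-mers."""
    x = np.asarray(packed, dtype=np.uint64).copy()
    # scramble the seed once (splitmix64 step) so that seed=0 still mixes
    mask = (1 << 64) - 1
    s = (int(seed) + 0x9E3779B97F4A7C15) & mask
    s = ((s ^ (s >> 30)) * int(_M1)) & mask
    x ^= np.uint64(s)
    x ^= x >> np.uint64(33)
    x *= _M1
    x ^= x >> np.uint64(33)
    x *= _M2
    x ^= x >> np.uint64(33)
    return x


def encode_kmer(kmer: str) -> np.uint64:
    """Pack a single k-mer string (must be ACGT-only)."""
    codes = encode_sequence(kmer)
    if codes.size == 0 or (codes >= 4).any():
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    val = np.uint64(0)
    for c in codes:
        val = val * np.uint64(4) + np.uint64(c)
    return val


def decode_kmer(packed: int, k: int) -> str:
    """Unpack a 2-bit encoded k-mer back to its string form."""
    out = np.empty(k, dtype=np.uint8)
    v = int(packed)
    for j in range(k - 1, -1, -1):
        out[j] = _BASES[v & 3]
        v >>= 2
    return out.tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc
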