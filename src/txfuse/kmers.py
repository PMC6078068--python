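"""Vectorised 2-bit k-mer encoding, canonicalisation and hashing.

All sequence-sketching, similarity and seed-mapping code in this package runs on
the same primitive: a sliding window of k-mers packed big-endian, two bits per
base, into machine words.  For k <= 32 a k-mer fits one ``uint64`` and the packed
value itself is an exact identifier; for 32 < k <= 64 the k-mer is split into a
(high, low) word pair whose lexicographic word order equals the lexicographic
base order (A < C < G < T).  The canonical form of a k-mer is the smaller of the
forward and reverse-complement packings, which makes every derived quantity
strand-independent.

Hashing uses splitmix64 (Steele, Lea & Flood's finaliser; constants below), a
fixed, documented 64-bit mixer, so sketches are stable across runs and machines.

``N`` (and any non-ACGT character, which upstream I/O normalises to ``N``) is
encoded as 4 and invalidates every window that contains it.
"""

from __future__ import annotations

import numpy as np

# base encoding: A=0 C=1 G=2 T=3, everything else (incl. N) = 4
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # complement in code space
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes (A0 C1 G2 T3, other 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (codes >= 4 render as ``N``)."""
    return _DEC[np.minimum(codes, 4)].tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return decode(_COMP[encode(seq)][::-1])


def splitmix64(x) -> np.ndarray:
    """Vectorised splitmix64 finaliser: a fixed 64-bit avalanche hash."""
    z = np.asarray(x, dtype=np.uint64) + _GOLDEN
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


def _window_valid(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over windows: True where the window holds no N."""
    n = codes.size - k + 1
    bad = (codes >= 4).astype(np.int32)
    if not bad.any():
        return np.ones(n, dtype=bool)
    cum = np.concatenate(([0], np.cumsum(bad)))
    return (cum[k:] - cum[:-k]) == 0


def kmer_words(codes: np.ndarray, k: int):
    """Pack every k-window of ``codes`` forward and reverse-complement.

    Returns ``(fwd_hi, fwd_lo, rc_hi, rc_lo, valid)``; each array has one entry
    per window position.  The high word holds the first ``min(k, 32)`` bases
    big-endian, the low word the remainder, so (hi, lo) compares like the base
    string.  Requires ``k <= 64``.
    """
    if k > 64:
        raise ValueError("k-mers above 64 bases are not supported")
    n = codes.size - k + 1
    if n <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, z, z.copy(), z.copy(), np.zeros(0, dtype=bool)
    h = min(k, 32)
    b = codes.astype(np.uint64)
    four = np.uint64(4)
    three = np.uint64(3)
    fwd_hi = np.zeros(n, dtype=np.uint64)
    rc_hi = np.zeros(n, dtype=np.uint64)
    for j in range(h):
        fwd_hi = fwd_hi * four + b[j : j + n]
        rc_hi = rc_hi * four + (three - b[k - 1 - j : k - 1 - j + n])
    fwd_lo = np.zeros(n, dtype=np.uint64)
    rc_lo = np.zeros(n, dtype=np.uint64)
    for j in range(h, k):
        fwd_lo = fwd_lo * four + b[j : j + n]
        rc_lo = rc_lo * four + (three - b[k - 1 - j : k - 1 - j + n])
    return fwd_hi, fwd_lo, rc_hi, rc_lo, _window_valid(codes, k)


def canonical_words(codes: np.ndarray, k: int):
    """Canonical (hi, lo) word pair per window plus strand and validity.

    ``is_fwd[i]`` is True when the forward packing is the canonical one
    (ties, i.e. palindromes, count as forward).
    """
    fwd_hi, fwd_lo, rc_hi, rc_lo, valid = kmer_words(codes, k)
    is_fwd = (fwd_hi < rc_hi) | ((fwd_hi == rc_hi) & (fwd_lo <= rc_lo))
    hi = np.where(is_fwd, fwd_hi, rc_hi)
    lo = np.where(is_fwd, fwd_lo, rc_lo)
    return hi, lo, is_fwd, valid


def canonical_kmer_set(seq_or_codes, k: int) -> np.ndarray:
    """Exact set of canonical k-mers of a sequence, k <= 32.

    Returns the sorted unique packed ``uint64`` values (exact identifiers, no
    hashing).  Sequences shorter than k yield an empty set.
    """
    if k > 32:
        raise ValueError("exact canonical sets require k <= 32")
    codes = encode(seq_or_codes) if isinstance(seq_or_codes, str) else seq_or_codes
    hi, _lo, _f, valid = canonical_words(codes, k)
    return np.unique(hi[valid])


def canonical_hashes(seq_or_codes, k: int) -> np.ndarray:
    """splitmix64 hashes of every valid canonical k-mer window (with repeats)."""
    codes = encode(seq_or_codes) if isinstance(seq_or_codes, str) else seq_or_codes
    hi, lo, _f, valid = canonical_words(codes, k)
    return splitmix64(hi[valid] ^ splitmix64(lo[valid]))
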