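"""Bit-packed nucleotide and purine/pyrimidine (RY) kmer encodings.

Two reduced representations of DNA kmers underpin the rescue index:

* the standard 2-bit-per-base nucleotide encoding (A=00, C=01, G=10, T=11),
  packing a kmer of up to 31 bases into the low 62 bits of a 64-bit key;
* the 1-bit-per-base RY encoding (purine A/G -> 0, pyrimidine C/T -> 1),
  packing up to 62 bases into the same key width.

The RY encoding is invariant under transitions (C<->T, G<->A), which is
exactly the substitution class produced by cytosine deamination in ancient
DNA.  A length-k kmer carries 2k bits of Shannon information, its RY
reduction only k bits; the projection from kmer space to RY space is
surjective but not injective (4^k kmers collapse onto 2^k RY codes).

In both encodings the first base of the sequence occupies the most
significant bits, so lexicographic order of sequences coincides with
integer order of their codes.  Keys shorter than the full width are
zero-padded in the unused high bits; the base count is carried alongside
the bits and never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MAX_KMER_LENGTH",
    "MAX_RYMER_LENGTH",
    "KmerCode",
    "RyCode",
    "encode_kmer",
    "decode_kmer",
    "encode_rymer",
    "decode_rymer",
    "kmer_to_rycode",
    "reverse_complement",
    "hash64",
    "hash64_array",
    "kmer_information_bits",
    "rymer_information_bits",
]

#: Longest kmer that fits 2 bits/base into a 62-bit key.
MAX_KMER_LENGTH = 31
#: Longest RYmer that fits 1 bit/base into a 62-bit key.
MAX_RYMER_LENGTH = 62

_BASES = "ACGT"
_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
#: Complement in 2-bit code space: A<->T (0<->3), C<->G (1<->2), i.e. XOR 3.
_CODE_COMPLEMENT_XOR = 3

_U64 = np.uint64
_MASK64 = _U64(0xFFFFFFFFFFFFFFFF)


def kmer_information_bits(k: int) -> float:
    """Shannon information of a length-k kmer over {A,C,G,T}: log2(4^k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(np.log2(float(4**k)))


def rymer_information_bits(k: int) -> float:
    """Shannon information of a length-k RYmer over {R,Y}: log2(2^k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(np.log2(float(2**k)))


@dataclass(frozen=True)
class KmerCode:
    """A nucleotide kmer packed 2 bits per base, first base most significant."""

    bits: int
    length: int

    def __post_init__(self) -> None:
        if not 1 <= self.length <= MAX_KMER_LENGTH:
            raise ValueError(
                f"kmer length must be in 1..{MAX_KMER_LENGTH}, got {self.length}"
            )
        if not 0 <= self.bits < 4**self.length:
            raise ValueError("bits out of range for kmer length")


@dataclass(frozen=True)
class RyCode:
    """An RY (purine/pyrimidine) string packed 1 bit per base."""

    bits: int
    length: int

    def __post_init__(self) -> None:
        if not 1 <= self.length <= MAX_RYMER_LENGTH:
            raise ValueError(
                f"RYmer length must be in 1..{MAX_RYMER_LENGTH}, got {self.length}"
            )
        if not 0 <= self.bits < 2**self.length:
            raise ValueError("bits out of range for RYmer length")


def _check_seq(seq: str, max_len: int) -> str:
    if not 1 <= len(seq) <= max_len:
        raise ValueError(f"sequence length must be in 1..{max_len}, got {len(seq)}")
    seq = seq.upper()
    for ch in seq:
        if ch not in _BASE_TO_CODE:
            raise ValueError(f"ambiguous or invalid base {ch!r} cannot be encoded")
    return seq


def encode_kmer(seq: str) -> KmerCode:
    """Pack a DNA string into a :class:`KmerCode`.

    Bases map as A->00, C->01, G->10, T->11 and are concatenated with the
    first base in the most significant position.  Ambiguous bases (N etc.)
    are rejected: such kmers are never indexed.
    """
    seq = _check_seq(seq, MAX_KMER_LENGTH)
    bits = 0
    for ch in seq:
        bits = (bits << 2) | _BASE_TO_CODE[ch]
    return KmerCode(bits, len(seq))


def decode_kmer(code: KmerCode) -> str:
    out = []
    for i in range(code.length):
        shift = 2 * (code.length - 1 - i)
        out.append(_BASES[(code.bits >> shift) & 3])
    return "".join(out)


def encode_rymer(seq: str) -> RyCode:
    """Pack a DNA string into its RY reduction: purine->0, pyrimidine->1."""
    seq = _check_seq(seq, MAX_RYMER_LENGTH)
    bits = 0
    for ch in seq:
        bits = (bits << 1) | (_BASE_TO_CODE[ch] & 1)
    return RyCode(bits, len(seq))


def decode_rymer(code: RyCode) -> str:
    """Render an :class:`RyCode` as a string over {R, Y}."""
    out = []
    for i in range(code.length):
        shift = code.length - 1 - i
        out.append("RY"[(code.bits >> shift) & 1])
    return "".join(out)


def kmer_to_rycode(code: KmerCode) -> RyCode:
    """Project a packed kmer onto its RY code without decoding to text.

    With the printed base codes, purines (A=00, G=10) are exactly the even
    codes, so the RY bit of each base is the low bit of its 2-bit code; the
    projection is a mask-and-compress over the packed key.
    """
    bits = 0
    for i in range(code.length):
        shift = 2 * (code.length - 1 - i)
        bits = (bits << 1) | ((code.bits >> shift) & 1)
    return RyCode(bits, code.length)


def _revcomp_str(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[ch] for ch in reversed(seq.upper()))


def _revcomp_kmer_bits(bits: int, length: int) -> int:
    out = 0
    for _ in range(length):
        out = (out << 2) | ((bits & 3) ^ _CODE_COMPLEMENT_XOR)
        bits >>= 2
    return out


def reverse_complement(x):
    """Reverse complement in the input's own representation.

    Strings get the standard Watson-Crick reverse complement.  For a
    :class:`KmerCode` each 2-bit base is complemented (XOR 3) and the base
    order reversed.  For an :class:`RyCode` complementation swaps purine
    and pyrimidine, so the bit string is reversed and flipped.
    """
    if isinstance(x, str):
        return _revcomp_str(x)
    if isinstance(x, KmerCode):
        return KmerCode(_revcomp_kmer_bits(x.bits, x.length), x.length)
    if isinstance(x, RyCode):
        bits = 0
        b = x.bits
        for _ in range(x.length):
            bits = (bits << 1) | ((b & 1) ^ 1)
            b >>= 1
        return RyCode(bits, x.length)
    raise TypeError(f"cannot reverse-complement {type(x).__name__}")


def hash64(key: int) -> int:
    """Thomas Wang's 64-bit integer mix (xor-shift/multiply ladder).

    Deterministic and invertible; the variant is pinned as part of the
    index format version, since two indexes are only comparable under the
    same hash.
    """
    m = 0xFFFFFFFFFFFFFFFF
    key &= m
    key = (~key + (key << 21)) & m
    key = key ^ (key >> 24)
    key = (key + (key << 3) + (key << 8)) & m
    key = key ^ (key >> 14)
    key = (key + (key << 2) + (key << 4)) & m
    key = key ^ (key >> 28)
    key = (key + (key << 31)) & m
    return key


def hash64_array(keys: np.ndarray) -> np.ndarray:
    """Vectorized :func:`hash64` over a uint64 array."""
    key = keys.astype(_U64, copy=True)
    with np.errstate(over="ignore"):
        key = (~key + (key << _U64(21))) & _MASK64
        key ^= key >> _U64(24)
        key = (key + (key << _U64(3)) + (key << _U64(8))) & _MASK64
        key ^= key >> _U64(14)
        key = (key + (key << _U64(2)) + (key << _U64(4))) & _MASK64
        key ^= key >> _U64(28)
        key = (key + (key << _U64(31))) & _MASK64
    return key
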