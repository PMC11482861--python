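"""Paired minimizer index and RY-derived rescue index over a haplotype panel.

The minimizer index is the classic (w, k) winnowing sketch: slide a window
of ``w`` consecutive kmer start positions along each reference sequence,
hash the 2-bit encoding of every kmer in both orientations, and record the
canonical kmer (the orientation with the smaller hash) whose hash is the
window minimum.  Keys are packed kmer codes; values are lists of
``(sequence, offset, orientation)`` hits.

The rescue (RYmer) index is *derived from the minimizer set* rather than
selected independently in RY space: every minimizer key is projected onto
its purine/pyrimidine code, and the RY table maps each RY code back to the
minimizer keys that produced it.  Positions are never duplicated — a query
in RY space returns minimizer keys, and hits are fetched from the
minimizer table by a second constant-time lookup.  This guarantees that
any read kmer equal to an indexed minimizer up to transitions only (the
deamination case) can still reach that minimizer's hits.

Circular sequences are indexed on a linearization extended by a virtual
copy of their first k-1 bases, with offsets reduced modulo the length.
Kmers spanning an ambiguous base are never candidates.
"""

from __future__ import annotations

import io
import struct
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .ry_encoding import (
    KmerCode,
    RyCode,
    hash64_array,
    kmer_to_rycode,
    reverse_complement,
)

__all__ = [
    "IndexParams",
    "PanelSequence",
    "ReferencePanel",
    "Hit",
    "MinimizerIndex",
    "RymerIndex",
    "RymerMatch",
    "build_minimizer_index",
    "build_rymer_index",
    "query_minimizers",
    "query_rymers",
    "serialize_index",
    "deserialize_index",
    "IndexFormatError",
]

_U64 = np.uint64
_INVALID_HASH = np.iinfo(np.uint64).max

# ASCII -> 2-bit base code; 4 marks ambiguous.
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    """Map a DNA string to a uint8 code array (A=0,C=1,G=2,T=3, other=4)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class IndexParams:
    """Winnowing parameters shared by both indexes of a pair."""

    k: int
    w: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 31:
            raise ValueError(f"k must be in 1..31, got {self.k}")
        if self.w < 1:
            raise ValueError(f"w must be >= 1, got {self.w}")


@dataclass(frozen=True)
class PanelSequence:
    name: str
    seq: str
    circular: bool = False


@dataclass
class ReferencePanel:
    """An ordered panel of reference haplotype sequences.

    Stands in for the embedded haplotypes of a pangenome graph: each record
    is a named linear or circular sequence with 0-based coordinates.
    """

    sequences: List[PanelSequence]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sequences]
        if len(set(names)) != len(names):
            raise ValueError("panel sequence names must be unique")

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, i: int) -> PanelSequence:
        return self.sequences[i]

    @property
    def names(self) -> List[str]:
        return [s.name for s in self.sequences]

    @classmethod
    def from_fasta(
        cls, path: str, circular: Optional[Iterable[str]] = None
    ) -> "ReferencePanel":
        """Load a multi-FASTA; ``circular`` names records that wrap."""
        import pysam

        circ = set(circular or ())
        records = []
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                records.append(
                    PanelSequence(entry.name, entry.sequence.upper(), entry.name in circ)
                )
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        unknown = circ - {r.name for r in records}
        if unknown:
            raise ValueError(f"circular names not in panel: {sorted(unknown)}")
        return cls(records)


class Hit(NamedTuple):
    """One occurrence of a minimizer: panel sequence, 0-based start, strand."""

    seq_id: int
    offset: int
    is_reverse: bool


@dataclass
class MinimizerIndex:
    params: IndexParams
    table: Dict[int, List[Hit]] = field(default_factory=dict)
    #: keys whose hit lists were truncated at the cap
    truncated_keys: int = 0

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MinimizerIndex)
            and self.params == other.params
            and self.table == other.table
        )


@dataclass
class RymerIndex:
    """Maps RY codes to the minimizer keys that project onto them."""

    params: IndexParams
    table: Dict[int, List[int]] = field(default_factory=dict)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RymerIndex)
            and self.params == other.params
            and self.table == other.table
        )


# ---------------------------------------------------------------------------
# windowed canonical-minimizer selection
# ---------------------------------------------------------------------------


def _kmer_code_array(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Packed kmer codes for every offset, plus a validity mask.

    Returns ``(kcodes, valid)`` where ``kcodes[i]`` packs ``codes[i:i+k]``
    (garbage where invalid) and ``valid[i]`` is False when the window spans
    an ambiguous base.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=_U64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (_U64(4) ** np.arange(k - 1, -1, -1, dtype=_U64)).astype(_U64)
    safe = np.where(windows < 4, windows, 0).astype(_U64)
    kcodes = (safe * powers).sum(axis=1, dtype=_U64)
    valid = (windows < 4).all(axis=1)
    return kcodes, valid


def _canonical_codes(
    codes: np.ndarray, k: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Forward/canonical codes and hashes for every kmer offset.

    Returns ``(fwd, canon, canon_hash, is_rev, valid)``.  Invalid offsets
    get the maximal hash so they never win a window.  Hash ties between
    orientations break toward forward.
    """
    fwd, valid = _kmer_code_array(codes, k)
    if len(fwd) == 0:
        e = np.empty(0, dtype=_U64)
        return e, e, e, np.empty(0, dtype=bool), valid
    rc_codes_all, _ = _kmer_code_array(
        np.where(codes[::-1] < 4, 3 - codes[::-1], 4), k
    )
    rev = rc_codes_all[::-1]
    hf = hash64_array(fwd)
    hr = hash64_array(rev)
    is_rev = hr < hf
    canon = np.where(is_rev, rev, fwd)
    canon_hash = np.where(is_rev, hr, hf)
    canon_hash = np.where(valid, canon_hash, _U64(_INVALID_HASH))
    return fwd, canon, canon_hash, is_rev, valid


def _window_minima_positions(canon_hash: np.ndarray, w: int) -> np.ndarray:
    """Offsets selected by (w,k)-winnowing: per-window minima, all ties kept.

    When fewer than ``w`` kmers exist the whole run is one window, so very
    short query sequences can still seed.
    """
    n = len(canon_hash)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    weff = min(w, n)
    view = np.lib.stride_tricks.sliding_window_view(canon_hash, weff)
    winmin = view.min(axis=1)
    informative = winmin != _U64(_INVALID_HASH)
    rows, cols = np.nonzero(view == winmin[:, None])
    keep = informative[rows]
    pos = np.unique(rows[keep] + cols[keep])
    return pos


def build_minimizer_index(panel: ReferencePanel, params: IndexParams,
                          max_hits: int = 512) -> MinimizerIndex:
    """Winnow every panel sequence into a minimizer hash table.

    Both orientations of each kmer are hashed and the smaller-hash
    (canonical) form keyed; every per-window minimum is recorded with all
    of its occurrences.  Keys with more than ``max_hits`` occurrences keep
    only the first ``max_hits`` (sorted) hits, with a warning.
    """
    if len(panel) == 0:
        raise ValueError("empty reference panel")
    k, w = params.k, params.w
    table: Dict[int, List[Hit]] = {}
    for sid, rec in enumerate(panel.sequences):
        L = len(rec.seq)
        if L < k:
            continue
        codes = seq_to_codes(rec.seq)
        if rec.circular:
            codes = np.concatenate([codes, codes[: k - 1]])
        _, canon, canon_hash, is_rev, _ = _canonical_codes(codes, k)
        for off in _window_minima_positions(canon_hash, w):
            off = int(off)
            key = int(canon[off])
            table.setdefault(key, []).append(
                Hit(sid, off % L if rec.circular else off, bool(is_rev[off]))
            )
    idx = MinimizerIndex(params=params, table={})
    for key in sorted(table):
        hits = sorted(set(table[key]))
        if len(hits) > max_hits:
            idx.truncated_keys += 1
            hits = hits[:max_hits]
        idx.table[key] = hits
    if idx.truncated_keys:
        warnings.warn(
            f"{idx.truncated_keys} minimizer key(s) exceeded the {max_hits}-hit "
            "cap; hit lists truncated",
            stacklevel=2,
        )
    return idx


def build_rymer_index(minidx: MinimizerIndex) -> RymerIndex:
    """Project the minimizer key set into RY space.

    One entry per distinct RY projection; each entry lists (sorted) every
    minimizer key projecting to it, so every indexed kmer is reachable
    through the rescue path.
    """
    k = minidx.params.k
    table: Dict[int, List[int]] = {}
    for key in minidx.table:
        ry = kmer_to_rycode(KmerCode(key, k)).bits
        table.setdefault(ry, []).append(key)
    return RymerIndex(
        params=minidx.params,
        table={ry: sorted(keys) for ry, keys in sorted(table.items())},
    )


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------


class MinimizerSelection(NamedTuple):
    """A read window's canonical minimizer (whether or not it is indexed)."""

    read_offset: int
    is_reverse: bool  # canonical orientation relative to the read
    fwd_code: int  # kmer code in read orientation
    canon_code: int


def select_read_minimizers(read: str, params: IndexParams) -> List[MinimizerSelection]:
    """Apply the index's windowing scheme to a query sequence."""
    k = params.k
    if len(read) < k:
        return []
    codes = seq_to_codes(read)
    fwd, canon, canon_hash, is_rev, _ = _canonical_codes(codes, k)
    return [
        MinimizerSelection(int(o), bool(is_rev[o]), int(fwd[o]), int(canon[o]))
        for o in _window_minima_positions(canon_hash, params.w)
    ]


def query_minimizers(
    idx: MinimizerIndex, read: str
) -> List[Tuple[int, bool, KmerCode, List[Hit]]]:
    """Exact-match seed lookup: the read's windowed canonical minimizers
    that exist as keys, each with its reference hits."""
    out = []
    for sel in select_read_minimizers(read, idx.params):
        hits = idx.table.get(sel.canon_code)
        if hits is not None:
            out.append(
                (sel.read_offset, sel.is_reverse, KmerCode(sel.canon_code, idx.params.k), hits)
            )
    return out


class RymerMatch(NamedTuple):
    """A rescue-path lookup result for one read window.

    ``via_reverse`` records which orientation of the read kmer matched in
    RY space; ``candidates`` are minimizer keys stored under that RY code.
    ``read_fwd_code`` is the read's kmer in read orientation, kept for
    downstream mismatch counting.
    """

    read_offset: int
    via_reverse: bool
    read_fwd_code: int
    candidates: List[int]


def query_rymers(ryidx: RymerIndex, read: str) -> List[RymerMatch]:
    """RY-space seed lookup over the read's windowed minimizers.

    Both orientations of each selected read kmer are projected (the
    complement swaps purine and pyrimidine, so the two RY codes differ),
    ensuring a deaminated read kmer finds its source minimizer regardless
    of which orientation won canonicalization on either side.
    """
    k = ryidx.params.k
    out: List[RymerMatch] = []
    for sel in select_read_minimizers(read, ryidx.params):
        fwd = KmerCode(sel.fwd_code, k)
        ry_f = kmer_to_rycode(fwd).bits
        ry_r = reverse_complement(RyCode(ry_f, k)).bits
        cands = ryidx.table.get(ry_f)
        if cands:
            out.append(RymerMatch(sel.read_offset, False, sel.fwd_code, cands))
        cands = ryidx.table.get(ry_r)
        if cands:
            out.append(RymerMatch(sel.read_offset, True, sel.fwd_code, cands))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_MAGIC = b"RYSEED1"
_VERSION = 1
_KIND_MIN = 1
_KIND_RY = 2


class IndexFormatError(ValueError):
    pass


def serialize_index(idx, path: str) -> None:
    """Write an index in the little-endian 'RYSEED1' container.

    Records are sorted by key, making serialization deterministic:
    identical inputs and params yield byte-identical files.
    """
    buf = io.BytesIO()
    if isinstance(idx, MinimizerIndex):
        kind = _KIND_MIN
    elif isinstance(idx, RymerIndex):
        kind = _KIND_RY
    else:
        raise TypeError(f"cannot serialize {type(idx).__name__}")
    buf.write(_MAGIC)
    buf.write(struct.pack("<BBBI", _VERSION, kind, idx.params.k, idx.params.w))
    buf.write(struct.pack("<Q", len(idx.table)))
    if kind == _KIND_MIN:
        for key in sorted(idx.table):
            hits = idx.table[key]
            buf.write(struct.pack("<QI", key, len(hits)))
            for h in hits:
                buf.write(struct.pack("<IIB", h.seq_id, h.offset, int(h.is_reverse)))
    else:
        for key in sorted(idx.table):
            keys = idx.table[key]
            buf.write(struct.pack("<QI", key, len(keys)))
            for mk in keys:
                buf.write(struct.pack("<Q", mk))
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def _read_exact(fh, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise IndexFormatError("truncated index file")
    return data


def deserialize_index(path: str):
    """Read back a serialized index; rejects bad magic/version/truncation."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise IndexFormatError(f"bad magic {magic!r}; not a RYSEED1 index")
        version, kind, k, w = struct.unpack("<BBBI", _read_exact(fh, 7))
        if version != _VERSION:
            raise IndexFormatError(f"unsupported index format version {version}")
        if kind not in (_KIND_MIN, _KIND_RY):
            raise IndexFormatError(f"unknown index kind {kind}")
        params = IndexParams(k=k, w=w)
        (nkeys,) = struct.unpack("<Q", _read_exact(fh, 8))
        if kind == _KIND_MIN:
            idx = MinimizerIndex(params=params, table={})
            for _ in range(nkeys):
                key, nhits = struct.unpack("<QI", _read_exact(fh, 12))
                hits = []
                for _ in range(nhits):
                    sid, off, rev = struct.unpack("<IIB", _read_exact(fh, 9))
                    hits.append(Hit(sid, off, bool(rev)))
                idx.table[key] = hits
            return idx
        idx = RymerIndex(params=params, table={})
        for _ in range(nkeys):
            key, nk = struct.unpack("<QI", _read_exact(fh, 12))
            idx.table[key] = [
                struct.unpack("<Q", _read_exact(fh, 8))[0] for _ in range(nk)
            ]
        return idx
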