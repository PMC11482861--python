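"""Seed-and-extend read mapping with deaminated-seed rescue.

Mapping proceeds in the classic stages: the read's windowed canonical
minimizers are looked up exactly in the minimizer index; in parallel the
RY (purine/pyrimidine) projections of the same kmers are looked up in the
rescue index, and candidates passing the Bayesian deamination filter are
converted back to minimizer keys (constant-time back-pointer) and their
hits fetched.  Exact and rescued seeds are aggregated, clustered by
(sequence, strand, diagonal), and clusters are extended — gapless with an
X-drop first, then a banded affine gapped fallback — into scored
alignments.  Everything downstream of seed finding is identical with or
without the rescue path, so disabling rescue (or setting the posterior
threshold to 1.0, or supplying a zero-damage profile) reproduces the
baseline aligner's output byte for byte.

Output is SAM with deterministic headers and tie-breaking.  Alignments on
circular references may cross the origin: they are computed on the
doubled sequence and reported with the start reduced modulo the length
and a ``ZC:i:1`` tag.  Rescued-seed provenance is carried in ``ZR``
(count of rescued seeds in the winning cluster) and ``ZP`` (their minimum
posterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .damage_model import DamageProfile
from .rescue_filter import FilterConfig, filter_candidates
from .seed_index import (
    Hit,
    MinimizerIndex,
    ReferencePanel,
    RymerIndex,
    query_rymers,
    select_read_minimizers,
    seq_to_codes,
)

__all__ = [
    "ScoringParams",
    "Seed",
    "SeedCluster",
    "Alignment",
    "collect_seeds",
    "cluster_seeds",
    "extend",
    "map_read",
    "map_fastq",
    "write_sam",
    "score_cigar",
    "cigar_to_string",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class ScoringParams:
    """Extension scoring: gapless X-drop plus banded affine fallback.

    Defaults are chosen so a single transition mismatch survives while
    random short matches fail the score floor: a full-length alignment
    scores ``match`` per base and must reach ``score_floor_frac`` of the
    perfect score.  A gap of length g costs ``-(gap_open + (g-1) *
    gap_extend)``.
    """

    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    xdrop: int = 20
    band: int = 16
    diagonal_band: int = 16
    score_floor_frac: float = 0.5
    max_clusters: int = 8


class Seed(NamedTuple):
    """An anchored kmer match in strand coordinates.

    ``strand_offset`` is the kmer's offset within the read *as it maps*:
    for reverse-strand seeds it is the offset within the reverse
    complement of the read, so diagonal = ref_offset - strand_offset is
    strand-consistent.
    """

    seq_id: int
    is_reverse: bool
    strand_offset: int
    ref_offset: int
    diagonal: int
    rescued: bool
    posterior: float


@dataclass
class SeedCluster:
    seq_id: int
    is_reverse: bool
    seeds: List[Seed]

    @property
    def support(self) -> int:
        """Number of distinct read offsets backing the cluster."""
        return len({s.strand_offset for s in self.seeds})

    @property
    def diagonal(self) -> int:
        """Most common member diagonal (smallest wins ties)."""
        counts: Dict[int, int] = {}
        for s in self.seeds:
            counts[s.diagonal] = counts.get(s.diagonal, 0) + 1
        return min(counts, key=lambda d: (-counts[d], d))

    @property
    def rescued_count(self) -> int:
        return sum(1 for s in self.seeds if s.rescued)

    @property
    def min_posterior(self) -> float:
        return min((s.posterior for s in self.seeds), default=1.0)


@dataclass
class Alignment:
    """A reference placement with an edit script and score."""

    read_name: str
    seq_id: int
    pos: int  # 0-based leftmost reference coordinate (mod length if circular)
    is_reverse: bool
    cigar: List[Tuple[str, int]]
    score: int
    mapq: int = 0
    nm: int = 0
    rescued_seed_count: int = 0
    min_posterior: float = 1.0
    wraps_origin: bool = False
    seq: str = ""  # strand-oriented (as aligned to the forward reference)
    qual: str = ""


def collect_seeds(read: str, minidx: MinimizerIndex, ryidx: Optional[RymerIndex],
                  profile: Optional[DamageProfile],
                  cfg: FilterConfig = FilterConfig(),
                  no_rescue: bool = False) -> List[Seed]:
    """Union of exact minimizer seeds and filter-surviving rescued seeds.

    The rescue path only ever adds seeds: candidates duplicating an
    exact-match minimizer are dropped, so with rescue disabled, a
    threshold of 1.0, or a zero-damage profile the seed set is exactly
    the exact-match set.
    """
    k = minidx.params.k
    L = len(read)
    seeds: List[Seed] = []
    exact_keys = set()
    for sel in select_read_minimizers(read, minidx.params):
        hits = minidx.table.get(sel.canon_code)
        if hits is None:
            continue
        exact_keys.add(sel.canon_code)
        for h in hits:
            rev = sel.is_reverse ^ h.is_reverse
            soff = (L - k - sel.read_offset) if rev else sel.read_offset
            seeds.append(Seed(h.seq_id, rev, soff, h.offset,
                              h.offset - soff, False, 1.0))
    if not no_rescue and ryidx is not None and profile is not None:
        matches = query_rymers(ryidx, read)
        for rs in filter_candidates(matches, profile, cfg, read_length=L,
                                    exact_keys=frozenset(exact_keys), k=k):
            hits = minidx.table.get(rs.minimizer_key)
            if hits is None:
                continue
            for h in hits:
                rev = h.is_reverse ^ rs.via_reverse
                soff = (L - k - rs.read_offset) if rev else rs.read_offset
                seeds.append(Seed(h.seq_id, rev, soff, h.offset,
                                  h.offset - soff, rs.rescued, rs.posterior))
    # deterministic order; drop exact/rescued duplicates of the same anchor
    best: Dict[Tuple[int, bool, int, int], Seed] = {}
    for s in sorted(seeds, key=lambda s: (s.seq_id, s.is_reverse, s.strand_offset,
                                          s.ref_offset, s.rescued)):
        best.setdefault((s.seq_id, s.is_reverse, s.strand_offset, s.ref_offset), s)
    return list(best.values())


def cluster_seeds(seeds: Sequence[Seed],
                  diagonal_band: int = 16) -> List[SeedCluster]:
    """Single-linkage grouping of seeds along diagonals.

    Seeds on the same (sequence, strand) whose diagonals differ by at most
    the band are chained into one cluster (equivalent to connected
    components of the all-pairs |d_i - d_j| <= band relation).  Clusters
    are returned ranked by distinct-read-offset support, ties broken by
    (seq_id, strand, diagonal) for determinism.
    """
    groups: Dict[Tuple[int, bool], List[Seed]] = {}
    for s in seeds:
        groups.setdefault((s.seq_id, s.is_reverse), []).append(s)
    clusters: List[SeedCluster] = []
    for (sid, rev), members in sorted(groups.items()):
        members.sort(key=lambda s: (s.diagonal, s.strand_offset))
        cur = [members[0]]
        for s in members[1:]:
            if s.diagonal - cur[-1].diagonal <= diagonal_band:
                cur.append(s)
            else:
                clusters.append(SeedCluster(sid, rev, cur))
                cur = [s]
        clusters.append(SeedCluster(sid, rev, cur))
    clusters.sort(key=lambda c: (-c.support, c.seq_id, c.is_reverse, c.diagonal))
    return clusters


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------


class _RefView(NamedTuple):
    """Reference codes prepared for extension (doubled when circular)."""

    codes: np.ndarray
    length: int
    circular: bool


def _prepare_refs(panel: ReferencePanel) -> List[_RefView]:
    views = []
    for rec in panel.sequences:
        codes = seq_to_codes(rec.seq)
        if rec.circular:
            codes = np.concatenate([codes, codes])
        views.append(_RefView(codes, len(rec.seq), rec.circular))
    return views


def _xdrop_ok(scores: np.ndarray, xdrop: int) -> bool:
    """True when cumulative score never falls ``xdrop`` below its best."""
    if len(scores) == 0:
        return True
    c = np.cumsum(scores)
    best = np.maximum.accumulate(np.maximum(c, 0))
    return bool(np.all(best - c <= xdrop))


def _gapless(q: np.ndarray, ref: _RefView, diag: int, anchor: int, k: int,
             sp: ScoringParams) -> Optional[Tuple[int, int, int]]:
    """Full-length gapless candidate at one diagonal.

    Returns (score, ref_start, n_mismatch), or None when the placement
    leaves the reference or the bidirectional X-drop fails before covering
    the read.
    """
    L = len(q)
    start = diag
    if ref.circular:
        start %= ref.length
        if L > ref.length:
            return None
    elif start < 0 or start + L > len(ref.codes):
        return None
    window = ref.codes[start:start + L]
    matches = (q == window) & (q < 4) & (window < 4)
    s = np.where(matches, sp.match, sp.mismatch)
    a0, a1 = anchor, min(anchor + k, L)
    if not _xdrop_ok(s[a1:], sp.xdrop):
        return None
    if not _xdrop_ok(s[:a0][::-1], sp.xdrop):
        return None
    return int(s.sum()), start, int(L - matches.sum())


_M, _X, _Y = 0, 1, 2  # DP states: match/mismatch, deletion (ref gap), insertion


def _banded(q: np.ndarray, ref: _RefView, diag: int,
            sp: ScoringParams) -> Optional[Tuple[int, int, List[Tuple[str, int]], int]]:
    """Banded affine-gap alignment, global in the read, free ref ends.

    The band of width 2*band+1 is centered on the cluster diagonal.
    Returns (score, ref_start, cigar, nm) or None when no in-band path
    exists.  Gap of length g costs gap_open + (g-1)*gap_extend.
    """
    L, B = len(q), sp.band
    o0 = diag - B
    if ref.circular:
        o0 %= ref.length
    refc = ref.codes
    ninf = -1e18
    width = 2 * B + 1
    S = np.full((3, L + 1, width), ninf)
    ptr = np.zeros((3, L + 1, width), dtype=np.int8)
    S[_M, 0, :] = 0.0
    for i in range(1, L + 1):
        qi = q[i - 1]
        for c in range(width):
            rj = o0 + i + c - 1
            # M: consume ref base rj and read base i-1
            if 0 <= rj < len(refc):
                sub = sp.match if (qi == refc[rj] and qi < 4 and refc[rj] < 4) else sp.mismatch
                prev = (S[_M, i - 1, c], S[_X, i - 1, c], S[_Y, i - 1, c])
                b = int(np.argmax(prev))
                if prev[b] > ninf / 2:
                    S[_M, i, c] = prev[b] + sub
                    ptr[_M, i, c] = b
            # Y: consume read base only (insertion w.r.t. reference)
            if c + 1 < width:
                open_s = S[_M, i - 1, c + 1] + sp.gap_open
                ext_s = S[_Y, i - 1, c + 1] + sp.gap_extend
                if open_s >= ext_s:
                    S[_Y, i, c], ptr[_Y, i, c] = open_s, _M
                else:
                    S[_Y, i, c], ptr[_Y, i, c] = ext_s, _Y
            # X: consume ref base only (deletion in read)
            if c >= 1 and 0 <= o0 + i + c - 1 < len(refc):
                open_s = S[_M, i, c - 1] + sp.gap_open
                ext_s = S[_X, i, c - 1] + sp.gap_extend
                if open_s >= ext_s:
                    S[_X, i, c], ptr[_X, i, c] = open_s, _M
                else:
                    S[_X, i, c], ptr[_X, i, c] = ext_s, _X
    # best end over final row, preferring M for determinism
    end_state, end_c, best = _M, -1, ninf
    for st in (_M, _X, _Y):
        for c in range(width):
            if S[st, L, c] > best:
                best, end_state, end_c = S[st, L, c], st, c
    if best <= ninf / 2:
        return None
    # traceback
    ops: List[str] = []
    nm = 0
    st, i, c = end_state, L, end_c
    while not (i == 0 and st == _M):
        if st == _M:
            rj = o0 + i + c - 1
            qi = q[i - 1]
            if not (qi == refc[rj] and qi < 4 and refc[rj] < 4):
                nm += 1
            ops.append("M")
            st = int(ptr[_M, i, c])
            i -= 1
        elif st == _Y:
            ops.append("I")
            nm += 1
            st = int(ptr[_Y, i, c])
            i -= 1
            c += 1
        else:  # _X
            ops.append("D")
            nm += 1
            st = int(ptr[_X, i, c])
            c -= 1
    ref_start = o0 + i + c
    ops.reverse()
    cigar: List[Tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return int(round(best)), ref_start, cigar, nm


def extend(cluster: SeedCluster, strand_read: np.ndarray, ref: _RefView,
           sp: ScoringParams = ScoringParams(), k: int = 0) -> Optional[Alignment]:
    """Extend one cluster into a full-read alignment, or fail.

    A gapless placement on the cluster diagonal is tried first with a
    bidirectional X-drop from the anchor seed; if it cannot cover the
    read, a banded gapped alignment around the same diagonal is computed.
    Alignments scoring below ``score_floor_frac * read_length * match``
    fail (failure is a value: None).
    """
    L = len(strand_read)
    diag = cluster.diagonal
    anchor = min(s.strand_offset for s in cluster.seeds if s.diagonal == diag)
    res = _gapless(strand_read, ref, diag, anchor, k, sp)
    if res is not None:
        score, ref_start, nm = res
        cigar = [("M", L)]
    else:
        banded = _banded(strand_read, ref, diag, sp)
        if banded is None:
            return None
        score, ref_start, cigar, nm = banded
    if score < sp.score_floor_frac * L * sp.match:
        return None
    ref_span = sum(n for op, n in cigar if op in "MD")
    wraps = ref.circular and (ref_start % ref.length) + ref_span > ref.length
    return Alignment(
        read_name="", seq_id=cluster.seq_id,
        pos=ref_start % ref.length if ref.circular else ref_start,
        is_reverse=cluster.is_reverse, cigar=cigar, score=score, nm=nm,
        rescued_seed_count=cluster.rescued_count,
        min_posterior=cluster.min_posterior, wraps_origin=wraps,
    )


# ---------------------------------------------------------------------------
# read-level orchestration
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def map_read(name: str, read: str, qual: str, minidx: MinimizerIndex,
             ryidx: Optional[RymerIndex], panel: ReferencePanel,
             profile: Optional[DamageProfile],
             cfg: FilterConfig = FilterConfig(),
             sp: ScoringParams = ScoringParams(),
             no_rescue: bool = False,
             _refs: Optional[List[_RefView]] = None) -> Optional[Alignment]:
    """Map one read; returns the primary alignment or None (unmapped).

    The best-scoring extension wins; ties break toward the lowest
    (seq_id, position, orientation).  Mapping quality is
    min(60, round(40 * (1 - s2/s1))) from the best two scores.
    """
    read = read.upper()
    if len(read) < minidx.params.k:
        return None
    seeds = collect_seeds(read, minidx, ryidx, profile, cfg, no_rescue)
    if not seeds:
        return None
    refs = _refs if _refs is not None else _prepare_refs(panel)
    fwd_codes = seq_to_codes(read)
    rc_codes = None
    candidates: List[Alignment] = []
    for cluster in cluster_seeds(seeds, sp.diagonal_band)[: sp.max_clusters]:
        if cluster.is_reverse:
            if rc_codes is None:
                rc_codes = np.where(fwd_codes[::-1] < 4, 3 - fwd_codes[::-1], 4).astype(np.uint8)
            q = rc_codes
        else:
            q = fwd_codes
        aln = extend(cluster, q, refs[cluster.seq_id], sp, minidx.params.k)
        if aln is not None:
            candidates.append(aln)
    if not candidates:
        return None
    # dedupe identical placements, keep the best score at each
    best_at: Dict[Tuple[int, int, bool], Alignment] = {}
    for a in candidates:
        key = (a.seq_id, a.pos, a.is_reverse)
        if key not in best_at or a.score > best_at[key].score:
            best_at[key] = a
    ranked = sorted(best_at.values(),
                    key=lambda a: (-a.score, a.seq_id, a.pos, a.is_reverse))
    primary = ranked[0]
    s1 = primary.score
    s2 = max(ranked[1].score, 0) if len(ranked) > 1 else 0
    primary.mapq = min(60, int(round(40.0 * (1.0 - s2 / s1)))) if s1 > 0 else 0
    primary.read_name = name
    primary.seq = _revcomp(read) if primary.is_reverse else read
    primary.qual = qual[::-1] if primary.is_reverse else qual
    return primary


def cigar_to_string(cigar: List[Tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def score_cigar(aln: Alignment, panel: ReferencePanel,
                sp: ScoringParams = ScoringParams()) -> int:
    """Independently re-score an alignment's edit script (test oracle hook)."""
    rec = panel.sequences[aln.seq_id]
    L = len(rec.seq)
    score = 0
    qpos, rpos = 0, aln.pos
    for op, n in aln.cigar:
        if op == "M":
            for _ in range(n):
                rb = rec.seq[rpos % L if rec.circular else rpos]
                score += sp.match if aln.seq[qpos] == rb else sp.mismatch
                qpos += 1
                rpos += 1
        elif op == "I":
            score += sp.gap_open + (n - 1) * sp.gap_extend
            qpos += n
        elif op == "D":
            score += sp.gap_open + (n - 1) * sp.gap_extend
            rpos += n
        else:
            raise ValueError(f"unexpected CIGAR op {op}")
    return score


def write_sam(results: Iterable[Tuple[str, str, str, Optional[Alignment]]],
              panel: ReferencePanel, path: str,
              progname: str = "ryseed", cmdline: Optional[str] = None) -> None:
    """Write a deterministic SAM file.

    ``results`` yields (name, read, qual, alignment-or-None) in input
    order.  Headers carry @HD/@SQ/@PG; bodies are byte-stable under fixed
    inputs.
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for rec in panel.sequences:
        lines.append(f"@SQ\tSN:{rec.name}\tLN:{len(rec.seq)}")
    pg = f"@PG\tID:{progname}\tPN:{progname}"
    if cmdline:
        pg += f"\tCL:{cmdline}"
    lines.append(pg)
    for name, read, qual, aln in results:
        if aln is None:
            lines.append(
                f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\t{read}\t{qual or '*'}"
            )
            continue
        flag = 16 if aln.is_reverse else 0
        tags = [f"NM:i:{aln.nm}", f"AS:i:{aln.score}"]
        if aln.rescued_seed_count > 0:
            tags.append(f"ZR:i:{aln.rescued_seed_count}")
            tags.append(f"ZP:f:{aln.min_posterior:.6g}")
        if aln.wraps_origin:
            tags.append("ZC:i:1")
        lines.append(
            "\t".join([
                name, str(flag), panel.sequences[aln.seq_id].name,
                str(aln.pos + 1), str(aln.mapq), cigar_to_string(aln.cigar),
                "*", "0", "0", aln.seq, aln.qual or "*", *tags,
            ])
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def map_fastq(fastq_path: str, minidx: MinimizerIndex,
              ryidx: Optional[RymerIndex], panel: ReferencePanel,
              profile: Optional[DamageProfile],
              cfg: FilterConfig = FilterConfig(),
              sp: ScoringParams = ScoringParams(),
              out_sam: Optional[str] = None,
              no_rescue: bool = False) -> List[Tuple[str, str, str, Optional[Alignment]]]:
    """Map every FASTQ record in file order; optionally write SAM."""
    import pysam

    refs = _prepare_refs(panel)
    results = []
    with pysam.FastxFile(str(fastq_path)) as fh:
        for entry in fh:
            if not entry.sequence:
                raise ValueError(f"malformed FASTQ record {entry.name!r}: empty sequence")
            qual = entry.quality or "I" * len(entry.sequence)
            aln = map_read(entry.name, entry.sequence, qual, minidx, ryidx,
                           panel, profile, cfg, sp, no_rescue, _refs=refs)
            results.append((entry.name, entry.sequence.upper(), qual, aln))
    if out_sam is not None:
        write_sam(results, panel, out_sam)
    return results
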