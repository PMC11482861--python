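"""Position-dependent deamination rate matrices (damage profiles).

Ancient-DNA deamination converts cytosine to uracil, sequenced as thymine.
The resulting substitution rates are strongly position dependent,
concentrating at fragment termini: C->T at the 5' end and, for
double-stranded library preparations, the complementary G->A at the 3'
end.  A :class:`DamageProfile` holds two rate matrices — one indexed by
distance from the 5' end, one by distance from the 3' end — over the 12
off-diagonal substitution types, plus the library chemistry.

This module loads and writes the profile TSV dialect (one file per
fragment end, a header of ``X>Y`` substitution columns, row i = position i
from that end), answers per-position rate queries (the delta of the rescue
filter's deamination likelihood), estimates a profile from aligned reads
by direct counting, and compares profiles by root-mean-squared error.

Sequencing error is deliberately not part of the model: the rescue filter
targets deamination only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SUBSTITUTIONS",
    "DamageProfile",
    "SubstitutionCounts",
    "load_profile",
    "write_profile",
    "delta",
    "count_substitutions",
    "estimate_profile",
    "generating_profile",
    "profile_rmse",
]

_BASES = "ACGT"
#: All 12 off-diagonal substitution columns, fixed order.
SUBSTITUTIONS = tuple(
    f"{x}>{y}" for x in _BASES for y in _BASES if x != y
)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _empty_matrix(depth: int) -> pd.DataFrame:
    return pd.DataFrame(
        np.zeros((depth, len(SUBSTITUTIONS))), columns=list(SUBSTITUTIONS)
    )


def _validate_matrix(df: pd.DataFrame, name: str) -> pd.DataFrame:
    unknown = [c for c in df.columns if c not in SUBSTITUTIONS]
    if unknown:
        raise ValueError(f"{name}: unknown substitution column(s) {unknown}")
    out = _empty_matrix(len(df))
    for c in df.columns:
        out[c] = df[c].to_numpy(dtype=float)
    vals = out.to_numpy()
    if np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals > 1):
        raise ValueError(f"{name}: rates must be finite and within [0, 1]")
    for x in _BASES:
        cols = [f"{x}>{y}" for y in _BASES if y != x]
        if np.any(out[cols].sum(axis=1).to_numpy() > 1 + 1e-9):
            raise ValueError(f"{name}: rates out of base {x} sum to more than 1")
    return out


@dataclass
class DamageProfile:
    """Substitution-rate matrices from each fragment end.

    ``five_prime``/``three_prime`` are DataFrames with the 12 ``X>Y``
    columns; row i is position i from the respective end.  ``library_type``
    is ``"ds"`` (double-stranded: C->T read from the 5' matrix, G->A from
    the 3') or ``"ss"`` (single-stranded: C->T read from both ends'
    matrices).  ``beyond_depth`` selects whether queries past the last
    profiled row clamp to that row or return zero.
    """

    five_prime: pd.DataFrame
    three_prime: pd.DataFrame
    library_type: str = "ds"
    beyond_depth: str = "clamp"

    def __post_init__(self) -> None:
        if self.library_type not in ("ds", "ss"):
            raise ValueError("library_type must be 'ds' or 'ss'")
        if self.beyond_depth not in ("clamp", "zero"):
            raise ValueError("beyond_depth must be 'clamp' or 'zero'")
        self.five_prime = _validate_matrix(self.five_prime, "5' matrix")
        self.three_prime = _validate_matrix(self.three_prime, "3' matrix")

    @classmethod
    def zero(cls, depth: int = 5, library_type: str = "ds") -> "DamageProfile":
        return cls(_empty_matrix(depth), _empty_matrix(depth), library_type)

    @property
    def depth(self) -> int:
        return max(len(self.five_prime), len(self.three_prime))

    def _rate(self, end: str, pos: int, column: str) -> float:
        mat = self.five_prime if end == "5p" else self.three_prime
        if len(mat) == 0:
            return 0.0
        if pos >= len(mat):
            if self.beyond_depth == "zero":
                return 0.0
            pos = len(mat) - 1
        return float(mat[column].iat[pos])

    def delta(self, pos_from_5p: int, pos_from_3p: int,
              ref_base: str, read_base: str) -> float:
        """Per-position substitution rate for ``ref_base -> read_base``.

        The deamination pair C->T is read from the 5' matrix (both ends'
        matrices, combined as independent events, for single-stranded
        libraries) and G->A from the 3' matrix.  Other substitutions
        return whatever rate the matrices profile for them, combining both
        ends, else 0.
        """
        ref_base, read_base = ref_base.upper(), read_base.upper()
        if ref_base not in _BASES or read_base not in _BASES:
            raise ValueError(f"invalid base pair {ref_base!r}->{read_base!r}")
        if pos_from_5p < 0 or pos_from_3p < 0:
            raise ValueError("positions must be >= 0")
        if ref_base == read_base:
            return 0.0
        col = f"{ref_base}>{read_base}"
        if col == "C>T":
            r5 = self._rate("5p", pos_from_5p, col)
            if self.library_type == "ss":
                r3 = self._rate("3p", pos_from_3p, col)
                return 1.0 - (1.0 - r5) * (1.0 - r3)
            return r5
        if col == "G>A":
            return self._rate("3p", pos_from_3p, col)
        r5 = self._rate("5p", pos_from_5p, col)
        r3 = self._rate("3p", pos_from_3p, col)
        return 1.0 - (1.0 - r5) * (1.0 - r3)


def delta(profile: DamageProfile, pos_from_5p: int, pos_from_3p: int,
          ref_base: str, read_base: str) -> float:
    """Functional form of :meth:`DamageProfile.delta`."""
    return profile.delta(pos_from_5p, pos_from_3p, ref_base, read_base)


def load_profile(path_5p: str, path_3p: str, library_type: str = "ds",
                 beyond_depth: str = "clamp") -> DamageProfile:
    """Load a profile from its two per-end TSV files.

    Each file is tab-separated with a header of ``X>Y`` columns (any order,
    any subset of the 12; missing columns are zero) and row i giving rates
    at position i from that end.
    """
    def _read(path: str) -> pd.DataFrame:
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] == 0 or not any(c in SUBSTITUTIONS for c in df.columns):
            raise ValueError(f"{path}: malformed header; expected X>Y columns")
        return df

    return DamageProfile(_read(path_5p), _read(path_3p), library_type,
                         beyond_depth)


def write_profile(profile: DamageProfile, path_5p: str, path_3p: str) -> None:
    profile.five_prime.to_csv(path_5p, sep="\t", index=False, float_format="%.6g")
    profile.three_prime.to_csv(path_3p, sep="\t", index=False, float_format="%.6g")


@dataclass
class SubstitutionCounts:
    """Raw per-end, per-position substitution counts and opportunities.

    ``counts[end]`` maps ``X>Y`` to an int array over positions;
    ``opportunities[end]`` maps origin base X to the number of reference-X
    sites observed at each position.
    """

    depth: int
    counts: dict = field(default_factory=dict)
    opportunities: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for end in ("5p", "3p"):
            self.counts.setdefault(
                end, {s: np.zeros(self.depth, dtype=np.int64) for s in SUBSTITUTIONS}
            )
            self.opportunities.setdefault(
                end, {b: np.zeros(self.depth, dtype=np.int64) for b in _BASES}
            )

    def add(self, end: str, pos: int, ref_base: str, read_base: str) -> None:
        if pos >= self.depth:
            return
        self.opportunities[end][ref_base][pos] += 1
        if read_base != ref_base:
            self.counts[end][f"{ref_base}>{read_base}"][pos] += 1

    def to_profile(self, library_type: str = "ds") -> DamageProfile:
        mats = {}
        for end in ("5p", "3p"):
            mat = _empty_matrix(self.depth)
            for sub in SUBSTITUTIONS:
                x = sub[0]
                opp = self.opportunities[end][x]
                with np.errstate(divide="ignore", invalid="ignore"):
                    rate = np.where(opp > 0, self.counts[end][sub] / opp, 0.0)
                mat[sub] = rate
            mats[end] = mat
        return DamageProfile(mats["5p"], mats["3p"], library_type)


def _iter_sam(alignments):
    import pysam

    if isinstance(alignments, (str, bytes)):
        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


def count_substitutions(alignments, panel, depth: int = 5) -> SubstitutionCounts:
    """Tally substitutions in read orientation from primary SAM alignments.

    Reads mapped to the reverse strand are complemented and position-
    flipped before counting, so position 0 is always the sequenced 5' end.
    Reference bases come from the panel (circular coordinates wrap).
    """
    name_to_sid = {s.name: i for i, s in enumerate(panel.sequences)}
    sc = SubstitutionCounts(depth=depth)
    nused = 0
    for aln in _iter_sam(alignments):
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        if aln.reference_name not in name_to_sid:
            continue
        rec = panel.sequences[name_to_sid[aln.reference_name]]
        refseq, L = rec.seq, len(rec.seq)
        q = aln.query_sequence
        if q is None:
            continue
        qlen = len(q)
        nused += 1
        for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
            rb = refseq[rpos % L if rec.circular else rpos]
            qb = q[qpos]
            if rb not in _BASES or qb not in _BASES:
                continue
            if aln.is_reverse:
                pos5 = qlen - 1 - qpos
                rb, qb = _COMPLEMENT[rb], _COMPLEMENT[qb]
            else:
                pos5 = qpos
            pos3 = qlen - 1 - pos5
            sc.add("5p", pos5, rb, qb)
            sc.add("3p", pos3, rb, qb)
    if nused == 0:
        warnings.warn("no usable alignments; damage profile has zero opportunities",
                      stacklevel=2)
    return sc


def estimate_profile(alignments, panel, depth: int = 5,
                     library_type: str = "ds") -> DamageProfile:
    """Estimate a damage profile as count/opportunity rates per position.

    Positions with zero opportunities report rate 0.
    """
    return count_substitutions(alignments, panel, depth).to_profile(library_type)


def generating_profile(profile: DamageProfile, depth: int = 5,
                       interior: int = 25) -> DamageProfile:
    """The per-cell substitution rates the damage process actually applies.

    With beyond-depth clamping, a fragment's interior bases still deaminate
    at the last profiled row's rate, so e.g. the cells of the 3' matrix
    that track C->T pick up the clamped 5' rate.  This helper evaluates
    :meth:`DamageProfile.delta` at each end with the opposite end held at
    an interior distance, yielding the ground-truth matrix an estimator
    counting real fragments (longer than ``2 * depth``) should recover.
    """
    five, three = _empty_matrix(depth), _empty_matrix(depth)
    for sub in SUBSTITUTIONS:
        x, y = sub.split(">")
        for pos in range(depth):
            five.loc[pos, sub] = profile.delta(pos, interior, x, y)
            three.loc[pos, sub] = profile.delta(interior, pos, x, y)
    return DamageProfile(five, three, profile.library_type,
                         profile.beyond_depth)


def profile_rmse(a: DamageProfile, b: DamageProfile,
                 deamination_only: bool = False) -> float:
    """Root-mean-squared difference over all compared matrix cells.

    Matrices of different depth are compared at the deeper one, extending
    the shallower by its last row (the clamp rule).  ``deamination_only``
    restricts the comparison to the C>T and G>A columns.
    """
    cols = ["C>T", "G>A"] if deamination_only else list(SUBSTITUTIONS)
    depth = max(a.depth, b.depth)

    def _cells(p: DamageProfile) -> np.ndarray:
        out = []
        for mat in (p.five_prime, p.three_prime):
            m = mat[cols].to_numpy(dtype=float)
            if len(m) == 0:
                m = np.zeros((depth, len(cols)))
            elif len(m) < depth:
                pad = np.repeat(m[-1:, :], depth - len(m), axis=0)
                m = np.vstack([m, pad])
            out.append(m[:depth])
        return np.concatenate(out)

    diff = _cells(a) - _cells(b)
    return float(np.sqrt(np.mean(diff**2)))
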