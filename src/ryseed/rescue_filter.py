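"""Bayesian filter deciding whether a RY-matched seed was deaminated or spurious.

A seed candidate reaching this module matches an indexed minimizer exactly
in RY (purine/pyrimidine) space but not in nucleotide space, so every
mismatch between the read kmer and the candidate minimizer is a
transition.  Two hypotheses compete:

* M — the alignment is genuine and the mismatches are deamination events
  (C->T against a reference C, or G->A against a reference G, at rates
  given by the position-dependent damage profile);
* not-M — the RY match is a coincidence between unrelated sequences.

The spurious likelihood is a binomial over the k seed positions with a
power-law per-base mismatch probability p = a * k**b (constants fitted
elsewhere and adopted as configuration); past the k cutoff the mismatch
distribution tapers and a small constant is used instead.  The
deamination likelihood is an independent-site product over the seed's k
bases; any mismatch inconsistent with deamination forces it to zero.
Bayes' rule with a user prior gives the posterior P(M | seed), and a
candidate is rescued when the posterior reaches the threshold.  Exact
(zero-mismatch) candidates always pass, so at threshold 1.0 the rescue
path degenerates to baseline behavior.

Sequencing errors and private mutations are intentionally not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, NamedTuple, Optional, Sequence

from scipy.stats import binom

from .damage_model import DamageProfile
from .ry_encoding import KmerCode, kmer_to_rycode, reverse_complement
from .seed_index import RymerMatch

__all__ = [
    "FilterConfig",
    "Mismatch",
    "SeedComparison",
    "RescuedSeed",
    "make_comparison",
    "spurious_likelihood",
    "deamination_likelihood",
    "posterior",
    "filter_candidates",
]

#: Underflow clamp for log-space products.
_TINY = 1e-300

_BASES = "ACGT"


@dataclass(frozen=True)
class FilterConfig:
    """Constants of the spurious model and the user-facing knobs.

    ``a``/``b`` parameterize the power-law per-base mismatch rate of the
    spurious model; ``long_k_constant`` replaces the binomial above
    ``k_cutoff`` where the mismatch distribution is no longer well
    modeled.  ``prior_V`` is the prior on the deamination hypothesis
    (flag -V) and ``threshold_j`` the posterior cutoff (flag -j).
    """

    a: float = 1.0014
    b: float = -0.6628
    k_cutoff: int = 22
    long_k_constant: float = 0.01
    prior_V: float = 0.5
    threshold_j: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.prior_V <= 1.0:
            raise ValueError("prior_V must be in [0, 1]")
        if not 0.0 <= self.threshold_j <= 1.0:
            raise ValueError("threshold_j must be in [0, 1]")
        if not 0.0 < self.long_k_constant < 1.0:
            raise ValueError("long_k_constant must be in (0, 1)")


class Mismatch(NamedTuple):
    """One transition mismatch between read kmer and candidate minimizer."""

    pos_in_read: int
    pos_from_5p: int
    pos_from_3p: int
    ref_base: str
    read_base: str


@dataclass(frozen=True)
class SeedComparison:
    """A (read kmer, candidate minimizer) pair matched in RY space.

    Both kmers are held in read orientation, so the damage geometry
    (position from each sequenced fragment end) is well defined.  The RY
    projections are identical by construction; every mismatch is a
    transition.
    """

    read_kmer: KmerCode
    candidate: KmerCode  # in read orientation
    k: int
    m: int
    mismatches: tuple
    read_offset: int
    read_length: int


def make_comparison(read_fwd_code: int, candidate_key: int, k: int,
                    read_offset: int, read_length: int,
                    via_reverse: bool) -> SeedComparison:
    """Build a :class:`SeedComparison` from packed codes.

    ``candidate_key`` is the minimizer key as stored in the index; when the
    RY match occurred against the reverse orientation of the read kmer the
    candidate is reverse-complemented first so the comparison happens in
    read orientation.  Mismatch count and positions come from the XOR of
    the packed codes: a transition flips exactly the high bit of a base's
    2-bit code, a transversion would flip the low bit (and is rejected,
    since it contradicts the RY match).
    """
    read_kmer = KmerCode(read_fwd_code, k)
    cand = KmerCode(candidate_key, k)
    if via_reverse:
        cand = reverse_complement(cand)
    if kmer_to_rycode(read_kmer).bits != kmer_to_rycode(cand).bits:
        raise ValueError("candidate does not match read kmer in RY space")
    diff = read_kmer.bits ^ cand.bits
    mismatches = []
    for i in range(k):
        shift = 2 * (k - 1 - i)
        if (diff >> shift) & 3:
            rb = _BASES[(cand.bits >> shift) & 3]
            qb = _BASES[(read_kmer.bits >> shift) & 3]
            pos = read_offset + i
            mismatches.append(
                Mismatch(pos, pos, read_length - 1 - pos, rb, qb)
            )
    return SeedComparison(
        read_kmer=read_kmer,
        candidate=cand,
        k=k,
        m=len(mismatches),
        mismatches=tuple(mismatches),
        read_offset=read_offset,
        read_length=read_length,
    )


def spurious_likelihood(k: int, m: int, cfg: FilterConfig = FilterConfig()) -> float:
    """P(seed | spurious RY coincidence).

    Binomial(k, p) at m mismatches with p = a * k**b for k below the
    cutoff; the constant plateau above it.  p is clamped into [0, 1]
    (the power law exceeds 1 only at k = 1).
    """
    if not 0 <= m <= k:
        raise ValueError(f"need 0 <= m <= k, got m={m}, k={k}")
    if k >= cfg.k_cutoff:
        return cfg.long_k_constant
    p = min(1.0, max(0.0, cfg.a * float(k) ** cfg.b))
    return float(binom.pmf(m, k, p))


def deamination_likelihood(cmp: SeedComparison, profile: DamageProfile) -> float:
    """P(seed | deamination explains every mismatch).

    Independent-site product over the seed's k bases: a read T over a
    reference C contributes delta(C->T) at its 5'-distance, a read A over
    a reference G contributes delta(G->A) at its 3'-distance, a matching
    base contributes 1 - delta for the deamination its reference base is
    exposed to, and any other mismatch forces the product to zero.
    Computed in log space with underflow clamped.
    """
    mism_by_pos = {mm.pos_in_read: mm for mm in cmp.mismatches}
    log_p = 0.0
    for i in range(cmp.k):
        pos = cmp.read_offset + i
        pos5, pos3 = pos, cmp.read_length - 1 - pos
        mm = mism_by_pos.get(pos)
        if mm is None:
            shift = 2 * (cmp.k - 1 - i)
            rb = _BASES[(cmp.candidate.bits >> shift) & 3]
            if rb == "C":
                d = profile.delta(pos5, pos3, "C", "T")
            elif rb == "G":
                d = profile.delta(pos5, pos3, "G", "A")
            else:
                d = 0.0
            factor = 1.0 - d
        elif mm.ref_base == "C" and mm.read_base == "T":
            factor = profile.delta(pos5, pos3, "C", "T")
        elif mm.ref_base == "G" and mm.read_base == "A":
            factor = profile.delta(pos5, pos3, "G", "A")
        else:
            return 0.0
        if factor <= 0.0:
            return 0.0
        log_p += math.log(factor)
    return max(math.exp(log_p), _TINY)


def posterior(cmp: SeedComparison, profile: DamageProfile,
              cfg: FilterConfig = FilterConfig()) -> float:
    """P(M | seed) by Bayes' rule; defined as 0 when both likelihoods vanish."""
    p_m = deamination_likelihood(cmp, profile)
    p_not = spurious_likelihood(cmp.k, cmp.m, cfg)
    num = p_m * cfg.prior_V
    den = num + p_not * (1.0 - cfg.prior_V)
    if den <= 0.0:
        return 0.0
    return num / den


class RescuedSeed(NamedTuple):
    """A candidate that survived the filter, back-pointing to its minimizer."""

    minimizer_key: int
    read_offset: int
    via_reverse: bool
    posterior: float
    m: int
    rescued: bool  # False for exact (m=0) pass-throughs


def filter_candidates(matches: Iterable[RymerMatch], profile: DamageProfile,
                      cfg: FilterConfig = FilterConfig(),
                      read_length: int = 0,
                      exact_keys: FrozenSet[int] = frozenset(),
                      k: int = 0) -> List[RescuedSeed]:
    """Run the filter over RY-space lookup results.

    Exact candidates (m = 0) pass unconditionally.  Mismatched candidates
    pass iff posterior >= threshold (inclusive, so a threshold of 1.0
    admits only the degenerate posterior-1 cases).  Each (read kmer,
    candidate) pair is evaluated independently.  Candidates whose
    minimizer already appears in the read's exact-match seed set are
    duplicates of seeds the standard path found and are dropped.
    """
    if k < 1:
        raise ValueError("filter_candidates requires the index kmer length k")
    out: List[RescuedSeed] = []
    seen = set()
    for match in matches:
        for cand_key in match.candidates:
            if cand_key in exact_keys:
                continue
            dedup = (match.read_offset, match.via_reverse, cand_key)
            if dedup in seen:
                continue
            seen.add(dedup)
            cmp = make_comparison(
                match.read_fwd_code, cand_key, k,
                match.read_offset, read_length, match.via_reverse,
            )
            if cmp.m == 0:
                out.append(RescuedSeed(cand_key, match.read_offset,
                                       match.via_reverse, 1.0, 0, False))
                continue
            post = posterior(cmp, profile, cfg)
            if post >= cfg.threshold_j:
                out.append(RescuedSeed(cand_key, match.read_offset,
                                       match.via_reverse, post, cmp.m, True))
    return out
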