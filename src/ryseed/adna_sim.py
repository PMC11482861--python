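"""Ancient-DNA read simulation with per-read ground truth.

Fragments are drawn from a panel of reference haplotypes: a uniformly
chosen sequence, a uniform start (wrapping on circular references), a
length from an empirical or truncated-lognormal fragment-length
distribution, and a Bernoulli(0.5) strand.  Deamination is then applied
base by base in sequenced-read orientation: a C at distance i from the 5'
end becomes T with the profile's C->T rate at i, and (for double-stranded
libraries) a G at distance j from the 3' end becomes A with the G->A rate
at j.  Damage therefore never introduces transversions, so the RY
encoding of every simulated read equals that of its undamaged source —
the invariant the rescue index relies on.

Contaminant (exogenous) reads are drawn by the same process from a
contaminant panel when one is given, or from i.i.d. uniform random
sequence otherwise, and carry the same damage process.  Every read is
recorded in a truth table (TSV) for downstream benchmark classification.
Sequencing error is off by default and available as a separate uniform
per-base knob; it is not part of the damage model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .damage_model import DamageProfile, _empty_matrix
from .seed_index import PanelSequence, ReferencePanel

__all__ = [
    "FragmentLengthDist",
    "SimulatedRead",
    "fixture_profile",
    "FIXTURE_PROFILES",
    "random_panel",
    "simulate_reads",
    "write_fastq",
    "write_truth",
    "write_truth_sam",
    "read_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: Monotone terminal deamination decay over 5 positions per stratum.
#: These are artifact-defined strata: zero, double-stranded mid and high,
#: and single-stranded low (C->T at both ends, no 3' G->A geometry).
FIXTURE_PROFILES: Dict[str, dict] = {
    "zero": {"library": "ds", "rates": [0.0] * 5},
    "ds-mid": {"library": "ds", "rates": [0.20, 0.12, 0.07, 0.04, 0.02]},
    "ds-high": {"library": "ds", "rates": [0.45, 0.30, 0.18, 0.10, 0.06]},
    "ss-low": {"library": "ss", "rates": [0.08, 0.05, 0.03, 0.02, 0.01]},
}


def fixture_profile(name: str) -> DamageProfile:
    """One of the shipped damage strata as a :class:`DamageProfile`."""
    if name not in FIXTURE_PROFILES:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURE_PROFILES)}"
        )
    spec = FIXTURE_PROFILES[name]
    rates = spec["rates"]
    five = _empty_matrix(len(rates))
    three = _empty_matrix(len(rates))
    five["C>T"] = rates
    if spec["library"] == "ds":
        three["G>A"] = rates
    else:
        three["C>T"] = rates
    return DamageProfile(five, three, spec["library"])


def random_panel(length: int = 16569, gc: float = 0.44, seed: int = 1,
                 circular: bool = True, name: str = "synthetic_mt") -> ReferencePanel:
    """A seeded pseudorandom circular sequence standing in for a mitogenome.

    Synthetic: matches the mitogenome in length and GC content only, so
    the test suite needs no external download; a real FASTA drops in
    unchanged.
    """
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=p)
    seq = bytes(_BASES[codes]).decode("ascii")
    return ReferencePanel([PanelSequence(name, seq, circular)])


# ---------------------------------------------------------------------------
# fragment lengths
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentLengthDist:
    """Empirical table or truncated lognormal over fragment lengths.

    The default lognormal (median 55 bp, log-sd 0.35, truncated to
    [30, 120]) emulates the short-fragment shape of empirical aDNA
    length distributions.
    """

    lengths: Optional[np.ndarray] = None
    probs: Optional[np.ndarray] = None
    log_mean: float = float(np.log(55.0))
    log_sd: float = 0.35
    min_length: int = 30
    max_length: int = 120

    def __post_init__(self) -> None:
        if (self.lengths is None) != (self.probs is None):
            raise ValueError("empirical dist needs both lengths and probs")
        if self.lengths is not None:
            lengths = np.asarray(self.lengths, dtype=np.int64)
            probs = np.asarray(self.probs, dtype=float)
            if np.any(lengths < 1):
                raise ValueError("all fragment lengths must be >= 1")
            if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
                raise ValueError("probabilities must be nonnegative and sum to 1")
            object.__setattr__(self, "lengths", lengths)
            object.__setattr__(self, "probs", probs)
        elif self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("need 1 <= min_length <= max_length")

    @property
    def empirical(self) -> bool:
        return self.lengths is not None

    @classmethod
    def from_tsv(cls, path: str) -> "FragmentLengthDist":
        """Two-column TSV (length, probability), no header required."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (length, probability)")
        return cls(lengths=df.iloc[:, 0].to_numpy(np.int64),
                   probs=df.iloc[:, 1].to_numpy(float))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.empirical:
            return rng.choice(self.lengths, size=size, p=self.probs)
        out = np.empty(size, dtype=np.int64)
        have = 0
        while have < size:
            draw = np.rint(rng.lognormal(self.log_mean, self.log_sd,
                                         size=max(size - have, 64))).astype(np.int64)
            ok = draw[(draw >= self.min_length) & (draw <= self.max_length)]
            take = min(len(ok), size - have)
            out[have:have + take] = ok[:take]
            have += take
        return out

    @property
    def smallest(self) -> int:
        return int(self.lengths.min()) if self.empirical else self.min_length


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    sequence: str
    source: str  # panel sequence name, or "random" for synthetic contaminants
    start: int
    end: int  # start + fragment length (may exceed source length when wrapping)
    strand: str  # "+" or "-"
    damage_events: Tuple[Tuple[int, str], ...]  # (read position, "C>T"/"G>A")
    label: str  # "endogenous" | "contaminant"


def _damage_rate_vectors(profile: DamageProfile, flen: int,
                         cache: dict) -> Tuple[np.ndarray, np.ndarray]:
    """Per-position C->T and G->A rates for a fragment of given length."""
    if flen not in cache:
        ct = np.array([profile.delta(i, flen - 1 - i, "C", "T") for i in range(flen)])
        ga = np.array([profile.delta(i, flen - 1 - i, "G", "A") for i in range(flen)])
        cache[flen] = (ct, ga)
    return cache[flen]


def _apply_damage(codes: np.ndarray, profile: DamageProfile,
                  rng: np.random.Generator, cache: dict) -> Tuple[np.ndarray, list]:
    ct, ga = _damage_rate_vectors(profile, len(codes), cache)
    draws = rng.random(len(codes))
    out = codes.copy()
    events = []
    ct_hit = np.nonzero((codes == 1) & (draws < ct))[0]
    ga_hit = np.nonzero((codes == 2) & (draws < ga))[0]
    out[ct_hit] = 3
    out[ga_hit] = 0
    for pos in ct_hit:
        events.append((int(pos), "C>T"))
    for pos in ga_hit:
        events.append((int(pos), "G>A"))
    events.sort()
    return out, events


def _sequencing_error(codes: np.ndarray, rate: float,
                      rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    hit = rng.random(len(codes)) < rate
    shift = rng.integers(1, 4, size=len(codes))
    out = codes.copy()
    out[hit] = (codes[hit] + shift[hit]) % 4
    return out


def simulate_reads(panel: ReferencePanel, dist: FragmentLengthDist,
                   profile: DamageProfile, n: int, seed: int,
                   contaminant_panel: Optional[ReferencePanel] = None,
                   n_contaminant: int = 0,
                   error_rate: float = 0.0) -> List[SimulatedRead]:
    """Draw ``n`` endogenous and ``n_contaminant`` exogenous damaged reads.

    Fully reproducible from the integer seed: identical inputs yield
    byte-identical FASTQ and truth files.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lengths_ok = [len(s.seq) for s in panel.sequences
                  if s.circular or len(s.seq) >= dist.smallest]
    if not lengths_ok:
        raise ValueError("fragment length distribution exceeds every "
                         "linear panel sequence")
    rng = np.random.default_rng(seed)
    cache: dict = {}
    reads: List[SimulatedRead] = []

    panel_codes = [np.frombuffer(s.seq.encode(), dtype=np.uint8) for s in panel.sequences]
    code_lut = np.full(256, 0, dtype=np.uint8)
    for b, c in _CODE_OF.items():
        code_lut[ord(b)] = c

    def _draw_from(src_panel: ReferencePanel, src_codes, label: str,
                   prefix: str, count: int):
        for i in range(count):
            for _attempt in range(1000):
                sid = int(rng.integers(len(src_panel)))
                rec = src_panel.sequences[sid]
                L = len(rec.seq)
                flen = int(dist.sample(rng, 1)[0])
                if rec.circular:
                    if flen > L:
                        continue
                    start = int(rng.integers(L))
                    break
                if flen <= L:
                    start = int(rng.integers(L - flen + 1))
                    break
            else:
                raise ValueError("could not place a fragment after 1000 attempts")
            idx = np.arange(start, start + flen) % L if rec.circular \
                else np.arange(start, start + flen)
            frag = code_lut[src_codes[sid][idx]]
            strand = "-" if rng.random() < 0.5 else "+"
            if strand == "-":
                frag = (3 - frag)[::-1]
            damaged, events = _apply_damage(frag, profile, rng, cache)
            damaged = _sequencing_error(damaged, error_rate, rng)
            reads.append(SimulatedRead(
                id=f"{prefix}{i:07d}",
                sequence=bytes(_BASES[damaged]).decode("ascii"),
                source=rec.name, start=start, end=start + flen,
                strand=strand, damage_events=tuple(events), label=label,
            ))

    _draw_from(panel, panel_codes, "endogenous", "endo", n)

    if n_contaminant > 0:
        if contaminant_panel is not None:
            cont_codes = [np.frombuffer(s.seq.encode(), dtype=np.uint8)
                          for s in contaminant_panel.sequences]
            _draw_from(contaminant_panel, cont_codes, "contaminant", "cont",
                       n_contaminant)
        else:
            for i in range(n_contaminant):
                flen = int(dist.sample(rng, 1)[0])
                frag = rng.integers(0, 4, size=flen).astype(np.uint8)
                damaged, events = _apply_damage(frag, profile, rng, cache)
                damaged = _sequencing_error(damaged, error_rate, rng)
                reads.append(SimulatedRead(
                    id=f"cont{i:07d}",
                    sequence=bytes(_BASES[damaged]).decode("ascii"),
                    source="random", start=0, end=flen, strand="+",
                    damage_events=tuple(events), label="contaminant",
                ))
    return reads


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_fastq(reads: List[SimulatedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_sam(reads: List[SimulatedRead], panel: ReferencePanel,
                    path: str) -> None:
    """Render the simulation ground truth as a SAM of perfect placements.

    Each endogenous read is emitted at its true position with a
    full-length match CIGAR (contaminants are unmapped records).  Useful
    as an alignment-independent input to the damage-profile estimator.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for rec in panel.sequences:
        lines.append(f"@SQ\tSN:{rec.name}\tLN:{len(rec.seq)}")
    names = {s.name for s in panel.sequences}
    for r in reads:
        L = len(r.sequence)
        if r.label != "endogenous" or r.source not in names:
            lines.append(f"{r.id}\t4\t*\t0\t0\t*\t*\t0\t0\t{r.sequence}\t{'I' * L}")
            continue
        flag = 16 if r.strand == "-" else 0
        seq = r.sequence.translate(comp)[::-1] if r.strand == "-" else r.sequence
        lines.append(
            f"{r.id}\t{flag}\t{r.source}\t{r.start + 1}\t60\t{L}M\t*\t0\t0"
            f"\t{seq}\t{'I' * L}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_TRUTH_COLUMNS = ["id", "class", "seq_id", "start", "end", "strand",
                  "n_damage_events"]


def write_truth(reads: List[SimulatedRead], path: str) -> None:
    df = pd.DataFrame(
        [(r.id, r.label, r.source, r.start, r.end, r.strand,
          len(r.damage_events)) for r in reads],
        columns=_TRUTH_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _TRUTH_COLUMNS:
        raise ValueError(f"{path}: malformed truth header {list(df.columns)}")
    bad = df[df["id"].isna() | df["class"].isna()]
    if len(bad):
        raise ValueError(f"{path}: malformed row at line {bad.index[0] + 2}")
    return df
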