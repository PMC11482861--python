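# Methods

## Model overview

ryseed treats the reference as a panel of haplotype sequences (multi-FASTA,
optionally circular per record) rather than a pangenome graph; a hit is a
`(sequence, offset, orientation)` triple. The method has four moving
parts, described bottom-up.

### Encodings and hashing

Nucleotide kmers are packed 2 bits per base (A=00, C=01, G=10, T=11),
first base most significant, so lexicographic order coincides with integer
order; the maximum kmer length is 31 bases in a 62-bit key. The RY
reduction packs 1 bit per base (purine → 0, pyrimidine → 1), allowing up
to 62 bases in the same key width. With this code table purines are
exactly the even base codes, so the kmer→RY projection is a per-base
extraction of the low bit — no decoding to text. An information-theoretic
note: a length-k kmer carries 2k bits, its RY reduction k bits; the ratio
is exactly 2 for every k. The projection is surjective but not injective
(4^k kmers onto 2^k RY codes), which is why the RY table is never larger
than the minimizer table.

Minimizer selection hashes keys with Thomas Wang's invertible 64-bit
xor-shift/multiply mix. Several variants of that mix exist in the
literature; the one used here is pinned in `ry_encoding.hash64` and is
part of the index format version, since serialized indexes are only
comparable under one fixed hash.

### Winnowing and the paired indexes

Standard (w, k)-winnowing: for every window of w consecutive kmer start
positions, both orientations of each kmer are hashed; the canonical form
(smaller hash, ties toward forward) with the window-minimum hash is
indexed with all its occurrences. All kmers tying the window minimum are
kept — conservative, never loses a seed. Kmers spanning an ambiguous base
are never candidates. Circular sequences are indexed on a linearization
extended by a virtual copy of the first k−1 bases, offsets reduced modulo
the length. Keys exceeding a configurable hit cap (default 512) keep only
their first 512 sorted hits, with a warning.

The rescue index is *derived*: the RY projections of the minimizer keys,
each RY key mapping back to the minimizer keys that produced it. Indexing
RY-space minima independently would select a different sketch and lose the
guarantee that every indexed kmer is reachable through the RY path.
Queries project both orientations of each selected read kmer (the
complement swaps purine and pyrimidine, so the two RY codes differ);
this makes rescue completeness independent of which orientation happened
to win canonicalization on either side.

One deliberate departure from strict (w, k)-winnowing: a query sequence
with fewer than w kmers (length k..k+w−2) is treated as a single window.
Under the strict scheme such reads have no windows at all and could never
seed; with 30–120 bp fragments and k=29 that would discard a meaningful
fraction of real input. Reference sequences are long enough that this
rule only affects queries.

### The rescue filter

For a candidate pair (read kmer, minimizer) matched in RY space with m
transition mismatches over k bases, two likelihoods compete (see README
for the formulas): deamination — an independent-site product using the
position-dependent rates δ; and spurious coincidence — Binomial(k, p)
with p = a·k^b, a = 1.0014, b = −0.6628, replaced by the constant 0.01
for k ≥ 22 where the mismatch distribution tapers off. These constants
are adopted as configuration (`FilterConfig`), not re-fitted. The
posterior threshold comparison is inclusive (`posterior ≥ j`): since the
spurious likelihood is strictly positive, posteriors are generically < 1
and j = 1.0 reproduces the baseline exactly; the degenerate posterior-1
cases (prior 1.0) are documented as passing. Each (read kmer, candidate)
pair is evaluated independently — candidates sharing an RY code have
different mismatch patterns. Exact (m = 0) candidates always pass, and
candidates duplicating a minimizer already found by the exact path are
dropped, which is what makes the no-rescue, zero-damage, and j = 1.0 runs
byte-identical.

The likelihood product runs over the seed's k bases, not the whole read:
the seed is what is available before extension. Matching bases contribute
1 − δ using only the deamination-relevant rate for their reference base
(C→T for reference C, G→A for reference G, nothing otherwise).
Computation is in log space with underflow clamped at 1e−300; 0/0
posteriors are defined as 0 (fail).

### Damage profiles

A profile is a pair of rate matrices over the 12 `X>Y` substitution
columns, row i = position i from the respective fragment end, stored as
per-end TSV files with a header naming the columns (any order, missing
columns are zero). Default depth is 5 positions per end — terminal
deamination decays fast and 5 rows capture the shoulder. Queries beyond
the last profiled row **clamp** to that row by default (`beyond_depth =
"zero"` is available): residual interior deamination is real, and
clamping is the conservative choice for rescue sensitivity. Doubled-
stranded geometry reads C→T from the 5' matrix and G→A from the 3';
single-stranded libraries read C→T from both ends' matrices, combined as
independent events (1 − (1−r5)(1−r3)).

Estimation is direct counting over primary alignments in read orientation
(reverse-strand records are complemented and position-flipped first):
rate = substitutions / reference-base opportunities per cell, 0 where no
opportunities. `generating_profile` evaluates the rates the damage
process *actually applies* under clamping — e.g. interior C→T at the last
row's rate shows up in the 3'-end matrix cells of any counting estimator —
and is the correct ground truth when scoring estimator recovery; comparing
against the raw input matrix instead adds a constant structural term that
obscures the survivor-bias effect being measured.

### Extension and output

Clusters group seeds by (sequence, strand) with single-linkage chaining
along diagonals (band ±16), ranked by distinct-read-offset support; the
top 8 clusters are extended. Extension tries a gapless placement on the
cluster's modal diagonal first, with a bidirectional X-drop of 20 from the
anchor seed (match +1, mismatch −4); if the gapless pass cannot cover the
read, a banded affine alignment (gap open −6, extend −1 per additional
base, band ±16, global in the read, free reference ends within the band)
is computed. Alignments scoring below 0.5 × read length fail — the floor
is what lets spurious rescued seeds die at extension, and the defaults are
chosen so a single transition mismatch survives while random ~30-mers do
not. These extension details are this package's own concrete stand-in for
a production aligner's haplotype-consistent extension; the property the
filter relies on (excess mismatches kill the alignment) is preserved.

MAPQ = min(60, round(40·(1 − s₂/s₁))) from the best two candidate scores —
an artifact-defined monotone rule, not a calibrated error probability.
Ties for primary break toward the lowest (sequence, position,
orientation). Circular alignments are computed on the doubled sequence
and reported with start mod length plus a `ZC:i:1` tag; rescued-seed
provenance is carried in `ZR` (count) and `ZP` (minimum posterior). SAM
is written by a small deterministic text writer so that identical inputs
give byte-identical output — an invariant the equivalence tests assert;
parsing uses pysam throughout.

## The simulator

`adna_sim` emulates short deaminated fragments from a small (e.g.
mitochondrial) genome plus exogenous contamination. Defaults: a seeded
pseudorandom 16,569 bp circular reference at GC ≈ 0.44 standing in for a
mitogenome (synthetic — real FASTAs drop in unchanged); fragment lengths
lognormal with median 55 bp, log-sd 0.35, truncated to [30, 120]
(qualitatively the short-fragment shape of empirical aDNA length
distributions; empirical tables are accepted as TSV); uniform start,
Bernoulli(0.5) strand; damage applied per base in sequenced-read
orientation through the same `delta` the filter uses. Four shipped
strata with monotone terminal decay over 5 positions:

| name | library | terminal rates (positions 0–4) |
|---|---|---|
| zero | ds | 0, 0, 0, 0, 0 |
| ds-mid | ds | 0.20, 0.12, 0.07, 0.04, 0.02 |
| ds-high | ds | 0.45, 0.30, 0.18, 0.10, 0.06 |
| ss-low | ss | 0.08, 0.05, 0.03, 0.02, 0.01 |

Contaminants default to i.i.d. uniform random sequence (a user FASTA is
accepted), drawn with the same length and damage process. Sequencing
error is off by default and available as a separate uniform knob.

What the simulator does **not** model: NuMT-like homologous near-copies,
PCR duplicates, adapters, quality-score structure, indel errors,
reference divergence/private mutations, and fragmentation biases. Passing
tests therefore demonstrate the rescue machinery under its own stated
damage model — transitions only, position-dependent, independent sites —
not robustness to every artifact of real libraries. Because simulated
contaminants are random sequence, specificity figures here are easier
than against real bacterial genomes or NuMTs; the score floor and the
k ≥ 22 spurious plateau are the defenses that real data would exercise
harder.

## Problem sizes

The shipped benchmarks run on one core: equivalence suites use 10,000
reads, the rescue-direction comparison 20,000 endogenous + 5,000
contaminant reads, and damage-recovery 50,000 fragments per stratum, all
on the 16.5 kb synthetic circular reference at the default (k, w) =
(29, 11). These sizes give clear separation of every directional effect
(TP gain ≈ 9 percentage points of sensitivity at ds-high) while keeping
the full suite around two minutes.

## Known limitations

* The haplotype panel stands in for a pangenome graph; graph coordinates,
  haplotype-walk extension, and surjection are out of scope.
* The spurious-match power law was fitted elsewhere against bacterial
  contamination of a mitogenome; its constants are configuration here and
  may misfit other contaminant mixtures (the k ≥ 22 plateau is a blunt
  guard).
* Rescued seeds are re-scored as ordinary mismatches during extension; a
  damage-aware extension score is a possible refinement.
* Rescue requires the read's winnowed minimizer to coincide positionally
  with an indexed one; damage can shift which kmer wins a read window, a
  loss mode the RY path does not address.
* MAPQ is a monotone heuristic, not a calibrated probability.
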