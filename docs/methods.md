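# Methods

This note documents the models and procedures implemented in `fragtiler`,
the parameter choices that matter, and what the simulations do and do not
demonstrate about real sequencing data.

## Alignment model

Fragments are located by **semi-global (infix) alignment**: the whole
fragment must align, unaligned flanks of the target segment cost nothing,
and interior gaps in either sequence cost 1, as do substitutions. The
production aligner is edlib in "HW" mode with a traceback; the test suite
cross-checks its minimal distances against an independently written
quadratic dynamic program.

**Identity.** A hit is scored by `I = (|A| − E)/|A|`, where `|A|` counts
the columns of the infix alignment (matches, mismatches, interior gaps;
free flanks excluded) and `E` is its edit distance. The score is exact
rational arithmetic internally (`fractions.Fraction`), so threshold
comparisons and tie-breaks never depend on floating-point rounding.

**Edit-distance cap.** Any hit with identity ≥ `T` satisfies
`E ≤ |A|(1 − T)` and `|A| ≤ |f| + E`, hence `E ≤ |f|(1/T − 1)`. The
aligner is therefore banded at `k = ⌈|f|(1/T − 1)⌉`; the cap provably
never excludes a qualifying hit (property-tested), it only prunes.

**Tie-breaking.** Among equal-identity candidates: first fragment in
library order wins, forward orientation before reverse complement, then
the positional rule of the aligner — leftmost end position, then the
shortest alignment. The positional rule is a convention chosen for
reproducibility; any deterministic rule would do.

**Degenerate cases.** `N` bases in reads mismatch every fragment base
(edit distance stays a metric). An empty segment yields no hit rather
than an error. If the optimal alignment consumes no target base at all
(every fragment base inserted, `E = |f|`), the equal-cost form that
substitutes one segment base is reported instead, so spans are never
empty; such hits have identity 0 and never pass a positive threshold.

## Greedy recursive covering

Each read is processed by repeatedly placing the highest-identity
fragment on the current uncovered segment, splitting at the placed span
`[i, j)` into `[0, i)` and `[j, |r|)`, and recursing. A segment is
aligned only if it is longer than `min_segment_len` (default 5 bp), and a
segment where no fragment reaches identity `T` (default 0.75) stays
uncovered. Placements are reported in read order with 0-based half-open
coordinates; placements and uncovered intervals partition the read — an
invariant enforced by property tests.

Fragments longer than the current segment are still aligned (their
overhang pays interior-gap costs); they can win only if identity clears
`T`. Left sub-segments are processed before right ones purely by
convention — segments are disjoint, so the outcome is order-independent,
and covering a batch equals covering each read alone (the per-read
parallelism contract; execution is sequential, which is ample at the
problem sizes treated here).

By default each fragment is also searched as its reverse complement, with
the orientation recorded per placement, because double-stranded ligation
products are read from either strand; `--no-search-rc` disables this to
match simulations that concatenate forward fragments only.

## Fragment library design

The designer rejection-samples sequences per length class under three
constraints, then validates the result with an independent checker:

- **Homopolymers** (a nanopore error hotspot): no run longer than
  `max_homopolymer` (default 1, i.e. no two equal adjacent bases).
- **Melting temperature**: Wallace rule `Tm = 2(A+T) + 4(G+C)`, adequate
  for 10–20-mers; each length class is held within `tm_window` (default
  4 °C) of the balanced-GC midpoint `2n + 2·round(n/2)` for length `n`. A
  fixed midpoint (rather than a running class mean) keeps acceptance
  deterministic and order-independent.
- **Orthogonality**: minimum pairwise edit distance across the whole
  library, comparing each candidate and its reverse complement against
  every accepted sequence (default ≥ 4).

The default design — two fragments per length 10–20 nt, 22 in total —
mirrors the combinatorial-ligation use case. An explicit error naming the
violated constraint is raised if the attempt budget is exhausted, rather
than silently relaxing anything.

**Similarity pools.** To probe how fragment confusability degrades
covering, `similarity_pool` pairs one random fragment per length with a
copy carrying exactly `n` substitutions (distinct positions, base always
changed). Small `n` gives nearly indistinguishable pairs; accuracy should
be — and is, in the acceptance suite — non-decreasing in `n`.
Substitutions (not indels) are used so length classes stay intact.

## Read simulation

Reads are simulated by concatenating `n_fragments` (default 10) fragments
drawn uniformly with replacement, then corrupting them. Each emitted base
suffers an error with the probability attached to its **output position**
(so a positional profile describes position-in-the-sequenced-read, which
is what basecaller quality profiles measure); the error type is drawn
from a substitution/insertion/deletion mix, default (⅓, ⅓, ⅓) —
configurable, since real nanopore mixes vary by chemistry and basecaller.
Substitutions pick a different base uniformly; insertions insert one
uniform base before the current one; deletions drop it.

Ground-truth fragment intervals are propagated through every edit and
always tile the output sequence exactly. An insertion landing on an
interval boundary is assigned to the left interval (at the very start of
the read, to the first interval) — an arbitrary but fixed convention.

Three regimes are provided:

- **uniform**: one rate for the whole read (0–30% in the studies here);
- **profile**: per-position rates for the first `L = 100` bases plus a
  constant tail equal to the mean of positions 51–100. The built-in
  default profile emulates a nanopore read start: 0.40 for positions
  1–10, linear decay to 0.15 at 20 and to 0.02 at 40, flat 0.02 after.
  `profile_from_fastq` builds the same structure from real data as the
  per-position mean of `p = 10^(−Q/10)` over Phred+33 qualities;
- **random**: i.i.d. uniform bases, no truth — every placement on these
  reads is by construction a false positive.

Simulated FASTQ carries a constant placeholder quality (`I`): the
covering algorithm does not read qualities, and modelling realistic
quality strings is out of scope. All simulators are byte-reproducible
given a seed.

## Evaluation

A placement is **correct** when it names the same fragment id (and, when
reverse-complement search is on, orientation) as the truth interval it
overlaps most, with overlap ≥ 50% of the shorter interval; a truth slot
with no correct placement is **missed**; a read is **fully covered** when
every slot is matched and no placement is incorrect. The 50% rule is this
package's operational definition of "the right fragment in the right
place" — the matching threshold is configurable and echoed in the report.
Note that under errors a fully covered read need not have base-coverage
1.0 (spans shrink and grow with indels); both metrics are reported.

## Problem sizes

The acceptance studies use 1000 reads × 10 fragments for the positional-
profile experiments, 1000 × 1000 nt for the fragment-free false-positive
counts, 1000 random pairs for aligner/oracle equivalence, and 200 reads
per condition for the similarity sweep — sizes at which the binomial
sampling error on the reported percentages is a point or two, small
against the library-regeneration variability discussed next.

## Limitations

- **Regenerated inputs.** The fragment sequences and the positional error
  profile are regenerated from their design constraints and narrative
  shape at each run; all downstream percentages inherit that systematic
  variability (a few points across seeds), which is why the acceptance
  checks use wide tolerances rather than printed-precision comparisons.
- **Short fragments are weakly identifiable on arbitrary DNA.** With
  per-column identity, a random 10-mer has on the order of 10³ strings
  within edit distance 2 (identity ≥ 0.78 ≥ 0.75) out of 4¹⁰ ≈ 10⁶, so in
  1000 nt of fragment-free sequence it finds a qualifying hit with high
  probability. At `T = 0.75` the shortest pool members therefore place
  liberally on random DNA — the false-positive counts the acceptance
  script computes are dominated by them — and lowering `T` to 0.5 admits
  the longer fragments too, producing the characteristic jump in
  false-positive counts between the two thresholds. Fragment-free
  sequence can only be distinguished reliably with longer fragments or a
  stricter, length-aware score; the identity statistic itself does not
  penalize shortness.
- **Error model realism.** The simulator draws independent per-base
  errors; real nanopore errors cluster (homopolymers, k-mer context), and
  the default ⅓/⅓/⅓ type mix is a neutral assumption. Passing the
  simulated studies shows robustness to the *amount* and *position* of
  noise, not to its sequence-context structure.
- **Greedy, not optimal.** The recursion commits to the best local
  placement; a dynamic program over candidate placements could trade a
  high-identity short hit for a better global tiling. On orthogonal
  libraries the greedy choice is almost always the true one, which is the
  designed-for regime.
- **No quality-aware alignment.** Phred scores are parsed only to build
  error profiles; alignment itself is quality-blind.
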