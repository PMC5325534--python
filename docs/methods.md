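# Methods

## The analysis model

The pipeline operates on per-sample variant call tables from a fixed
experimental design: 3 cattle breeds (Polish Red, Polish
Holstein-Friesian, Hereford) × 3 ages (6, 9, 12 months) × 2 biological
replicates = 18 animals.  Calls carry, per alternate allele at a
position: total read depth, alternate-supporting depth, and the derived
SNP ratio (alternate / total).  All statistics downstream reason only
about these integers; base and mapping qualities are deliberately out of
scope.

Coordinates are 1-based inclusive throughout, matching the
`BTA19_24970466`-style locus identifiers used for bovine markers.  BED
input/output is converted at the boundary; chromosome labels are
normalised by stripping a `BTA`/`chr` prefix for keying while the
original spelling is preserved for display.  The SNP-database key is
(chromosome, position, alternate allele): two breeds share a SNP only
when the mutation itself matches.  The ratio criterion "100%" is
evaluated as `alt_depth == total_depth` on integers — never with
floating-point comparison — and general exact ratios are compared as
rationals.

## Stage-by-stage conventions

**Error records.**  After combining a breed's samples, a genomic
position carrying more than one distinct alternate allele is treated as
a caller error and removed entirely (all alleles at the position).  The
operation is idempotent and its removed-key count is reported.  The
interpretation of "more than one SNP mutation" at a position is a
design choice: only multi-sample combination can create such conflicts,
and removing the whole position is the conservative reading.

**Filters.**  The depth threshold applies to alternate-supporting
reads, not total depth (under a 100% ratio the two coincide).  A
database key survives when *any* of its evidence records passes both
criteria; requiring *all* records is available via
`evidence_mode="all"`.  Depth-only, ratio-only and combined outputs are
all emitted because each was a reported intermediate.  All filters are
monotone (output keys ⊆ input keys) and idempotent, and depth/ratio
filtering commutes — properties the test suite checks on random
evidence.

**Replicate concordance.**  For the Venn analysis a key enters a
breed's set when, in at least one age cell, both replicates support it
with alternate depth ≥ 5.  A cell missing a replicate is a hard error,
not a silent skip.  The Venn decomposition is performed on these
concordant sets before error removal, following the order in which the
analyses are presented.

**Locus classification.**  A SNP hits a locus when its position lies
inside the 1-based inclusive interval; overlapping loci each count it.
"Monomorphic" is operationalised as fixed-alternate evidence: every hit
position carries a single alternate breed-wide and every supporting
record is at 100% ratio.  This reading (rather than "exactly one hit")
is motivated by the interpretation of monomorphic loci as genotype
fixation; the alternative is exposed as `mono_def="single-hit"`.
Polymorphic loci are ranked by distinct hit positions, descending, ties
broken lexicographically by symbol so the ranking is a total order.

**Mapping percentages.**  Properly-paired % = properly_paired / mapped
× 100 and overall alignment % = mapped / total × 100, both *truncated*
(not rounded) to two decimals using integer arithmetic
(`n * 10000 // d / 100`).  Truncation reproduces all four published
values where half-up rounding reproduces only two.  Breed percentage
shares of the raw database are rounded half-up to one decimal, and the
per-animal average uses floor division — again matching the published
arithmetic conventions.

## Exact tests

**Fixed-margin enumeration.**  Both differentiation tests share one
null: non-negative integer tables with the observed margins, each with
multivariate-hypergeometric mass P(T) = Π rᵢ! Π cⱼ! / (N! Π tᵢⱼ!).
Enumeration is exact rational arithmetic (`fractions.Fraction`), so the
total null mass is exactly 1 (asserted in tests) and tail sums carry no
rounding error.  The probability-test tail is {T : P(T) ≤ P(obs)}; the
G-test tail is {T : G(T) ≥ G(obs)} with G = 2 Σ o ln(o/e) and zero
cells skipped.

**Markov chain.**  When the table space exceeds the enumeration bound
(200,000 tables), a Metropolis chain over fixed-margin tables is run:
pick two rows and two columns, propose the ±1 swap, accept with ratio
(t_il · t_jk)/((t_ik+1)(t_jl+1)).  The chain starts at the observed
table, discards a dememorisation run, and estimates the tail
probability as the mean of batch frequencies with standard error
sd(batches)/√B.  Defaults follow the Genepop conventions
(dememorisation 10,000; 20 batches × 5,000 iterations); a seed is
mandatory.  Where the suite compares chain estimates against
enumeration 100 times, it uses 100 batches × 1,000 iterations (the same
total chain length): with only 20 batches the standard-error estimate
itself is noisy enough (≈ t with 19 df) that a 3-SE band covers only
~99.3% rather than its nominal ~99.7%.

**Hardy-Weinberg.**  Conditional on allele counts, P(n_RA) ∝
n! 2^(n_RA) / (n_RR! n_RA! n_AA!) over heterozygote counts of the
correct parity; the p-value sums outcomes no more probable than the
observed one.  The Markov-chain variant walks heterozygote states ±2
(pairing two heterozygotes into the homozygotes and back) with the
corresponding Metropolis ratios — the biallelic case of the
Guo-Thompson sampler — and estimates the same tail.  Because the exact
conditional test is discrete it is conservative: under the null at
p = 0.5, n = 50 its rejection rate at α = 0.05 sits near 3½–4%, which
the calibration test bounds at 5%.

**Global combination.**  Fisher's method, X = −2 Σ ln p ~ χ²(2k).  A
p of exactly 0 (possible only from a chain estimate) is clamped to the
chain resolution with a warning.

Markers homozygous in every typed animal carry no information and are
excluded from testing with an explicit report line rather than a
failure — the behaviour appropriate for validation panels in which some
assays turn out fixed.

## Synthetic panels

The generator emulates the *statistical shape* of per-sample RNA-seq
variant calls, not reads or alignments.  Each site draws a latent class
— breed-private, shared by a breed pair, shared by all, multi-allele
error, or unassembled-reference (`N`, "de novo") — and a latent
zygosity (fixed alternate or heterozygous).  Every sample of a carrier
breed then draws total depth from a negative binomial (mean 30,
dispersion 5 — a standard bulk RNA-seq coverage shape; the source data
give no depth distribution) and alternate depth from Binomial(depth, q)
with q = 1 − ε for fixed sites (sequencing error ε = 0.005 by default)
and q = ½ for heterozygous sites.  Error sites emit two records with
distinct alternate alleles at one position; a configurable fraction of
ordinary sites is emitted as indels to exercise the accounting.  A
record with a sampled alternate depth of zero is not emitted, so all
emitted records satisfy 0 < alt_depth ≤ total_depth by construction.
Everything is a pure function of the seed.

Default class fractions (30% private, 40% shared by all, 2% error, 1%
de-novo, remainder pairwise; 60% fixed / 40% heterozygous) were chosen
once as a plausible regime that exercises every pipeline branch with
non-trivial counts; they are not estimates of the real breed
structure.

What the generator does *not* model — alignment artifacts, batch
effects, allele-specific expression, position-dependent error — bounds
what passing tests show: plant-and-recover results demonstrate that the
set algebra, filters and classifications implement their definitions
exactly, not that those definitions are robust to real-data artifacts
beyond the depth/ratio evidence they consume.

Because sequencing error makes a fixed site occasionally emit a
non-full-ratio record (P ≈ 1 − (1−ε)^depth ≈ 14% per record at the
defaults), the monomorphic-locus recovery check runs on a noise-free
panel (ε = 0), where latent zygosity maps deterministically to the
evidence; on noisy panels expectations are always computed from the
emitted evidence itself.

## Problem sizes and determinism

The shipped test suite and the acceptance script use a 10,000-site
panel for pipeline plant-and-recover, 2,000 sites for filter
equivalence, 2,000 replicates for HWE calibration and 100 seeded chains
for MC-vs-enumeration agreement — sizes at which every check is exact
or statistically stable while the whole battery runs in seconds.  All
randomness flows through explicit seeds; pipeline stage outputs are
pure functions of (inputs, settings), and output files carry provenance
headers recording the operation chain and parameters.

## Known limitations

* Genotype likelihoods, base/mapping quality and multi-sample calling
  models are out of scope; the pipeline consumes caller output.
* The exact differentiation tests enumerate or sample tables with fixed
  margins; extremely large tables rely on the chain, whose standard
  error is a batch estimate, not a bound.
* HWE enumeration is biallelic; multi-allelic markers are not
  supported.
* The published headline discovery counts that depend on the raw
  sequencing data (breed-specific record totals, unique-locus counts,
  per-breed monomorphic counts) are procedure-covered but not
  reproducible without those inputs; the arithmetic that is
  reproducible from printed tables is checked exactly.
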