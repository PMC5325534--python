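# bovisnp

Breed-specific SNP discovery from bovine liver RNA-seq variant calls.

RNA-seq of liver tissue from young bulls of three cattle breeds (Polish
Red, Polish Holstein-Friesian, Hereford; three ages × two biological
replicates, 18 animals) yields millions of per-sample SNP and indel
calls.  `bovisnp` implements, as a tested pipeline, the downstream
analysis that turns those calls into breed-specific SNP databases and
validated markers:

* **Database construction** — per-sample calls are combined per breed
  into a SNP database keyed by (chromosome, position, alternate allele)
  with all supporting evidence retained; positions carrying more than
  one distinct alternate allele in the combined breed data are treated
  as caller error records and removed wholesale.
* **Stringent filtering** — a key survives when the reads supporting the
  alternate allele number at least *d* (default 10) and the SNP ratio
  (alternate reads / covering reads) equals 100%, i.e. `alt_depth ==
  total_depth` on integers.  Depth-only and ratio-only filters are
  emitted alongside the combined one, and a replicate-concordance rule
  (depth ≥ 5 in both replicates of an age cell) feeds a three-breed
  Venn decomposition.
* **Breed comparison** — pairwise and two-versus-one unique SNP sets;
  two breeds share a SNP only when the alternate allele matches, not
  merely the position.
* **De novo detection** — confidently supported variants whose
  reference base is `N` (unassembled regions of the UMD3.1 bovine
  assembly).
* **QTL/candidate-gene analysis** — intersection with growth-trait gene
  intervals (1-based inclusive); loci classify as *monomorphic* (every
  hit position has a single alternate allele and all evidence at 100%
  ratio — genotype fixation) or *polymorphic*, ranked by distinct hit
  positions with the top-k flagged highly polymorphic.
* **Validation statistics** (Genepop-style) — per-breed genotype/allele
  frequencies, Pearson chi-square, Fisher's exact probability test on
  allele counts and the exact G test on genotype counts (fixed-margin
  null, exact rational enumeration with a Metropolis Markov-chain
  fallback), the Hardy-Weinberg exact test conditional on allele counts
  (enumeration or Guo-Thompson-style chain), and Fisher's method for
  combining loci.
* **Synthetic panels** — a generator that emulates the breed × age ×
  replicate design with planted private/shared/error/de-novo sites and
  a ground-truth table, so every stage is testable by plant-and-recover.

## Statistical core

For a biallelic marker with genotype counts (n_RR, n_RA, n_AA) and
allele counts n_R, n_A, the HWE exact test conditions on the allele
counts: P(n_RA | n_R, n_A) ∝ n! 2^(n_RA) / (n_RR! n_RA! n_AA!), and the
p-value sums P over heterozygote counts of the correct parity whose
probability does not exceed the observed one.  Differentiation tests
hold contingency-table margins fixed: the probability-test tail is all
tables with hypergeometric mass ≤ the observed mass; the G-test tail is
all tables with G = 2 Σ o ln(o/e) ≥ the observed G.  Markov-chain
estimates carry a batch standard error (defaults: dememorisation
10,000; 20 batches × 5,000 iterations).

## Worked example

Published mapping and raw-count tables ship with the package:

```python
from bovisnp.data import mapping_profiles, raw_snpdb_counts
from bovisnp.mapping import aggregate_and_percentages
from bovisnp.build import summarize_counts_from_table

for name, s in aggregate_and_percentages(mapping_profiles(), "breed").items():
    print(f"{name}: properly paired {s.properly_paired_pct:.2f}%")
overall = aggregate_and_percentages(mapping_profiles(), "global")
print(f"overall alignment {overall.overall_alignment_pct:.2f}%")

s = summarize_counts_from_table(raw_snpdb_counts())
print("grand total", s["grand_totals"]["snps_and_indels"],
      "average per bull", s["average_per_bull"])
```

prints

```
PolishRed: properly paired 81.35%
PolishHF: properly paired 82.81%
Hereford: properly paired 84.21%
overall alignment 98.55%
grand total 5641401 average per bull 313411
```

— the pooled per-breed properly-paired percentages (truncated to two
decimals), the overall alignment rate, and the 5.6-million-record raw
accounting with its floor-divided per-animal average.

The full pipeline on a synthetic panel:

```python
from bovisnp import (SimulationConfig, simulate_variant_panel,
                     PipelineSettings, run_pipeline)

per_sample, truth = simulate_variant_panel(SimulationConfig(seed=1, n_sites=2000))
report = run_pipeline(per_sample, PipelineSettings(seed=1))
st = report["stages"]
print("error positions removed:",
      {b: v["removed"] for b, v in st["error_removal"].items()})
print("combined filter:", {b: v["combined"] for b, v in st["filters"].items()})
```

prints

```
error positions removed: {'Hereford': 86, 'PolishHF': 86, 'PolishRed': 86}
combined filter: {'Hereford': 775, 'PolishHF': 791, 'PolishRed': 767}
```

(86 removed keys per breed = the 43 planted multi-allele error
positions × 2 alleles each; the combined counts are the keys whose
evidence reaches depth ≥ 10 at 100% ratio).

A `bovisnp` command-line tool exposes the same stages
(`simulate`, `build`, `filter`, `denovo`, `compare`, `qtl`, `mapstats`,
`validate`, `run`); see `bovisnp --help`.

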