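# meiomut

Analysis toolkit for meiotic-mutagenesis experiments in yeast: estimates
mutation rates from Luria-Delbrück fluctuation tests, computes a
single-division meiotic mutation rate from matched pre-/post-sporulation
frequencies, performs tetrad and random-spore recombination analysis with
crossover-interference statistics, classifies mutation spectra, and
simulates inputs for every stage.

## Modules

| Module | Purpose |
|---|---|
| `meiomut.fluctuation` | Ma-Sandri-Sarkar maximum-likelihood estimate of mutations per culture (`m`), per-division rate conversion, Foster-style 95% CIs. Jackpot counts above a configurable ceiling enter the likelihood as a censored tail. |
| `meiomut.meiotic` | Median over cultures of (meiotic − mitotic) mutant frequency; fold changes; Welch/Student t test. |
| `meiomut.tetrads` | PD/NPD/TT classification (non-2:2 tetrads flagged as gene conversions and excluded), Perkins map distance `50(T+6N)/(P+N+T)`, % recombination `100(T+2N)/n`, Perkins standard error, cM/kb, chi-square strain comparisons. |
| `meiomut.spores` | Random-spore crossover-interval classification, crossover-class tallies, expected multiple-crossover percentages (product rule), observed/expected interference ratios, mutant-vs-non-mutant group comparison. |
| `meiomut.spectrum` | Frameshift (contraction/expansion), substitution (transition/transversion), complex and in-frame-indel classification; per-phase summaries; spectrum and 200-bp positional-distribution chi-square tests. |
| `meiomut.synthetic` | Seeded generators: fluctuation cultures (synchronous-doubling or continuous growth), tetrads (Poisson four-strand model), random spores (with crossover-mutation association enrichment and interference thinning), mutation lists. |

## CLI

Every analysis reads plain TSV (UTF-8, `#` comments); structured options
(marker intervals, parental phase) come from small YAML configs.

```sh
# fluctuation-test mutation rate
meiomut rate --cultures cultures.tsv [--divisor final|final-ln2] [--out rate.tsv]

# meiotic rate from matched mitotic/meiotic counts
meiomut meiotic-rate --pairs pairs.tsv

# tetrad analysis (PD/NPD/TT, % recombination, cM ± SE, cM/kb)
meiomut tetrads --genotypes tetrads.tsv --config intervals.yaml

# random-spore crossover analysis, grouped by canavanine phenotype
meiomut spores --genotypes spores.tsv --config phase.yaml --group-by canavanine

# mutation-spectrum summary (optionally validating ref alleles against the ORF)
meiomut spectrum --mutations mutations.tsv [--orf orf.fasta]

# synthetic inputs in the same dialects
meiomut simulate {cultures|tetrads|spores|mutations} [--config sim.yaml] --seed N --out FILE
```

Input dialects:

- cultures: `culture_id  mutant_count  total_cells` (whole-culture
  equivalents; dilution/plating scaling is the caller's job)
- pairs: `culture_id  mitotic_mutants  mitotic_total  meiotic_mutants  meiotic_total`
- tetrads: `tetrad_id  spore_index  <marker...>` with two leading
  `parental_1`/`parental_2` haplotype rows
- spores: `spore_id  canavanine  <marker...>` with a `phase:` YAML mapping
  each marker's alleles to parents P1/P2
- mutations: `isolate_id  phase  position  ref  alt` (`-` for an empty
  allele; positions 1-based from the ORF start codon)

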