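# ystr

Y-chromosomal STR analysis for forensic genetics: haplotype statistics,
father–son mutation-rate estimation with exact binomial confidence
intervals, and sequence-based repeat-structure parsing.

Y-STR haplotypes are paternally inherited without recombination, so a
match identifies a patrilineage rather than an individual; the quantities
that matter in casework are how often haplotypes repeat in a population
and how often they mutate between father and son.  `ystr` computes both
sides from plain genotype tables:

* **Haplotype statistics** over configurable marker panels (minimal
  haplotype through 41-locus kits): allele and haplotype frequencies by
  counting, shared-haplotype screening, and the standard forensic
  parameters — gene/haplotype diversity `GD = n/(n−1)(1 − Σ pᵢ²)`,
  discrimination capacity `DC = N_diff/n`, and the fraction of unique
  haplotypes `F_UH = N_unique/N_diff`.  The four duplicated markers
  (DYF387S1a/b, DYF404S1a/b, DYS385a/b, DYS527a/b) are handled as
  unordered allele combinations.
* **Mutation rates** from father–son pairs: per-locus mutation counts
  with step sizes (stepwise mutation model) and gain/loss directions,
  rates `μ̂ = mutations / allele transfers` (dual-copy markers give two
  transfers per meiosis), and exact Clopper–Pearson 95% CIs.  Copies at
  dual-copy loci are matched by the parsimony pairing; the nested
  DYS389I/II pair is scored on the subtracted value II − I so a DYS389I
  event is not double-counted.
* **Repeat-structure parsing**: bracket notation such as
  `[TAGA]11 [CAGA]2 N48 [TAGA]11 [CAGA]4` is parsed into blocks, allele
  designations (including microvariants such as 19.2 from spacer
  deletions) are derived under per-locus rules, and sequence variants
  are classified as repeat-region (isoallele) or flanking-region.
* **Mutation patterns**: rate dependence on average allele repeat
  number, allele size class (25/50/25% short/moderate/long), motif
  complexity, repeat-unit length, and paternal age at gametogenesis.
* **Synthetic pedigrees**: a seeded simulator of father populations and
  father–son pairs with known per-locus rates, step and direction
  distributions, so every statistic can be validated against ground
  truth.

## Worked example

Rates and exact CIs recomputed from the shipped per-locus counts of a
published 2 548-pair Northern Han Chinese cohort:

```python
from ystr.mutation_stats import summaries_from_counts, summary_table, clopper_pearson, rate_per_1000
from ystr.refdata import load_mutation_counts

table = summary_table(summaries_from_counts(load_mutation_counts()))
print(table[table.locus.isin(["DYS392", "DYS576", "DYS627"])])
```

```
 locus  transfers  mutations  ...  rate_x1000  ci95_lower_x1000  ci95_upper_x1000
DYS392       2548          0  ...         0.0               0.0               1.4
DYS576       2548         27  ...        10.6               7.0              15.4
DYS627       2548         32  ...        12.6               8.6              17.7
```

DYS627 mutated 32 times in 2 548 transfers: rate 12.6 × 10⁻³ with exact
95% CI 8.6–17.7 × 10⁻³ (a Wald interval would print 8.2 for the lower
bound — the exact tail inversion matters at these counts).  Forensic
parameters from the cohort's full-kit haplotype sharing spectrum
(2 387 singletons, 73 doubles, 5 triples):

```python
from ystr.haplotype_stats import summary_from_spectrum
from ystr.refdata import load_sharing_spectra

s = summary_from_spectrum(load_sharing_spectra()["full"])
print(f"N_diff={s.n_diff} F_UH={s.f_uh:.4f} DC={s.dc:.4f}")
# N_diff=2465 F_UH=0.9684 DC=0.9674
```

96.84% of the 2 465 distinct haplotypes occur once; 96.74% of the 2 548
men carry a haplotype that distinguishes them from everyone sampled.

From the shell, the same pipeline on synthetic data:

```sh
ystr simulate --n-pairs 200 --seed 7 --out sim/
ystr mutation --in sim/pairs.csv --out res/
# pairs=200 transfers=8200 mutations=25 rate=3.0e-3 discriminated=11.50%
```

Subcommands: `qc`, `haplotype`, `mutation`, `pattern`, `parse-seq`,
`simulate`; each writes CSV (or `--format xlsx`) tables plus a
`manifest.json` with input digests and the seed, so identical inputs
reproduce identical tables.

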