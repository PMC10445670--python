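# Methods

## Data model and input conventions

Haplotype tables carry one row per male sample and one column per locus;
pedigree tables carry two rows per father–son pair tagged `P`/`O`.
Alleles are repeat numbers, positive, with at most one decimal place
(microvariants such as 23.2); internally they are stored as integers in
tenths of a repeat so that `14 == 14.0` holds exactly and no floating
comparison is involved.  Multi-copy genotypes are comma-separated and
canonicalized as ascending pairs — every statistic is therefore
invariant to entry order.  A single value at a dual-copy marker is
expanded to a homozygous pair (the CE single-peak convention) and noted
in the QC report.  Invalid cells (text, non-positive, over-precise) and
empty cells are excluded and logged, one message per cell, and are never
imputed; a father–son pair with an invalid locus keeps its other loci
(per-locus exclusion — whole-pair exclusion was the alternative; the
per-locus rule preserves more transfers and its effect is fully visible
in the transfer counts).

## Haplotype statistics

Frequencies are maximum-likelihood counting estimates.  Diversity uses
the unbiased estimator GD (or HD over haplotypes) = n/(n−1)(1 − Σ pᵢ²);
it is 0 for a monomorphic locus and exactly 1 when all n observations
differ.  DC = N_diff/n and F_UH = N_unique/N_diff; F_UH is reported as
not-applicable when fewer than two distinct haplotypes exist.  Samples
missing any panel locus are excluded from that panel's haplotype
statistics and counted, the conservative choice when missingness is
uninformative.  `summary_from_spectrum` computes the same parameters
directly from a multiplicity spectrum, which is how published sharing
tables can be re-analyzed without genotypes.

Two inconsistencies in the source spectra are documented rather than
patched: (i) the 17-locus column prints N_diff = 2 241 while its own
spectrum sums to 2 221 (F_UH and DC printed in the same column are
consistent with 2 221, which the package reproduces); (ii) the full-kit
HD recomputed from the printed spectrum with the stated formula is
0.999 972 88, not the printed 0.999 956 608 — the formula is followed,
the printed value is not matched, and HD is excluded from the
reproduction suite for that reason.

## Mutation detection and rate estimation

Single-copy loci: any allele difference is one event with step
|Δ| rounded to whole repeats and direction gain/loss by sign.
Fractional differences (flanking indels producing microvariants) are
counted as mutations, flagged `non_stepwise`, with a step of 0 when the
repeat count itself did not change.  Dual-copy loci: the two father
copies are matched to the two son copies by the pairing minimizing
first the number of mutated copies, then the total step count — a
parsimony rule; tests prove it equal to exhaustive enumeration of both
pairings.  Coincident mutations on both copies that happen to mimic a
single-copy change are merged by parsimony; the simulator documents
this as the one situation where detected events can undercount truth.

DYS389II contains DYS389I within its amplicon, so DYS389II is scored on
the subtracted value II − I; the raw II comparison is retained as a
diagnostic (published methods compute both).  A pair with II < I on
either side is flagged and skipped at both loci.  Both loci require all
four alleles; otherwise the pair contributes no transfer at either.

Rates are mutations per allele transfer; a dual-copy locus contributes
two transfers per meiosis, giving 33 + 2×4 = 41 transfers per pair for
the full kit.  Confidence intervals are Clopper–Pearson, computed from
beta quantiles (lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k)),
exactly 0/1 at the boundaries.  These intervals are conservative by
construction (coverage ≥ nominal).  Reported rates and bounds use the
×10³, one-decimal, half-up convention of the forensic literature; with
that convention every printed per-locus rate and CI bound of the
reference cohort table is reproduced exactly.

The reference table's own text mentions 375 stepwise mutations counted
versus the 356 = 344+8+4 that its step columns sum to; the package
reports the column-consistent totals.

## Repeat structures and designations

The grammar is whitespace-separated tokens: `[MOTIF]k` (repeat block),
bare `MOTIF` (single unit), `Nk` (spacer of k bp).  Lowercase tokens are
spacer-sequence annotations and normalized to spacers of their base
length, keeping the raw text; serialization round-trips.  Designation:
sum of repeat-block counts plus single units whose length equals the
locus repeat unit, plus a per-locus offset; spacers are excluded.  A
locus may declare a canonical spacer length (DYS448: 42 bp), and a
deviation is folded in at base-pair resolution — total bp mod unit
becomes the .x suffix, so an N38 structure with 20 counted units
designates 19.2.  The DYS460 offset (−1) is seeded from the single
published example whose trailing single unit is evidently not counted;
it is config, editable per nomenclature sheet.  All 16 published novel
repeat-region variant structures reproduce their printed designations
under the shipped rules.

Mutation attribution within compound/complex motifs ("larger" vs
"smaller" variable unit) compares block skeletons: the changed block is
"larger" when its father-side count is the maximum over repeat blocks
(ties → larger), matching both published worked examples.

## Pattern analyses

Group rates are always pooled (Σ mutations / Σ transfers), never means
of locus rates; pooling reproduces the printed tri/tetra/penta/hexa
rates (1.8/4.1/1.5/0.4 ×10⁻³) from the per-locus counts, which also
pins down the unit-length class membership shipped in the registry.
Allele size classes cut the ascending cumulative frequency at 25% and
75%, assigning a boundary allele to the class holding most of its mass
(ties → moderate); rate-by-size classifies each transfer by the
*father's* allele (the son's is a documented switch away).  The
regression of per-locus rate (×10⁻³) on frequency-weighted average
repeat number is ordinary least squares; excluding the initially
defined rapidly mutating loci is a flag.  Association tests report the
uncorrected chi-square alongside an exact test — Fisher for 2×2, a
seeded Monte-Carlo conditional test (`scipy.stats.random_table`) for
larger tables — because printed χ²/p pairs in this literature are not
always internally consistent and the two statistics can disagree at
small counts.  Paternal age: Welch's t-test for mutated vs unmutated
pairs, OLS of per-integer-age pooled rate on age, and pooled rates per
10-year interval (<20, 20–30, 30–40, >40) with a chi-square across
intervals.  Everything is deterministic given the input and the
explicit seed.

## Simulator

Fathers are drawn i.i.d. per locus from configurable allele spectra;
sons inherit each copy, which mutates with probability μ per transfer.
Steps are 1/2/3+ with a geometric tail (default split 344:8:4 with tail
continuation 0.5, matching the observed one/two/multi-step mix);
direction is a gain with probability 173/356 by default; an optional
log-linear age effect multiplies μ by exp(β·(age − mean)) with father
ages from a truncated normal (26.29 ± 4.21 years, truncated 15–55,
matching the cohort's age distribution; β defaults to 0 so marginal
rates equal μ in recovery tests).  DYS389 is simulated coherently —
DYS389I and the II-specific stretch mutate independently and the
reported II allele is their sum — so the nested constraint always
holds and the subtraction rule recovers the stretch events.

The cohort-like profile takes per-locus μ from the shipped counts table
(so DYS392 and DYS596 are exactly 0) and allele spectra as discretized
normals (sd 1.2 repeats) around typical modal alleles.  The spectra are
illustrative: real Y-STR spectra are skewed and multimodal and real
pairs share population structure, so passing recovery tests demonstrates
correctness of the estimator under the stepwise model, not calibration
to any real population.  With a 2 548-pair simulation the expected
event count is 356 and estimated per-locus rates cover the truth at the
nominal CI rate.  At sites near one repeat the step is reflected to
keep alleles positive; with realistic spectra this never triggers.

Problem sizes in the test suite (2 548 simulated pairs for recovery,
10 000 genotypes for the matcher equivalence, 10 000 replicates for CI
coverage, 500 samples for panel monotonicity) were chosen to make each
check statistically decisive at desk scale.

## Known limitations

* Motif-complexity classes (simple/compound/complex) ship as a
  provisional, editable config: the authoritative per-locus assignment
  lives in a supplementary table that is not redistributed, so pooled
  motif-class rates are not asserted against published values.
* The PowerPlex Y23 panel is shipped as the standard 23-locus kit while
  carrying the literature's reported N_L = 25 as metadata; the two are
  knowingly inconsistent and both visible.
* Panel monotonicity of F_UH is an empirical regularity, not a theorem
  (a refinement can in principle split a shared class without creating
  singletons); it is verified on simulated data where it holds.
* No genotype calling, no read-level processing, no population-genetic
  comparisons (AMOVA/Rst) and no paternity-index computation; alleles
  and structures arrive pre-called, pairs pre-confirmed.
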