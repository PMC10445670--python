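# Cohort-level reference figures from the 2 548-pair Northern Han Chinese
# father-son study (CE-typed at the 41-locus kit).  Used by the worked
# examples and the reproduction script; the per-locus mutation counts are
# in han_mutation_counts.csv and the panel sharing spectra in
# han_sharing_spectra.csv.
n_pairs: 2548
# number of father-son pairs by how many loci mutated (pairs with zero
# mutated loci make up the remainder of n_pairs)
pairs_by_mutated_loci: {1: 268, 2: 33, 3: 6, 4: 1}
father_age_mean: 26.29
father_age_sd: 4.21
father_age_median: 25
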