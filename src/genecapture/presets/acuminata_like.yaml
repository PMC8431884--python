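# Near-complete selfer with occasional apomixis: high inbreeding, very low
# heterozygosity, few multilocus genotypes among seeds, and a strongly
# dominated allele spectrum (one common allele per locus plus a tail of
# rare ones that population samples observe but single mothers rarely
# carry). Seed bunches are nearly clonal: one seed holds >90% of a bunch's
# alleles, and five bunches fall well short of 70% of the extrapolated
# regional total.
description: selfing syndrome (M. acuminata-like)
n_loci: 19
alleles_per_locus: 8
regional_alpha: 0.6
dominant_weight: 250
n_populations: 5
theta: 0.15
n_adults_per_pop: 15
inbreeding_f: 0.8
selfing_rate: 0.95
apomixis_rate: 0.1
migrant_pollen_rate: 0.01
seeds_per_bunch: 16
missing_rate: 0.04
spatial_gradient: false
rng_seed: 0
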