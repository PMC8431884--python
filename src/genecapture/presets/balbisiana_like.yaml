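# Mixed mating with low regional diversity: partial selfing and some
# apomixis, moderate differentiation, a dominated allele spectrum, and a
# higher missing-data rate (embryo extractions yield less DNA than leaf
# material).
description: mixed-mating, low-diversity syndrome (M. balbisiana-like)
n_loci: 10
alleles_per_locus: 10
regional_alpha: 0.4
dominant_weight: 25
n_populations: 5
theta: 0.25
n_adults_per_pop: 15
inbreeding_f: 0.1
selfing_rate: 0.5
apomixis_rate: 0.05
migrant_pollen_rate: 0.05
seeds_per_bunch: 16
missing_rate: 0.08
spatial_gradient: false
rng_seed: 0
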