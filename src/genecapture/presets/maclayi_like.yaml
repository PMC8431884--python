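# Outcrossing syndrome: no selfing or apomixis, high per-locus allelic
# diversity, Hardy-Weinberg-like heterozygosity, isolation by distance
# along the sampling transect.
description: outcrossing syndrome (M. maclayi-like)
n_loci: 14
alleles_per_locus: 20
regional_alpha: 1.0
n_populations: 5
theta: 0.2
n_adults_per_pop: 15
inbreeding_f: 0.0
selfing_rate: 0.0
apomixis_rate: 0.0
migrant_pollen_rate: 0.05
seeds_per_bunch: 16
missing_rate: 0.05
spatial_gradient: true
rng_seed: 0
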