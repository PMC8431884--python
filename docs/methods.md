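# Methods

## Problem and data model

The package quantifies *genetic capture*: the share of a wild population
system's allelic diversity that is present in an ex situ seed collection,
and the number of collection units needed to reach a capture target. Input
is a table of diploid codominant genotypes (integer allele codes, typically
SSR fragment lengths in bp) with sample metadata: source population, role
(wild-population plant vs seed), maternal bunch for seeds, and optional
coordinates. Allele order within a call is not meaningful; a call with one
absent allele is normalised to fully missing (half-calls are not
interpretable under diploid scoring) with a warning. Ploidy is fixed at
diploid; polyploids are out of scope.

## Quality filter

Loci whose missing fraction across all samples strictly exceeds the
threshold (default 25%) are removed first; samples are then evaluated
against the retained loci only, with the same strict threshold. Entities at
exactly the threshold are retained. Loci-first ordering maximises retained
samples and is reported in the filter report so it can be audited; the
alternative (samples first) is a defensible choice and would occasionally
retain a different margin — the report makes the consequence visible.

## Diversity indices

* **Rarefied allelic richness.** Per locus,
  `AR_l = Σ_i [1 − C(N−N_i, g) / C(N, g)]` — the expected number of
  distinct alleles in a hypergeometric subsample of `g` of the `N`
  non-missing gene copies (binomials with `N − N_i < g` contribute zero to
  the subtracted term). Group AR is the **sum** over loci, matching how SSR
  survey tables report it (a 19-locus panel yields AR in the tens to
  hundreds). The default depth `g` is, per locus, the minimum copy count
  across the groups being compared (El Mousadik–Petit practice); loci where
  any compared group has fewer than 2 usable copies are excluded from every
  group, keeping groups comparable, and flagged in the per-locus table.
* **Private alleles** are per-locus set differences of observed alleles,
  summed over loci, counted after the quality filter.
* **MLG.** A multilocus genotype is the tuple of unordered calls across
  loci. Missing is a distinct state by default (two samples differing only
  in missingness are different MLGs — conservative for clonality claims); a
  wildcard mode merges compatibility classes via union-find, documented as
  potentially chaining non-identical samples, since compatibility is not
  transitive.
* **Genotypic diversity** on MLG abundances: `H' = −Σ p_i ln p_i` (natural
  logs), `λ = 1 − Σ p_i²`, `E5 = (1/Σp_i² − 1)/(e^{H'} − 1)`, with
  `E5 = 1` for a single MLG.
* **Heterozygosity.** `Ho_l` is the heterozygous fraction of non-missing
  calls; `Hexp_l = n_c/(n_c−1) · (1 − Σ p_i²)` (Nei's unbiased gene
  diversity; the small-sample factor can be disabled). Group values are
  unweighted means over loci with data.
* **Fis** is the ratio of averages `1 − H̄o/H̄exp` over loci with
  `Hexp > 0` (standard hierarchical-F practice; per-locus Fis is also
  emitted). It is undefined, and signalled as such, when every locus is
  monomorphic.
* **Welch t tests** compare per-locality index values between seed bunches
  and populations (unequal variances, Welch–Satterthwaite fractional df).
  Using the five per-locality values per side as replicates gives the df in
  the single digits that such comparisons produce; per-locus replicates
  would be the main alternative and are not used.

## Accumulation and extrapolation

A unit × allele incidence matrix (presence of each (locus, allele) pair in
each collection unit) drives everything. The accumulation curve is the
expected cumulative number of distinct alleles as units are added in random
order: the `exact` method evaluates
`E[S_k] = Σ_i [1 − C(n−f_i, k)/C(n, k)]` (equal to the average over all
`n!` orderings); the `random` method averages seeded random permutations
(999 by default) and also yields per-step SDs. Sampling units *with*
replacement is available behind a flag for strict bootstrap semantics; the
default permutation scheme is the natural reading of cumulative addition
of distinct units.

Total richness is extrapolated from incidence: the bootstrap estimator
`Ŝ = S_obs + Σ_i (1−p_i)^n` for the regional population total, Chao2
(classic form, bias-corrected when no doubletons) as the default for
within-bunch totals where only ~16 units exist, and first-order jackknife
as a third option. Curves are normalised as percentages of `Ŝ`; bunch-level
curves are normalised against the extrapolated *regional population* total,
so "bunches needed for 70%" is relative to what the region is estimated to
hold, not to what seeds happened to contain.

Units-to-target reports the smallest `k` whose normalised mean reaches each
target (70% and 90% by default). When the observed units never reach the
target, a two-parameter Michaelis–Menten curve `S(k) = V·k/(K+k)` is fitted
to the mean curve by least squares (initial values `V = Ŝ`, `K = n/2`) and
solved for the required `k`; such readouts are always flagged as
extrapolated, and no extrapolation is attempted from fewer than 3 points.

## Population structure

AMOVA uses inter-individual allele-mismatch distances: per locus 0/1/2
shared-allele mismatches (multiset overlap of the unordered pairs), loci
with missing data in either sample skipped, and the total rescaled by
`L/L_compared` so missingness does not shrink distances. Sums of squares
follow the standard squared-distance decomposition with unequal group
sizes; `σ²_within = MS_w`, `σ²_among = (MS_a − MS_w)/n₀` (negative values
truncated to zero and flagged), `φ = σ²_among/(σ²_among + σ²_within)`. The
permutation test shuffles individuals among populations with sizes fixed
and uses the one-sided plus-one p-value `(#{φ* ≥ φ} + 1)/(n+1)`, so p is
never zero.

Nei (1972) distance between groupings: `D = −ln I` with
`I = J_XY/√(J_X J_Y)` and the J sums taken over loci before the ratio.
Pairs sharing no alleles get `D = +∞`, stored and flagged rather than
raised; complete-linkage clustering (scipy) refuses infinite inputs instead
of silently capping them. Dendrograms export to Newick with branch lengths
taken from merge-height differences.

The Mantel test correlates upper-triangle entries of a geographic and a
genetic distance matrix (Pearson), with simultaneous row/column
permutations of one matrix and the same one-sided plus-one p-value.
Geographic distance defaults to plain Euclidean distance on raw
coordinates (great-circle is available behind a flag) — adequate at the
within-region scale the analysis targets.

## The simulator

The generator mirrors the sampling design the analysis assumes: `P` local
populations on a 1-D transect, `N` adults each, and one maternal bunch of
`B` seeds per population with a uniformly chosen mother (one mother per
population, as in the motivating collections).

* Regional allele frequencies per locus: Dirichlet draws with symmetric
  concentration `regional_alpha`. An optional `dominant_weight ≥ 1`
  multiplies the first component's concentration. This asymmetric extension
  exists because the symmetric family cannot generate the spectrum that
  highly selfing SSR surveys show — one reliably common allele per locus
  plus several rare ones: in the sparse symmetric limit the off-dominant
  mass converges to ≈0.24 and concentrates in a single second allele of
  appreciable frequency, which is neither "rare tail" nor realistic for
  such data.
* Local populations drift around the regional mean via Balding–Nichols:
  `Dirichlet(p·(1−θ)/θ)`, so `θ` acts as an Fst-like differentiation
  parameter. With `spatial_gradient`, the Dirichlet mean is linearly
  interpolated between two independent regional draws along the transect,
  inducing isolation by distance.
* Adults are drawn with inbreeding coefficient `F`:
  `P(ii) = p_i² + F·p_i(1−p_i)`, `P(ij) = 2p_ip_j(1−F)`.
* Each seed follows a hierarchical cascade (order matters only for
  bookkeeping): apomixis (exact maternal clone, probability `a`), else a
  Mendelian maternal gamete plus a paternal gamete from the mother
  (selfing, `s`), from a migrant genotype drawn from the regional
  frequencies (`m`), or from a uniformly chosen other adult of the same
  population. Missing data is then masked per call, independently. A
  TruthRecord retains local frequencies and per-seed parentage so
  parameter-recovery tests can check the generator against the estimators.

### Presets

Three shipped YAML presets encode the mating syndromes the analysis
contrasts. Their fixed mating parameters are the syndrome definitions
(selfer: `s=0.95, F=0.8, a=0.1`; outcrosser: `s=0, F=0, θ=0.2`); the free
spectrum parameters were chosen once so each preset reproduces its
syndrome's published signatures (allele counts, heterozygosity,
differentiation, capture behaviour) and then frozen:

* `acuminata_like` — near-complete selfing with apomixis. 19 loci, 8
  allele classes, `alpha=0.6`, `dominant_weight=250`, `θ=0.15`, `m=0.01`,
  4% missing. Populations carry a rare-allele tail that single mothers
  rarely do, so five bunches fall well short of 70% of the extrapolated
  regional total while one seed holds >90% of its bunch's alleles. The
  price of that contrast within this model family is a pooled expected
  heterozygosity (~0.05) at the extreme low end of the selfing syndrome.
* `balbisiana_like` — mixed mating, low diversity, 8% missing (embryo
  extractions).
* `maclayi_like` — outcrossing, 14 loci with up to 20 alleles each,
  near-HWE populations (per-population |Fis| < 0.15), isolation by
  distance via the spatial gradient. Capture ≈ 90%+; three to five bunches
  reach the 70% regional target; within a bunch the seed curve keeps
  rising past 10 seeds.

### What the simulator does not emulate

Single-generation mating only (no multi-generation drift or pedigree
structure), no linkage or mutation models, no null alleles, stutter or
allele-calling error, and missingness is independent per call rather than
concentrated in low-quality extractions. Passing tests therefore show the
statistics and the sampling arithmetic are right, not that any particular
field system matches the generative family.

## Numerical choices and degenerate inputs

Binomial coefficients in rarefaction and exact curves use exact integer
arithmetic (`math.comb`), so oracle comparisons hold to 1e-9 and beyond.
Frequency tables must sum to 1 within 1e-9 per locus. Genetic identity is
clipped to ≤1 before the logarithm to absorb float excess for identical
profiles. Welch tests return `t=0, p=1` for two zero-variance groups with
equal means rather than NaN. Permutation p-values use the plus-one rule.
All randomness flows from explicit integer seeds: simulations from
`rng_seed` in the config, pipeline stages from child seeds derived from a
single `SeedSequence`, so a rerun with the same config is byte-identical
(the manifest, which echoes paths, is the only exception).

## Pipeline problem sizes

The default pipeline run uses the preset study design (5 populations × 15
adults + 5 × 16 seeds), 999 resamples for accumulation curves and 999
permutations for AMOVA and Mantel tests. The test suite and the
reproduction script use the same design with 10–20 replicates and 99–199
permutations where many replicates are aggregated, sizes at which the
Monte-Carlo properties they assert are stable.

## Known limitations

* AMOVA is one-level (among/within populations); hierarchical region
  strata and partial Mantel tests are out of scope.
* The AMOVA distance is the allele-mismatch count; φ values are therefore
  not numerically comparable across packages using other codominant
  distances, though orderings are.
* Rarefaction of private-allele counts is not implemented; PA counts are
  raw set differences and grow with sample size.
* The Michaelis–Menten units-to-target extrapolation is a convenience
  summary of a saturating trend, not a statistical estimator with an
  error bar; it is flagged wherever reported.
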