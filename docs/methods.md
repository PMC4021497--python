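# Methods

This note records the models and conventions behind `rhizospec`, the
reasoning for choices the underlying methods leave open, and what the
synthetic-data generators do and do not emulate.

## Genotype calling

Aligned marker sequences (aligned FASTA, one record per nodule isolate) are
processed per locus:

1. **Indel removal.** Every alignment column containing a gap in *any*
   sequence is removed. Ribosomal-spacer alignments carry indel-rich
   regions whose columns are not reliably homologous; per-column removal is
   deterministic and invariant to record order. The number of removed
   columns is reported.
2. **Genotype collapse.** Sequences identical after filtering share a
   genotype; a single nucleotide difference separates genotypes. Labels are
   G1, G2, … in order of first appearance, so the partition is
   deterministic and, up to relabelling, order-invariant.
3. **Ambiguity handling.** Positions where either sequence carries N are by
   default excluded both from the identity comparison and from pairwise
   difference counts (a flag treats N as a mismatch instead). Because the
   N-ignoring relation is not transitive, isolates are assigned greedily,
   in input order, to the first genotype whose *representative* (first
   member) they match; with clean data this coincides with exact
   partitioning. Other IUPAC ambiguity codes are normalised to N on input.

Distances are raw counts of differing sites. Model-based distances
(GTR/HKY) are deliberately out of scope: the downstream variance
partitioning operates on difference counts.

Isolates sequenced at only one locus keep their label there and are simply
absent from the other locus's outputs; multi-locus genotype combinations
are counted over isolates genotyped at all loci.

## Association specificity

Link strength `P_ij = n_ij / n_i` counts only nodules genotyped at the
focal locus. The genotype universe of the link matrix is the union over
all hosts, so a host is penalised for available genotypes it never uses.

**PDI denominator.** The Paired Differences Index divides the summed
differences from the strongest link by the number of partner categories
minus one, which bounds the statistic in [0, 1] for proportion inputs.
Printed variants of the formula sometimes divide by a nodule count instead;
an explicit numeric denominator mode reproduces those conventions exactly.
Ties at the maximum contribute zero terms and never affect the result.

**Simulated null.** Each replicate draws, for each of the surveyed hosts
independently, a fixed number of nodules (default 20) multinomially from
the pooled genotype frequencies of the whole survey — the availability
distribution under random sampling. The joint PDI of the replicate is the
PDI of the across-host mean link profile. A `shared` mode draws one
population per replicate for all hosts instead; per-host drawing is the
default because hosts sample nodules independently in the field. The 95%
confidence limits on the null mean are mean ± 1.96·sd/√reps (the half-width
shrinks as reps^(−1/2)); the replicate standard deviation and empirical
2.5/97.5 percentiles are also stored. Observed PDIs are declared
significant when outside those limits, and an add-one empirical tail
proportion `(#{replicates ≥ observed} + 1)/(reps + 1)` is reported
alongside.

Degenerate inputs: a single-genotype frequency vector yields an all-zero
null (valid, zero half-width); PDI of a vector shorter than 2 is an error.

## Population structure

All statistics operate on squared pairwise nucleotide differences, with
populations = host species and groups = host genera.

**Diversity summary.** Within-population diversity is the mean over
unordered isolate pairs; the corrected between-population distance is the
raw cross-population mean minus the average of the two within values. For
very small samples this corrected distance is biased slightly negative
(self-pairs are excluded from the within means but identical cross pairs
are counted); the bias vanishes as samples grow. Singleton populations
report missing within values and no Φst.

**Φst.** From the one-level variance partition of squared distances:
SSD(S) = Σ_{i<j∈S} d²_ij / |S|, among/within components via the unbalanced
expected mean squares, Φst = σ²_among / (σ²_among + σ²_within). When every
sequence is identical the statistic is undefined and reported as missing
with p = 1. The permutation test shuffles isolates between the two
populations, one-sided (permuted ≥ observed) with the add-one correction.

**Two-level AMOVA.** The total SSD is partitioned into between-group,
between-population-within-group and within-population levels; variance
components solve the standard unbalanced nested expected-mean-square
equations. Negative components are reported as computed — never truncated —
and percentages are taken on the raw components, so they always sum to
100%. Permutation schemes per level: Φ_ST permutes isolates across
everything; Φ_SC permutes isolates among populations within their group;
Φ_CT permutes whole populations among groups (preserving the number of
populations per group). With few populations the group-level test has very
few distinct relabelings; the report then flags the minimum attainable
p-value rather than pretending to resolution it lacks. Default permutation
count is 10,000 (configurable; the calibration tests use a few hundred).

A single-group partition is accepted for the degenerate case where the
design collapses to a flat two-population comparison; the
population-within-group component then reproduces Φst exactly.

## Greenhouse analyses

**Contamination rule.** Control plants that formed nodules were
cross-contaminated and are excluded; treatment plants are never excluded by
this rule. A block left without any usable conspecific control is an error,
because the block's fitness effects would be undefined.

**Fitness effect vs growth response.** Two related quantities are
implemented: the fitness effect `p = (w − w_C)/w` (bounded above by 1,
unboundedly negative) used inside the block PDIs, and the fold increase
`(w − w_C)/w_C` (bounded below by −1) used for growth-response summaries.
They always agree in sign. The block control value `w_C` is the block mean
of surviving conspecific controls: each block contains several controls,
and the mean is well-defined after contamination exclusions and has lower
variance than any single plant.

**Block PDIs.** The response PDI applies the PDI to the within-block
per-strain fitness effects; the per-block values are averaged over blocks,
with SE = sd/√k and a t-based 95% CI on the among-block variance (k = 10
blocks by default). N defaults to the strains actually present in a block
(missing strains reduce N, and the per-block N is recorded); a fixed
explicit denominator is available. Because fitness effects are signed and
unnormalised, block PDIs may exceed 1 — the statistic is scale-equivariant
and translation-insensitive in its numerator.

**Effect PDIs.** Host effect on symbiont fitness uses the nodule traits
directly — controls carry no nodules, so control normalisation is
meaningless there. Defaults: natural log for nodule counts, square root
for total nodule area (variance stabilisation for count and area data).
If any count is zero the log transform falls back to ln(x + 1) with a
logged notice. Missing nodule data are excluded trait-wise, never imputed.

**Genotype means, feedback, Mantel.** Per-(host, strain) means use only
non-contaminated records with the trait measured; the mean individual
nodule area is total area / count computed per plant *before* averaging.
Feedback correlations are Pearson correlations across strain means (two-
sided p from the t distribution, n − 2 df), optionally ln-transforming the
nodule variable. Phenotypic difference matrices are |mean_a − mean_b| over
strains, with configurable exclusions (reference strains not part of the
original sample, and strains unsequenced at the locus under test). The
Mantel statistic is the Pearson correlation over strictly-lower-triangle
entries; p permutes the rows and columns of the phenotype matrix jointly,
one-sided with the add-one correction. Constant matrices make r undefined
and raise an error.

## Synthetic-data generators

The generators default to the study's shape and are bit-reproducible under
their seeds, returning their ground truth for recovery tests.

**Association.** Four hosts in two genera with genotyped-nodule totals
{19, 18, 21, 23} sample from per-host Dirichlet preference profiles over a
22-genotype universe. The universe is split between the genera, with each
host placing 98% of its preference mass on its own genus's block —
emulating the observed clustering of symbiont genotypes by host genus. The
concentration parameter α = 0.2 produces the moderately skewed profiles
(host PDIs roughly 0.25–0.75) typical of nodule surveys. Both marker loci
receive the same drawn genotype label (perfect linkage) — a simplification;
real loci recombine, so multi-locus combination counts from the generator
understate reality.

**Sequences.** A random root sequence spawns per-cluster consensus
sequences at the between-cluster divergence (default 25 expected
differences over 756 sites) and per-genotype sequences at the
within-cluster divergence (default 6), giving the several-fold
between/within contrast seen in symbiont marker data. Gap columns shared
within a random cluster are injected at a configurable rate for
spacer-like alignments. Sequence evolution is intentionally naive — no
coalescent, rate variation or recombination.

**Greenhouse.** 2 hosts × 31 strains × 10 blocks with 5 controls per
block. Shoot weight is gamma-distributed (shape 10) with a log-scale
linear predictor: host baseline (0.05 g / 0.15 g), inoculation effect
(log 2.8 / log 2.9), a conspecific-genus origin bonus (0.25), strain
effects (sd 0.15), host×strain interaction (sd 0.5 for the specialist
host, 0.08 for the generalist — the planted response-specificity
contrast), and block effects (sd 0.1). Nodule counts are negative binomial
(host-level means 15/25, dispersion 5) with log-normal per-nodule areas
summed to a total. Controls are uninoculated except for a 7% cross-
contamination probability (small late nodules), and the generalist host
loses nodule data on ~4% of plants, mirroring realistic handling losses.
Host-benefit effects and symbiont-fitness effects are drawn
*independently*: under defaults the feedback correlations and
genotype–phenotype Mantel tests are true nulls, and their statistical
power is demonstrated instead with explicitly planted associations
(phenotype tracking sequence-cluster identity) in the test suite. Passing
tests on these generators therefore show correct recovery of planted
structure and calibrated error rates — not that real nodule data meet the
generators' distributional assumptions.

## Problem sizes and numerical conventions

The test suite and the results script run at the study's own scale: 81
isolate sequences for the population-genetic statistics, 1,000-replicate
nulls, and 999–1,000 permutations for Φst/AMOVA/Mantel where calibration
matters (permutation defaults remain 10,000 for interactive use).
Calibration checks use 200 simulated datasets per statistic with 199
permutations each, which bounds the achievable p-resolution at 0.005.

Floating-point conventions: SSD additivity holds to 1e-9 and is tested;
permutation p-values always carry the add-one correction, so the smallest
attainable p is 1/(perms + 1); all stochastic stages take explicit seeds
and identical seeds give bit-identical results. Pipeline runs derive
per-stage seeds from the run seed and record them in the manifest together
with input checksums, so every reported number is regenerable from the
manifest and inputs alone.

## Known limitations

- Genotype calling with N-ignoring identity is greedy and order-dependent
  in pathological cases (chains of mutually compatible ambiguous
  sequences); real datasets with few Ns are unaffected.
- The AMOVA group-level test is underpowered by construction when there
  are only two groups (one degree of freedom, a handful of distinct
  population relabelings); the report flags this instead of hiding it.
- Corrected between-population distances are slightly negatively biased
  for very small samples (see above).
- The generators emulate design shape and effect structure, not sequence
  realism or the spatial layout of the greenhouse bench.
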