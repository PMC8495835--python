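# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions a maintainer needs.

## Data model

A microhaplotype locus is a sequenced fragment with a catalogue of haplotype
alleles (equal-length DNA strings); genotypes are unordered diploid pairs of
allele indices with explicit missingness (both gene copies present or both
missing). Per-locus gene-copy counts n_l are always recomputed from the
calls, never cached, so filters cannot desynchronize counts. The phased-VCF
collapser re-creates the haplotype table from already-phased genotypes (one
contig = one locus, sites concatenated in coordinate order); read-backed
phasing belongs upstream and is out of scope. The Benjamini–Hochberg
correction is applied within each analysis family separately (pairwise F_ST
matrix; outlier scan; per-locus neutrality tests per estuary) and never
pooled across analyses.

## Coalescent simulator

`coalescent.sim_genealogy` implements the standard event-driven Hudson
coalescent. Conventions:

* **Time unit:** 2N generations per deme, so the within-deme pairwise
  coalescence rate is 1 at time 0. (ms users note: ms scales by 4N, so ms
  parameter values are not interchangeable with ours.)
* **Migration:** M = 4Nm scaled rate; each lineage migrates at total rate
  M/2. A scalar M gives a strict island model (destination uniform over the
  other demes); a matrix gives arbitrary topologies (the generator uses
  stepping stones).
* **Growth:** rate α in the same units; backwards in time the deme size is
  N(t) = N(0)e^{−αt}, handled exactly by mapping exponential waiting times
  through the cumulative coalescence intensity Λ(t) = (e^{αt} − 1)/α.
  Competing migration clocks stay homogeneous, so the event race is exact
  (no thinning).
* **Mutations:** infinite sites. Fixed-S mode places exactly S mutations
  uniformly on total branch length (conditioning only on S, not on tree
  shape); theta mode draws S ~ Poisson(θ·T_total/2), so E[S] = θ·a₁.
* **Guard rails:** an event cap (default 10⁷) turns pathological
  parameterizations into errors; M = 0 with samples in two demes errors
  immediately instead of hanging.

Verified against closed forms: E[T₂] = 1; E[T_total(n=10)] = 2Σ₁⁹ 1/k;
E[S] = θa₁; island-model E[T | same deme] = d and
E[T | different demes] = d + (d−1)/M.

## Tajima machinery

Constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ follow the classical definitions
(n ≥ 4; for n < 4 the variance terms degenerate and D is reported as NaN).
D = (k̂ − S/a₁)/√(e₁S + e₂S(S−1)); monomorphic loci have undefined D and are
excluded from genome-wide summaries (and from the matched null), logged.
The per-locus test uses the beta approximation: a beta density rescaled to
[D_min, D_max] with mean 0 and variance 1, two-sided p = 2·min(F(D), 1−F(D)).
Both Θ estimators are reported per locus and per site (divided by the
locus's nominal fragment length).

The genome-wide test conditions each of R replicate null genomes on the
observed configuration: for every locus with S > 0, one constant-size
coalescent with that locus's observed (missingness-reduced) gene-copy count
and exactly its S segregating sites. Reported p-values are the literal
one-sided proportions of replicates at or beyond the observed mean/median;
a (1+count)/(R+1) variant is available behind the `plus_one` flag. Group
comparisons of Θ use two-sided Mann–Whitney tests with BH across the
comparison family; per-locus and per-site Θ are both exposed (per-locus is
the default).

## AMOVA

Gene copies are units; the distance between copies is allele identity
(0/1), making the statistics F_ST-like rather than Φ_ST-like (the sequence
of the alleles is deliberately ignored at this stage). Per locus, sums of
squares come from the standard T(X) = (n² − Σc²)/(2n) identities; degrees
of freedom count only the populations/groups observed at that locus;
variance components use the unequal-size coefficients n′, n″, n‴; components
are summed over loci and F-statistics are ratios of the sums (the
ratio-of-sums convention — the alternative mean-of-ratios is not
implemented). Negative components are kept in all sums.

Permutation schemes: F_ST permutes individuals among populations; F_SC
permutes individuals among populations within their group; F_CT permutes
whole populations among groups. p = (count of permuted ≥ observed + 1)/(n_perm + 1).
A hierarchical call with a single distinct group falls back to the
single-level design with a warning. Pairwise F_ST analyzes each pair as a
two-population single-level AMOVA with BH across pairs.

## Outlier scan

The island-model null is calibrated so the simulated mean F_ST (ratio of
summed components) matches the observed genome-wide value. The initializer
comes from the coalescent identity for this estimator,
F = (T_b − T_w)/T_b = (d−1)/(Md + d−1) ⟹ M = (1/F − 1)(d−1)/d, and is
refined by geometric bisection on pilot batches (±0.005 tolerance, ≤30
steps, explicit failure diagnostics). Simulated loci are infinite-sites
haplotypes collapsed to allele identities — the same reduction applied to
observed microhaplotypes. Per-locus θ is drawn log-uniformly over a range
inferred from observed heterozygosities via θ ≈ H/((1−H)·d): the d factor
is the within-deme pairwise coalescence scale of the island model; omitting
it over-disperses simulated θ and makes the test conservative.

Conditioning on heterozygosity uses equal-count strata (default 20 bins,
widened automatically so each stratum keeps ≥ 100 simulated loci) rather
than kernel smoothing; p_high is the within-stratum proportion of simulated
loci with F_ST at least the observed value. Only the high tail is tested.
The consensus partition takes a second flag list from any external method
and intersects; with none supplied the partition is conservative (no
outliers).

## Diversity

Rarefaction depth defaults, per locus, to the smallest per-group gene-copy
count across the compared groups, and is reported in the output. E5 of a
monomorphic locus is set to 1 (the 0/0 limit) so distribution comparisons
do not drop loci asymmetrically. Group comparisons use Friedman tests with
loci as complete blocks (incomplete blocks dropped and counted; the k = 2
case uses the same rank formula on 1 df, which scipy does not cover) and
pairwise Wilcoxon signed-rank post hocs with BH. Fixed-allele intersections
use exclusive (UpSet) semantics: each locus counts in exactly the
combination of groups where it is fixed.

## RDA and variance partitioning

The response is per-allele dosage (0/1/2), mean-imputed for missing
genotypes, column-centered. Columns with allele frequency outside
[f, 1−f] (default f = 0.02) are dropped: near-monomorphic columns carry no
usable association signal, and their near-zero variance makes the loading
cloud heavy-tailed, which would break the χ²₂ calibration of the
Mahalanobis flags; set `min_allele_freq=0` to keep everything.

The fit projects the (optionally Z-residualized) response onto the column
space of the (residualized) constraints; canonical axes come from the SVD
of the projected matrix, eigenvalues are s²/(n−1). R² is reported against
the **total unconditioned** response variance so partial and marginal
fractions are commensurable; adjusted R² is the Ezekiel form
1 − (1−R²)(n−1)/(n−m−p_cond−1) with m the constraint rank and p_cond the
conditioning rank. (vegan agrees to numerical precision on unconstrained
models; for partial models vegan's RsquareAdj uses a different semipartial
convention — variance partitioning is unaffected because it only combines
marginal and full models by inclusion–exclusion.) Saturated models report
R² with NaN adjusted values. Permutation tests shuffle rows of the
residualized response and recompute pseudo-F; fitted sums of squares are
computed by projection, so permutations cost one small matrix product each.

Forward selection adds the candidate with the largest adjusted-R² gain,
tested by permutation conditional on the current selection, stopping when
p > α or when the cumulative adjusted R² would exceed that of the
all-candidate model (double stopping rule). Variance partitioning reports
[a+b], [b+c], [a+b+c] and derives [a], [b], [c], residual by
inclusion–exclusion; the identities hold to 1e−12 by construction; the
testable fractions get permutation p-values from the corresponding
(partial) models. Environmental scores attach to individuals by estuary
(constant within estuary); the landscape stage deliberately does **not**
apply the ≥18-individuals filter, so small estuaries still contribute.
Coastline distance enters as centered orthogonal polynomials (default
degree 3) of per-individual jittered distances (jitter sd 2 km by default;
its influence on R² is bounded below 1% relative in tests).

Genotype–environment flags: Mahalanobis D² of allele loadings (plain raw
right-singular-vector coordinates, plain empirical mean and covariance —
no robustification) on the first two canonical axes, flagged when D² > 25;
under approximate bivariate normality D² ~ χ²₂ so the threshold corresponds
to a ≈3.7×10⁻⁶ tail. A locus is flagged when any of its alleles is; flags
are annotated with linkage groups when a map is supplied.

## Synthetic-data generator

Each locus is one structured-coalescent genealogy: estuaries are demes in a
stepping-stone chain along the coastline within each basin (scaled neighbor
rate M_within), the two basins are coupled diffusely so each deme's total
cross-basin rate is M_between, and all demes grow exponentially (rate α).
Haplotype strings map derived/ancestral site states to random distinct
bases; diploids are formed by random pairing within deme.

Environmental association is a **selection surrogate**, not forward-time
selection: for a designated fraction of loci, the gene copies within each
deme are resampled with weights ∝ exp(β · env · carrier state of a tag
mutation chosen nearest 50% frequency), producing an allele-frequency cline
along a latent environmental axis without altering the allele catalogue.
The latent axes (2 by default) are rotated into 39 correlated observables
with added noise, so PCA is genuinely needed to recover them.

Defaults were fixed once by pilot calibration to the target signal
structure and are not data-dependent: θ = 0.8 per locus, M_within = 700,
M_between = 2.0, α = 2.0, giving neutral-locus F_CT ≈ 0.04 between basins,
F_SC ≈ 0.002 within, and clearly left-shifted genome-wide Tajima's D. The
paper-like configuration uses 15 estuaries (9 Gulf of Mexico, 6 US
Atlantic) at the published per-estuary sample sizes (304 individuals) and
approximate coastline spacings, 39 environmental variables, and 5%
environment-associated loci.

What the generator does **not** emulate: genotyping error and allele
dropout, missing data (the emitted tables are complete; the I/O layer and
filters handle missingness, tested separately), linkage between loci
(linkage-group labels are assigned uniformly at random, matching the
observation that flagged loci scatter across chromosomes, but there is no
shared genealogy between loci), recombination within loci, temporal/cohort
structure, and real selection dynamics. Passing pipeline tests on this
generator therefore demonstrates statistical correctness and calibration of
the methods under the intended signal structure — not robustness to
genotyping artifacts.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep Monte-Carlo
error well inside the asserted tolerances: 10⁵ genealogies for branch-length
recovery, 10⁴ fixed-S loci for the neutral mean of D, 200 meta-replicates
(R = 99) for null-test calibration, 2,000 loci for island-model F_ST
recovery (±0.01), 1,000 observed loci / 4,000 simulated for outlier-scan
calibration, and 120–400-locus scenarios for pipeline recovery. Production
defaults remain at the conventional scales (10,000 AMOVA permutations,
20,000 outlier simulations, 1,000 null genomes, 1,000 RDA permutations).

Ties in permutation tests count as exceedances (≥ observed − 1e−15) and the
observed arrangement is included, so p ∈ (0, 1]. Rank tolerances in linear
algebra are relative (1e−9 of the leading singular value). All randomness
flows through `numpy.random.Generator`; seeded runs are bit-reproducible,
and the CLI derives per-stage substreams from one master seed by hashing
the stage name.

## Known limitations

* The outlier scan's empirical stratified p differs in detail from
  arlequin's undocumented quantile interpolation; it is validated by null
  calibration (uniform p, ≈nominal false-positive rate) rather than
  bit-for-bit agreement.
* The Bayesian outlier method is not reimplemented; the consensus step
  accepts its flag list as a file.
* AMOVA supports at most three levels and the identity distance (a
  mismatch-count Φ_ST-like variant is not currently exposed).
* Partial-model adjusted R² follows the Ezekiel-with-conditioning formula;
  numbers are not directly comparable to vegan's semipartial convention for
  partial models.
* The per-locus beta test is an approximation; for very small n or S its
  p-values are coarse, which is why the genome-wide conclusions rest on the
  matched coalescent null instead.
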