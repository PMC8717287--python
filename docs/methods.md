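# Methods

`mimicline` analyzes a one-dimensional secondary-contact (hybrid) zone
between two color forms of a haplodiploid bee: a northern ferruginous
form and a southern black form, each ancestrally paired with a distinct
mitochondrial (COI) haplogroup.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Transect projection

Specimens are projected onto a north–south transect as the great-circle
distance from the southernmost specimen measured along a meridian
(`distance = R · |Δlat| · π/180`, R = 6371.0088 km, the IUGG mean
radius, fixed for bit-reproducibility).  Longitude is ignored by
default because the zone is a latitudinal cline and a full 2D distance
would make the 1D coordinate depend on east–west scatter; a
`great_circle` mode using both coordinates is available.

## Allele frequencies under dominance and haplodiploidy

The color locus is a single Mendelian locus with ferruginous `f`
dominant over black `b`.  Females (queens, workers) are diploid, so
only the black phenotype class is genotypically unambiguous (`bb`) and
the female black-allele frequency is the Hardy–Weinberg inversion
`b = sqrt(n_black / n_females)`.  Males (drones) are haploid: phenotype
equals genotype and `b` is the plain black proportion.  Sexes are
combined treating individuals equally — each female contributes
`b_female` effective black individuals, each black male one — rather
than weighting females as two allele copies.  Temporal change per
locality is a Pearson chi-square test of independence on the 2 × P
effective-count table (no continuity correction; effective counts may
be non-integer).  Females with a sequenced color locus can instead
contribute exact allele doses (`--use-known-genotypes`).

The estimator is consistent but slightly biased at finite n (Jensen
effect of the square root); the test suite verifies |bias| < 0.01 at
n = 10⁴ for true b from 0.1 to 0.9.

## Equilibrium cline models

The cline center sigmoid is `s(x) = (1 + tanh(2(x − c)/w))/2` with
center `c` (km) and width `w` (km, inverse of the maximum slope of the
unit-range sigmoid); the trait is `p(x) = pmin + (pmax − pmin)·s(x)`.
Model classes follow the usual fixed/free-scaling, no-tails/both-tails
taxonomy:

| class | scaling | tails | free parameters |
|-------|---------|-------|-----------------|
| I     | fixed to data extremes | none | c, w |
| II    | free    | none  | c, w, pmin, pmax |
| III   | free    | both  | + deltaL, tauL, deltaR, tauR |

Model III replaces the sigmoid beyond `c − deltaL` and `c + deltaR`
with value-continuous exponential tails whose initial slope is `tau`
times the sigmoid slope at the junction (`tau = 1` is slope-continuous).
This tail parameterization is this package's own, chosen in the spirit
of the classic two-tail cline families; bit-identity with any existing
cline package is a non-goal.  The tail rate uses the algebraically
exact ratio `s'(x_j)/s(x_j) = 2(1 ∓ tanh)/w`, which stays finite where
`s` and `s'` individually underflow.

Likelihoods treat each specimen as its own locality: Bernoulli for
binary traits (haplogroup, phenotype; predicted p clamped to
[1e−9, 1−1e−9]) and Gaussian with a free residual SD for continuous
ancestry proportions.  Posteriors are sampled by component-wise
random-walk Metropolis under uniform priors (`c` over the data range,
`w ∈ (0, 3·range]`, `pmin < pmax ∈ [0,1]`, `delta ∈ [0, range]`,
`tau ∈ [0,1]`, `σ ∈ (0,1]`).  Proposal scales adapt toward a 0.2–0.4
acceptance rate every 50 burn-in sweeps and are then frozen, so the
post-burn-in chain is a valid fixed-kernel sampler.  Defaults: 10⁵
iterations, 10% burn-in, thin 10; the test suite and acceptance script
use 8k–20k iterations, which at n = 500–2000 Bernoulli observations
already yields posterior-median centers within a few km of truth
(verified by the 20-seed recovery test).

The point estimate is the maximum-posterior sample.  The "center
range" is reported two ways — 95% equal-tailed credible interval and
the 2-log-likelihood support region — because the field's customary
phrase does not pin down either.  Model selection uses
AICc = 2k − 2logL + 2k(k+1)/(n−k−1) with ties broken toward fewer
parameters.  Width is reported both as the `w` parameter and as
`w/(pmax − pmin)` (the inverse maximum slope of the full trait range),
which differ under free scaling; printed default is `w`, labelled.

## Mito-nuclear discordance tests

Within the hybrid-zone window (default: from the southernmost
northern-haplogroup specimen to the northernmost southern-haplogroup
specimen), two df = 1 Pearson goodness-of-fit tests are computed from
all males plus females with sequenced color loci:

1. observed (northern, southern) haplogroup counts against expectations
   proportional to the (ferruginous, black) color-allele frequencies,
   the northern haplogroup being paired with its ancestral ferruginous
   allele;
2. observed (f, b) allele counts within one haplogroup against the
   overall hybrid-zone color frequencies.

Allele counting weights diploid females as two copies and males as one
by default; an individuals-equal mode (female = 0.5/0.5 for a
heterozygote) is provided because the source description is ambiguous
about the category unit.  Type-I calibration at the nominal 5% level is
verified by simulation.

## COI statistics and haplotype network

Variable sites require ≥ 2 unambiguous non-gap states;
parsimony-informative sites require ≥ 2 states each in ≥ 2 sequences.
Divergence is the percent p-distance over pairwise-comparable sites.
Divergence time is `T = divergence% / rate%`, default rate 1.5%/Myr for
COI.  Gap runs are simple-indel-coded (one presence/absence character
per distinct run) and weighted one step each in haplotype distances.

The haplotype network is the union of all minimum spanning trees of the
complete haplotype graph (an edge survives iff its endpoints are in
different components of the strictly-lighter subgraph), so tied
alternative connections are retained as reticulations.  This replaces
TCS-style statistical parsimony: at the divergence scale involved
(≤ 8 steps between haplogroup cores) both constructions give the same
two-cluster topology, and the MSN is exactly defined and cheap.  It is
an approximation, not a statistical-parsimony reimplementation.
Heterozygous individuals (IUPAC two-state codes) can be excluded before
collapsing, as is appropriate for a diploid nuclear color locus.

## NUMT-aware SNP filtering

The cascade, in order: (1) quality — biallelic sites only, calls with
depth < 3 or GQ < 20 set missing (both thresholds inclusive on the
passing side); (2) structural — drop sites on contigs < 20 kb and
sites with any missing call; (3) tiered interval exclusion —
annotation intervals, homology hits, and flank-verified fixed-scan
sites; intervals are 1-based closed internally and converted from
0-based half-open BED at I/O.  The fixed-SNP scan marks a site fixed
iff every group-A sample is homozygous for one allele and every group-B
sample homozygous for the other; any het or missing call disqualifies
(conservative, and the no-missing filter precedes the scan anyway).
Cluster diagnostics label consecutive fixed-site distances by NUMT
involvement; genuine NUMTs show as tight clusters (< 1 kb pairs).

`naive_homology_scan` is a deliberately simple exact-seed (k = 15),
ungapped-extension matcher for synthetic tests — it finds planted
near-identical insertions on either strand and essentially nothing in
random sequence (seed collision probability 4⁻¹⁵ per position).  Real
analyses should supply externally computed homology intervals as BED.

## Nuclear structure

Distances are allele-sharing distances (mean |dosage difference|/2 over
shared called sites).  Neighbor joining follows Saitou–Nei with the
Studier–Keppler criterion; Q-ties break toward the smallest index pair,
and negative branch lengths are clamped to zero with the deficit moved
to the sibling edge.  LD pruning is a deterministic keep-first scan
(drop a site iff r² > 0.5 with a kept site within 5 kb; the strict
bound carries a 1e−12 guard against correlation-rounding asymmetry).
PCA operates on the column-centered dosage matrix with a deterministic
sign convention (largest-magnitude loading positive).

Ancestry proportions come from a simplex-constrained factorization of
the dosage/2 matrix, `X ≈ Q G` with Q rows on the simplex and G in
[0, 1] (an "sNMF-like" analysis; the original's regularized solver is
not reproduced).  The solver is alternating constrained least squares:
a batched bounded per-site solve for G and a penalty-augmented NNLS per
sample row for Q; multiplicative updates were rejected because the
interleaved simplex renormalization let them stall at non-global fixed
points on planted two-population data.  A random 5% of entries is held
out; mean held-out binomial cross-entropy over 10 restarts scores each
K and its minimizer is selected.  The full cross-entropy curve is
always reported — on weakly structured data the K = 1/K = 2 choice can
be close, and interpretation is left to the user.

## Synthetic data generator

Defaults plant the fitted field values as simulation truth: color
cline (661.6, 134.3) km, mtDNA cline (607.0, 157.6) km, nuclear
admixture cline (650.6, 292) km on a 0–1300 km transect, 2000
specimens with 20% drones, a 500 bp COI alignment with 8 fixed
inter-haplogroup differences plus 4 shared-pair and 1 singleton private
variants (13 variable / 12 parsimony-informative sites, 1.6%
divergence), and a 20-sample SNP matrix (3 southern-haplogroup
carriers) with 2 planted 1 kb NUMT intervals of 15 clustered fixed
sites each, 30 scattered ancestry-fixed sites, 2% low-quality calls,
1% non-biallelic sites and two sub-20 kb contigs so every filter tier
has work to do.  Admixture carries Gaussian observation noise
σ = 0.1 (clipped to [0, 1]).  All generators are pure functions of the
configuration, which includes the seed.

What the generator does **not** emulate: linkage disequilibrium and
recombination structure (sites are independent given ancestry),
coalescent genealogies, selection, spatial clustering of collection
effort, sequencing-error haplotypes, or genotype-calling artifacts
beyond flat low-quality calls.  Passing recovery tests therefore show
that the estimators invert the generative models they assume, not that
those models capture every property of field data.

## Known limitations

- At the study's genomic sample size (n = 20) the nuclear cline width
  is weakly identified from NMF ancestry coefficients: replicate-mean
  estimates range from ~290 to ~490 km across generator seeds against a
  planted 292 km, with an upward tendency because the stacked noise
  layers (admixture noise clipped at the trait bounds, binomial
  genotype sampling, factorization shrinkage) flatten the trait
  extremes, which fixed-scaling fits absorb as extra width.  On direct
  Gaussian draws from the cline the width estimator is unbiased at the
  same n.  Centers are robust (recovered within ~3% at n = 20).
- Per-sample ancestry precision at 500 informative sites and ancestral
  allele-frequency divergence 0.2 is roughly ±0.08, which caps the
  attainable rank correlation between estimated and planted admixture
  at n = 20.
- The MCMC reports the maximum-posterior sample, not a mode-hunting
  optimum; with very short chains the AICc comparison inherits Monte
  Carlo error in logL_max.  Chain lengths in the tests were chosen so
  this error is negligible relative to the assertion tolerances.
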