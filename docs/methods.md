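# Methods

`bathypop` re-implements, as one tested pipeline, the population-genetic
analysis of a bathyal fish sampled on both sides of the Strait of Gibraltar:
six localities in three regions (northern Atlantic: northern Mid-Atlantic
Ridge MAR1 and Rockall ROC; southern Atlantic: MAR2 and MAR3; Mediterranean:
MED1 and MED2), genotyped at nine microsatellite loci (375 diploids) and
sequenced for a 613-bp mtDNA COI fragment (193 sequences). This note records
the statistical machinery, the simulation models, the defaults and the
numerical choices, and what the synthetic data do and do not establish.

## Containers and formats

Diploid genotypes live in a `GenotypeDataset` (integer allele codes,
0 = missing half-call; any half-missing call is treated as fully missing —
the conservative reading of the genepop `000` convention). Sequences live in
a `HaplotypeDataset` (equal-length uppercase A/C/G/T/N/-). The genepop
3-digit dialect is parsed and written in-package (both newline- and
comma-separated locus headers; populations named by the last individual id
of each block, per the format's convention, so round-trips are exact on that
canonical form). Sites holding N or `-` are excluded pair-by-pair in all
distance computations (pairwise deletion, the default of the standard
distance software).

## Diversity statistics

* HO = fraction of heterozygous individuals among scored ones; HE is Nei's
  unbiased estimator `(2n/(2n-1))(1 - Σp²)`; HT applies the same estimator
  to pooled allele frequencies (gene copies weighted equally, i.e.
  populations weighted by sample size — the pooling weight is not specified
  by the cited estimator family, so the simplest one is used).
* Allelic richness is the hypergeometric rarefaction estimator
  `Rs = Σ_a [1 - C(N-N_a, g)/C(N, g)]` at a user-chosen gene count `g`.
  The rarefaction unit is *genes*; when a source states a minimum sample
  size in individuals, `g = 2 × individuals` is the presumed mapping.
* FIS is Weir & Cockerham's within-population *f*, with multilocus values
  formed by summing the b and c variance components across loci before
  taking the ratio (the same weighting as the multilocus θ).
* Hardy-Weinberg tests are two-sided conditional exact tests (Levene's
  distribution): complete enumeration for two alleles, seeded Monte Carlo
  (default 10⁵ table draws, `(hits+1)/(draws+1)`) otherwise.
* Haplotype diversity uses the unbiased `(n/(n-1))(1 - Σ(c_i/n)²)`;
  nucleotide diversity is the mean pairwise proportion of differing sites.
  Reported tables round to 3 decimals at the reporting layer only.

## Differentiation and spatial structure

FST is Weir & Cockerham's θ from the a/b/c variance components, summed
across loci for the multilocus value; negative estimates are reported as
computed. ΦST is the two-level AMOVA ratio on the matrix of pairwise
nucleotide differences. Jost's D_est uses the Nei–Chesser unbiased Hs/Ht
with harmonic-mean sample size and the `k/(k-1)` correction; it equals 1
exactly for equal-size samples sharing no alleles, and multilocus values
are arithmetic means of per-locus estimates. The microsatellite AMOVA
distance is allele non-identity per locus (an FST-analogue, not the
squared-size RST distance), because FST-family statistics are the ones
reported throughout.

Significance everywhere is by seeded label permutation (default 10⁴, fewer
in the desk-scale drivers) — the same exchangeable null the classical
Markov-chain exact tests target, simpler and exactly reproducible. Ties are
counted as exceedances (`p = (hits+1)/(perms+1)`), which is conservative for
heavily discrete statistics. Families of pairwise tests are controlled by
Benjamini–Hochberg FDR at α ∈ {0.05, 0.01, 0.001}, mirroring the three-star
reporting convention.

The three-level AMOVA uses the standard sums of squares on squared
distances with the unequal-sample-size coefficients (n′, n″, n‴); F_CT is
tested by permuting whole populations among groups and F_SC by permuting
individuals among populations within groups. The grouping search ranks
candidate groupings by F_CT (descending) with F_SC as tiebreak. Two checks
anchor the implementation: a two-level AMOVA on a pair reproduces ΦST
exactly, and the components are validated against first-principles
sums-of-squares oracles in the tests.

Isolation by distance regresses genetic on geographic distance (raw or
FST/(1−FST)-linearized; raw is the default since the study's printed mtDNA
intercept is on the raw ΦST scale) with a Mantel permutation p-value
(joint row/column permutation). Geographic distances are supplied by the
user; shortest sea paths are not computed. Frequency PCA is a centered PCA
of the unit × allele (or haplotype) frequency table; axis significance
permutes individuals among units and compares per-axis inertia.

Between-group p-distances average the proportion of differing sites over
inter-group sequence pairs, with a site-bootstrap SE. Both weightings —
all sequences, or unique haplotypes per group — are available; the
haplogroup divergence quoted for this system (~0.54%) is reproduced by the
unique-haplotype weighting, which is therefore what the mimic asserts.

## Neutrality and demographic tests

Tajima's D uses the standard a₁…e₂ constants. Fu's Fs evaluates
`S' = P(K ≥ k_obs | θ = π̂)` under the Ewens sampling formula with unsigned
Stirling numbers of the first kind carried by a log-space recurrence
(stable far beyond n = 60); `Fs = ln(S'/(1-S'))`. R2 is
`sqrt(mean_i (U_i − k/2)²)/S` with U_i the singleton sites carried by
sequence i. P-values come from neutral constant-size coalescent simulation
conditioned on n and θ = π̂ (lower tail, the conventional one-tailed usage
for expansion); the conventional 0.02 significance cutoff for Fs is exposed
as a documented constant. All three statistics are cross-checked against
independent slow-path implementations on random alignments.

Bottleneck tests compare each locus' observed unbiased HE to its simulated
mutation–drift-equilibrium distribution given the observed allele count:
θ is calibrated by bisection (seeded, cached per configuration) so the
simulated mean allele count matches the observed one, under strict SMM or
a two-phase model (single-step probability and multi-step variance mapped
to a geometric step-size law). One-tailed Wilcoxon signed-rank tests across
loci report heterozygosity excess (bottleneck) and deficiency (expansion)
separately; note the signed-rank test cannot reach p < 0.05 with fewer than
five loci.

## Median-joining network

The network iterates: (1) a minimum-spanning network over the current node
set (Kruskal by distance bands; with tolerance ε = 0, the union of all
minimum spanning trees — the cited software's default); (2) median
(per-site majority consensus) vectors of triplets touching the network,
added greedily while they shorten the minimum-spanning-tree length;
(3) maximum-parsimony cleaning that removes inferred vectors whose removal
does not lengthen the tree. Ties among equal-cost candidates break
lexicographically for reproducibility. Edge annotations carry mutation
counts and 1-based positions in the supplied alignment's coordinates.

## Coalescent simulator

The two-population divergence model has present sizes N_ATL and N_MED,
optional post-split sizes Nb (between the split at `t` and `t1 < t`,
looking backwards), and an ancestral size N_anc. Four scenarios toggle the
size changes (none / MED only / ATL only / both). Ancestry is simulated by
msprime's continuous-time coalescent with piecewise-constant sizes.
Default priors (uniform): N_ATL 10–2×10⁶, N_MED 10–5×10⁵, t 1–7×10⁴
generations, t1 1–2×10⁴ with t1 < t by constrained redraw, Nb 1–4×10⁴;
microsatellite mean rate 10⁻⁶–5×10⁻⁴ per generation with per-locus rates
Gamma(shape 2) around the mean, truncated to the prior support; mtDNA rate
10⁻⁹–8×10⁻⁸ per site per generation. N_anc is never stated by the sources
this model emulates; the default ties it to the N_ATL draw, with an
independent prior available.

Microsatellite mutations follow the strict stepwise model (±1 repeat),
applied by a vectorized edge walk on the simulated genealogy (Poisson
counts per branch, net displacement by a binomial sign sum); a two-phase
variant adds geometric multi-steps. Allele sizes are reflected into
[50, 300]. This edge walk is distributionally identical to a matrix
mutation model for sampled allele sizes and about 50× faster. The mtDNA
locus is haploid and maternal, so its effective sizes are the nuclear ones
divided by 4; substitutions use msprime's HKY with equal base frequencies —
i.e. the Kimura two-parameter model — with transition/transversion
parameter κ = 2.

The summary-statistic vector is fixed and ordered: per population, mean
allele number, mean unbiased HE, mean allele-size variance, haplotype
number, haplotype diversity, mean pairwise differences and Tajima's D;
between populations, multilocus θ, ΦST, shared-allele distance and shared
haplotype count. Undefined entries carry a −999 sentinel and are imputed
with the reference-table column mean before any distance computation (an
undefined observed statistic therefore carries no signal).

## ABC

Model choice standardizes the summaries by reference-table mean/sd (MAD
optional), retains the closest fraction by Euclidean distance, and fits a
multinomial logistic regression of scenario identity on the summaries with
Epanechnikov weights, evaluated at the observed point; confidence bounds
come from a bootstrap over the retained set. Parameter posteriors use the
local-linear (weighted least squares) regression adjustment on parameters
logit-transformed to their prior bounds, back-transformed afterwards —
so adjusted draws respect the prior support by construction — with
weighted means/medians/quantiles and the mode from a weighted Gaussian KDE
(Silverman bandwidth) on the transformed scale; a singular regression falls
back to the rejection-only posterior with a warning. Scenario confidence
classifies pseudo-observed datasets from every scenario (type I: true but
not selected; type II: selected though another is true). The model check
resimulates from the posterior and reports lower-tail probabilities of the
observed values for the held-out statistics (default holdout: the two
Tajima's D entries, shared-allele distance and shared haplotype count) plus
a PCA overlay of the simulated cloud and the observed point.

Scale: the original analysis used 6×10⁶ simulations and retained 10⁴. The
desk-scale defaults here are hundreds of rows per scenario for the
narrative drivers and 800/scenario in the acceptance experiments, with
sample sizes of 20+20 diploids and 6 loci. At such table sizes the retained
*count*, not the retained *fraction*, is what matters for the local
regression (14 predictors need well over 14 retained points), so the
posterior experiments retain ~100–150 draws (fraction 0.1–0.15) rather than
the 1% used at full scale. Full-fidelity reproduction of the printed
posterior is explicitly not claimed; the acceptance surface is
self-classification of strong-size-change pods (≥80%), credible-interval
coverage for the split time (within 10 points of nominal 95%), and the
calibration properties above. Times convert to years with a 9-year
generation time, held as a configuration constant.

## Power analysis

Power is estimated by drifting every locality's allele frequencies
independently from common base frequencies for t generations at diploid
size Ne (multinomial resampling of 2Ne genes per generation), sampling the
empirical design's genotype counts, and testing with per-locus permutation
G-tests combined by Fisher's method (an asymptotic χ² option exists for
speed; it is anticonservative at sparse tables and is used only where
calibration is not the question). `t` is chosen from the closed form
`FST = 1 − (1 − 1/(2Ne))^t`; Ne defaults to 3000. The permutation budget
replaces the original software's Markov-chain settings; the equivalence is
statistical, not numerical.

## Synthetic study mimic

The generator reproduces the study's observable structure with recorded
truth. mtDNA is built from an explicit 10-haplotype tree on 11 variable
sites (9 transitions, 2 transversions) in a 613-bp backbone: the basins are
fixed for an A↔G transition at position 91, the dominant haplotypes (82%
of Atlantic samples, 74% of Mediterranean) sit one step apart, northern
Atlantic localities are nearly fixed for the Atlantic dominant haplotype
while MAR2/MAR3 share the same derived haplotypes (so the north/south
contrast is strong and the southern pair internally homogeneous), and the
designed per-locality counts reproduce the published per-locality haplotype
diversities (0.000/0.600/0.119/0.307 exactly; 0.57 vs 0.54 for MAR3, where
ten haplotypes across six localities cannot satisfy every printed cell at
once — MAR3 carries four haplotypes rather than three for the same reason).
The unique-haplotype inter-basin mean p-distance is 0.536% by construction.
Because this side is an explicit design rather than a coalescent draw,
network topology and diversity targets are guaranteed, and a coalescent
route remains available through the simulator module.

Nuclear genotypes come from the divergence coalescent with both basins at
Ne = 20 000, per-locus mutation rates log-spaced over 4×10⁻⁶–5×10⁻⁴
(allele counts spanning roughly 3–20, emulating the 2–35 spread), and the
split time calibrated by bisection until the realized between-basin
multilocus θ is within ±30% of the 0.02 target; locality samples inside a
basin are exchangeable partitions of the basin sample, so within-basin
differentiation is ~0 by construction. The truth record (JSON) stores every
generating parameter.

What the mimic does not emulate: genotyping artefacts (null alleles,
scoring error, missing data), temporal replicates, selection signatures,
within-basin nuclear substructure, and realistic mtDNA genealogical noise
(the haplotype design is deterministic given the configuration). Passing
tests on the mimic therefore establish that the estimators and the search/
classification machinery recover known structure — not that the pipeline is
robust to those artefacts.

## Problem sizes

The test suite runs at deliberately small scales: reference tables of 800
rows/scenario, 100 pods per ABC experiment, 150–200 power replicates, 199
permutations where a p-value is only checked for calibration, and 25
random alignments for the brute-force cross-checks. The analysis drivers
under `analysis/` use similar scales and state their settings at the top of
each script.
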