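# Methods

## The model of a diagnostic-SNP hybrid zone

The package assumes two divergent parental gene pools ("north" and "south")
and a panel of unlinked biallelic loci whose allele frequencies differ
strongly between the pools. Genotypes are coded 0/1/2 as copies of the
southern-lineage allele, so that a pure northern homozygote reads 0
throughout; `orient_to_south` establishes this orientation per locus from a
designated southern reference population at load time (loci where the
orientation is ambiguous — frequency exactly 0.5 or no calls — are left as
loaded and recorded). Missing data are handled by pairwise-complete
per-locus deletion in every statistic; individuals are never dropped.

At a single locus, each gene copy of a diploid descends from one of the two
pools. For unlinked, freely recombining loci a hybrid category is fully
characterised by the probability triple (p_NN, p_NS, p_SS) of the unordered
pool-of-origin pair of its two copies. The triples follow from a
gamete-origin recursion: a parent with triple (p_NN, p_NS, p_SS) transmits a
north-descended gamete with probability g = p_NN + p_NS/2, and an offspring
of parents with gamete probabilities g1, g2 has p_NN = g1 g2,
p_NS = g1(1−g2) + (1−g1)g2, p_SS = (1−g1)(1−g2). The 12 categories are the
two parentals, F1, F2, the first-generation backcrosses bWH = WH×F1 and
bMI = MI×F1, and the six second-generation backcrosses of bWH/bMI with WH,
MI and F1. F3 and later intercross generations share the F2 triple and are
deliberately not separate classes — on genotype frequencies alone they are
indistinguishable from F2, so an "F2" call should be read as "F2 or later
generation".

## Synthetic data

`make_lineage_frequencies` draws per-locus pool frequencies with a minimum
absolute differential δ (southern pool always the higher B-allele
frequency): north ~ U(0, 1−δ), south ~ U(north+δ, 1). δ = 1 gives a fully
diagnostic panel (0 vs 1). The default δ = 0.9 represents a well-designed
diagnostic array in which most loci are nearly fixed between lineages but
retain residual within-lineage polymorphism; the default panel size is 96
loci, the capacity of the common nano-fluidic genotyping arrays the
generator emulates.

Parental genotypes are Binomial(2, pool frequency) per locus
(Hardy–Weinberg, linkage equilibrium). Hybrid genotypes are generated by
two independent routes: `simulate_category` samples the origin pair from
the category triple and then each copy from its pool, while
`simulate_pedigree_category` simulates the explicit pedigree (parents,
gamete choice per locus with free recombination, offspring). For unlinked
loci the two routes define the same genotype law; the test suite verifies
this with chi-square goodness of fit at n = 10,000 per category. The
generator treats pool frequencies as known truth — parental frequency
uncertainty is not propagated into simulated genotypes; the classifier
handles that uncertainty separately through its pseudocount.

What the generator does *not* emulate: linkage between loci, genotyping
error, within-lineage population structure, and selection against hybrids.
Passing tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness of any conclusion to those realities
of field data.

## Diversity and differentiation

Observed heterozygosity is the fraction of called genotypes that are
heterozygous, averaged over loci. Expected heterozygosity uses the
small-sample correction He = (2n/(2n−1))(1 − p² − q²) with n called
diploids per locus. Allelic richness is hypergeometric rarefaction to g
gene copies, AR = Σ_i [1 − C(N−N_i, g)/C(N, g)], computed with log-gamma
binomials for stability; g defaults to the smallest per-locus called copy
count so populations of different size are comparable. Cross-population
comparisons use one-way ANOVA over per-locus values grouped by population
(the natural unit for locus-level statistics on a fixed panel).

Pairwise F_ST is the two-population Weir–Cockerham θ: per-locus variance
components a (among populations), b (among individuals within populations)
and c (within individuals) from the standard closed formulas, multilocus θ
as ratio of summed components (Σa / Σ(a+b+c), the Arlequin convention), loci
monomorphic across the pair excluded, negative θ reported as computed.
Significance is a permutation test over individuals between the pair,
p = (1 + #{θ* ≥ θ}) / (n_perm + 1), default 10,000 permutations. The test
suite checks θ against an independent oracle that computes the same
components from raw ANOVA sums of squares over allele indicators.

Temporal pooling follows the field rule: for a location sampled in two
years, compute θ between the year groups; pool unless p < 0.05, otherwise
split the location into per-year populations for all downstream analyses.

## PCA and Tracy–Widom

Genotype columns are centred by 2p̂ and scaled by √(p̂(1−p̂)); missing
entries are imputed to the column mean (zero after centring) for PCA only.
Eigen-decomposition of the sample covariance gives coordinates
(eigenvectors scaled by √eigenvalue) and variance explained. Axis
significance tests the largest remaining eigenvalue sequentially against a
Wishart null, using a moment-based effective marker count; the effective
count is estimated from the *noise* spectrum excluding the tested
eigenvalue, because a dominant signal eigenvalue collapses the classical
estimate and masks real structure. Tracy–Widom (β = 1) tail probabilities
come from the shifted-gamma approximation (shape 46.446, scale 0.18605,
shift 9.84801), accurate to about 1e−3 over the relevant range. Testing
stops at the first axis with p ≥ 0.05. Calibration note: with a very
dominant first axis and small samples (tens of individuals) the sequential
test for the second axis is anti-conservative; at sample sizes around 200
individuals it is well calibrated, and the test suite exercises it at that
scale.

## Admixture EM and Evanno ΔK

The admixture model is the standard one: individual i carries ancestry
proportions q_i over K pools with pool allele frequencies f_k, and
g_il ~ Binomial(2, Σ_k q_ik f_kl). Estimation is maximum likelihood by EM
on expected allele-origin counts, which is monotone in the log-likelihood
(asserted in tests). Missing genotypes are marginalised. Initialisation is
random (Dirichlet q, uniform f) from an explicit seed; convergence when the
log-likelihood gain drops below 1e−6 (default cap 2,000 iterations;
non-convergence flags the result rather than raising). Frequencies are
clipped to [1e−9, 1−1e−9] to keep the likelihood finite at fixed loci.
Label switching across replicate runs is resolved by the best cluster
permutation against a reference replicate.

K is chosen by Evanno's ΔK = mean|L(K+1) − 2L(K) + L(K−1)| / SD(L(K)) over
replicate log-likelihoods (10 replicates by default), maximised over
interior K. Because the replicates here are ML fits rather than MCMC
posterior estimates, their spread at the optimal K is tiny — which sharpens
rather than degrades the ΔK peak; a zero SD (exactly constant likelihoods)
is treated as an error. An individual's "admixture proportion" in summaries
is its minor-cluster ancestry 1 − max_k q_ik, with 10% as the default
threshold for calling an individual admixed.

## Hybrid classification

The classifier is the genotype-frequency-class model in plug-in
empirical-Bayes form. Pool frequencies are estimated from parental baseline
samples with an additive pseudocount of 0.5 per allele
(p̂ = (count + 0.5)/(copies + 1)), which keeps likelihoods finite when a
baseline is fixed and encodes the sampling uncertainty of small baselines.
Per individual, log L(c) = Σ_loci log Σ_w p_w(c) · P(g | w) with origin-pair
genotype likelihoods: NN and SS are Hardy–Weinberg within the respective
pool; NS draws one Bernoulli copy from each pool. Missing loci drop out.
The prior over the 12 categories is uniform by default. Individuals with no
called loci are flagged unclassifiable.

Identifiability: F1 and F2 share the expected admixture proportion 0.5 and
heterozygosity structure at diagnostic loci; they are separated only by
recombinant homozygous genotypes, which F1 cannot carry at diagnostic loci.
Consequently a small fraction of F2-like F1 assignments (and vice versa) is
expected, and the power report counts F1→{F1, F2} as a tolerated assignment
in its paper-style summary column while always emitting the raw confusion
matrix.

The marker-power harness simulates n individuals per category (default
10,000, i.e. 120,000 total for 12 categories) from known pool frequencies,
estimates baselines from independently simulated parental samples (default
30 each), classifies blind, and tabulates the confusion matrix, percent
correct and mean confidence of correct assignments. On a fully diagnostic
96-locus panel, parental categories are recovered at 100% with posterior
confidence ≈ 1, and F1 individuals are never assigned to parental or
backcross categories.

## ABBA-BABA / Patterson's D

D uses population derived-allele frequencies rather than single-genome
pattern counts, the appropriate estimator for population samples (and the
reason pattern "counts" are non-integer): with the ancestral state set to
the outgroup's major allele per locus, abba_l = (1−p1) p2 p3 (1−pO) and
baba_l = p1 (1−p2) p3 (1−pO), summed over loci; D = (ΣA − ΣB)/(ΣA + ΣB).
Loci with no outgroup calls are dropped; a polymorphic outgroup is counted
and reported. The standard error is a delete-one-locus jackknife over
informative loci (each unlinked array SNP is its own block; at least three
informative blocks required), Z = D/SE with a two-sided normal p. Raw
weighted sums and per-locus means are both reported, since published tables
differ in scaling convention. A significantly positive D is labelled
gene flow P3→P2, significantly negative as excess P1–P3 shared ancestry.

## Pipeline

`run_pipeline` executes diversity → temporal pooling → pairwise F_ST →
PCA + Tracy–Widom → admixture + ΔK → hybrid classification → D-statistics
from one YAML config (exactly one of a real-input block or a synthetic
block), writing every table as TSV plus a run log that records seeds and
the per-location pooling decisions. Every stochastic stage takes a seed
derived from the single config seed, so re-runs are byte-identical.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to make the statistical
assertions sharp while staying light: simulator-equivalence chi-square at
10,000 individuals per category on 3 loci; the full 12 × 10,000 power study
on 96 fully diagnostic loci; 200 replicate null-D panels of 1,000 loci with
20 diploids per population; permutation-uniformity at 1,000 replicate tests
of 199 permutations; admixture recovery on 80 individuals at 96 loci; and
Tracy–Widom cluster tests at 200 individuals.

## Known limitations

* The classifier is the plug-in posterior; it conditions on point estimates
  of baseline frequencies (softened only by the pseudocount) rather than
  integrating over them as a full Bayesian treatment would. No MCMC variant
  is provided.
* The admixture estimator assumes independent pool frequencies; correlated
  allele-frequency priors are out of scope.
* Linked loci, genotyping error and within-lineage substructure are outside
  the simulation and the likelihoods.
* The VCF reader is a convenience for biallelic SNPs with GT fields only.
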