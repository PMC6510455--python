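# Methods

This note documents the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Consensus genotyping

Faecal DNA yields unreliable single amplifications: allelic dropout turns
heterozygotes into false homozygotes and stutter produces false alleles one
repeat unit away. The consensus protocol accepts a per-locus call only when
two independent amplifications agree exactly. A pair with one called and
one missing replicate is treated as a *conflict*, not as a pass-through
call: it is precisely the signature of dropout, and accepting it would bias
toward false homozygotes. If round 1 (replicates 1–2) conflicts anywhere
and a second extraction exists, round 2 (replicates 3–4) must itself be
conflict-free at the previously conflicting loci; otherwise the sample is
discarded. Loci consistent in either accepted round enter the consensus.
A genotype is retained with consistent calls at ≥ `min_consistent_loci`
loci (default 12 on the 16-locus field panel; analyses of reduced panels
pass an explicit threshold). The threshold is deliberately configurable:
published protocols are ambiguous about whether sexing loci count toward
it, so locus subsetting is always explicit rather than implied by the
threshold.

## Individual matching and probability of identity

Samples are clustered into individuals by single linkage over the graph
connecting pairs with ≤ `max_mismatch` allele mismatches (multiset
arithmetic per locus: 2 − |intersection of the two allele pairs|) across
≥ `min_shared_loci` loci called in both. Single linkage mirrors tolerant
genotype-matching software: dropout chains (A→A′→A″) collapse into one
individual. `min_shared_loci = 6` guards against spurious merges of
mostly-missing genotypes — at six informative loci the sibling PID is
already far below one over the population sizes this pipeline targets.
The per-individual consensus call is the majority call per locus; ties go
to the most complete member, then the lexicographically smallest sample id,
which makes clustering invariant to input order.

PID estimators per locus (aⱼ = Σ pᵢʲ):

* naive: 2a₂² − a₄ (probability two random HWE genotypes match);
* unbiased: [n³(2a₂² − a₄) − 2n²(a₃ + 2a₂) + n(9a₂ + 2) − 6] /
  [(n−1)(n−2)(n−3)], where n is the number of genotyped individuals behind
  the frequency estimates at that locus (undefined below n = 4; converges
  to the naive form as n → ∞ and corrects its downward small-sample bias);
* full-sibling: 0.25 + 0.5a₂ + 0.5a₂² − 0.25a₄ (verified in the tests
  against brute-force enumeration of sibling genotype pairs under HWE).

Cumulative values are products across loci, which assumes linkage
equilibrium — the LD permutation test is the companion diagnostic.

## Diversity statistics

All statistics use the per-locus number of genotyped individuals n_l, not
the global sample size, because missingness varies by locus.

* H_E is Nei's unbiased gene diversity (2n/(2n−1))(1 − Σp²).
* F_IS is the Weir–Cockerham f from within-population variance components;
  the multilocus value is the ratio of components summed over loci and
  alleles, not a mean of per-locus ratios (per-locus ratios are unstable at
  small n). Monomorphic loci are excluded. A heuristic 1 − H_O/H_E variant
  exists behind `fis_simple` for sensitivity checks only.
* A_R(g) is hypergeometric rarefaction to 2g genes, the exact expectation
  of the distinct-allele count in a subsample (validated against exhaustive
  subset enumeration in the tests). Default g = 8 genotypes, the smallest
  common group size in the cross-population comparisons this mirrors.
* Null-allele frequency defaults to the Chakraborty estimator
  (H_E − H_O)/(H_E + H_O), with Brookfield's (H_E − H_O)/(1 + H_E) as an
  option; on the motivating dataset's per-locus table the Chakraborty form
  back-calculates the printed values far more closely than Brookfield's.
* The HWE test is the exact conditional (Levene) test: the p-value sums the
  conditional probabilities P(table | allele counts) =
  n! Πmᵢ! 2ʰ / ((2n)! Πnᵢⱼ!) of all genotype tables no more probable than
  the observed one. Enumeration is exact up to a configurable table bound
  (default 2×10⁵ tables, a few seconds); beyond it the function directs the
  caller to the Monte-Carlo mode (random gene pairings, add-one p
  estimate). Because the null distribution is discrete the test is
  conservative; with ≥ 4 alleles and n ≈ 50 its empirical size is close to
  nominal (checked by simulation in the acceptance suite).
* LD uses the log-likelihood-ratio G on the two-locus genotype contingency
  table with a permutation null (p = (1 + #{G* ≥ G}) / (1 + n_perm)).

## Relatedness

M_xy is the allele-sharing index: per comparable locus, similarity ∈
{0, 0.5, 1} = half the shared-allele count; M_xy is the mean over loci. It
measures identity in state, so its baseline between unrelated individuals
rises as allele numbers fall — sibship thresholds are therefore empirical.
The shipped defaults (≥ 0.59 full-sib/parent-offspring, ≥ 0.43 half-sib)
are the field-calibrated values for the motivating 10-locus panel;
comparisons are inclusive so a pair at exactly the threshold belongs to the
named class. Pairs with < 5 comparable loci are flagged low-confidence
(the variance of a mean over so few trinary values is large). The
offspring-candidate rule assigns a genotype to the most-related resident
female only when that relatedness exceeds 0.5 *and* independent field
evidence (small faecal diameter) indicates a juvenile; ties assign nothing.

## Spatial structure

Each individual gets one planar coordinate: the GPS home-range centroid
when available, else the area centroid of the minimum convex polygon of its
observation locations (degenerate point sets fall back to the arithmetic
mean). Coordinates are projected meters; at study extents of a few hundred
km² planar Euclidean distances (reported in km) are adequate.

The autocorrelogram converts per-locus codominant squared distances
(0/1/2/3/4 by shared-allele configuration, summed over loci) into a
covariance matrix by double centering (−½ J D² J). Per distance class, r is
the sum of off-diagonal covariance over the class's pairs divided by the
summed diagonal terms of the individuals involved. "Even classes" splits
the sorted pair distances into classes of equal pair count (±1), which
equalizes the power per class. The null reassigns genotypes to locations by
permutation (default 999; envelope = 2.5–97.5 percentiles; one-tailed p on
the side of the observed sign); the bootstrap resamples pairs within class.
The class count is a required analysis choice, not a silent default: class
width trades spatial resolution against per-class precision. For the
default synthetic population (~23 individuals, 253 pairs) 12 classes (~21
pairs each) resolve the mother–daughter/litter scale; that is the setting
under which the shortest-class r is significantly positive in ≥ 80% of
replicates.

The dissimilarity-vs-distance curve uses Kosman–Leonard codominant
dissimilarity, which for this diploid case is exactly 1 − M_xy (asserted as
a cross-module identity in the tests). Binned means (default 2 km) are
descriptive; no smoothing claims are made.

## Sampling-source comparison

Groups (invasive, non-invasive, combined) are compared at equal sample
sizes by subsampling: for each size g and iteration, g genotypes are drawn
without replacement and the per-locus allele count and unbiased H_E
(computed with the subsample's own per-locus n; the plug-in variant is
available behind a flag) are averaged across loci. Defaults follow the
study design this emulates: sizes 2–12, 100 iterations. Per size, the
groups' iteration values are compared by one-way ANOVA plus Tukey HSD;
the significance threshold is Bonferroni-adjusted by the number of
comparisons (11 sizes × 3 group pairs = 33 → 0.05/33 ≈ 0.0015). Using the
unbiased H_E removes the mechanical sample-size effect, so remaining group
differences reflect composition (who was sampled), which is the question
of interest.

## Synthetic populations

`simulate_population` builds: territorial females on a jittered hexagonal
lattice (spacing 7.1 km, jitter 40% of the 2.5 km field SD); a deliberately
oversized lattice leaves vacancies so daughters can settle; founders =
⌈n_F/3⌉ unrelated females, every later female a daughter of a random
existing female (matrilines therefore span generations) placed on the
vacant slot nearest her mother with probability `philopatry_prob` (default
0.8), else uniformly; territorial males as unrelated immigrants on a 12.1
km lattice; kittens in litters (size ≤ 2 by default) from a resident mother
and one random sire, at the mother's centroid; floaters and dispersers as
unrelated immigrants with uniform activity centers. Genotypes: 11
autosomal loci, 3–7 alleles, Dirichlet(1) founder frequencies (floored so
no founder allele is vanishingly rare in a ~20-animal population),
Mendelian inheritance, plus two error-free sexing loci with male-specific
alleles.

`simulate_sampling` emulates the two observation processes. Faecal: Poisson
scat counts per class (territorial 11, kitten 5, floater 5, disperser 3 —
totalling ≈ 171 scats for the default population, the field collection
effort this mirrors), scats scattered around the activity center (1.5–2 km
residents, 5 km transients), four replicate amplifications each with
independent errors: dropout (a heterozygote loses one allele, default
0.2), false allele (one allele shifts ± one repeat unit — mimicking
stutter and creating the one-mismatch near-duplicates that exercise the
tolerant matcher, default 0.05) and missingness (default 0.05; real
amplification failure also includes sample-degradation effects outside this
model, so the simulated per-replicate success rate is higher than a typical
field study's). Trap: 5 stations in the contiguous block of territories
around a randomly chosen *reproducing* female (trap placement follows prior
monitoring of residents), and 20 capture events drawn with class weights
(residents/kittens 1.0, floater 0.1, disperser 0.05) times a Gaussian decay
of the animal's distance to the nearest station (range 4 km); recaptures
collapse, leaving ~10 distinct trapped individuals. This station
clustering plus philopatry is what concentrates kin in the trap sample —
the mechanism under study.

What the generator does **not** emulate: movement and home-range overlap
(positions are static centroids), genotyping-quality covariates (sample
age, inhibitors), mutation, immigration during sampling, and realistic
M_xy baselines for very small allele pools (identity-in-state inflates
absolute relatedness values relative to field panels with more alleles, so
synthetic sibship *counts* are higher than a real population's even though
orderings and contrasts behave correctly). Passing tests therefore
establish the pipeline's internal correctness and the direction and
robustness of the sampling-design effect, not field-calibrated absolute
values.

## Numerical conventions

* Allele pairs are stored sorted; missing is both-or-neither per locus.
* Permutation/bootstrap p-values use the add-one convention; all stochastic
  routines take explicit seeds and are deterministic given them.
* Exact HWE enumeration compares log-probabilities with a 10⁻⁹ slack to
  absorb floating-point ties.
* Monomorphic loci: H_E = H_O = 0, F_IS and the HWE test undefined
  (excluded from multilocus sums); rarefaction of a monomorphic locus is 1.
* Degenerate MCPs (≤ 2 points, collinear) use the arithmetic mean.
* Tukey comparisons where all groups are identical constants return p = 1.

## Problem sizes

The test suite and the acceptance script run simulation panels of 10–20
seeded replicates with 100 subsampling iterations, ~200 scats × 4
replicates per realization, and 199–999 permutations — sizes at which the
Monte-Carlo error of every asserted proportion is well below the asserted
margins while a full run stays in the tens of seconds on one CPU.
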