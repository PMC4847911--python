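# Methods

`kinpatch` analyses multilocus codominant genotype data (microsatellites)
for the signature of *kin aggregation*: spatially clustered family groups
that, when pooled into geographic samples, generate the classic
chaotic-genetic-patchiness (CGP) pattern — weak but significant
differentiation over short distances with no isolation by distance, plus
pervasive within-sample departures from Hardy–Weinberg equilibrium (HWE).
This note documents the models, defaults, numerical choices, and the
limits of what the synthetic-data checks demonstrate.

## Genotype model

Genotypes are unordered pairs of positive integer allele sizes, stored
canonically sorted; a missing genotype is whole-locus (both alleles).
Half-missing records are demoted to missing with a warning — single-allele
calls in fragment data are almost always scoring artifacts.  Expected
heterozygosity is the plain gene diversity He = 1 − Σ p², pooled across
sites for the one-row-per-locus summary table; an unbiased (2n/(2n−1))
option exists but is off by default, because the plain form is the
simplest defensible reading of the kind of per-locus summary tables this
package reproduces, and at n in the hundreds the two differ in the third
decimal.

## Hardy–Weinberg diagnostics

Both randomization tests condition on the observed allele counts.  The
null is sampled by shuffling the multiset of gene copies and re-pairing
them — an exact draw from the conditional distribution, chosen over an
MCMC walk because it is unbiased, simple, and fast at these sample sizes
(n ≤ ~100 per site).  The exact test ranks tables by conditional
probability; the homozygote-excess statistic is the total homozygote
count, one-tailed upper.  A per-allele weighted variant
(Σ_a (Obs_aa − E[Obs_aa])/p_a, with the without-replacement expectation)
is available behind `weighted=True`; the count version is the default
because it is exactly documented and monotone-equivalent for the
one-tailed decision in the common cases.  All Monte Carlo p-values use
the add-one rule (x+1)/(n+1), so p ∈ (0, 1].

F_IS = 1 − Ho/He from within-site frequencies, NA when He = 0.
Significance is a one-tailed allele-permutation test; because re-pairing
conserves allele counts (hence He), the permutation only has to track Ho.
Multiple testing in the site × locus grids is deliberately left at
per-test α = 0.05; Holm step-down is applied only where the analysis
corrects — the 36 pairwise differentiation tests.

The null-allele diagnostic is an OLS regression of |He − Ho| on the
missingness proportion across all site × locus samples: null alleles
create apparent homozygotes and missing genotypes from the same cause, so
a positive slope is their signature and a flat fit argues against them.

## Differentiation

P_D ("proportion of different alleles") is defined at the
population-frequency level: P_D(A,B) = 1 − (1/L) Σ_l Σ_a min(p_a^A,
p_a^B), over loci scored in both sites.  The quantity is named but rarely
defined in the field's reports; this definition (one minus the mean
shared-allele proportion, i.e. half the Manhattan/total-variation
distance subtracted from one) is documented and pluggable precisely
because reproductions of printed P_D tables hinge on it.

F_ST defaults to Weir–Cockerham θ with variance components summed over
alleles and loci (ratio of sums); a Nei G_ST-style estimator is the
sensitivity option.  Negative estimates are reported as computed.
Significance is a conditional permutation test per pair — only the pair's
individuals are re-assigned, preserving both sample sizes — with
sequential Bonferroni (Holm) across pairs.  The same vectorized engine
evaluates the observed statistic and every permutation from one
membership matrix, which keeps 10,000 permutations per pair affordable.

Geographic distances are haversine with Earth radius 6371.0088 km.  The
Mantel test correlates lower-triangle entries under simultaneous
row/column permutation, one-tailed upper (isolation by distance predicts
positive correlation), 10,000 permutations by default to match the
differentiation tests.

## Relatedness

The relationship of a non-inbred dyad is the IBD-mode vector
k = (k0, k1, k2), r = k2 + k1/2.  Genotyping error follows the class-II
model: each observed allele is, with probability e (default 0.01, the
rate assumed in the sibship analysis), a random draw from the locus
frequencies.  Per-locus emission probabilities have a closed form built
from S(x,y) = (1−e)² p_x [x=y] + e(2−e) p_x p_y; at e = 0 they reduce to
the textbook genotype-pair probabilities.

The estimator maximizes the triad likelihood — the joint probability of
the focal pair plus a randomly drawn reference individual — over the
k-simplex.  With the reference unrelated to the pair, its genotype term
is constant in k, so the triad likelihood factorizes and the maximizer
equals the dyadic ML estimate; the implementation computes it that way.
The likelihood is linear in k, so the log-likelihood is concave on the
simplex and EM (three deterministic starts, tolerance 1e-8) provably
reaches the global maximum; this was additionally verified against a
brute-force grid search over the simplex.  A `joint-trio` variant
maximizes over all 16 IBD configurations of the trio's six genes
(enumerated programmatically: partitions with at most one gene per
individual per class, collapsed under within-individual gene exchange),
relaxing the unrelated-reference assumption.

**Known bias.** Both variants are boundary-constrained ML: r̂ cannot go
below 0, so estimates for truly unrelated dyads pile up at 0 and the
mean bias is positive.  Measured at the default 10-locus panel
(richness 7–50, symmetric Dirichlet frequencies, e = 0.01): mean r̂ for
unrelated dyads ≈ +0.04 (seed-dependent 0.038–0.047), about half the
dyads exactly at 0; the joint-trio variant is *worse* (≈ +0.05) because
its extra boundary parameters leak into the dyad marginal.  FS and HS
means recover 0.50 and 0.25–0.26.  The bias shrinks with panel size and
is a property of the estimator class, not of the optimizer (grid-checked)
nor of frequency estimation (unchanged with true frequencies).

Allele frequencies for the estimator come from the full pooled sample by
default: within-site frequencies are inflated by the very kin structure
under test.  Group mean relatedness r̄ is the arithmetic mean over
unordered within-group pairs with its standard error.  The permutation
test permutes whole individuals among groups preserving sizes; since
this only relabels membership, the precomputed pairwise matrix is reused
and group means recomputed per replicate — mathematically identical to
re-running the estimator, at a tiny fraction of the cost.  The returned
2.5/97.5 percentile envelope supports the shaded-null style of figure.

## Clustering

Genotypes are one-hot allele-dosage encoded (0/1/2 per observed allele),
missing cells imputed by the per-locus mean dosage (standard in this
framework; keeps n complete), centered, optionally scaled, and projected
onto all principal components with positive variance — the clustering
step is not overfitting-sensitive, unlike discriminant projection, so
nothing is gained by truncating.  K-means runs for k = 1..max_k (default
10, lowered for small sites) with 50 restarts, and k is chosen by
minimum BIC(k) = n·ln(W_k/n) + k·ln(n), W_k the total within-cluster sum
of squares.  Clustering runs per site independently.  Discriminant axes
for plotting come from an LDA of the retained PCs on the selected labels
(≤ k−1 axes; with k = 2 a single axis, rendered as density data), with
67% inertia ellipses scaled by the χ² quantile.

## Sibship

Dyads are scored under full-sib (¼,½,¼), half-sib (½,½,0) and unrelated
(1,0,0) hypotheses by multiplying the error-aware per-locus emissions;
posteriors are prior × likelihood with a uniform default prior (none is
given in the analyses this mirrors), and a label is assigned only at
≥ 95% posterior confidence, else UNASSIGNED (as are dyads with < 3
overlapping loci).  This pairwise classifier deliberately replaces
full-pedigree sibship reconstruction: it cannot exploit sibship-group
transitivity constraints, and avuncular or grandparent–grandchild dyads
share the half-sib k-vector and are indistinguishable from half sibs.
Dyad counts from full-pedigree software are therefore expected to match
only qualitatively.

The exclusion-probability power analysis draws groups of (default) three
unrelated genotypes per locus from the panel frequencies and asks whether
any ordered parental genotype pair could have produced all of them.
Candidate parents are enumerated over the group's observed alleles only.
Sketch of sufficiency: if a compatible parent carries an allele never
transmitted to any group member, every offspring uses that parent's
*other* allele, so substituting the untransmitted allele by any observed
one preserves compatibility — hence restricting the search to observed
alleles cannot miss a compatible pair.  Per-locus exclusion probabilities
combine as 1 − Π(1 − E_l); the random-subset variant reports the mean and
2.5/97.5 percentiles over subsets.

## Networks

Each cluster's sibship graph has an edge per FS/HS call (kind kept as an
attribute).  Mean local transitivity counts degree-<2 nodes as 0 — the
only convention under which clusters made solely of disjoint sib pairs
score exactly 0.000, as such clusters do in the kind of table this
mirrors.  The ± value reported with it is the SD across nodes (the
across-simulations alternative is available from the null replicates).
The null is G(n, m): m distinct pairs drawn uniformly, identical order
and size, one-tailed upper add-one p; m = 0 and complete graphs are
degenerate (every replicate equals the observation) and flagged with
p = 1.

## Synthetic data

The simulator emulates a nine-site survey (34–85 individuals per site),
each site pooling 2–5 clusters of 8–36 individuals built from full-sib
families of 2–6 offspring; with probability 0.5 a family shares its
father with the previous family in the cluster, chaining families into
half-sib groups (this generates the predominance of HS over FS dyads
such surveys report).  Ten loci carry 13, 9, 14, 24, 10, 7, 33, 19, 50
and 24 alleles (matching the survey panel's richness) with frequencies
from a symmetric Dirichlet (concentration 1); per-locus missingness is
drawn from 0.06–0.26; genotyping error is 1% per gene copy,
frequency-weighted substitution.  Null alleles are off by default and
available per locus (null/null → missing; null/visible → apparent
homozygote).

Two deliberate design choices:

* **One shared baseline frequency distribution across sites.**  The
  hypothesis under study is that *family sampling alone* generates
  differentiation; baking real frequency divergence into the baseline
  would confound that, and the panmictic control must give F_ST ≈ 0.
  `site_divergence > 0` switches real divergence on.
* **Cluster founder pools (default 4 founders).**  Breeding adults of a
  cluster are themselves bred from a small founder set, so parents are
  related and offspring inbred.  Without this, a site that pools a few
  families shows *negative* F_IS (the within-family heterozygote excess
  under sample frequencies outweighs the between-family Wahlund effect,
  measured ≈ −0.05 here), whereas persistent kin aggregations inbreed —
  and with it the simulated sites show the homozygote excess
  (mean F_IS ≈ +0.06) that is part of the CGP signature.
  `founder_pool_size=None` restores unrelated parents; pedigree dyad
  labels (FS/HS/U) always refer to the immediate parents, so background
  founder relatedness is not counted in the truth labels.

`simulate_dyads` generates independent dyads with unrelated parents for
parameter-recovery checks, where the pedigree r must be exactly
0.5/0.25/0.  Coordinates lie on a reef-like arc with ~5–200 km pairwise
separations to exercise the Mantel test.  Everything is deterministic
given the seed.

What the simulator does **not** emulate: real microsatellite mutation or
allele-size homoplasy, oceanographic larval transport, temporal cohort
structure, linkage, and selection.  Passing the synthetic checks shows
the statistics recover the structure this generative model encodes — not
that field data meet the model's assumptions.

## Pipeline and reproducibility

`run_full_analysis` executes HWE → differentiation → clustering →
relatedness → sibship → networks.  Per-stage sub-seeds are the first
words of `numpy.random.SeedSequence(seed).spawn(7)` consumed in fixed
stage order, so a stage can be rerun alone, bit-for-bit.  Tabular outputs
are CSV with a schema-version comment line; the summary is versioned
JSON; a failed stage aborts with its name and leaves an `INCOMPLETE`
marker beside whatever was written.

## Validation design and problem sizes

The test suite validates each randomized procedure against an
independent oracle: Monte Carlo HWE/U p-values against full enumeration
of all achievable tables in the 2–3-allele, n ≤ 8 regime (tolerance
0.02); the Mantel test against scikit-bio; exclusion probabilities
against trio enumeration with an exhaustive parental search (tolerance
0.005); the Erdős–Rényi transitivity p against a frozen 10⁶-replicate
igraph run on a fixed 12-node graph.  Estimator calibration uses 1000
simulated HWE samples (n = 50, five equifrequent alleles; n_mc = 2000
per test, enough resolution for a 0.05 decision), 200 pedigree dyads per
relationship class, 100 clustering replicates, and 50 + 50
panmictic/kin-structured end-to-end replicates of a 4-site study of
34–44 individuals per site with 199-permutation tests — sizes chosen so
the whole suite runs in minutes while leaving the binomial noise small
against each tolerance.  Per-replicate CGP detection means: homozygote-
excess rejection count beating the upper 5% binomial point, ≥ 50% of
site pairs F_ST-significant (uncorrected), Mantel p > 0.05, and ≥ 50% of
estimated clusters with permutation-elevated r̄.

## Known limitations

* The relatedness estimator's positive boundary bias at r = 0 (above).
* The pairwise sibship classifier undercounts confident FS calls at the
  10-locus default panel relative to full-pedigree reconstruction.
* P_D and F_ST printed by other toolchains may follow different
  estimator conventions; both estimators and the P_D definition are
  switchable for sensitivity.
* Genepop support covers the 2-line-header, POP-block dialect with 2- or
  3-digit alleles; extended variants are out of scope.
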