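# Methods

This note documents the statistical models behind `tuberpop`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter when comparing
results across tools.

## Data model

A `GenotypePanel` is an individuals × loci matrix of allele dosages for
biallelic SNPs: entry (i, l) counts copies of the alternate allele, between
0 and the ploidy of individual *i*. Ploidy is per sample (2 or 4 in a
potato diversity panel; any ≥ 1 is accepted), and missing calls are NaN —
always distinguishable from dosage 0. The per-locus alternate-allele
frequency over a sample set is Σᵢ dosageᵢ / Σᵢ ploidyᵢ over non-missing
entries, so diploid wild-species accessions enter the denominator with 2
copies and tetraploids with 4; inflating diploids to pseudo-tetraploids
would bias frequencies and every statistic downstream.

MAF filtering keeps loci with min(p, 1−p) **strictly** greater than the
threshold (default 0.05); a locus at exactly the threshold is removed.
Filtering is idempotent.

Missing data are handled two ways, deliberately different by purpose:

- PCA/DAPC need a complete matrix, so missing cells are replaced by the
  locus mean dosage (the value that adds no variance on any axis).
- Diversity, distance and AMOVA statistics use pairwise/groupwise complete
  observations and never see imputed values, because mean imputation
  systematically deflates heterozygosity and distances.

## Cluster search and DAPC

The cluster search runs k-means (k-means++ seeding, 10 restarts, seeded)
for K = 1..k_max on PCA scores and scores each K with the spherical-
Gaussian criterion BIC(K) = n·ln(WSS_K/n) + K·ln(n); the supported number
of clusters is the argmin. Two defaults matter:

- The **search** stage keeps the *full* PC spectrum. Reducing to a few PCs
  first concentrates residual variance into few axes, where splitting a
  true cluster still buys k-means a ≳3% WSS reduction and the BIC keeps
  falling past the true K; with the noise spread over all components the
  relative gain beyond the true K drops below the K·ln(n) penalty and the
  minimum is sharp. On five-population tetraploid panels (40/pop, 500 loci,
  Fst 0.2) the argmin is the simulated K in essentially every seed.
- The **discriminant** stage reduces hard (default 10 PCs, or the
  cross-validated optimum in the pipeline), because LDA on too many
  dimensions overfits group means.

DAPC solves the generalized eigenproblem B·a = λ·W·a on the retained PC
scores (B between-group, W pooled within-group scatter; a tiny ridge,
1e-10·tr(W), keeps W positive definite when n_pca approaches n). Axes are
normalised to unit within-group variance, so squared Euclidean distance in
discriminant space is Mahalanobis-like, and membership posteriors are
softmax(−½·d²) to the group centroids with equal priors and a common
isotropic covariance — the simplest posterior consistent with LDA's
assumptions; the axis count is capped at min(groups−1, n_pca).
Per-locus "variable loadings" compose the PCA loadings (and any column
scaling) with the discriminant coefficients, so centered data times
loadings reproduces the individual coordinates exactly.

Cross-validation is stratified: each replicate holds out 10% of every
group (at least one individual, never the whole group), fits on the rest,
and scores the fraction of held-out individuals assigned to their true
group. Per grid point RMSE = sqrt(mean((1 − success)²)) over replicates
(default 30); ties in the argmin break toward fewer PCs (parsimony).
Dosage columns are commensurate (same 0..ploidy scale), so PCA defaults to
centering only; a `scale` flag exists throughout for unit-variance
columns.

Structural-SNP selection (snpzip) clusters the absolute loadings of one
discriminant axis in 1-D (Ward linkage by default; the linkage is a
parameter), cuts into two groups, and calls the group with the larger mean
"structural". The split is scale-equivariant and errors out when all
loadings are equal.

## Nei distance, dendrograms, agreement

For biallelic frequency profiles x = (p, 1−p), y = (q, 1−q) over shared
loci: J_xy = mean(pq + (1−p)(1−q)), J_x and J_y the self-identities,
I = J_xy/√(J_x·J_y) and D = −ln I (Nei's 1972 standard distance with
mean-over-loci identities). Individual-level distances use
within-individual frequencies dosage/ploidy — the polyploid convention —
and population-level distances use pooled frequencies. Loci missing in
either member of a pair are excluded for that pair only. Disjoint fixation
gives I = 0 and infinite D; identities below 1e-10 are capped at
D = −ln(1e-10) ≈ 23.03 and flagged, keeping Ward arithmetic finite.

Ward clustering uses the Lance–Williams recurrence on squared distances
(scipy's implementation); heights are non-decreasing and the greedy merge
order equals direct minimisation of the within-cluster SS increase for
Euclidean inputs, which the tests verify by brute force. Newick export is
ultrametric with leaf depth = merge height/2. Partition agreement between
two labelings is the fraction of identically assigned entities under the
best label bijection (rectangular assignment on the confusion matrix),
reported as a percentage.

## Diversity, AMOVA and F-statistics

Per subpopulation and locus: Ho is the fraction of scored individuals
carrying both alleles (dosage strictly between 0 and ploidy) — note that
for a tetraploid under polysomic Hardy–Weinberg this is 1 − p⁴ − q⁴, well
above the diploid 2pq, which is why tetraploid panels report Ho > He as a
matter of course; He = 2p(1−p) from the pooled frequency, uncorrected for
sample size; %P is the percentage of loci with both alleles present.
Summaries report means and SE = sd/√L over loci.

The AMOVA is two-level (among/within populations) on squared Euclidean
distances whose units are **allele copies**: each individual contributes
ploidy-many 0/1 copies per locus. Because squared Euclidean distance adds
over loci, every sum of squares depends only on per-locus allele counts
(for M copies with c ones, Σ_{i<j}(xᵢ−xⱼ)²/M = c(M−c)/M), never on phase,
and equals the deviation-from-centroid sum of the explicit copy expansion.
Degrees of freedom come from copy counts (df_within = Σploidy − K), n0 is
the weighted average subpopulation copy count, Vw = MS_within,
Va = (MS_among − MS_within)/n0 and Φst = Va/(Va+Vw) with Va truncated at 0
(raw value still reported). This copy-level accounting is what codominant
AMOVA software does — visible in published tables whose within-population
df exceed the genotype count — and it is what makes Φst estimate the
allele-frequency differentiation parameter: a genotype-vector AMOVA with
individual units instead estimates m·Fst/(1+(m−1)·Fst) for ploidy m
(≈ 0.5 at Fst = 0.2 for tetraploids), which is not comparable across
ploidies. On Balding–Nichols panels the copy-level Φst tracks the
simulated Fst within a few thousandths.

Fis = 1 − H̄o/H̄e with means over subpopulation × locus cells with He > 0,
weighted by subpopulation size (ratio of means, not mean of ratios, for
stability at small He). With the both-allele-carrier Ho, tetraploid
panels under polysomic random mating give strongly negative Fis; the
statistic is primarily useful for its permutation test and for comparing
like with like.

Permutation tests use p = (1 + #{perm ≥ observed})/(n_perm + 1) (default
999 permutations), so p is never 0 and the test is one-sided — a strong
heterozygote excess therefore shows p near 1. Φst permutes whole
individuals among populations; Fis redistributes allele copies among
individuals within each population (a columnwise multivariate-
hypergeometric reshuffle that preserves every allele frequency and hence
He). Because Φst is truncated at 0, its permutation p-values under a true
null are uniform in the rejection tail but pile up near 1 (observed
Φst = 0 can never look extreme); the achievable rejection rate at
α = 0.05 with 199 permutations is 9/200 = 0.045, and calibration
experiments land there.

## Pedigree statistics

Kinship uses the tabular method in topological order:
f(i,j) = ½(f(mother_i, j) + f(father_i, j)) for earlier j,
f(i,i) = ½(1 + f(mother_i, father_i)), F(i) = f(mother_i, father_i);
unknown parents are unrelated, non-inbred founders. This is the standard
diploid-meiosis expectation, applied to cultivar pedigrees as breeding
programmes conventionally do; it is not a tetrasomic-inheritance kinship.
CR(i,j) = 2f(i,j)/√((1+F_i)(1+F_j)), and the summary reports the fraction
of within-subpopulation pairs above a threshold (default 0.5).

Contribution accounting enumerates all upward parent chains of length 1..G
(parents are level 1; the cap G = 5 is inclusive and applies to occurrence
counting as well as contributions). A path is maternal or paternal by its
*first* step from the focal individual, matching how breeding-programme
tables separate maternal-path and paternal-path ancestors. The
contribution of ancestor a to individual i is Σ(½)^level over qualifying
paths; uncapped and summed over founders it is exactly 1 for any
individual with both parents known. For a subpopulation S (members with at
least one recorded parent), occurrence% of a is the share of members whose
capped ancestry contains a on the chosen side, and MAC% is the mean
contribution of a among exactly those members. The MAC wording in the
literature admits several normalisations; the conditional mean is used
because it reproduces the characteristic signature of breeding histories —
an ancestor present in most pedigrees but only at deep levels (a
"background" progenitor) scores high occurrence and low MAC, while a
recent parent of a few members scores the reverse — and the tests
construct and assert exactly that ordering.

## Synthetic data

`simulate_panel` draws ancestral frequencies p_l ~ U(0.1, 0.9) (bounded
away from fixation so loci are informative but MAF filtering still has
work to do), per-population frequencies from the Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F) with F the Fst parameter (F = 0 copies the
ancestral frequency exactly), and dosages Binomial(ploidy, p_{k,l}) —
polysomic inheritance, appropriate for an autotetraploid. Defaults mirror
a potato diversity panel: K = 5 subpopulations (four tetraploid, one
diploid), 40 individuals each, 500 loci, 2% missing calls masked uniformly
at random. `fst` may be a per-locus vector, which is how divergence can be
confined to a chosen locus subset. `simulate_structural_panel` builds the
two-population structural-SNP scenario with *deterministic* frequency
pairs p̄ ∓ √(Fst·p̄(1−p̄)) at the structural loci (the two-population Fst
identity) so that each structural locus genuinely carries the stated
contrast — a Balding–Nichols draw at the same Fst leaves a sizeable
fraction of loci near-undiverged and would make "recover the 10 structural
loci" an unattainable target for any method. `simulate_pedigree` mates
random distinct pairs from the previous generation (no selfing, as for
clonally propagated cultivars) and records exact founder contributions
during construction as ground truth.

What the generator does **not** emulate: linkage and LD between loci
(independent loci suffice for the statistics implemented here, but real
SNP-array data have LD structure), genotype-calling error from intensity
clustering, non-uniform missingness (real arrays fail by marker and by
sample), admixed individuals, and null alleles. Passing recovery tests on
these simulations therefore demonstrates correctness of the estimators
under their own model assumptions, not robustness to array artefacts.

## Problem sizes and determinism

The test and acceptance experiments use the study-scale conditions
directly (K = 5 × 40 individuals × 500 loci for recovery; 10 seeds per
condition; 199 permutations × 200 replicates for calibration; 10⁵
gene-dropping iterations for the kinship oracle), which keeps the full
suite within minutes on one CPU. All randomness flows from explicit seeds
(numpy `default_rng`; sub-experiments derive independent streams via
`SeedSequence`), k-means restarts are seeded, and pipeline reports are
written with a fixed float format, so a pipeline run is reproducible
byte for byte from its manifest.

## Known limitations

- AMOVA is two-level only; no region/population/individual hierarchy.
- The kinship is the diploid tabular expectation (no tetrasomic double
  reduction), and CR assumes it.
- Nei distances cap at −ln(1e-10) for disjoint fixation, so Ward heights
  saturate on panels containing totally disjoint profiles.
- VCF input accepts called genotypes only; intensity-based dosage calling
  is out of scope.
- Membership posteriors assume equal priors and a common isotropic
  covariance in discriminant space; strongly unbalanced or
  heteroscedastic groups would need a richer classifier.
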