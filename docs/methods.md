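# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Genotype handling

Genotypes are diploid autosomal SNP dosages in {0, 1, 2}, counting copies
of `allele2` — by convention the lexicographically larger of the two
observed alleles, since PED text carries no orientation.  Missing genotypes
("0 0" in PED) use an internal sentinel outside {0, 1, 2}.  Consequences of
the convention: a monomorphic column read from file cannot recover its
orientation (only its missingness pattern), and merging two panels must
re-orient dosages whenever their allele2 choices differ.

Merging intersects SNP identifiers.  Where one panel's allele pair is the
base-complement of the other's (A/G vs T/C), the second panel was typed on
the opposite strand: its alleles are complement-mapped and its dosages
re-oriented.  A/T and C/G SNPs are self-complementary, so strand cannot be
inferred from the alleles; they are kept under a same-strand assumption by
default (a flag drops them), and the count is logged.  Allele pairs that
agree in neither orientation are irreconcilable and dropped with a warning.

QC filters, in order: per-SNP missingness (default cap 10%), monomorphism,
minor-allele frequency, and a two-sided exact conditional Hardy–Weinberg
test run separately within each population (a SNP is removed when any
population's p falls below the configured alpha; the default alpha of 0
disables the filter, since HWE screening belongs to reference-panel
preparation rather than to newly collected indigenous samples).  Each SNP
is counted against the first filter it violates, so the report's removal
counts plus retentions always sum to the input count.

LD pruning is a greedy sliding window (defaults 50 SNPs, step 10,
r² > 0.1) on squared Pearson correlation of dosages over
pairwise-complete individuals — a standard composite-LD surrogate that
needs no phasing.  Within a window the member of an offending pair with
more missing data is removed (ties break toward the later column).  Windows
are re-swept until no window over the retained SNPs contains a pair above
the threshold, which makes the documented output invariant (max within-
window r² ≤ threshold) hold exactly rather than approximately.

## LD blocks and haplotype heterozygosity

Blocks are runs of 5–15 contiguous dataset SNPs in which every inter-SNP
mean recombination rate is below 0.5 cM/Mb.  The inter-SNP rate is the
unweighted mean of map rates at map positions strictly inside the interval;
an interval containing no map point takes the linear interpolation of the
flanking map rates at its midpoint.  Construction is greedy left-to-right:
a run is extended while the next rate passes the rule and the block holds
fewer than 15 SNPs, and emitted if it reached 5.  Greedy disjoint tiling
was chosen because the alternative definitions are explicitly
non-overlapping; the rule sits behind a mode flag ("below", "above",
"random"), where random mode reproduces a reference block-length multiset
at random disjoint positions for scale comparisons.

Haplotype frequencies within a block come from an EM algorithm over phase
configurations: an individual with h heterozygous sites is compatible with
2^(h−1) unordered haplotype pairs; the E-step weights pair (h₁, h₂) by
f(h₁)f(h₂) (doubled when h₁ ≠ h₂), the M-step re-estimates frequencies from
expected counts.  Initialization is the linkage-equilibrium product of
single-SNP frequencies; convergence is a maximum frequency change below
1e-8; the 15-SNP cap bounds the enumeration at 2¹⁴ pairs per individual,
so no partition-ligation is needed.  Individuals with any missing call in
a block are excluded from that block — the simplest defensible contract.
Haplotypes are encoded as integers (bit j = allele 2 at site j) so the
E-step runs as flat vectorized array operations.

Block heterozygosity is the Nei estimator with small-sample correction,
H = n/(n−1)(1 − Σ p̂²), n = 2 × individuals used; a toggle gives the
uncorrected plug-in form.  Population summaries average blocks within each
chromosome, then take mean and SD across chromosome means, so chromosomes
(not blocks) are the replication unit of the reported SD.

## Geography and the serial-founder regression

Distances are haversine great-circle sums on a sphere of radius 6,371 km
from Addis Ababa along continental waypoint routes, following the
serial-founder literature.  Waypoint coordinates are a packaged fixture
(Cairo, Istanbul, Phnom Penh, Anadyr, Prince Rupert); the Americas route
(Cairo → Istanbul → Anadyr → Prince Rupert) reproduces published waypoint
distances for seven Pacific Northwest and Mexican populations within 0.5%.
Synthetic route populations lie on the founder chain itself, so their
distance is the cumulative chain distance.  The regression of genome-wide
mean haplotype heterozygosity on distance is ordinary least squares with
the two-sided Pearson correlation-test p-value; populations flagged as
non-indigenous admixed panels are excluded before fitting.

## Population differentiation

Pairwise F_ST is the Weir–Cockerham (1984) θ with variance components
a (among populations), b (among individuals within populations) and
c (within individuals), combined across loci as a ratio of sums
Σa / Σ(a+b+c) — the estimator's recommended multilocus form — over SNPs
whose whole-sample minor allele frequency exceeds 5%.  Negative per-locus
components are kept, not truncated, so slightly negative θ is possible and
is recorded raw.

Classical (Torgerson) MDS double-centers the squared distance matrix,
B = −½ J D² J, and embeds with the top eigenpairs; an error is raised if a
requested dimension has a negative eigenvalue, while negative trailing
eigenvalues are retained and logged.  Fidelity is the Spearman rank
correlation ρ between embedded and input distances over the lower triangle.

Trees are BIONJ (Gascuel 1997): standard NJ pair selection and branch
lengths, with the reduction step weighting the joined pair by λ chosen to
minimize the variance of the new distance estimates (variances initialized
at the distances and reduced alongside them).  Negative branch lengths are
clamped to zero with a log entry.  Edge support bootstraps loci: each
replicate resamples SNP columns with replacement, recomputes the F_ST
matrix and tree, and counts replicates containing each internal-edge leaf
bipartition of the full-data tree.  Bootstrapping over loci was chosen
because loci are the only resampling unit that regenerates a valid F_ST
matrix; bipartitions are canonicalized (smaller side, lexicographic ties)
so the count is invariant to rotation and rooting.

## Individual-level structure

ASD between two individuals is 1 minus the mean shared-allele proportion
(per SNP: 1 − |x−y|/2 from dosages) over SNPs genotyped in both; a pair
with no overlapping SNP is an error rather than a silent zero.

Balanced resampling forms population groups before subsampling: special
groups first (e.g. the indigenous target populations and admixed reference
panels), then remaining populations ordered by distance from the origin
and chained into one group whenever successive distances differ by less
than d (transitively, so a group may span more than d end to end).  Each
replicate samples min(82, group size) individuals per group without
replacement, runs MDS on the ASD submatrix and records ρ; the replicate
with the highest ρ is returned, ties broken by first occurrence.

Procrustes alignment centers both configurations and scales each to unit
sum of squares, then finds the rotation/reflection and dilation minimizing
the squared difference, so the minimized D lies in [0,1] and the
similarity statistic is t₀ = √(1−D) (t₀ = 1 exactly for any similarity
transform of the same configuration).  This normalization was chosen to
make D's range — and hence t₀ — well defined.

The L₀ statistic is the mean 2-D Euclidean distance over all cross-group
pairs.  Its permutation test shuffles group labels over the pooled
individuals; p is the raw fraction of permuted L₀ ≥ observed (no add-one
correction), displayed as "< 1/n_perm" when zero.  Under the null the raw
fraction is uniform on {0, 1/n, …, 1} up to rank ties, which the type-I
calibration check confirms at the 5% level.

## Ancestry estimation and mode grouping

Both estimators maximize the binomial admixture likelihood
Π_il Binom(x_il | 2, Σ_k q_ik f_kl) by EM.  The supervised variant holds
source frequencies fixed (clamped away from 0/1 at 1/(2n) to avoid log 0
on fixed alleles) and fits each individual's membership vector on the
simplex; the unsupervised variant fits (Q, F) jointly from a seeded random
start (flat Dirichlet rows, Uniform(0.05, 0.95) frequencies).  Termination
is a log-likelihood increase below 1e-4, the convention of the standard
maximum-likelihood clustering tools; the likelihood trace is stored so
monotonicity is testable.  No quasi-Newton or block-relaxation acceleration
is used — runs are desk-scale.  The replicate protocol (30 seeded runs per
K) and SSC > 0.9 mode threshold follow the standard practice for
label-switching-aware summaries.

The SSC between two membership matrices is
max_Π 1 − ‖Q₁ − Q₂Π‖_F / √(2n) over column permutations Π — 1 exactly iff
the matrices agree up to relabeling, 0 at maximal disagreement.  The
optimum is exhaustive for K ≤ 8 and a linear assignment on column distances
for larger K (the two coincide because the Frobenius objective separates
over columns).  Modes are single-linkage components of the SSC > 0.9
relation; within a mode all runs are aligned to the first run's columns,
averaged elementwise, and rows renormalized to absorb floating-point drift.

## Dating a single admixture pulse

Under one founding pulse (fraction s from the source) followed by closed
random mating, individual ancestry fractions have mean s in every
generation and variance s(1−s)/2^g after g generations — the founding
generation averages two independent parental source indicators, and each
later generation averages two random parents, halving the variance.
Inverting with sample moments gives ĝ = log₂(μ̂(1−μ̂)/σ̂²), with the
unbiased (n−1) variance by default (a toggle gives the plug-in form).
Estimates are reported as years before present, YBP = (ĝ + 1) × 25: the
moment estimator dates the pulse relative to the sampled individuals'
birth, so their own generation is added, at 25 years per generation.
σ̂² ≥ μ̂(1−μ̂) implies ĝ ≤ 0 and is flagged as inconsistent with
post-founding random mating; σ̂² = 0 or μ̂ ∈ {0,1} are errors.

Pooled estimates concatenate the member populations' membership vectors
before taking moments (they do not average per-population estimates), and
the cross-K summary reports mean and SD of YBP (not of ĝ) across the K
range, labeling each source cluster at each K by the maximal mean
membership among designated reference individuals.

Caveat: memberships estimated from genotypes are noisy estimates of the
true fractions; estimation noise inflates σ̂² and biases ĝ downward (and
finite reference panels can shrink memberships, biasing it upward).  No
correction is applied; the recovery checks therefore validate the
estimator on true simulated fractions and treat genotype-derived dating as
approximate.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
sequence-level realism:

- **Serial-founder chain** — root allele frequencies Uniform(0.05, 0.95);
  each colonization step draws Balding–Nichols frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.02 per step (ten steps give a
  clearly detectable heterozygosity decline at desk scale while keeping
  per-population diversity realistic for array SNPs).  Two colonist
  sources drift from the root at F = 0.15, the scale of continental human
  differentiation.
- **Admixture pulses** — a finite Monte-Carlo pedigree (default 500 per
  generation, so the small-n behavior of the moment estimator is visible):
  founders average two source labels drawn with probabilities s, later
  generations average two uniformly drawn parents.  Default study-like
  mixes: two coastal-like populations (g = 3, higher European-like
  fraction) and two interior-like populations (g = 2, higher Asian-like
  fraction), 20 individuals each — pulse ages on the YBP scale of the
  recent-contact history the pipeline targets.
- **Genotypes** — individual i's allele-2 probability is Σ_k H_ik f_kl,
  dosage Binomial(2, ·), i.i.d. missingness at 0.5% (the order of array
  missingness rates).  SNPs are unlinked by default; an optional
  haplotype-pool mode draws each individual's haplotypes inside planted
  low-recombination runs from a finite population-specific pool, creating
  real within-block LD and bounded haplotype diversity for the EM stage.
- **Recombination map** — SNPs every 10 kb with one map point per
  interval; planted low-rate runs (0.1 cM/Mb) of length 5–15 alternate
  with high-rate breaks (2.0 cM/Mb), so expected block boundaries are known
  exactly.
- **Seeding** — one master seed; per-stage seeds derive from a stable hash
  of the stage name, so outputs are byte-reproducible without seed
  bookkeeping.

What it does not emulate: recombination-aware gamete transmission (LD
decay within blocks, admixture LD), ascertainment bias of array SNPs,
genotyping error, or relatedness.  Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions, not
robustness to those real-data complications.

Under the haplotype-pool simulation, blocks built from low-recombination
runs ("below" mode) necessarily carry fewer distinct haplotypes — and
hence lower heterozygosity — than same-length blocks from the
linkage-equilibrium background ("above" mode); the property test asserts
that ordering.  On real data the corresponding comparison changes the
scale of heterozygosity without strongly affecting population rankings.

## Problem sizes and determinism

Verification runs use desk-scale sizes chosen to keep each check sharp:
400–800 SNPs and 20 individuals/population for pipeline fixtures (the
serial-founder regression check uses 800 SNPs ≈ 60 blocks, enough power
for p < 0.01 in ≥ 95/100 seeds), L = 5,000–10,000 unlinked SNPs for
estimator calibration, pedigrees of 1,000 for dating recovery, and 1,000
simulations × 200 permutations for permutation-test calibration.  All
stochastic stages take explicit seeds and are exactly reproducible; the
pipeline manifest records output hashes so identical configs verify as
byte-identical.

## Known limitations

- The EM ancestry estimator converges linearly; near-boundary memberships
  approach their MLE slowly (the tolerance is on the likelihood, not the
  parameters).  Accelerated solvers are out of scope.
- BIONJ on non-additive matrices can produce negative branch estimates;
  they are clamped to zero, which slightly shortens path distances.
- The HWE exact test enumerates heterozygote counts per SNP and
  population; with very large samples the enumeration is the cost driver
  when the filter is enabled.
- Strand-ambiguous (A/T, C/G) SNPs cannot be verified at merge time; the
  same-strand default is only as good as the upstream panel harmonization.
- The waypoint fixture is a reconstruction from the cited literature, not
  published coordinates; it is validated against printed distances to 1%.
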