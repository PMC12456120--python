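# Methods

## The genotype-likelihood model

All inference starts from per-read likelihoods under a single global
per-base error rate ε (default 0.01). For a diploid genotype with
`g ∈ {0,1,2}` copies of the minor allele,

    P(read = minor | g) = (g/2)(1−ε) + ((2−g)/2)(ε/3)
    P(read = major | g) = ((2−g)/2)(1−ε) + (g/2)(ε/3)

and the site likelihood is the product over reads, computed in log space
and rescaled so the per-(site, individual) maximum is 1 (the Beagle/ANGSD
convention). A constant ε stands in for per-read base qualities: the
simulated reads carry no quality strings, and a fixed minimum-quality
filter upstream makes a single error rate the matching abstraction. Reads
matching neither the major nor the minor allele are treated as dropped by
upstream quality filtering and never enter the likelihood; the simulator
still emits them (at rate 2ε/3 regardless of genotype) so that this
filtering step has something to do.

A missing individual is an all-equal likelihood triple. Missing
individuals stay in the EM denominator: a flat triple's posterior
expectation equals the prior mean `2f`, which leaves the EM fixed point
unchanged (`f = S/2n` with or without flat individuals) while keeping the
bookkeeping honest. This identity is tested.

## Allele-frequency EM and the SNP test

The minor-allele frequency per site is the fixed point of
`f ← (1/2n) Σᵢ E[gᵢ | GLᵢ, f]` with Hardy–Weinberg prior
`{(1−f)², 2f(1−f), f²}`. The EM starts at f₀ = 0.2 (any interior point
reaches the same maximum; fixed for reproducibility), stops at |Δf| < 10⁻⁶
or 100 iterations, and its log-likelihood (triples renormalised to
probabilities, hence ≤ 0) is non-decreasing by construction. Equivalence
with a 10⁻⁴-grid brute-force maximiser to 2·10⁻⁴ is asserted in the
acceptance suite.

The SNP test is `LRT = 2(ℓ(f̂) − ℓ(0))` referred to chi-square with 1 df.
This is deliberately not the boundary ½χ²₀+½χ²₁ mixture: the plain 1-df
reference matches the behaviour of the standard low-coverage toolchain and
errs conservative by at most a factor of two. A site is a SNP when
p < 10⁻⁶ and min(f̂, 1−f̂) > 0.05. Two site lists are maintained
throughout, mirroring an asymmetry that matters in practice: nucleotide
diversity is computed on the *unfiltered* site list (MAF cut-offs bias
frequency-spectrum statistics), while Fst and the genome-wide contrast use
the MAF-filtered SNP list. Where a contrast within one lake is run, the
SNP list is built per lake.

## Site filters

A site passes for a sample group when at least 50% of its individuals
have a read (90% when the group has fewer than 12 individuals; both
boundaries inclusive) and total depth is at most 3× the expected total
(the sum of per-individual mean depths) — the standard guard against
collapsed repeats in a duplicated-genome context.

## SAF, SFS, θ

The site-allele-frequency likelihood over total minor counts j ∈ {0..2n}
is built by dynamic programming over individuals,
`h_i(j) = Σ_g h_{i−1}(j−g)·GL_i(g)·w(g)` with allele-pairing weights
w = (1,2,1)/4, renormalised per site after each individual to avoid
underflow. For n ≤ 3 the DP is checked against explicit summation over
all genotype configurations. The sample SFS is the EM fixed point
`p(j) ← (1/S) Σ_s SAF_s(j)p(j)/Σ_k SAF_s(k)p(k)` from a uniform start;
folding (merging j with 2n−j) happens only at reporting time, because the
ancestral allele is never assumed known. Per-site diversity is the
posterior expectation `π_s = E[2j(2n−j)/(2n(2n−1)) | SAF_s, SFS]`;
window θ is the mean over covered sites in 20-kb non-overlapping windows
anchored at position 1, with empty windows reported missing (never zero)
and terminal windows keeping their true span. A 2-D SFS EM over
outer-product SAF likelihoods is provided for reporting.

## Fst

Windowed Fst uses the Hudson estimator in Bhatia's recommended
ratio-of-sums form: per site
`N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)` and
`D = p₁(1−p₂) + p₂(1−p₁)` with p the per-group EM frequencies and n in
sampled alleles; a window's value is ΣN/ΣD (20-kb windows, 10-kb step).
This replaces the 2-D-SFS-posterior machinery of the reference toolchain
with an analytically checkable estimator of the same quantity that stays
well-behaved at low coverage — per-site ratios are undefined at sites
monomorphic in both groups, sums are not. Under Balding–Nichols drift the
estimator's expectation equals the drift coefficient F regardless of the
ancestral frequency distribution (both ΣN and ΣD are proportional to
Σp(1−p)), which is what the F = 0.19 recovery experiment exercises.
Global summaries are the unweighted mean ± sd over windows (not
per-scaffold means of means).

## Genome-wide contrast

The contrast fits one EM frequency to the pooled groups (null) and one
per group (alternative); `LRT = 2(ℓ₁ + ℓ₂ − ℓ₀)` with a chi-square(1)
reference. No covariates and no score-test variant — this is the plain
frequency-difference test. Sites where either group is entirely missing
are recorded and skipped. p-values below 10⁻³²⁰ are reported as
−log10 p = 320. The Bonferroni threshold is `−log10(α/N)`; N defaults to
the analysed SNP count but is overridable (the experiments fix N = 10⁷,
giving −log10 cuts of 10 and 15 at α = 10⁻³ and 10⁻⁸).

## Inversion scanning

"Block-like" is operationalised as: significant SNPs (−log10 p ≥ 10)
merged while consecutive gaps ≤ 100 kb, clusters kept with ≥ 20 SNPs,
and the significant-SNP density inside at least 5× the density in 250-kb
flanks (edge sharpness); blocks are trimmed to their outermost
significant SNPs. All four numbers are exposed as parameters; the
defaults would pass real blocks of hundreds of SNPs over 0.45–3.25 Mb
with wide margin. LD support is the r² of each significant SNP's
posterior dosage against the top SNP (maximum −log10 p, leftmost on
ties), reported as mean ± sd excluding the top SNP.

Haplotype genotyping uses diagnostic markers (−log10 p ≥ 15): the tracked
allele per site is the allele most common in a designated reference
group; each individual's tracked-allele dosage is averaged over its
informative sites and thresholded at the symmetric midpoints 0.5/1.5 —
the maximum-a-posteriori boundaries for counts {0,1,2}. An individual
with no informative site is unassigned. A local-PCA alternative clusters
PC1 scores by 1-D k-means initialised at the 10th/50th/90th percentiles;
if the middle cluster does not lie between the homozygote clusters the
block is flagged unresolved.

Per-haplotype diversity runs the θ machinery (20-kb windows, no MAF cut)
separately for each homozygote class inside the block and genome-wide for
the same individuals, then compares window θ with a Wilcoxon rank-sum
test — both between classes within the block and block-vs-genome within
each class, since published figures are ambiguous about which comparison
was drawn. The Wilcoxon is implemented in-package (exact
generating-function DP when both sides have ≤ 20 untied observations,
otherwise a tie-corrected normal approximation) so the pipeline's
contract carries no statistical-package dependency; scipy serves as the
independent oracle in tests.

## Haplotype sharing

Diagnostic SNPs from a reference lake's contrast (−log10 p ≥ 15, outside
excluded candidate blocks) are single-linkage clustered along scaffolds
with gap ≤ 50 kb; clusters need more than four SNPs. For each cluster a
tracked-allele frequency matrix over every (lake, morph) group is built,
the tracked allele per column being the most common allele in the
designated reference morph (column-wise orientation — no phasing is
attempted anywhere). A cluster is *shared* with a partner lake when the
mean frequency contrast is sign-concordant with the reference contrast
and |Δf_ref| ≥ 0.5, |Δf_partner| ≥ 0.3; partners with more than half
their columns missing are untestable. The numeric rule operationalises
what is otherwise a visual heatmap judgement; the thresholds are
parameters, and the defaults reflect that the reference contrast is large
by construction (diagnostic markers were selected on it). Validation
restricts to homozygote individuals: PCA on in-region SNPs, NJ trees from
covariance distances in- and out-of-region, and pairwise Hudson Fst
between the (lake × haplotype) groups in-region — a genuinely shared
haplotype shows within-haplotype cross-lake Fst far below cross-haplotype
Fst, and the in-region tree groups by haplotype while the out-of-region
tree groups by lake.

## The synthetic-data generator

Frequencies follow a two-level Balding–Nichols hierarchy: ancestral
frequencies (Uniform(0.05, 0.95) over a configurable fraction of sites;
the rest fixed) drift into lakes with coefficient F_lake and further into
morphs with F_morph, drawn `Beta(p(1−F)/F, (1−p)(1−F)/F)` so the variance
is F·p(1−p) and the expected pairwise Hudson Fst between two groups
drifted by F is F; F = 0 bypasses sampling and is an exact identity. The
two levels let between-lake (~0.3–0.4) and within-lake (~0.01–0.19)
differentiation be tuned independently, matching the scales reported for
the four-lake system this emulates. Genotypes are binomial(2, f) per
morph; per-individual mean depths are Gamma with mean 2.1X and sd 0.9X
(floored at 0.05X); read counts are Poisson with the error model above.

Planted regions override genotypes with a haplotype model: each
individual draws two non-recombining background labels (A/B) from its
morph's B-haplotype frequency; a site in the region is a fixed A/B
difference with probability `fixed_diff_prob`, otherwise it is a 50:50
polymorphism present on background A with probability 2·θ_A (likewise B),
which makes the per-site heterozygosity within a background exactly θ.
θ ≤ 0.5 follows from this parameterisation. Cross-lake shared blocks
reuse the same machinery keyed by (lake, morph) with all sites fixed
differences by default. No recombination occurs inside a region — the
blocks are modelled as the effectively non-recombining units they are
analysed as. What the generator does **not** emulate: linkage
disequilibrium outside planted regions (sites are exchangeable given
frequencies), mapping artefacts, indels, base-quality variation, and
coalescent genealogies — so passing tests demonstrate estimator
correctness under the model's assumptions, not robustness to alignment
pathology.

## Experiment sizes and numerical choices

The acceptance experiments (scripts/acceptance.py, mirrored by
tests/test_acceptance.py) use: 5,000 sites × 100 individuals at 2.1X for
EM calibration (1,000 sites for the grid oracle); 20,000 null sites ×
2×50 at 2X for type-I calibration and 10,000 sites at 20X for the QQ
slope (fitted through the origin on the central 99% of order statistics);
100,000 sites × 2×50 at 20X for F = 0.19 recovery; 200,000 sites over
1 Mb × 20 individuals with the segregating fraction thinned so expected
per-site π = 0.0016 (θ targets); and 20 planted + 20 null replicates of
2,000 sites over 10 Mb × 2×40 at 2X with a 1-Mb planted block
(haplotype frequencies 0.9/0.1, fixed-difference probability 0.6,
θ_A = 0.45, θ_B = 0.225). In the replicate experiment the Wilcoxon for
the planted θ_A = 2θ_B asymmetry is computed on the pooled per-haplotype
block windows of all replicates — the asymmetry is a property of the
planted condition, and pooling uses all windows the experiment generates;
per-replicate θ ordering is additionally exercised (at planted ratio 2)
in the module tests.

Numerical details: EM tolerances 10⁻⁶ (frequencies) and 10⁻⁸ (SFS);
likelihoods clamped at 10⁻³⁰⁰ before logs; SAF renormalised per
individual step; LD pruning repeats passes until no site is removed,
making it idempotent, with the most-entangled site removed first and the
lowest index kept on ties; PCA eigenvector signs fixed by forcing the
largest-magnitude loading positive; Nei distances capped at 50 when the
genetic identity is zero; negative NJ branch lengths floored at zero with
a warning and Q-matrix ties resolved to the lowest index pair; admixture
EM uses 3 seeded restarts and keeps the best likelihood.

## Known limitations

The PCA uses a single pass with pooled frequencies rather than iterating
individual allele frequencies; with strong structure this slightly
compresses PC scales (parameter recovery, not software mimicry, is the
target; an iterated refinement is a natural extension point). LD pruning
translates VIF = 2 to pairwise r² < 0.5 rather than a multiple-correlation
VIF. Dosage-based r² stands in for two-locus haplotype EM everywhere LD
is quantified. The inversion scan cannot distinguish a true inversion
from any other suppressed-recombination haplotype — breakpoint evidence
is out of scope — and the share/not-share rule is a numeric stand-in for
a judgement that is ultimately visual.
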