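# Methods

## The statistic

For two populations A, B and a gene-level differentiation value
Z_ST ∈ [0, 1] (F_ST for genotypes, P_ST for expression), the distance is
E_{A,B} = −log[1 − Z_ST(A,B)] (natural log). On the unrooted quartet
((W,X),(Y,Z)) the external branch of the focal population is estimated by

    PBS4_W = ¼ (2·E_WX + E_WY + E_WZ − E_XY − E_XZ),

with roles permuted by cherry symmetry: the focal population's cherry
partner carries the doubled term, and the two cross-cherry populations
enter positively with the focal population and negatively with the
partner. Two exact algebraic properties anchor the implementation and are
asserted in tests: on additive distances every external branch is
recovered exactly, and pre-clamp PBS4_W + PBS4_X = E_WX (likewise
PBS4_Y + PBS4_Z = E_YZ) for *any* distance matrix. Negative branch
estimates are set to 0. The three-population PBS_W = ½(E_WX + E_WY − E_XY)
is provided for comparison and coincides with PBS4 when the internal
branch vanishes.

The cherry assignment (which populations are sisters) is configuration,
never inferred from the data: the intended use fixes the quartet topology
from known population history.

Order of clamping: gene-level Z_ST is clamped at 0 before the −log
transform (negative differentiation has no biological interpretation), the
transform is applied, and branch estimates are clamped at 0 last. Z_ST = 1
(fixed differences at every SNP of a gene) would give an infinite
distance; it is clamped to 1 − 10⁻¹² with a logged warning, yielding a
large finite branch.

## Genetic differentiation

Per biallelic SNP with alternate-allele sample frequencies p₁, p₂ and
allele sample sizes n₁, n₂, Hudson's estimator components are

    numerator   = (p₁ − p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    denominator = p₁(1−p₂) + p₂(1−p₁).

Gene-level F_ST is the ratio of averages: numerators and denominators are
summed separately across the SNPs in the gene's annotated span (introns
included) before dividing, which reduces estimator bias relative to
averaging per-SNP ratios; per-SNP values are never clamped. n is the
realized allele count (2 × non-missing genotypes), since the finite-sample
correction requires the realized sample size. Sites where a pair is fixed
for the same allele (denominator 0) are uninformative for that pair and
excluded from its sums only; the global filter removes indels,
multiallelic records and sites monomorphic across the union of analyzed
samples. An optional union-MAF cutoff (conventionally 0.01) is off by
default. Coordinates: VCF positions are 1-based, annotation intervals
0-based half-open; the conversion lives in one function
(`io.vcf_pos_to_zero_based`), and a SNP overlapping k genes contributes to
all k.

Background-selection correction: B values (fraction of neutral diversity
surviving background selection, per-gene medians in (0, 1]) enter through
a pluggable correction; the default rescales the gene's log-distance by
B_gene / median(B) before back-transforming, so genes under stronger
linked selection (low B) have their F_ST deflated, and a gene at the
reference B is unchanged. Users with a preferred derivation can pass any
`correction(fst, b_gene, b_ref)` callable.

## Expression differentiation

Counts are normalized by median-of-ratios size factors (the per-sample
median of count/geometric-mean over genes positive in all samples), then
FPKM_gj = 10⁹·(c_gj/s_j)/(L_g·N_j) with N_j the sample's total normalized
count, then log(FPKM+1) with natural log (the base only rescales, never
reorders). Gene filters: lowly expressed (fewer than 10 reads in *every*
sample — the weakest reading of the rule; a flag switches to the stricter
any-sample version), sex-chromosome, and non-protein-coding genes are
removed, with per-rule removal counts logged.

P_ST = σ²_B / (σ²_B + 2h²σ²_W). Variance components come from one-way
ANOVA method-of-moments: σ²_W = MSW (pooled within-population variance),
σ²_B = max(0, (MSB − MSW)/n₀) with n₀ the balanced-size coefficient; a
`method="means"` option uses the sample variance of the two population
means instead, since the estimator choice is genuinely open — rankings are
nearly identical on synthetic data, and the ANOVA component is the
default because it is unbiased under the one-way model. h² defaults cover
0.5 (environment and non-additive effects absorb half the variance) and 1
(P_ST reduces to Q_ST); P_ST at h²=0.5 ≥ P_ST at h²=1 always. Genes with
zero total variance for a pair are flagged undefined (NaN) and dropped
from rankings rather than scored.

## Trees

Gene trees are built by UPGMA (average linkage) on the Z_ST distance
matrix of the four populations; the population tree is the majority-rule
extended consensus: clades are tallied across gene trees, considered in
decreasing frequency (ties: larger clade first, then lexicographic by
sorted labels) and accepted when compatible with those already accepted.
Strict-majority clades are always mutually compatible, hence always
included; supports are exact clade frequencies. All tie-breaking —
including UPGMA merge ties — is lexicographic on sorted leaf-label
tuples, making every run bit-reproducible; a different (equally valid)
tie rule in other software may diverge on degenerate inputs. The
Robinson–Foulds distance is the rooted-clade version: the number of
nontrivial clades (excluding leaves and the full set) present in exactly
one tree, giving 0, 2 or 4 for binary four-taxon trees. Genes missing any
pairwise value are excluded from tree building.

## Permutation tests and group comparisons

The two-sample test statistic is the difference of group medians; labels
are shuffled n_perm = 1,000 times and the two-sided p value is the
proportion of permutations with |statistic| ≥ |observed| (a flag enables
the (count+1)/(n_perm+1) convention). One caveat the test suite documents
explicitly: with two-valued data the median of a half-mixed group sits at
an extreme, so even totally separated constant groups yield a large exact
p (34/70 at n = 4+4 by full enumeration) — the test has power for
continuous-valued statistics like PBS4, not for degenerate two-point
distributions. Monte-Carlo p values converge to the exact enumeration and
the type-I error at α = 0.05 calibrates to the nominal level.

CNV comparisons summarize each gene by its maximum PBS4 across the four
branches (one value per gene; a per-population mode exists behind a flag)
and compare CNV-bearing vs remaining genes. Correlation analyses report
Pearson r and Spearman ρ with t = r√((n−2)/(1−r²)) two-sided p values.
Group-comparison p values are reported raw; Benjamini–Hochberg adjustment
is available but off by default. Ranked gene lists (descending PBS4, ties
lexicographic) are exported one id per line for ranked-list GO tools.

## Synthetic data

The genotype generator is a hierarchical Balding–Nichols model on the
rooted quartet ((W,X),(Y,Z)): ancestral frequency p ~ Uniform(0.05, 0.95)
per SNP (avoiding near-monomorphic sites dominating; configurable), then
along each branch with drift F the frequency is redrawn from
Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes are Binomial(2, p_pop). Default
drift is 0.05 per branch with 50 diploids per population. Genes occupy
contiguous blocks with a fixed or uniformly drawn SNP count. Sites that
come out monomorphic are still written to the VCF so that consumers must
exercise their filters. A configurable 10% of genes get CNV labels, half
of which receive extra drift (default F = 0.2) on a chosen branch, giving
the CNV permutation test real signal; per-gene B values are drawn
Uniform(0.5, 1).

The expression generator draws counts from a negative binomial with mean
s_j·L_g·μ_g·fold(g, pop(j)) — log-normal size factors (log-sd 0.25,
typical library-size spread), uniform gene lengths 500–5,000 bp,
log-normal per-bp rates, dispersion 0.2 (typical bulk RNA-seq) — with 90
samples per population as the cohort-scale default and user-specified
fold shifts.

What the generators do *not* emulate: linkage between SNPs (sites are
independent given the tree — no recombination or coalescent structure),
gene flow or admixture, shared eQTL structure between the genotype and
expression layers, batch effects, and positional B-value tracks (B enters
as a per-gene median). Passing tests therefore demonstrate correctness of
the estimators and calibration of the tests under the assumed model, not
robustness to those real-data complications.

The additive-quartet distance oracle returns exact path-length distances
for given branch lengths; its outputs satisfy the four-point condition
and drive machine-precision recovery tests.

## Problem sizes and numerical choices

Simulation-based checks run at 500 genes × 20 SNPs with 4 × 50 diploids
(consensus recovery over 20 seeds; elevated-drift ranking over 10), 500
genes × 90 samples/population for expression ranking (10 seeds), and
1,000 replicates for permutation calibration — sizes at which the checked
effects are decisive while a full run stays within minutes on one CPU.
Simulation studies use in-memory arrays; the VCF/TSV path is exercised by
the CLI end-to-end test. Consensus recovery is assessed under clock-like
drift: UPGMA assumes ultrametricity, so a strongly elevated external
branch correctly repositions that population as most distant, which is a
property of UPGMA, not a defect of the consensus.

## Limitations

- The quartet topology must be supplied; misassigned cherries silently
  redistribute branch lengths.
- PBS4 ranks genes; it defines no null distribution, so no per-gene
  significance is attached.
- P_ST inherits all caveats of a single expression measurement per sample
  and the assumed h²; at small per-population sample sizes the
  between-population component is noisy and P_ST is upward-biased by the
  max(0, ·) clamp.
- The background-selection correction is a deliberately simple default;
  it is a plug-in point, not a derivation.
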