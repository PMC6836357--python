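# Methods

## Marker QC and association

Genotypes are alternate-allele dosages 0/1/2 with missing values excluded
from all counts; a marker's call rate is typed/total per group. MAF is
computed on pooled typed cases+controls by default (`maf_group="controls"`
switches to controls only) — the pooled choice matches common array-QC
practice. The Hardy-Weinberg test is the exact conditional test
(Wigginton-style "less likely or equal" two-sided summation) rather than
the chi-square approximation, because the 10⁻⁴ rejection threshold sits in
the tail where the asymptotic test is unreliable; probabilities are
computed in log space via `gammaln` and the observed probability is
compared with a 1 + 10⁻¹² relative guard against ties lost to rounding.
Association under the additive model is the Cochran-Armitage trend test
with weights (0, 1, 2), in its score form

    z = U / sqrt(V),  U = Σ w_j (r_j − R n_j / N),
    V = (R/N)(1 − R/N) (Σ w_j² n_j − (Σ w_j n_j)² / N),

which is algebraically identical to the score test of a logistic
regression of status on dosage; z² is referred to the χ²(1) upper tail.
Markers monomorphic in the pooled sample have an undefined statistic: the
single-marker function raises, the vectorized scan reports NaN/p = 1.

## SNP annotation

Region classification uses per-transcript exon/UTR intervals (1-based,
inclusive) with precedence coding exon > UTR5 > UTR3 > intronic >
upstream > downstream > intergenic; positions inside non-coding
transcripts are classed `ncRNA_intronic`. The upstream/downstream flank is
1,000 bp (the convention of standard variant annotators), configurable.
When a position is simultaneously upstream of one transcript and
downstream of another, upstream wins — a deterministic tie-break.

LD expansion keeps proxies with r² strictly above 0.8 within 100 kb
(inclusive) of an index SNP, in a single pass: proxies of proxies are not
chased, which matches the contract "variants in high LD with the
associated variants".

Chromatin states 1–19 are active, 20–25 inactive, missing not-available.
Cell-type enrichment counts distinct SNPs with an active state per cell
type and standardizes against the across-cell-type mean with the *sample*
standard deviation (n−1), the default of mainstream statistics
environments; the one-sided p is the upper normal tail. Cell types to
exclude (e.g. brain-related) are removed from the enriched set *after*
testing, configurable. With all counts equal the SD is zero and the test
refuses to run rather than returning arbitrary z values.

For the radar-style summary a SNP counts as active if it has at least one
active state in any cell type. When one SNP maps to several genes, all
rows are retained, since seed selection is gene-centric.

Twelve raw eQTL tissue labels map onto seven categories (four osteoblast
culture conditions → bone, two adipose depots → adipose, two skin sites →
skin, plus blood/breast/fibroblast/skeletal-muscle singletons). The map is
total on those twelve labels and raises on anything else, naming the
label. Seed genes per tissue are the union of that tissue's eGenes and the
tissue-independent non-synonymous gene set, with per-gene provenance.

## Expression preprocessing

The pipeline order is fixed: RIN filter (< 6.0 removed; matrices without
RIN annotation, e.g. array data, skip this step with a warning) →
duplicate-symbol aggregation by the per-sample mean → log₂(E+1) →
low-expression filter → latent-covariate adjustment. The low-expression
rule keeps genes with scaled expression > 1 (strict) in at least 80 %
(inclusive, configurable) of samples of at least one tissue, and the
shared keep-set is applied to every tissue so all matrices stay on one
gene universe. The rule is evaluated after the RIN filter (pipeline
order).

Latent-covariate adjustment gene-centers the matrix and removes the
leading right singular vectors (sample-space principal components);
residuals are exactly orthogonal to each removed component. The number of
components is the one genuinely free parameter: the module default is 10
(a common surrogate-variable count for bulk cohorts) and a
permutation-based parallel-analysis helper (`estimate_latent_components`,
Buja–Eyuboglu style) is provided for choosing it from data. In the
synthetic end-to-end runs the pipeline removes exactly the number of
planted batch factors (1): in data whose dominant principal components
*are* the planted biology, removing ten components would remove the
modules themselves — a deliberate property of the synthetic design, not of
real tissue data, where technical variance dominates the leading
components.

## Network construction

For each seed, the k genes with the highest Pearson correlation to the
seed (k ∈ {10, 15, 20, 25, 30}), ranked descending with lexicographic
tie-break for deterministic builds; zero-variance genes are excluded, and
a seed that is absent or constant is skipped with a warning (it still
anchors a PPI-only subnetwork, so annotation-only genes are not silently
lost). PPI expansion is one hop from seeds only; partners absent from the
expression matrix are admitted (they can still carry gene statistics in
the enrichment step). Pruning removes self-loops and collapses duplicate
links within a kind; a coexpression and a PPI link between the same pair
are distinct evidence and both survive. Fusion computes connected
components of the shares-a-gene relation to a fixpoint, so chained
overlaps collapse into one subnetwork and gene sets partition each
network. Edge kinds and weights are preserved through fusion for
provenance even though enrichment consumes only gene sets.

## Subnetwork enrichment

Genes are ranked by the gene-level statistic descending (ties broken by
symbol). The enrichment score is the signed extremum of the weighted
running sum: +|stat|/Σ_set|stat| at member genes (uniform weights if the
set's statistics are all zero), −1/(n−m) elsewhere; an exact tie between
the positive and negative extremum resolves positive. The null is
size-matched random gene sets (gene-label permutation, the preranked
convention); p = (1 + #{|ES_perm| ≥ |ES_obs|}) / (n_perm + 1), two-sided
on |ES| with the +1 pseudocount avoiding zero p-values, and the direction
is read from sign(ES_obs). NES divides ES by the mean |ES| of same-sign
permutations. BH adjustment is applied per network (one family per
(tissue, k) run) by default; a global family across all networks is a
flag, since either reading of "adjusted across subnetworks" is defensible.
The default permutation count is 99,999; tests and the acceptance script
run 999–19,999 with fixed seeds, which bounds the attainable p at 1/(n+1)
but changes nothing structural. Genes of significant subnetworks inherit
the subnetwork's ±1; a direction conflict for one gene is impossible after
fusion and is asserted, not repaired.

## Repositioning sign logic

Mechanism tables are filtered to human, non-endogenous rows with non-empty
action and type, the action outside {binding, mixed, neutral}, and a
usable gene symbol; rows listing several symbols are split one-per-symbol
and flagged. Matching is case-insensitive after trimming, and rows whose
action and type both fall outside the vocabulary are dropped with a logged
reason rather than failing the run (robust to vocabulary drift across
database versions). The action is consulted before the type, as the more
specific descriptor. A ligand-gene pair appearing with both signs is kept
and flagged conflicting. The drug-phenotype sign is the literal product of
the ±1 drug-gene and gene-phenotype signs; only +1 products are
candidates, ordered primary-targets-first, with unknown primary status
treated as non-primary for ordering but never excluded.

## Over-representation analysis

Classic independent-term hypergeometric ORA with BH correction replaces
topology-weighted GO decorrelation algorithms, whose internals are not
reproducible from their descriptions; the universe defaults to the genes
of the processed expression matrices plus PPI-added genes and is
configurable. Terms with zero overlap are still reported.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
real marginals. Genotypes are Hardy-Weinberg draws at uniform MAFs in
[0.05, 0.5] with 20 of 1,000 SNPs shifted in cases by an allele odds ratio
of 3 and a 0.5 % missing rate. Chromatin tables give one designated cell
type a doubled active rate. Expression is a latent-factor model: 2,000
genes × 60 samples per tissue, one module of 35 genes per network tissue
whose members load on a shared factor with loading √(ρ/(1−ρ)), ρ = 0.8,
one global batch factor (strength 0.5), a 5 % low-expression slab, and
five duplicated symbols; raw values are 2^(μ+z) so the log₂ scale recovers
the Gaussian structure. Gene statistics are standard normal noise plus a
±2 shift on module genes, with directions alternating −1/+1 across
modules so both repositioning sign cases occur. Each seed gene gets two
designated PPI partners plus background edges that never touch seeds.
Ligands: one activating and one inhibiting mechanism per planted target
(seeds and partners), decoys targeting genes outside the expression
universe, and deliberately invalid rows exercising every filter; the
beneficial subset is written to a truth sidecar. Non-synonymous genes are
also placed outside the expression universe, which exercises the
skip-with-warning paths without coupling them to the planted modules.

Module size (35) deliberately exceeds the largest k (30) so top-k
neighbor lists stay inside the planted module: member-to-seed correlations
(≈ 0.8 ± 0.05 at n = 60) clear the maximal noise correlation (≈ 0.5)
with margin, making end-to-end candidate recovery a sharp, reproducible
check. Fixture scales (2,000 genes, 60 samples, 1,000 SNPs) keep the full
suite in minutes on one CPU.

What passing synthetic tests do **not** show: performance under realistic
LD structure, overlapping or hierarchical coexpression modules,
non-Gaussian expression noise, incomplete mechanism annotations at
database scale, or the correct number of latent components for real
tissue — the generator's modules are disjoint and its batch dimension is
known.

## Numerical choices and degenerate inputs

Deterministic tie-breaks throughout (correlation ties by symbol, ranking
ties by symbol, positive ES on exact extremum ties); all randomness flows
through explicit `numpy` generators seeded per call or derived via
`SeedSequence` spawning; the generator is byte-stable per config. Zero
typed genotypes, empty matrices, empty keep-sets, zero-variance
enrichment counts, unknown tissue labels and out-of-range chromatin
states raise informative errors; empty LD expansions, empty seed sets and
no-overlap subnetworks are skipped with warnings, since they are expected
in sparse data.

## Known limitations

Sample-level genotype QC, population-stratification analysis and
batch-effect testing are out of scope, as are weighted (soft-threshold)
coexpression networks, sample-permutation GSEA, leading-edge analysis,
affinity/potency modeling, and live queries of external databases — the
package consumes files in their shapes. The bone-array path enters the
preprocessing at the aggregation step (no RIN), mirroring how array data
lack RNA integrity numbers.
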