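# gwas2drug

From case/control GWAS variants to tissue-specific coexpression subnetworks
and sign-logic drug repositioning.

## The problem

Familial short stature — short stature with a family history and otherwise
normal growth — is strongly heritable, yet recombinant growth hormone is
essentially the only treatment. Variants associated with the phenotype can
point at therapeutic targets, but single SNPs rarely map cleanly onto
druggable genes. `gwas2drug` implements an annotation-driven pipeline that
turns a set of associated variants into ranked, direction-aware drug
repositioning candidates. It is a library for analysts working at the
intersection of statistical genetics and pharmacology, with a thin CLI for
running the stages from a shell.

The pipeline has two halves:

**SNP-heuristic half.** Marker-level QC (MAF < 0.05, call rate < 0.98 in
either group, exact Hardy-Weinberg p < 10⁻⁴ in controls) and
Cochran-Armitage association under the additive model; genomic region
classification against a gene model; single-pass LD expansion (proxies with
r² > 0.8 within 100 kb); 25-state chromatin segmentation (states 1–19
"active") with a per-cell-type enrichment z-test,
Z = (N − mean N) / SD(N); merging of twelve raw eQTL tissue labels into
seven categories (adipose, blood, bone, breast, fibroblast, skeletal
muscle, skin); and seed-gene selection — tissue-specific eGenes plus genes
carrying non-synonymous variants.

**Expression-based half.** Per tissue, expression matrices are RIN-filtered
(< 6.0), duplicate-aggregated, log₂(E+1)-scaled, filtered to genes with
scaled expression > 1 in ≥ 80 % of samples of at least one tissue, and
residualized on leading sample-space principal components. Each seed gene
is joined to its top-k Pearson-correlated genes (k ∈ {10, 15, 20, 25, 30})
and its direct PPI partners; subnetworks sharing a gene are fused. Each
fused subnetwork is tested by permutation GSEA (weighted Kolmogorov-Smirnov
running sum, size-matched gene-set null, BH-adjusted, FDR < 0.1) against
gene-level height statistics; significant subnetworks give every member
gene a ±1 gene-phenotype direction. Ligand-target mechanism tables are
filtered and signed (+1 activating vocabulary, −1 inhibiting vocabulary),
and the product

    drug-gene sign × gene-phenotype sign = drug-phenotype sign

selects +1 pairs — drugs expected to enhance height — as repositioning
candidates, annotated by primary-target status.

A first-class synthetic-data module generates every input table with
planted structure (risk SNPs at a chosen odds ratio, a boosted chromatin
cell type, coexpression modules at a chosen correlation, signed height
effects, beneficial/neutral ligands with a truth sidecar), so the whole
pipeline is testable offline.

## Worked example

```python
from gwas2drug.pipeline import run_pipeline
from gwas2drug.simulate import SimConfig, generate_all

sim = generate_all(SimConfig(seed=1))
result = run_pipeline(sim, n_perm=2999, seed=1)
```

Running `python examples/06_full_pipeline.py` prints:

```
networks built: 30 (6 tissues x 5 k values)
significant subnetworks at FDR < 0.1: 30 of 30 tested
candidate ligand-gene pairs: 36 (truth: 36); exact match: True
```

Thirty networks are the 6 network tissues × 5 k values; each contains the
tissue's planted module as one fused subnetwork, detected with its planted
±1 direction; the 36 candidates are exactly the beneficial ligands the
generator wrote to its truth sidecar (inhibitors of −1-direction genes,
agonists of +1-direction genes). The other scripts in `examples/` walk
through each stage on its own: marker QC, SNP annotation, preprocessing and
network construction, GSEA plus repositioning, and over-representation
analysis.

The same stages are available from the shell:

```bash
gwas2drug simulate --seed 1 --out sim/
gwas2drug qc --cases sim/genotypes_cases.tsv --controls sim/genotypes_controls.tsv --out qc/
gwas2drug annotate --snps sim/snp_annotation.tsv --proxies sim/ld_proxies.tsv \
    --chromatin sim/chromatin_states.tsv --eqtl sim/eqtl.tsv --out anno/
```

## Layout

- `src/gwas2drug/` — `gwas` (QC + association), `annotation`, `preprocess`,
  `network`, `gsea`, `repositioning`, `ora`, `simulate`, `pipeline`, `io`,
  `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, parameter choices, and limitations
- `tests/` — unit, property and acceptance suites (oracles in
  `tests/helpers.py`)
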