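# coexgwas

Linking common-variant association signal with age-dependent transcriptional
networks. `coexgwas` is a Python library for analyses of the kind used to ask
whether the gene co-expression modules that change with age in brain tissue —
microglial and oligodendrocytic programmes in hippocampus, for example — are
enriched for genes carrying GWAS association with disease or longevity. It is
aimed at statistical geneticists and systems biologists who work from GWAS
summary statistics and bulk or single-cell expression matrices.

## What it computes

**LD-aware gene scores.** SNP p-values are aggregated per gene with the
SNP-wise mean model: for the *k* SNPs in a gene's (optionally 35 kb
upstream / 10 kb downstream, strand-aware) window,

    T = (1/k) Σ_i χ²_i,     χ²_i = [Φ⁻¹(p_i / 2)]²

Under the null, `T ~ Σ_j (λ_j / k) χ²₁` with `λ_j` the eigenvalues of the
gene's LD correlation submatrix; the tail probability is evaluated
essentially exactly with Ruben's mixture-of-chi-square series (Imhof
inversion as fallback). Scores get Benjamini-Hochberg q-values, and
significant genes within ±500 kb merge into loci.

**Co-expression modules.** Signed adjacency `a_ij = ((1 + cor_ij)/2)^β`,
topological overlap (TOM), average-linkage clustering of `1 − TOM` with a
fixed-height cut, then k-means-style refinement in eigengene space: each gene
moves to the module whose eigengene it has the highest kME with. Module
eigengenes are first principal components; module-age association is the
eigengene-age Pearson R². Cell-type enrichment of modules uses one-sided
Fisher/hypergeometric tests on marker sets.

**Module dynamics and preservation.** Module expression is proxied by the
mean of the 100 most central (highest-kME) genes, compared between two
groups by Student's t-test or across treatment time points by one-way ANOVA
with Dunnett's many-to-one test gated at ANOVA P < 0.05. Cross-dataset
preservation is quantified by permutation z-statistics: z.density (mean
within-module adjacency), z.connectivity (rank correlation of intramodular
connectivity), and z.summary, their mean. Orthologue tables map modules
across species; eigengenes can be projected into query datasets.

**Module-enrichment tests.** The bootstrap test draws size-matched random
gene sets from the scored universe (100 000 iterations by convention) and
reports the fraction with at least as many nominally significant
(gene-based P ≤ 0.01) genes as the module — so the smallest nonzero p is
1/100 000. A closed-form hypergeometric oracle validates it, and a
MAGMA-style competitive regression of per-gene `Z = Φ⁻¹(1 − p)` on module
membership plus gene-length and SNP-count covariates gives an independent
one-sided test.

A synthetic-data module generates all inputs with planted ground truth
(LD-blocked z-scores with planted gene signal, latent-factor modules whose
factors track age, marker sets), so the whole pipeline is testable offline.

## Worked example

```sh
python examples/05_enrichment.py
```

```
detected age module: 400 genes (Jaccard 1.00 vs planted), age R2 = 0.50
observed overlap with gene-based P <= 0.01 genes: 38
bootstrap p = 0   (hypergeometric oracle 7.99e-19)
competitive beta = 0.375, one-sided p = 3.06e-12
```

The pipeline simulated a 10 000-gene scored universe in which 40 of the 400
genes of a planted age-dependent module carry GWAS signal, re-detected the
module from expression alone (Jaccard 1.00 against the planted truth, with
eigengene-age R² = 0.50), and found 38 of its genes among the nominally
significant gene scores. No random size-matched gene set matched that
overlap in 100 000 bootstrap draws (p = 0 at the 1e-5 resolution floor,
hypergeometric tail 8e-19), and the competitive regression agrees. The other
examples (`examples/01…04`) walk through gene scoring, module detection,
group dynamics and preservation individually.

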