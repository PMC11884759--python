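# Methods

## Gene-based association under linkage disequilibrium

The gene statistic is the SNP-wise mean model: each SNP's two-sided p-value
is converted back to a chi-square, `χ²_i = [Φ⁻¹(p_i/2)]²`, and a gene's
statistic is the mean over its annotated SNPs. Annotation is strand-aware:
with upstream window *u* and downstream window *d* (defaults 35 000 and
10 000 bp; 0/0 for the window-free variant), a '+' gene spans
`[start−u, end+d]` and a '−' gene `[start−d, end+u]`; a SNP may annotate to
several genes, and genes without SNPs are absent from the score table rather
than scored zero. The mean model (rather than top-SNP) is used throughout;
both window modes are separate runs tagged in the output, and downstream
enrichment uses the window-free run, the more conservative choice that also
avoids double-counting SNPs shared by neighbouring windows.

Under the null, `T ~ Σ_j w_j χ²₁` with `w_j = λ_j / k`, the scaled
eigenvalues of the gene's LD submatrix (floored at zero if the matrix is
not positive semi-definite; the repair is logged). SNPs in perfect LD
(|r| = 1) with an already-included SNP are dropped before scoring: they
contribute an identical chi-square and no information, and dropping them
makes the gene p exactly invariant to duplication.

The null tail is evaluated with **Ruben's series**: with `β = min w_j`, the
distribution of the weighted sum is an infinite mixture
`Σ_r a_r · Chi2(k + 2r)` with non-negative coefficients from the recursion
`a_r = (1/r) Σ_{s<r} g_{r−s} a_s`, `g_r = ½ Σ_j (1 − β/w_j)^r`. The series
is truncated when the remaining mixture mass is below 1e-13, which bounds
the absolute error of any tail value by the same amount; coefficients
depend only on the spectrum, so genes sharing an LD pattern share one set
and the evaluation vectorizes. One distinct eigenvalue reduces to an exact
scaled chi-square (this covers the single-SNP identity and the perfect-LD
block). Ill-conditioned spectra whose series would need more than 5 000
terms fall back to Imhof's characteristic-function inversion per point.
A two-moment gamma approximation was evaluated first and rejected: for
block-equicorrelated spectra such as ten SNPs at ρ = 0.5 (eigenvalues
5.5, 0.5×9) its p-values are visibly mis-calibrated (a Kolmogorov-Smirnov
test against uniformity rejects overwhelmingly at 10 000 null genes), which
would break the pipeline's null-calibration guarantee.

FDR uses Benjamini-Hochberg step-up q-values. Locus merging is
single-linkage: significant genes (default gene-wide P ≤ 1e-6) on one
chromosome share a locus when the gap between their bodies is at most
500 kb; merging is transitive.

LD input is either a correlation matrix or a genotype panel; panels are
converted to correlation with shrinkage `(1−λ)R + λI` toward identity,
λ = 0.001 by default.

## Synthetic data with planted truth

All generators are pure functions of a `SimulationConfig` (master seed;
per-generator substreams use fixed spawn keys 0-3) and return their ground
truth alongside the data.

* **LD**: block-diagonal equicorrelation — within blocks of
  `ld_block_size` SNPs the correlation is `ld_rho`, across blocks zero.
  This is deliberately simpler than a recombination map: the eigenvalues
  are analytic, which makes oracle tests exact, while still exercising the
  LD-aware null.
* **GWAS**: z-scores are multivariate normal with the LD covariance
  (sampled through the factor representation of the equicorrelated block);
  SNPs inside a planted gene get mean equal to that gene's noncentrality
  (maximum if planted genes overlap). P-values are two-sided.
* **Expression**: each planted module has a latent factor
  `f = standardize(slope · age_std + ε)` and gene values
  `μ_g + noise_sd · (√r·f + √(1−r)·ε_g)`, so the within-module correlation
  is exactly `r` and the factor-age regression slope is the stated
  `age_slope`. Background genes are independent noise. Values are on an
  already-normalized log-like scale; downstream stages never re-normalize.
  Age is continuous uniform 20-90 years for bulk emulation or drawn from
  discrete levels (e.g. 3/6/12/21 months) for the single-cell-like design;
  the covariate table also carries a young/old median split and sex.

What the generator does **not** emulate: realistic allele-frequency spectra,
imputation noise, single-cell dropout or count noise, multiple overlapping
regulatory structures, or gene-length/LD confounding between module
membership and association (the competitive test's covariates are therefore
exercised with separately constructed confounded instances in the tests).
Passing tests demonstrate the statistics behave as designed under their
stated nulls and planted alternatives, not that real cohorts meet those
assumptions.

## Network construction and modules

Signed adjacency `((1+cor)/2)^β` with Pearson correlation (biweight
midcorrelation is not implemented), TOM
`(Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, average-linkage
clustering of `1 − TOM`. Tree cutting is a **static fixed-height cut** at a
configurable fraction (default 0.99) of the dendrogram height; clusters
smaller than `min_module_size` (default 30) become label 0 (grey). On
latent-factor data this cut cleanly separates planted blocks (measured
ARI = 1.0 on 50+50-gene instances) and sends pure noise almost entirely to
grey, because noise merges concentrate in a narrow height band just under
the cut while genuine modules merge far below it. The variant and its
parameters are recorded in `ModuleSet.provenance`.

Soft power is chosen as the smallest candidate whose scale-free fit R²
(signed log-log regression of binned connectivity frequency) reaches the
target, else the argmax — the WGCNA convention. One caveat found during
development: Gaussian latent-factor modules are not scale-free networks, so
their attainable fit plateaus around 0.4-0.75 and the default 0.8 target
routinely falls through to the argmax. Analyses of such synthetic data
should either pass an explicit power (the pipeline uses β = 6) or a target
near 0.5; with real transcriptomes the usual 0.8 convention applies.

Eigengenes are first right-singular vectors of the gene-standardized module
submatrix (unit norm, one value per sample), sign-oriented so the mean
own-module kME is non-negative; variance explained is `s₁²/Σs²`. kME is the
gene-eigengene Pearson correlation. Refinement reassigns every gene (fixed
input order, so the result is deterministic) to its best-kME module if that
kME reaches the floor (default 0.3, preventing noise capture), else grey,
recomputes eigengenes, and repeats to a fixed point or `max_iter` = 20. The
mean own-module kME is the monotone objective: a sweep that would lower it
is rejected and iteration stops, so refinement never degrades the
assignment it started from.

Module-trait association reports eigengene-age R², two-sided p and sign,
with a flag at |r| > 0.4 mirroring the usual reporting threshold for
age-dependent modules. Cell-type marker enrichment is the one-sided
hypergeometric tail with BH correction across (module, cell-type) pairs;
cross-set overlap uses Fisher's exact test.

## Module dynamics and preservation

Module proxy expression is the per-sample arithmetic mean of the module's
top-k (default 100) own-kME genes, intersected with the genes present in
the target matrix (k_used reported). Input expression is assumed already on
a log-like scale (the generator's output is); the proxy applies no further
transform. Two-group comparison is the classic equal-variance Student
t-test (Welch via `equal_var=False`). Time-course comparison is one-way
ANOVA, and Dunnett's many-to-one contrasts are computed **only** when the
ANOVA p < 0.05 — the gating is part of the procedure, not a convenience.
Dunnett p-values come from scipy's equicorrelated multivariate-t
implementation; the test-suite checks them against a 10⁶-draw Monte-Carlo
max-|t| oracle (agreement within 5e-4 measured, bound 0.005).

Preservation of a reference module in a query dataset (≥ 30 shared genes,
else skipped): observed z.density is the mean off-diagonal signed adjacency
among module genes in the query (reference soft power), observed
z.connectivity the Spearman correlation of intramodular connectivity
between reference and query; both are standardized against `n_perm`
(default 200) size-matched random sets drawn from the shared genes, and
z.summary is their mean. A zero permutation SD yields a ±inf sentinel with
a warning — this happens, for instance, when the query *is* the reference
matrix, where connectivity ranks agree perfectly for every gene set; the
meaningful self-preservation check therefore uses an independent replicate
of the same design. One property of exchangeable planted modules worth
knowing: all their genes are statistically identical hubs, so
z.connectivity carries no signal (≈ 0 or negative) and preservation is
driven by z.density; real modules with graded hub structure behave
differently.

Orthologue mapping is an offline two-column table lookup: one-to-one
mappings kept, one-to-many resolved by policy (default drop-and-count,
optionally lexicographic first), unmapped genes listed. Eigengene
projection recomputes the first PC of the query submatrix restricted to a
reference module's genes (≥ 5 shared required).

## Enrichment tests

The bootstrap null draws size-matched gene sets from the universe without
replacement and counts draws whose number of nominally significant genes
(gene-based p ≤ α, default 0.01) is **larger than or equal to** the
observed count; the p-value is that fraction, with resolution exactly
1/n_iter (default 100 000) and zero attainable. A `plus_one` flag offers
the (k+1)/(n+1) convention. Sampling is vectorized with chunked
random-key top-k selection, so results are independent of iteration order;
the RNG is seeded. Covariate-matched sampling is not implemented — the
default null is plain size-matched sampling, and confounding is instead
handled by the competitive test's covariates. Because the counting
statistic is discrete, null bootstrap p-values are valid (sub-uniform)
rather than exactly uniform; the tests check validity at multiple
thresholds.

Under this null the overlap count is exactly hypergeometric, so
`hypergeometric_tail` (direct log-factorial summation) is both a fast
oracle and a cross-check: the suite requires |p_boot − p_hyper| within
3 Monte-Carlo standard errors on every tested instance.

The competitive test regresses `Z = Φ⁻¹(1 − p_gene)` on 0/1 module
membership plus log gene length and log SNP count (absent covariates
skipped with a log message, collinear or constant ones dropped with a
warning), and reports the one-sided t-test of the membership coefficient.
Competitive mode — testing module genes against the remaining universe —
is the standard design for this question and the one implemented; a
self-contained variant is out of scope. The universe can be restricted to
reliably expressed genes (`restrict_universe`), mirroring how single-cell
module universes should exclude genes the assay cannot see.

## Problem sizes and numerical choices

Simulation sizes used by the test-suite and acceptance script are chosen to
make each statistical property measurable with comfortable margins: 10 000
genes × 10 SNPs for null calibration; 50+50-gene modules over 200 samples
for recovery; 200 permutations and 20 random draws for preservation
calibration; 100 (tests) or 20 (script) independent seeds for end-to-end
power with a 400-gene module in a 10 000-gene universe, 2 000 bootstrap
iterations where only p < 0.05 is at stake and 100 000 where the resolution
floor itself is. Ties in hierarchical clustering are broken by gene index;
module labels are renumbered by decreasing size. Eigenvalue flooring,
series truncation (1e-13) and the p-value floor at the smallest positive
double are the only numerical tolerances in the scoring path.

## Known limitations

* The preservation suite implements the two statistics that make up
  z.summary (density, connectivity), not the full seven-statistic medley.
* No conditional/joint SNP analysis, no MHC special-casing, no TWAS or
  pathway annotation; pseudotime and functional-annotation steps that
  surround these analyses in practice are out of scope.
* The static tree cut is a deliberate simplification of dynamic tree cut;
  on very unbalanced module structures a hybrid cut may recover more
  modules. Parameters are exposed and the choice is recorded in provenance.
* Group comparisons are plain t/ANOVA without covariate adjustment or
  mixed effects.
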