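"""Gene-based GWAS scores under an LD-aware null, FDR and locus merging.

Simulates LD-blocked GWAS summary statistics with two planted risk genes,
aggregates SNP p-values per gene (SNP-wise mean chi-square), corrects with
Benjamini-Hochberg and merges significant genes into +/-500 kb loci.
"""

import coexgwas as cg

cfg = cg.SimulationConfig(
    seed=42, n_snps=5_000, n_genes=200, ld_block_size=10, ld_rho=0.5,
    planted_genes={"g50": 5.0, "g120": 6.0},
)
genes = cg.simulate_gene_models(cfg)
ld = cg.simulate_ld(cfg)
gwas = cg.simulate_gwas(genes, ld, cfg)

# the conventional 35 kb upstream / 10 kb downstream annotation window
annotation = cg.annotate_snps(gwas, genes, window_up=35_000, window_down=10_000)
scores = cg.fdr_correct(cg.gene_based_test(gwas, annotation, ld, genes, window_mode="35k/10k"))
scores = cg.define_loci(scores, p_threshold=1e-6)

top = scores.nsmallest(5, "p_value")[["gene_id", "n_snps", "T", "p_value", "q_value", "locus_id"]]
print(top.to_string(index=False))
print(
    f"\n{int((scores.q_value <= 0.01).sum())} genes at FDR q <= 0.01; "
    f"{scores.locus_id.nunique()} locus/loci at gene-wide P <= 1e-6."
)
print("The two planted genes (g50, g120) should dominate the ranking; T is the")
print("mean per-SNP chi-square and its null accounts for the LD block structure.")
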