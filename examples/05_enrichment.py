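"""Module enrichment for GWAS association: bootstrap null and competitive test.

Runs the full planted-truth experiment: a 10 000-gene scored universe with an
age-dependent 400-gene module enriched for planted GWAS genes, then both
enrichment tests — the size-matched bootstrap overlap null (100 000-iteration
convention; here 2 000 for speed) and the competitive regression of gene
Z-scores on module membership with gene-length and SNP-count covariates.
"""

from coexgwas.pipeline import run_planted_enrichment

out = run_planted_enrichment(seed=1, n_iter_bootstrap=100_000)
print(f"detected age module: {out['module_size_detected']} genes "
      f"(Jaccard {out['module_recovery_jaccard']:.2f} vs planted), "
      f"age R2 = {out['age_R2']:.2f}")
print(f"observed overlap with gene-based P <= 0.01 genes: {out['observed_overlap']}")
print(f"bootstrap p = {out['bootstrap_p']:.3g}   (hypergeometric oracle {out['oracle_p']:.3g})")
print(f"competitive beta = {out['competitive_beta']:.3f}, one-sided p = {out['competitive_p']:.3g}")
print("\nBoth tests should reject decisively: the module carries planted GWAS")
print("signal. With 100 000 iterations the smallest nonzero bootstrap p is 1e-5;")
print("a reported 0 means no random draw matched the observed overlap.")
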