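import numpy as np
import pandas as pd
import pytest

import coexgwas as cg
from coexgwas.simulate import LDMatrix


def make_gwas_table(pvals, positions=None, chrom="chr1"):
    """Bare GWAS summary table for hand-built test instances."""
    pvals = np.asarray(pvals, dtype=float)
    if positions is None:
        positions = np.arange(1, len(pvals) + 1) * 100
    return pd.DataFrame(
        {
            "SNP": [f"s{i + 1}" for i in range(len(pvals))],
            "CHR": chrom,
            "BP": np.asarray(positions, dtype=np.int64),
            "A1": "A",
            "A2": "G",
            "P": pvals,
            "N": 10_000,
        }
    )


def gene_p_for(pvals, ld_dense):
    """Gene p-value for one gene covering all SNPs of a hand-built instance."""
    tab = make_gwas_table(pvals)
    ld = LDMatrix(tab["SNP"].to_numpy(), dense=np.asarray(ld_dense, dtype=float))
    return float(cg.gene_based_test(tab, {"g1": tab.index.to_numpy()}, ld)["p_value"][0])


@pytest.fixture(scope="session")
def two_block_expression():
    """Planted two-module expression (50+50 genes, r=0.7, 200 samples)."""
    cfg = cg.SimulationConfig(
        seed=11,
        n_genes=100,
        n_expr_samples=200,
        module_spec=(cg.ModuleSpec("A", 50, 0.7, 0.0), cg.ModuleSpec("B", 50, 0.7, 0.0)),
    )
    return cg.simulate_expression(cfg)


@pytest.fixture(scope="session")
def age_module_expression():
    """One planted module (50 genes, r=0.7) whose latent factor tracks age."""
    cfg = cg.SimulationConfig(
        seed=5,
        n_genes=150,
        n_expr_samples=200,
        module_spec=(cg.ModuleSpec("age", 50, 0.7, 1.0),),
    )
    return cg.simulate_expression(cfg)
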