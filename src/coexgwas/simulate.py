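"""Synthetic GWAS + co-expression data with planted ground truth.

Every generator is a pure function of a :class:`SimulationConfig` (including its
seed) and returns its ground truth alongside the data, so each downstream stage
of the pipeline — gene-based scoring, module detection, module dynamics and
gene-set enrichment — can be tested without any external download.

The statistical structure emulated:

* SNP association z-scores drawn from a multivariate normal whose covariance is
  a block-equicorrelation linkage-disequilibrium (LD) matrix, with the mean
  shifted for SNPs inside "planted" trait genes (a per-gene noncentrality).
* Expression matrices in which each planted co-expression module is generated
  from a shared latent factor (factor loading ``sqrt(within-module
  correlation)``) that is itself regressed on standardized sample age with a
  stated slope; the remaining genes are independent noise.

Seed substreams: one master seed; per-generator streams derived with fixed
spawn keys — 0: gene models, 1: LD genotype panel, 2: GWAS z-scores,
3: expression.  Same master seed implies bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneModel",
    "LDMatrix",
    "GwasSummary",
    "ExpressionMatrix",
    "ModuleSpec",
    "SimulationConfig",
    "simulate_gene_models",
    "simulate_ld",
    "simulate_gwas",
    "simulate_expression",
    "write_gwas_tsv",
    "write_gene_models_tsv",
    "write_expression_tsv",
]

# spawn keys for per-generator substreams (documented in module docstring)
_STREAM_GENES = 0
_STREAM_LD = 1
_STREAM_GWAS = 2
_STREAM_EXPR = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class GeneModel:
    """One gene body: 1-based inclusive coordinates, strand '+' or '-'."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``within_correlation`` is the pairwise gene-gene correlation inside the
    module (factor loading ``sqrt(r)``); ``age_slope`` is the regression slope
    of the module latent factor on standardized sample age.
    """

    module_id: str
    size: int
    within_correlation: float
    age_slope: float = 0.0

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if not 0.0 < self.within_correlation < 1.0:
            raise ValueError("within-module correlation must be in (0,1)")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_snps: int = 1000
    n_genes: int = 100
    ld_block_size: int = 10
    ld_rho: float = 0.5
    n_gwas_samples: int = 50_000
    planted_genes: dict[str, float] = field(default_factory=dict)
    n_expr_samples: int = 100
    module_spec: tuple[ModuleSpec, ...] = ()
    noise_sd: float = 1.0
    min_gene_gap: int = 1000
    chromosome: str = "chr1"
    chromosome_length: int | None = None
    age_levels: tuple[float, ...] | None = None

    def __post_init__(self):
        for name in ("n_snps", "n_genes", "ld_block_size", "n_gwas_samples", "n_expr_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0,1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        object.__setattr__(self, "module_spec", tuple(self.module_spec))

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


class LDMatrix:
    """Symmetric SNP x SNP correlation matrix with unit diagonal.

    Stored either densely or, for the block-equicorrelation simulation model,
    implicitly as a per-SNP block index plus a common within-block correlation
    (off-block correlation is zero).  ``submatrix`` materialises the dense
    correlation matrix for an arbitrary index subset, which is all the
    gene-based test needs.
    """

    def __init__(self, snp_ids, *, dense=None, block_index=None, rho=None):
        self.snp_ids = np.asarray(snp_ids)
        if dense is not None:
            dense = np.asarray(dense, dtype=float)
            if dense.shape != (len(self.snp_ids),) * 2:
                raise ValueError("dense LD shape does not match snp_ids")
            if not np.allclose(dense, dense.T):
                raise ValueError("LD matrix must be symmetric")
            if np.abs(dense).max() > 1 + 1e-8:
                raise ValueError("LD entries must lie in [-1, 1]")
            np.fill_diagonal(dense, 1.0)
            self._dense = dense
            self._block = None
            self._rho = None
        else:
            if not 0.0 <= rho < 1.0:
                raise ValueError("ld_rho must be in [0,1)")
            self._dense = None
            self._block = np.asarray(block_index, dtype=np.int64)
            self._rho = float(rho)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def submatrix(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.int64)
        if self._dense is not None:
            return self._dense[np.ix_(idx, idx)]
        blocks = self._block[idx]
        r = np.where(blocks[:, None] == blocks[None, :], self._rho, 0.0)
        np.fill_diagonal(r, 1.0)
        return r

    def to_dense(self) -> np.ndarray:
        if self._dense is not None:
            return self._dense.copy()
        return self.submatrix(np.arange(self.n_snps))

    def sample_panel(self, n: int, seed: int) -> np.ndarray:
        """Draw an n x n_snps Gaussian genotype-like panel with this correlation."""
        rng = _rng(seed, _STREAM_LD)
        if self._dense is not None:
            chol = np.linalg.cholesky(
                self._dense + 1e-10 * np.eye(self.n_snps)
            )
            return rng.standard_normal((n, self.n_snps)) @ chol.T
        # equicorrelated blocks: z = sqrt(rho)*shared + sqrt(1-rho)*own
        shared = rng.standard_normal((n, self._block.max() + 1))
        own = rng.standard_normal((n, self.n_snps))
        return np.sqrt(self._rho) * shared[:, self._block] + np.sqrt(1 - self._rho) * own

    @staticmethod
    def from_genotypes(panel: np.ndarray, snp_ids, shrinkage: float = 0.001) -> "LDMatrix":
        """Correlation matrix from a samples x SNPs panel, shrunk toward identity."""
        r = np.corrcoef(np.asarray(panel, dtype=float), rowvar=False)
        r = (1 - shrinkage) * r + shrinkage * np.eye(r.shape[0])
        np.fill_diagonal(r, 1.0)
        return LDMatrix(snp_ids, dense=r)


@dataclass
class GwasSummary:
    """Per-SNP association records plus an optional LD handle and planted truth."""

    table: pd.DataFrame  # columns SNP, CHR, BP, A1, A2, P, N
    ld: LDMatrix | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        p = self.table["P"].to_numpy()
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        if np.any(self.table["BP"].to_numpy() <= 0):
            raise ValueError("positions must be positive")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with sample covariates and planted truth."""

    values: pd.DataFrame  # index gene_id, columns sample ids
    covariates: pd.DataFrame  # index sample ids; columns age, group, sex
    truth: dict = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def simulate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping gene bodies along one chromosome.

    Gene lengths are uniform on [2 kb, 20 kb] and inter-gene gaps uniform on
    [min_gene_gap, min_gene_gap + 19 kb]; all pairwise gaps are therefore at
    least ``config.min_gene_gap``.  Raises if a fixed ``chromosome_length``
    cannot hold ``n_genes`` genes.
    """
    rng = _rng(config.seed, _STREAM_GENES)
    lengths = rng.integers(2_000, 20_001, size=config.n_genes)
    gaps = rng.integers(config.min_gene_gap, config.min_gene_gap + 19_001, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes = []
    pos = 1
    for i in range(config.n_genes):
        start = pos + int(gaps[i])
        end = start + int(lengths[i]) - 1
        genes.append(
            GeneModel(f"g{i + 1}", config.chromosome, start, end, str(strands[i]))
        )
        pos = end
    if config.chromosome_length is not None and pos > config.chromosome_length:
        raise ValueError(
            f"chromosome of length {config.chromosome_length} too short for "
            f"{config.n_genes} genes (need {pos})"
        )
    return genes


def simulate_ld(config: SimulationConfig) -> LDMatrix:
    """Block-diagonal equicorrelation LD: within-block r = ld_rho, 0 across.

    Blocks are consecutive runs of ``ld_block_size`` SNPs (last block possibly
    shorter).  The matrix is positive semi-definite for any rho in [0,1).
    """
    snp_ids = np.array([f"rs{i + 1}" for i in range(config.n_snps)])
    block_index = np.arange(config.n_snps) // config.ld_block_size
    return LDMatrix(snp_ids, block_index=block_index, rho=config.ld_rho)


def _snp_positions(config: SimulationConfig, gene_models: list[GeneModel]) -> np.ndarray:
    span = max(g.end for g in gene_models) + 50_000
    # even spacing keeps every gene covered and is deterministic
    return np.linspace(1, span, config.n_snps).astype(np.int64)


def simulate_gwas(
    gene_models: list[GeneModel], ld: LDMatrix, config: SimulationConfig
) -> GwasSummary:
    """Per-SNP z-scores ~ MVN(mean, LD); two-sided p-values.

    The mean is zero except at SNPs whose position falls inside a planted
    gene's body, where it equals that gene's noncentrality (the maximum if a
    SNP sits in several planted genes).
    """
    gene_by_id = {g.gene_id: g for g in gene_models}
    for gid in config.planted_genes:
        if gid not in gene_by_id:
            raise ValueError(f"planted gene {gid!r} not in gene models")
    pos = _snp_positions(config, gene_models)
    mean = np.zeros(config.n_snps)
    for gid, ncp in config.planted_genes.items():
        g = gene_by_id[gid]
        inside = (pos >= g.start) & (pos <= g.end)
        mean[inside] = np.maximum(mean[inside], ncp)
    z = ld.sample_panel(1, seed=_mix(config.seed, _STREAM_GWAS))[0] + mean
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "SNP": ld.snp_ids,
            "CHR": config.chromosome,
            "BP": pos,
            "A1": "A",
            "A2": "G",
            "P": p,
            "N": config.n_gwas_samples,
        }
    )
    truth = {
        "z": z,
        "mean": mean,
        "planted_genes": dict(config.planted_genes),
    }
    return GwasSummary(table=table, ld=ld, truth=truth)


def _mix(seed: int, stream: int) -> int:
    # stable sub-seed for samplers that take a plain integer seed
    return int(np.random.SeedSequence(seed, spawn_key=(stream,)).generate_state(1)[0] % (2**31))


def simulate_expression(
    config: SimulationConfig, gene_ids: list[str] | None = None
) -> ExpressionMatrix:
    """Genes x samples matrix with planted latent-factor modules.

    Module genes: ``x = mu_g + noise_sd * (sqrt(r) * f + sqrt(1-r) * eps)``
    with the latent factor ``f`` standardized after adding ``age_slope *
    age_std``; background genes are independent noise.  Values are on an
    already-normalized (log-like) scale; downstream stages never re-normalize.
    """
    total_module = sum(m.size for m in config.module_spec)
    if total_module > config.n_genes:
        raise ValueError("sum of module sizes exceeds n_genes")
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(config.n_genes)]
    elif len(gene_ids) != config.n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    rng = _rng(config.seed, _STREAM_EXPR)
    n = config.n_expr_samples
    if config.age_levels is None:
        age = rng.uniform(20.0, 90.0, size=n)
    else:
        age = np.asarray(config.age_levels, dtype=float)[
            rng.integers(0, len(config.age_levels), size=n)
        ]
    age_std = (age - age.mean()) / age.std() if age.std() > 0 else np.zeros(n)
    sex = rng.choice(["F", "M"], size=n)
    group = np.where(age >= np.median(age), "old", "young")

    values = np.empty((config.n_genes, n))
    mu = rng.normal(5.0, 2.0, size=config.n_genes)
    module_labels = {}
    factors = {}
    cursor = 0
    for m in config.module_spec:
        raw = m.age_slope * age_std + rng.standard_normal(n)
        f = (raw - raw.mean()) / raw.std()
        factors[m.module_id] = f
        r = m.within_correlation
        eps = rng.standard_normal((m.size, n))
        block = np.sqrt(r) * f + np.sqrt(1.0 - r) * eps
        values[cursor : cursor + m.size] = (
            mu[cursor : cursor + m.size, None] + config.noise_sd * block
        )
        for gid in gene_ids[cursor : cursor + m.size]:
            module_labels[gid] = m.module_id
        cursor += m.size
    n_bg = config.n_genes - cursor
    if n_bg:
        values[cursor:] = mu[cursor:, None] + config.noise_sd * rng.standard_normal((n_bg, n))

    samples = [f"s{i + 1}" for i in range(n)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples),
        covariates=pd.DataFrame(
            {"age": age, "group": group, "sex": sex}, index=pd.Index(samples, name="sample_id")
        ),
        truth={"module_labels": module_labels, "factors": factors, "age_std": age_std},
    )


# ---------------------------------------------------------------------------
# plain-text writers (TSV); gene models use 1-based inclusive coordinates


def write_gwas_tsv(gwas: GwasSummary, path: str | Path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False)


def write_gene_models_tsv(genes: list[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "gene_id": g.gene_id,
                "score": ".",
                "strand": g.strand,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path, truth_path=None) -> None:
    expr.values.to_csv(path, sep="\t")
    if truth_path is not None:
        pd.Series(expr.truth.get("module_labels", {}), name="module").rename_axis(
            "gene_id"
        ).to_csv(truth_path, sep="\t")
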