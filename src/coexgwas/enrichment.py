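"""Module enrichment against gene-based GWAS scores.

Two tests, applied to a co-expression module's gene set versus a scored gene
universe:

* **Bootstrap overlap-count null** — the observed count O of module genes
  with gene-based p <= alpha is compared with the counts in ``n_iter``
  (default 100 000) size-matched gene sets drawn from the universe without
  replacement; the bootstrap p-value is the fraction of draws whose count is
  *larger or equal* to O.  Its resolution is exactly 1/n_iter, so with the
  default iteration count the smallest nonzero reportable value is 1e-5.
  Under simple random sampling this null is exactly hypergeometric, which the
  closed-form oracle exploits.
* **Competitive gene-set regression** — per-gene ``Z = Phi^-1(1 - p_gene)``
  regressed by OLS on module membership plus nuisance covariates (log gene
  length, log SNP count); a one-sided t-test of the membership coefficient
  asks whether module genes are more associated than the rest of the
  universe.

Gene-based p-values should come from the window-free gene scoring run (the
more conservative variant that also avoids overlap between neighbouring
genes' windows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.api as sm

__all__ = [
    "EnrichmentResult",
    "bootstrap_enrichment",
    "hypergeometric_tail",
    "competitive_gene_set_test",
    "restrict_universe",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    module: str
    n_module_genes: int
    n_significant_in_module: int
    n_significant_in_universe: int
    universe_size: int
    n_iterations: int
    bootstrap_p: float
    oracle_p: float
    alpha: float
    seed: int
    null_counts: np.ndarray | None = None


def exceedance_fraction(null_counts: np.ndarray, observed: int, plus_one: bool = False) -> float:
    """Bootstrap p: #{C_i >= O} / n_iter ('larger or equal' rule).

    With ``plus_one`` the (k+1)/(n+1) convention is used instead, which can
    never report zero.
    """
    k = int(np.sum(np.asarray(null_counts) >= observed))
    n = len(null_counts)
    return (k + 1) / (n + 1) if plus_one else k / n


def bootstrap_enrichment(
    scores: pd.DataFrame | pd.Series,
    module_genes,
    universe,
    alpha: float = 0.01,
    n_iter: int = 100_000,
    seed: int = 0,
    plus_one: bool = False,
    keep_null_counts: bool = False,
    p_column: str = "p_value",
) -> EnrichmentResult:
    """Bootstrap test of low gene-based p-values in a module gene set.

    ``scores`` maps gene_id to gene-based p (a Series, or a frame with
    ``gene_id``/``p_column`` columns); ``universe`` must be a subset of the
    scored genes; module genes outside the universe are dropped with a log
    message.  Deterministic given ``seed``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    p = scores if isinstance(scores, pd.Series) else scores.set_index("gene_id")[p_column]
    universe = pd.Index(sorted(set(universe)))
    missing = universe.difference(p.index)
    if len(missing):
        raise ValueError(f"{len(missing)} universe genes have no score")
    module_genes = set(module_genes)
    dropped = module_genes - set(universe)
    if dropped:
        logger.info("%d module genes outside the universe dropped", len(dropped))
    module_genes &= set(universe)
    n = len(module_genes)
    N = len(universe)
    if n == 0:
        raise ValueError("module has no genes in the universe")
    if n > N:
        raise ValueError("module larger than universe")

    sig = (p.loc[universe].to_numpy() <= alpha)
    K = int(sig.sum())
    observed = int(sig[universe.get_indexer(pd.Index(sorted(module_genes)))].sum())

    rng = np.random.default_rng(seed)
    counts = _null_overlap_counts(sig, n, n_iter, rng)
    boot_p = exceedance_fraction(counts, observed, plus_one=plus_one)
    return EnrichmentResult(
        module="",
        n_module_genes=n,
        n_significant_in_module=observed,
        n_significant_in_universe=K,
        universe_size=N,
        n_iterations=n_iter,
        bootstrap_p=boot_p,
        oracle_p=hypergeometric_tail(observed, n, K, N),
        alpha=alpha,
        seed=seed,
        null_counts=counts if keep_null_counts else None,
    )


def _null_overlap_counts(
    sig: np.ndarray, set_size: int, n_iter: int, rng: np.random.Generator, chunk: int = 2048
) -> np.ndarray:
    """Significant-gene counts in n_iter random size-matched draws (no replacement).

    Vectorized via random-key top-k selection in chunks; each row of keys
    induces a uniform random subset of ``set_size`` universe genes.
    """
    N = len(sig)
    counts = np.empty(n_iter, dtype=np.int64)
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        keys = rng.random((m, N))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        counts[done : done + m] = sig[idx].sum(axis=1)
        done += m
    return counts


def hypergeometric_tail(observed: int, set_size: int, n_sig: int, universe_size: int) -> float:
    """Exact upper tail P(X >= O) for X ~ Hypergeom(N, K, n), via log-factorials.

    The closed-form twin of the bootstrap null: drawing ``set_size`` genes
    without replacement from a universe with ``n_sig`` significant ones makes
    the overlap count exactly hypergeometric.
    """
    N, K, n, O = universe_size, n_sig, set_size, observed
    if not (0 <= K <= N and 1 <= n <= N):
        raise ValueError("inconsistent counts")
    if O > min(n, K):
        raise ValueError("observed count exceeds min(set size, significant count)")
    if O <= 0:
        return 1.0
    ks = np.arange(O, min(n, K) + 1)
    log_terms = (
        _log_comb(K, ks)
        + _log_comb(N - K, n - ks)
        - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(log_terms).sum()))


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def competitive_gene_set_test(
    scores: pd.DataFrame,
    module_genes,
    universe,
    covariate_columns: tuple[str, ...] = ("log_length", "log_nsnps"),
    p_column: str = "p_value",
) -> tuple[float, float]:
    """Competitive gene-set regression: are module genes more associated?

    Per-gene ``Z = Phi^-1(1 - p)`` is regressed on a 0/1 module-membership
    indicator plus available covariates; returns (beta, one-sided p) for
    membership > 0.  Covariates listed but absent from ``scores`` are skipped
    with a log message; collinear/constant covariates are dropped with a
    warning.
    """
    df = scores.set_index("gene_id") if "gene_id" in scores.columns else scores
    universe = pd.Index(sorted(set(universe)))
    df = df.loc[universe]
    member = universe.isin(set(module_genes)).astype(float)
    n_in = int(member.sum())
    n_out = len(universe) - n_in
    if n_in < 10 or n_out < 10:
        raise ValueError("need >= 10 genes both inside and outside the set")
    pvals = np.clip(df[p_column].to_numpy(dtype=float), 1e-300, 1 - 1e-16)
    z = stats.norm.isf(pvals)

    X = [member]
    names = ["membership"]
    for c in covariate_columns:
        if c not in df.columns:
            logger.info("covariate %s absent; skipped", c)
            continue
        v = df[c].to_numpy(dtype=float)
        if np.std(v) == 0:
            logger.warning("covariate %s constant; dropped", c)
            continue
        X.append(v)
        names.append(c)
    X = np.column_stack(X)
    # drop collinear columns (keep membership)
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(universe)), trial])) == len(keep) + 2:
            keep.append(j)
        else:
            logger.warning("covariate %s collinear; dropped", names[j])
    X = X[:, keep]
    if np.std(X[:, 0]) == 0:
        raise ValueError("membership column is constant (module equals universe?)")
    design = sm.add_constant(X)
    fit = sm.OLS(z, design).fit()
    beta = float(fit.params[1])
    t = float(fit.tvalues[1])
    p_one_sided = float(stats.t.sf(t, df=fit.df_resid))
    return beta, p_one_sided


def restrict_universe(scores: pd.DataFrame | pd.Series, expressed_genes) -> list[str]:
    """Universe = scored genes intersected with reliably expressed genes."""
    if not len(expressed_genes):
        raise ValueError("expressed gene set is empty")
    scored = set(scores.index if isinstance(scores, pd.Series) else scores["gene_id"])
    universe = sorted(scored & set(expressed_genes))
    logger.info("universe: %d scored ∩ %d expressed = %d", len(scored), len(set(expressed_genes)), len(universe))
    if not universe:
        raise ValueError("no overlap between scored and expressed genes")
    return universe
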