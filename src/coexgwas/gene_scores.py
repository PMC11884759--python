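"""LD-aware gene-based association scores from GWAS summary statistics.

The gene statistic is the SNP-wise mean model: for the SNPs annotated to a
gene, ``T = mean of per-SNP chi-square(1)`` where each chi-square is
``[Phi^-1(p/2)]^2`` (the squared z-score recovered from the two-sided
p-value).  Under the null with LD correlation matrix ``R`` among the gene's
SNPs, ``T`` is distributed as a weighted sum of independent chi-square(1)
variables with weights ``eigenvalues(R)/n_snps``.  The null tail probability
is computed essentially exactly with Ruben's mixture-of-chi-square series
(coefficients depend only on the eigenvalue spectrum, so they are cached and
the evaluation vectorizes over genes that share an LD pattern), falling back
to Imhof characteristic-function inversion for ill-conditioned spectra.
A permutation oracle verifying the null lives in the test-suite, not here.

Annotation windows are strand-aware: with an upstream window ``u`` and a
downstream window ``d``, a '+' strand gene occupies ``[start-u, end+d]`` and a
'-' strand gene ``[start-d, end+u]``.  The conventional window is 35 kb
upstream / 10 kb downstream; a window-free run (u = d = 0) scores only SNPs
inside gene bodies and is the more conservative variant.

Significant genes within +/-500 kb of each other are merged into loci by
single-linkage (transitive) chaining.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GeneModel, GwasSummary, LDMatrix

__all__ = [
    "annotate_snps",
    "gene_based_test",
    "fdr_correct",
    "define_loci",
    "read_gene_models_tsv",
    "read_gwas_tsv",
]

logger = logging.getLogger(__name__)

#: gene-based genome-wide significance threshold used for locus reporting
GENOME_WIDE_P = 1e-6


def annotate_snps(
    gwas: GwasSummary | pd.DataFrame,
    gene_models: list[GeneModel],
    window_up: int = 35_000,
    window_down: int = 10_000,
) -> dict[str, np.ndarray]:
    """Map each gene to the (row) indices of SNPs in its strand-aware window.

    A SNP may map to several genes.  SNPs on chromosomes absent from the gene
    models stay unmapped and are only counted in a log summary.  Genes with no
    SNPs are absent from the result (never scored as zero).
    """
    if window_up < 0 or window_down < 0:
        raise ValueError("window sizes must be >= 0")
    table = gwas.table if isinstance(gwas, GwasSummary) else gwas
    ann: dict[str, np.ndarray] = {}
    known_chroms = {g.chromosome for g in gene_models}
    n_unmapped_chrom = int((~table["CHR"].isin(known_chroms)).sum())
    for chrom, sub in table.groupby("CHR", sort=False):
        if chrom not in known_chroms:
            continue
        order = np.argsort(sub["BP"].to_numpy(), kind="stable")
        rows = sub.index.to_numpy()[order]
        pos = sub["BP"].to_numpy()[order]
        for g in gene_models:
            if g.chromosome != chrom:
                continue
            strand = g.strand
            if strand not in ("+", "-"):
                logger.warning("gene %s has no strand; treating as '+'", g.gene_id)
                strand = "+"
            if strand == "+":
                lo, hi = g.start - window_up, g.end + window_down
            else:
                lo, hi = g.start - window_down, g.end + window_up
            i0 = np.searchsorted(pos, lo, side="left")
            i1 = np.searchsorted(pos, hi, side="right")
            if i1 > i0:
                ann[g.gene_id] = rows[i0:i1]
    if n_unmapped_chrom:
        logger.info("%d SNPs on chromosomes without gene models left unmapped", n_unmapped_chrom)
    return ann


def _drop_perfect_ld(R: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Indices keeping one SNP per perfect-LD (|r| = 1) group.

    A SNP in perfect LD with an already-kept SNP contributes an identical
    chi-square and no new information; dropping it keeps the gene p-value
    invariant to such duplication (the effective number of tests is
    unchanged).
    """
    n = R.shape[0]
    keep: list[int] = []
    for j in range(n):
        if all(abs(R[j, i]) < 1.0 - tol for i in keep):
            keep.append(j)
    return np.asarray(keep, dtype=np.int64)


def _null_weights(ld_sub: np.ndarray) -> np.ndarray:
    """Null weights lam_i/n for T = sum(lam_i chi2_1)/n, eigenvalues floored at 0."""
    lam = np.linalg.eigvalsh(ld_sub)
    if lam[0] < -1e-8:
        logger.warning("LD submatrix not PSD (min eig %.3g); flooring at 0", lam[0])
    lam = np.clip(lam, 0.0, None)
    return lam[::-1] / len(lam)


class WeightedChi2Tail:
    """Upper tail of Q = sum(w_i chi2_1) for fixed positive weights.

    Exact special cases (one distinct weight -> scaled chi-square), otherwise
    Ruben's series with beta = w_min: Q's distribution function is a mixture
    ``sum_j a_j Chi2(k + 2j)(x / beta)`` with non-negative coefficients from
    the recursion a_r = (1/r) sum_{j<r} g_{r-j} a_j, g_r = 0.5 sum_i
    (1 - beta/w_i)^r.  Coefficients depend only on the spectrum, so one
    instance evaluates the tail vectorized over any number of statistics.
    Ill-conditioned spectra (series would need too many terms) fall back to
    Imhof numerical inversion per point.
    """

    MAX_TERMS = 5_000
    TRUNC = 1e-13

    def __init__(self, weights: np.ndarray):
        w = np.asarray(weights, dtype=float)
        w = w[w > 1e-9 * w.max()]
        self.weights = np.sort(w)[::-1]
        self._coef = None
        self._mode = None
        if np.allclose(self.weights, self.weights[0], rtol=1e-12):
            self._mode = "chi2"
        else:
            beta = self.weights.min()
            ratio = 1.0 - beta / self.weights.max()
            n_terms = int(np.ceil(np.log(self.TRUNC) / np.log(ratio))) + len(w)
            if n_terms <= self.MAX_TERMS:
                self._mode = "ruben"
                self._beta = beta
                self._coef = self._ruben_coefficients(n_terms)
            else:
                self._mode = "imhof"
                logger.warning(
                    "ill-conditioned LD spectrum (ratio %.6f); using Imhof inversion", ratio
                )

    def _ruben_coefficients(self, n_terms: int) -> np.ndarray:
        w, beta = self.weights, self._beta
        b = 1.0 - beta / w
        a = np.empty(n_terms)
        a[0] = np.exp(0.5 * np.sum(np.log(beta / w)))
        # g_r computed on demand via log-free powers; b in [0,1) so stable
        g = np.array([0.5 * np.sum(b**r) for r in range(1, n_terms)])
        for r in range(1, n_terms):
            a[r] = np.dot(g[:r][::-1], a[:r]) / r
            if 1.0 - a[: r + 1].sum() < self.TRUNC:
                return a[: r + 1]
        return a

    def sf(self, x) -> np.ndarray:
        """P(Q >= x), vectorized; monotone decreasing in x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self._mode == "chi2":
            k = len(self.weights)
            out = stats.chi2.sf(x / self.weights[0], df=k)
        elif self._mode == "ruben":
            a = self._coef
            dofs = len(self.weights) + 2 * np.arange(len(a))
            y = x / self._beta
            out = np.empty(len(x))
            chunk = max(1, int(2e7 / len(a)))
            for i in range(0, len(x), chunk):
                out[i : i + chunk] = stats.chi2.sf(y[i : i + chunk, None], df=dofs) @ a
            # remainder mass of the truncated mixture bounds the deficit
            out = np.clip(out, 0.0, 1.0)
        else:
            out = np.array([_imhof_sf(v, self.weights) for v in x])
        return np.clip(out, np.finfo(float).tiny, 1.0)


def _imhof_sf(x: float, w: np.ndarray) -> float:
    """P(sum w_i chi2_1 > x) by Imhof's characteristic-function inversion."""
    from scipy import integrate

    if x <= 0:
        return 1.0

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(w * u)) - 0.5 * x * u
        log_rho = 0.25 * np.sum(np.log1p((w * u) ** 2))
        return np.sin(theta) / (u * np.exp(log_rho))

    val, _ = integrate.quad(integrand, 0, np.inf, epsabs=1e-12, epsrel=1e-9, limit=500)
    return min(max(0.5 + val / np.pi, 0.0), 1.0)


def gene_based_test(
    gwas: GwasSummary | pd.DataFrame,
    annotation: dict[str, np.ndarray],
    ld: LDMatrix,
    gene_models: list[GeneModel] | None = None,
    window_mode: str = "none",
) -> pd.DataFrame:
    """Score every annotated gene; returns a GeneScoreTable data frame.

    Columns: gene_id, n_snps, T (mean SNP chi-square), p_value, window_mode,
    plus gene coordinates when ``gene_models`` is given (needed for locus
    merging).  The p-value is monotone decreasing in T for fixed LD.
    """
    table = gwas.table if isinstance(gwas, GwasSummary) else gwas
    p_snp = table["P"].to_numpy()
    if np.any(p_snp <= 0) or np.any(p_snp > 1):
        raise ValueError("SNP p-values must lie in (0, 1]")
    chi2 = stats.norm.isf(p_snp / 2.0) ** 2
    row_to_pos = {r: i for i, r in enumerate(table.index)}
    coords = {g.gene_id: g for g in gene_models} if gene_models else {}

    gene_ids, n_snps_l, T_l, spectra = [], [], [], []
    for gid, rows in annotation.items():
        iloc = np.fromiter((row_to_pos[r] for r in rows), dtype=np.int64, count=len(rows))
        R = ld.submatrix(iloc)
        keep = _drop_perfect_ld(R)
        iloc, R = iloc[keep], R[np.ix_(keep, keep)]
        T = float(chi2[iloc].mean())
        w = _null_weights(R)
        gene_ids.append(gid)
        n_snps_l.append(len(iloc))
        T_l.append(T)
        spectra.append(tuple(np.round(w, 12)))

    # genes sharing an LD spectrum share a null; evaluate each null vectorized
    T_arr = np.asarray(T_l)
    p_gene = np.empty(len(T_arr))
    groups: dict[tuple, list[int]] = {}
    for i, key in enumerate(spectra):
        groups.setdefault(key, []).append(i)
    for key, idx in groups.items():
        tail = WeightedChi2Tail(np.asarray(key))
        p_gene[idx] = tail.sf(T_arr[idx])
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "n_snps": n_snps_l,
            "T": T_l,
            "p_value": p_gene,
            "window_mode": window_mode,
        }
    )
    if coords:
        out["chromosome"] = [coords[g].chromosome if g in coords else None for g in out["gene_id"]]
        out["start"] = [coords[g].start if g in coords else -1 for g in out["gene_id"]]
        out["end"] = [coords[g].end if g in coords else -1 for g in out["gene_id"]]
    return out


def fdr_correct(scores: pd.DataFrame, method: str = "fdr_bh") -> pd.DataFrame:
    """Attach Benjamini-Hochberg step-up q-values (column ``q_value``)."""
    if len(scores) == 0:
        raise ValueError("no genes scored")
    out = scores.copy()
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method=method)[1]
    return out


def define_loci(
    scores: pd.DataFrame,
    p_threshold: float = GENOME_WIDE_P,
    span: int = 500_000,
    p_column: str = "p_value",
) -> pd.DataFrame:
    """Merge significant genes within +/-span bp into loci (single linkage).

    Genes are significant when ``scores[p_column] <= p_threshold``.  Two
    significant genes on the same chromosome share a locus when the gap
    between their gene bodies is at most ``span``; merging is transitive.
    Non-significant genes get locus_id NA.  Requires coordinate columns.
    """
    for col in ("chromosome", "start", "end"):
        if col not in scores.columns:
            raise ValueError("define_loci needs gene coordinates in the score table")
    out = scores.copy()
    out["locus_id"] = pd.NA
    sig = out[out[p_column] <= p_threshold]
    n_loci = 0
    for chrom, sub in sig.groupby("chromosome", sort=True):
        sub = sub.sort_values("start")
        current_end = None
        for idx, row in sub.iterrows():
            if current_end is None or row["start"] - current_end > span:
                n_loci += 1
                current_end = row["end"]
            else:
                current_end = max(current_end, row["end"])
            out.at[idx, "locus_id"] = f"{chrom}_L{n_loci}"
    logger.info("%d significant genes merged into %d loci", len(sig), n_loci)
    return out


# ---------------------------------------------------------------------------
# TSV readers matching the writers in .simulate


def read_gene_models_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(r.gene_id, r.chromosome, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]


def read_gwas_tsv(path) -> GwasSummary:
    return GwasSummary(table=pd.read_csv(path, sep="\t"))
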