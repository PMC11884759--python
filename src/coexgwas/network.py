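"""Signed weighted co-expression networks: modules, eigengenes, kME, traits.

The construction mirrors the WGCNA/CoExpNets recipe: a signed adjacency
``a_ij = ((1 + cor_ij)/2)^power``, the topological overlap matrix (TOM),
average-linkage hierarchical clustering on the dissimilarity ``1 - TOM`` with
a fixed-height cut (modules smaller than ``min_module_size`` become label 0,
the grey/unassigned set), followed by a k-means-style refinement that
reassigns each gene to the module whose eigengene it correlates with best
(kME), recomputing eigengenes until a fixed point.

The module eigengene is the first right-singular vector of the
gene-standardized module submatrix (one value per sample, unit norm), with
its sign oriented so the mean own-module kME is non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModuleSet",
    "pick_soft_power",
    "signed_adjacency",
    "build_tom",
    "tom_from_adjacency",
    "detect_modules",
    "module_eigengenes",
    "compute_kme",
    "kmeans_refine",
    "correlate_with_trait",
    "celltype_enrichment",
    "overlap_fisher",
]

logger = logging.getLogger(__name__)

GREY = 0  # label for unassigned genes


@dataclass
class ModuleSet:
    """Gene -> module assignment with eigengenes, kME and provenance.

    ``labels`` maps gene_id to an integer module label (0 = unassigned).
    ``eigengenes`` is samples x modules; ``kme`` is genes x modules
    (correlation of each gene with each module eigengene).
    """

    labels: pd.Series
    eigengenes: pd.DataFrame | None = None
    kme: pd.DataFrame | None = None
    power: int | None = None
    variance_explained: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def modules(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != GREY)

    def genes_in(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]

    def hub_genes(self, module: int, k: int = 100) -> list[str]:
        """Top-k genes of a module by own-module kME ('most central genes')."""
        if self.kme is None:
            raise ValueError("kME not computed; run module_eigengenes/kmeans_refine first")
        own = self.kme.loc[self.genes_in(module), module]
        return own.sort_values(ascending=False).head(k).index.tolist()


def _standardize(values: np.ndarray) -> np.ndarray:
    """Z-score each gene (row) across samples; constant rows become zero."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def _gene_cor(values: np.ndarray) -> np.ndarray:
    z = _standardize(values)
    c = (z @ z.T) / z.shape[1]
    return np.clip(c, -1.0, 1.0)


def signed_adjacency(values: np.ndarray, power: int) -> np.ndarray:
    """Signed adjacency ((1 + cor)/2)^power with unit diagonal."""
    a = ((1.0 + _gene_cor(values)) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit (WGCNA convention).

    Connectivity k_i is the row sum of the adjacency minus the diagonal; the
    frequency of binned k is regressed on log10(k); the fit R^2 is negated
    when the slope is positive (scale-free topology requires a decreasing
    power law).
    """
    k = adjacency.sum(axis=1) - 1.0
    if np.allclose(k.max(), k.min()):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        freq = mask.mean()
        xs.append(np.log10(k[mask].mean() + 1e-9))
        ys.append(np.log10(freq))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def choose_power(powers, fits, r2_target: float = 0.8) -> int:
    """Smallest power whose fit meets the target, else the argmax-fit power."""
    powers = list(powers)
    fits = list(fits)
    for p, f in zip(powers, fits):
        if f >= r2_target:
            return p
    return powers[int(np.argmax(fits))]


def pick_soft_power(
    expr_values: pd.DataFrame | np.ndarray,
    r2_target: float = 0.8,
    candidate_powers=range(1, 21),
) -> int:
    """Pick the soft-threshold power by the scale-free topology criterion."""
    values = np.asarray(expr_values, dtype=float)
    keep = values.std(axis=1) > 0
    if not keep.all():
        logger.info("removed %d constant genes before power fit", int((~keep).sum()))
        values = values[keep]
    if values.shape[1] < 20:
        logger.warning("fewer than 20 samples; soft-power fit may be unstable")
    base = (1.0 + _gene_cor(values)) / 2.0
    fits = []
    for p in candidate_powers:
        a = base**p
        np.fill_diagonal(a, 1.0)
        fits.append(scale_free_fit(a))
    return choose_power(candidate_powers, fits, r2_target)


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1) - 1.0  # connectivity excludes the self-edge
    shared = a @ a - a * 2.0  # remove the u=i and u=j terms of the matrix product
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def build_tom(
    expr_values: pd.DataFrame | np.ndarray, power: int, max_genes: int = 16_000, force: bool = False
) -> np.ndarray:
    """Signed-adjacency TOM for a genes x samples matrix."""
    if power < 1:
        raise ValueError("power must be >= 1")
    values = np.asarray(expr_values, dtype=float)
    if values.shape[0] > max_genes and not force:
        raise MemoryError(
            f"{values.shape[0]} genes exceeds the {max_genes}-gene guard; pass force=True"
        )
    return tom_from_adjacency(signed_adjacency(values, power))


def detect_modules(
    tom: np.ndarray,
    gene_ids,
    min_module_size: int = 30,
    cut_height_fraction: float = 0.99,
) -> ModuleSet:
    """Average-linkage clustering of 1-TOM with a fixed-height cut.

    The dendrogram is cut at ``cut_height_fraction`` of its total height;
    clusters below ``min_module_size`` are sent to label 0.  Labels are
    renumbered 1..K by decreasing module size (ties by first gene index, so
    the partition is invariant to input gene order up to label names).
    """
    gene_ids = pd.Index(gene_ids)
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    link = linkage(squareform(dissim, checks=False), method="average")
    cut = cut_height_fraction * link[:, 2].max()
    raw = fcluster(link, t=cut, criterion="distance")
    labels = np.zeros(len(gene_ids), dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    kept.sort(key=lambda c: (-sizes[c], int(np.argmax(raw == c))))
    for new, old in enumerate(kept, start=1):
        labels[raw == old] = new
    ms = ModuleSet(
        labels=pd.Series(labels, index=gene_ids, name="module"),
        provenance={
            "tree_cut": "static",
            "cut_height_fraction": cut_height_fraction,
            "min_module_size": min_module_size,
            "linkage": "average",
        },
    )
    if not ms.modules:
        logger.warning("no module passed the size threshold; all genes unassigned")
    return ms


def module_eigengenes(
    expr_values: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, dict]:
    """First principal component per module, sign-oriented, with var explained.

    Returns (samples x modules eigengene frame with unit-norm columns,
    {module: variance explained}).  A single-gene module's eigengene is the
    standardized gene profile (normalised to unit length).
    """
    eig = {}
    varexp = {}
    for m in sorted(set(labels) - {GREY}):
        genes = labels.index[labels == m]
        sub = _standardize(expr_values.loc[genes].to_numpy(dtype=float))
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        v = vt[0]
        # orient: mean correlation of module genes with the eigengene >= 0
        if np.mean(sub @ v) < 0:
            v = -v
        eig[m] = v
        varexp[m] = float(s[0] ** 2 / np.sum(s**2)) if s.sum() > 0 else 0.0
    frame = pd.DataFrame(eig, index=expr_values.columns)
    return frame, varexp


def compute_kme(expr_values: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME: Pearson correlation of every gene with every module eigengene."""
    z_genes = _standardize(expr_values.to_numpy(dtype=float))
    e = eigengenes.to_numpy(dtype=float)
    ez = (e - e.mean(axis=0)) / e.std(axis=0)
    kme = (z_genes @ ez) / expr_values.shape[1]
    return pd.DataFrame(
        np.clip(kme, -1, 1), index=expr_values.index, columns=eigengenes.columns
    )


def _mean_own_kme(labels: pd.Series, kme: pd.DataFrame) -> float:
    assigned = labels[labels != GREY]
    if assigned.empty:
        return 0.0
    return float(
        np.mean([kme.at[g, m] for g, m in assigned.items()])
    )


def kmeans_refine(
    expr_values: pd.DataFrame,
    moduleset: ModuleSet,
    max_iter: int = 20,
    kme_floor: float = 0.3,
) -> ModuleSet:
    """k-means-style refinement of module labels in eigengene (kME) space.

    Each iteration reassigns every gene to the module whose eigengene it has
    the highest kME with (label 0 if below ``kme_floor``), then recomputes
    eigengenes.  Iteration is in fixed gene order; stops at a fixed point, at
    ``max_iter`` (with a warning), or — guarding the monotone objective — when
    a sweep would decrease the mean own-module kME, in which case the previous
    labels are kept.
    """
    labels = moduleset.labels.copy()
    if not (set(labels) - {GREY}):
        raise ValueError("refinement needs at least one non-empty module")
    eig, varexp = module_eigengenes(expr_values, labels)
    kme = compute_kme(expr_values, eig)
    objective = _mean_own_kme(labels, kme)
    for it in range(max_iter):
        best = kme.to_numpy().argmax(axis=1)
        best_val = kme.to_numpy().max(axis=1)
        new = np.where(best_val >= kme_floor, kme.columns.to_numpy()[best], GREY)
        new_labels = pd.Series(new, index=labels.index, name="module")
        moves = int((new_labels != labels).sum())
        logger.info("refinement iteration %d: %d moves", it + 1, moves)
        if moves == 0:
            break
        if not (set(new_labels) - {GREY}):
            labels = new_labels
            eig = pd.DataFrame(index=expr_values.columns)
            kme = pd.DataFrame(index=expr_values.index)
            varexp = {}
            break
        new_eig, new_varexp = module_eigengenes(expr_values, new_labels)
        new_kme = compute_kme(expr_values, new_eig)
        new_objective = _mean_own_kme(new_labels, new_kme)
        if new_objective < objective - 1e-12:
            logger.info("refinement stopped: objective would decrease")
            break
        labels, eig, kme, varexp, objective = new_labels, new_eig, new_kme, new_varexp, new_objective
    else:
        logger.warning("refinement did not converge within %d iterations", max_iter)
    return ModuleSet(
        labels=labels,
        eigengenes=eig,
        kme=kme,
        power=moduleset.power,
        variance_explained=varexp,
        provenance={**moduleset.provenance, "kmeans_refined": True, "kme_floor": kme_floor},
    )


def correlate_with_trait(
    eigengenes: pd.DataFrame, trait: pd.Series | np.ndarray, r_filter: float = 0.4
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a sample trait (age).

    Returns module, r, R2, p_value, direction and a ``passes_filter`` flag at
    ``|r| > r_filter``.  Constant eigengenes are reported as absent.
    """
    t = np.asarray(trait, dtype=float)
    rows = []
    for m in eigengenes.columns:
        e = eigengenes[m].to_numpy(dtype=float)
        if e.std() == 0 or t.std() == 0:
            logger.warning("module %s: constant eigengene or trait; correlation undefined", m)
            continue
        r, p = stats.pearsonr(e, t)
        rows.append(
            {
                "module": m,
                "r": r,
                "R2": r**2,
                "p_value": p,
                "direction": "+" if r >= 0 else "-",
                "passes_filter": abs(r) > r_filter,
            }
        )
    return pd.DataFrame(rows)


def celltype_enrichment(
    labels: pd.Series, marker_sets: dict[str, set], universe: set
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of marker sets in each module.

    For each (module, cell type): upper-tail p of the 2x2 overlap table over
    ``universe``, BH-corrected across all pairs.
    """
    universe = set(universe)
    rows = []
    for ct, markers in marker_sets.items():
        markers = set(markers) & universe
        if not markers:
            logger.info("marker set %s empty within universe; skipped", ct)
            continue
        for m in sorted(set(labels) - {GREY}):
            module_genes = set(labels.index[labels == m]) & universe
            k = len(module_genes & markers)
            p = stats.hypergeom.sf(k - 1, len(universe), len(markers), len(module_genes))
            rows.append(
                {"module": m, "cell_type": ct, "overlap": k,
                 "module_size": len(module_genes), "n_markers": len(markers),
                 "p_value": min(1.0, p)}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def overlap_fisher(set_a: set, set_b: set, universe: set) -> tuple[float, float]:
    """Fisher's exact test (two-sided) for the overlap of two gene sets.

    Returns (odds ratio, p).  Used e.g. to ask whether a human module and a
    mouse module (after orthologue mapping) share more genes than chance.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return float(odds), float(p)
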