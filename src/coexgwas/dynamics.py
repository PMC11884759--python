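"""Module behaviour across age/treatment groups and across datasets.

* Proxy expression: the per-sample mean of a module's top-k (default 100)
  most central genes (highest own-module kME), compared between two age
  groups by Student's t-test, or across treatment time points by one-way
  ANOVA followed by Dunnett's many-to-one test — Dunnett is run only when
  the ANOVA is significant at P < 0.05 (the gating is part of the procedure).
* Preservation: permutation z-statistics asking whether a reference module's
  internal connection strength (z.density: mean within-module adjacency) and
  connectivity pattern (z.connectivity: rank correlation of intramodular
  connectivity between reference and query) survive in a query dataset;
  z.summary is the mean of the two.
* Cross-species transfer: offline orthologue-table mapping and projection of
  reference module eigengenes into a query dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import ModuleSet, _standardize, signed_adjacency

__all__ = [
    "ProxySeries",
    "module_proxy",
    "compare_two_groups",
    "compare_timecourse",
    "preservation",
    "map_orthologues",
    "project_eigengenes",
]

logger = logging.getLogger(__name__)


@dataclass
class ProxySeries:
    """Per-sample mean expression of a module's top-k hub genes."""

    module: int | str
    values: pd.Series  # indexed by sample
    k_used: int


def module_proxy(
    expr_values: pd.DataFrame, moduleset: ModuleSet, module, k: int = 100
) -> ProxySeries:
    """Mean expression of the module's k most central genes (by own-module kME).

    If the module has fewer than k genes, all of them are used; the mean is
    taken over the intersection of the top-k list with the genes present in
    ``expr_values`` (an empty intersection is an error).
    """
    if module not in moduleset.modules:
        raise KeyError(f"module {module!r} not in module set")
    top = moduleset.hub_genes(module, k=k)
    present = [g for g in top if g in expr_values.index]
    if not present:
        raise ValueError(f"no top-{k} gene of module {module!r} present in expression data")
    if len(present) < len(top):
        logger.info("module %s: %d of top-%d genes present", module, len(present), len(top))
    vals = expr_values.loc[present].mean(axis=0)
    return ProxySeries(module=module, values=vals, k_used=len(present))


def compare_two_groups(
    proxy: ProxySeries | pd.Series, groups: pd.Series, equal_var: bool = True
) -> tuple[float, float]:
    """Student's two-tailed t-test of proxy expression between two groups.

    Classic equal-variance t by default; set ``equal_var=False`` for Welch.
    Returns (t, p) with t signed as group1 minus group2 (groups in sorted
    label order).
    """
    values = proxy.values if isinstance(proxy, ProxySeries) else proxy
    groups = groups.loc[values.index]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a = values[groups == levels[0]].to_numpy(dtype=float)
    b = values[groups == levels[1]].to_numpy(dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs n >= 2")
    if (len(a) == 2 and a.std() == 0) or (len(b) == 2 and b.std() == 0):
        logger.warning("a group of size 2 has zero variance; t-test still computed")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def compare_timecourse(
    proxy: ProxySeries | pd.Series, groups: pd.Series, control_label
) -> dict:
    """One-way ANOVA across groups; Dunnett many-to-one only if ANOVA P < 0.05.

    Returns {'anova_F', 'anova_p', 'dunnett': DataFrame or None}; the Dunnett
    frame has one row per non-control group with its two-sided adjusted p.
    """
    values = proxy.values if isinstance(proxy, ProxySeries) else proxy
    groups = groups.loc[values.index]
    levels = list(pd.unique(groups))
    if control_label not in levels:
        raise ValueError(f"control label {control_label!r} absent from groups")
    arrays = {lv: values[groups == lv].to_numpy(dtype=float) for lv in levels}
    if any(len(v) < 2 for v in arrays.values()):
        raise ValueError("each group needs n >= 2")
    treat_levels = [lv for lv in levels if lv != control_label]
    if not treat_levels:
        raise ValueError("need at least one non-control group")
    F, p = stats.f_oneway(*arrays.values())
    if np.isnan(F):  # all values identical across all groups
        F, p = 0.0, 1.0
    result = {"anova_F": float(F), "anova_p": float(p), "dunnett": None}
    if p < 0.05:
        dn = stats.dunnett(
            *[arrays[lv] for lv in treat_levels], control=arrays[control_label]
        )
        result["dunnett"] = pd.DataFrame(
            {
                "group": treat_levels,
                "statistic": np.atleast_1d(dn.statistic),
                "p_value": np.atleast_1d(dn.pvalue),
            }
        )
    return result


def _module_density(adj: np.ndarray) -> float:
    """Mean off-diagonal adjacency among module genes (connection strength)."""
    n = adj.shape[0]
    return float((adj.sum() - n) / (n * (n - 1)))


def _intramodular_connectivity(adj: np.ndarray) -> np.ndarray:
    return adj.sum(axis=1) - 1.0


def _preservation_stats(ref_vals: np.ndarray, query_vals: np.ndarray, power: int):
    a_ref = signed_adjacency(ref_vals, power)
    a_query = signed_adjacency(query_vals, power)
    density = _module_density(a_query)
    k_ref = _intramodular_connectivity(a_ref)
    k_query = _intramodular_connectivity(a_query)
    connectivity = stats.spearmanr(k_ref, k_query).statistic
    if np.isnan(connectivity):
        connectivity = 0.0
    return density, float(connectivity)


def preservation(
    reference_expr: pd.DataFrame,
    reference_labels: pd.Series,
    query_expr: pd.DataFrame,
    power: int = 6,
    n_perm: int = 200,
    seed: int = 0,
    min_shared: int = 30,
) -> pd.DataFrame:
    """Permutation module-preservation z-statistics in a query dataset.

    For each reference module with >= ``min_shared`` genes shared with the
    query: observed z.density (mean within-module signed adjacency in the
    query) and z.connectivity (Spearman correlation of intramodular
    connectivity between reference and query), each standardized against
    ``n_perm`` size-matched random gene sets drawn from the shared genes;
    z.summary = (z.density + z.connectivity)/2.  Adjacency in the query uses
    the reference soft power.  A zero permutation SD yields a +/-inf sentinel
    with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 (permutation null undefined)")
    rng = np.random.default_rng(seed)
    shared = reference_expr.index.intersection(query_expr.index)
    shared_ref = reference_expr.loc[shared]
    shared_query = query_expr.loc[shared]
    rows = []
    for m in sorted(set(reference_labels) - {0}):
        module_genes = reference_labels.index[reference_labels == m].intersection(shared)
        size = len(module_genes)
        if size < min_shared:
            logger.info("module %s: only %d shared genes (<%d); skipped", m, size, min_shared)
            continue
        obs_d, obs_c = _preservation_stats(
            shared_ref.loc[module_genes].to_numpy(dtype=float),
            shared_query.loc[module_genes].to_numpy(dtype=float),
            power,
        )
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        shared_arr = shared.to_numpy()
        for i in range(n_perm):
            draw = rng.choice(len(shared_arr), size=size, replace=False)
            genes = shared_arr[draw]
            null_d[i], null_c[i] = _preservation_stats(
                shared_ref.loc[genes].to_numpy(dtype=float),
                shared_query.loc[genes].to_numpy(dtype=float),
                power,
            )
        z_d = _perm_z(obs_d, null_d, f"module {m} density")
        z_c = _perm_z(obs_c, null_c, f"module {m} connectivity")
        rows.append(
            {
                "module": m,
                "n_shared": size,
                "density": obs_d,
                "connectivity": obs_c,
                "z_density": z_d,
                "z_connectivity": z_c,
                "z_summary": (z_d + z_c) / 2.0,
                "n_permutations": n_perm,
            }
        )
    return pd.DataFrame(rows)


def _perm_z(obs: float, null: np.ndarray, what: str) -> float:
    sd = null.std(ddof=1)
    if sd == 0:
        logger.warning("%s: permutation sd is 0; z reported as inf sentinel", what)
        return float(np.sign(obs - null.mean()) * np.inf) if obs != null.mean() else 0.0
    return float((obs - null.mean()) / sd)


def map_orthologues(
    gene_ids, ortho_table: pd.DataFrame, policy: str = "drop"
) -> tuple[dict, dict]:
    """Map gene ids through a two-column orthologue table (offline lookup).

    One-to-one source->target mappings are kept.  A source with several
    targets is resolved by ``policy``: 'drop' (default) excludes it, 'first'
    keeps the lexicographically first target.  Returns (mapping, report) with
    report = {'n_mapped', 'n_unmapped', 'n_ambiguous', 'unmapped': [...]}.
    """
    if ortho_table is None or len(ortho_table) == 0:
        raise ValueError("empty orthologue table")
    if policy not in ("drop", "first"):
        raise ValueError(f"unknown policy {policy!r}")
    src_col, dst_col = ortho_table.columns[:2]
    grouped = ortho_table.groupby(src_col)[dst_col].agg(lambda s: sorted(set(s)))
    mapping = {}
    n_ambiguous = 0
    unmapped = []
    for g in gene_ids:
        targets = grouped.get(g)
        if targets is None:
            unmapped.append(g)
        elif len(targets) == 1:
            mapping[g] = targets[0]
        elif policy == "first":
            mapping[g] = targets[0]
        else:
            n_ambiguous += 1
    report = {
        "n_mapped": len(mapping),
        "n_unmapped": len(unmapped),
        "n_ambiguous": n_ambiguous,
        "unmapped": unmapped,
    }
    return mapping, report


def project_eigengenes(
    query_expr: pd.DataFrame, reference_moduleset: ModuleSet, min_shared: int = 5
) -> pd.DataFrame:
    """Eigengenes of reference modules computed in a query dataset.

    For each reference module with >= ``min_shared`` genes present in the
    query: the first principal component of the query submatrix restricted to
    the module's genes, gene-standardized, unit norm, sign-oriented so the
    mean correlation of the module genes with it is non-negative.
    """
    eig = {}
    for m in reference_moduleset.modules:
        genes = reference_moduleset.genes_in(m).intersection(query_expr.index)
        if len(genes) < min_shared:
            logger.info("module %s: %d shared genes (<%d); projection skipped", m, len(genes), min_shared)
            continue
        sub = _standardize(query_expr.loc[genes].to_numpy(dtype=float))
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        v = vt[0]
        if np.mean(sub @ v) < 0:
            v = -v
        eig[m] = v
    return pd.DataFrame(eig, index=query_expr.columns)
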