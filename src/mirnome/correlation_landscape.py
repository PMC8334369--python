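"""miRNA x gene correlation landscape.

Builds the full Spearman correlation matrix between miRNA and gene
expression profiles over a shared sample set, groups miRNAs by
hierarchical clustering of their correlation vectors, derives
thresholded per-group correlated-gene lists, tests the sign balance of
correlations with predicted targets, and runs over-representation
analysis against a custom background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io_formats import CountMatrix, TargetMap
from .stats_core import TestResult, bh_adjust, binomial_two_sided, kendall_tau_test

__all__ = [
    "CorrelationMatrix",
    "GeneListCriteria",
    "pairwise_spearman",
    "cluster_mirnas",
    "correlated_gene_lists",
    "target_sign_balance",
    "hypergeometric_enrichment",
    "linkage_to_newick",
]


@dataclass
class CorrelationMatrix:
    """Spearman rho grid (miRNA rows x gene columns) over n_samples."""

    rho: pd.DataFrame
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("correlation needs at least 3 samples")
        arr = self.rho.to_numpy()
        finite = arr[np.isfinite(arr)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("correlation values outside [-1, 1]")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.rho.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rho.columns)

    @property
    def n_pairs(self) -> int:
        return self.rho.shape[0] * self.rho.shape[1]


@dataclass(frozen=True)
class GeneListCriteria:
    """Thresholds for confident per-group correlated-gene lists."""

    median_threshold: float = 0.3
    individual_threshold: float = 0.1
    direction: str = "negative"

    def __post_init__(self) -> None:
        if not 0 < self.individual_threshold < self.median_threshold <= 1:
            raise ValueError("need 0 < individual_threshold < median_threshold <= 1")
        if self.direction not in ("negative", "positive"):
            raise ValueError("direction must be 'negative' or 'positive'")


def _rank_standardize(values: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and scaled to unit norm."""
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norms > 0, ranks / norms, np.nan)


def pairwise_spearman(mirna_expr: CountMatrix, gene_expr: CountMatrix) -> CorrelationMatrix:
    """Spearman rho for every miRNA-gene pair over the shared samples.

    Computed as a cross-product of rank-standardized rows, so the full
    grid is one matrix multiplication. Constant rows yield NaN.
    """
    shared = [s for s in mirna_expr.values.columns if s in set(gene_expr.values.columns)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need at least 3")
    m = _rank_standardize(mirna_expr.values[shared].to_numpy(dtype=float))
    g = _rank_standardize(gene_expr.values[shared].to_numpy(dtype=float))
    rho = np.clip(m @ g.T, -1.0, 1.0)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=mirna_expr.values.index, columns=gene_expr.values.index),
        n_samples=len(shared),
    )


def cluster_mirnas(
    corr: CorrelationMatrix,
    k: int = 5,
    metric: str = "euclidean",
    method: str = "complete",
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of miRNA correlation profiles into k groups.

    Returns (assignment, linkage). Rows are pre-sorted lexicographically
    by miRNA id for deterministic tie-breaking; group labels G1..Gk follow
    dendrogram leaf order.
    """
    ids = sorted(corr.mirna_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of miRNAs ({len(ids)})")
    x = corr.rho.loc[ids].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("correlation matrix contains NaN rows; drop constant features first")
    linkage = hierarchy.linkage(x, method=method, metric=metric)
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    leaves = hierarchy.leaves_list(linkage)
    # relabel clusters G1..Gk in the order they first appear along the dendrogram
    order: dict[int, int] = {}
    for leaf in leaves:
        order.setdefault(raw[leaf], len(order) + 1)
    labels = pd.Series([f"G{order[c]}" for c in raw], index=ids, name="group")
    return labels.reindex(corr.mirna_ids), linkage


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"{render(tree, tree.dist)};"


def correlated_gene_lists(
    corr: CorrelationMatrix, group: list[str], criteria: GeneListCriteria
) -> list[str]:
    """Genes confidently correlated with every miRNA in a group.

    Negative list: median rho over the group's miRNAs below
    ``-median_threshold`` AND rho below ``-individual_threshold`` for
    every miRNA in the group; the positive list mirrors the signs.
    """
    if not group:
        raise ValueError("miRNA group is empty")
    missing = sorted(set(group) - set(corr.mirna_ids))
    if missing:
        raise ValueError(f"miRNAs absent from correlation matrix: {missing[:5]}")
    sub = corr.rho.loc[list(group)]
    med = sub.median(axis=0)
    if criteria.direction == "negative":
        keep = (med < -criteria.median_threshold) & (sub < -criteria.individual_threshold).all(axis=0)
    else:
        keep = (med > criteria.median_threshold) & (sub > criteria.individual_threshold).all(axis=0)
    return list(corr.rho.columns[keep])


def target_sign_balance(
    mirna_id: str,
    targets: TargetMap,
    mirna_expr: CountMatrix,
    gene_expr: CountMatrix,
    alpha: float = 0.05,
) -> tuple[int, int, TestResult]:
    """Sign balance of significant Kendall correlations with predicted targets.

    Counts targets whose tau with the miRNA is significant (p < alpha) and
    negative vs positive, then tests the split against a fair coin with an
    exact two-sided binomial test on the smaller count.
    """
    if mirna_id not in targets:
        raise ValueError(f"{mirna_id!r} has no predicted targets")
    if mirna_id not in corr_index(mirna_expr):
        raise ValueError(f"{mirna_id!r} not present in miRNA expression matrix")
    expressed = [g for g in sorted(targets[mirna_id]) if g in corr_index(gene_expr)]
    if not expressed:
        raise ValueError(f"no expressed targets for {mirna_id!r}")
    shared = [s for s in mirna_expr.values.columns if s in set(gene_expr.values.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    x = mirna_expr.values.loc[mirna_id, shared].to_numpy(dtype=float)
    n_neg = n_pos = 0
    for gene in expressed:
        y = gene_expr.values.loc[gene, shared].to_numpy(dtype=float)
        res = kendall_tau_test(x, y)
        if res.p_value < alpha:
            if res.statistic < 0:
                n_neg += 1
            elif res.statistic > 0:
                n_pos += 1
    total = n_neg + n_pos
    if total == 0:
        return 0, 0, TestResult(statistic=0.0, p_value=1.0, method="binomial-two-sided")
    return n_neg, n_pos, binomial_two_sided(min(n_neg, n_pos), total)


def corr_index(cm: CountMatrix) -> set[str]:
    return set(cm.values.index)


def hypergeometric_enrichment(
    query: list[str], sets: dict[str, set[str]], background: list[str]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation against a custom background.

    Every gene set is intersected with the background before testing; BH
    correction is applied across the tested sets. The query must be a
    subset of the background.
    """
    bg = set(background)
    q = set(query)
    offenders = sorted(q - bg)
    if offenders:
        raise ValueError(f"query genes absent from background: {offenders[:10]}")
    records = []
    for set_id in sorted(sets):
        members = sets[set_id] & bg
        if not members:
            continue
        hits = len(members & q)
        p = float(stats.hypergeom.sf(hits - 1, len(bg), len(members), len(q)))
        records.append((set_id, len(members), hits, len(q), len(bg), min(p, 1.0)))
    out = pd.DataFrame(
        records,
        columns=["set_id", "set_size", "query_hits", "query_size", "background_size", "p_value"],
    )
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out
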