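"""Community statistics: equalization, diversity, Bray-Curtis distances,
average-linkage clustering and ANOSIM.

The abundance matrix convention is a pandas DataFrame with samples as rows
and features (taxa or enzyme codes) as columns, holding non-negative
integer counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = [
    "AnosimResult",
    "equalize",
    "diversity",
    "bray_curtis",
    "hierarchical_cluster",
    "linkage_to_newick",
    "anosim",
]


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.empty:
        raise ValueError("abundance matrix is empty")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


def equalize(matrix: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample, without replacement, to the smallest total.

    Random subsampling (rarefaction to the minimum library size) removes the
    effect of unequal sequencing depth before diversity comparisons.
    """
    _check_matrix(matrix)
    totals = matrix.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive total")
    target = int(totals.min())
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    for sample in matrix.index:
        counts = matrix.loc[sample].to_numpy(dtype=np.int64)
        out.loc[sample] = rng.multivariate_hypergeometric(counts, target)
    return out


def diversity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Simpson concentration D = sum(P_i^2), inverse Simpson 1/D, richness S
    and evenness E = (1/D)/S, per sample."""
    _check_matrix(matrix)
    rows = []
    for sample in matrix.index:
        counts = matrix.loc[sample].to_numpy(dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total")
        p = counts / total
        d = float(np.sum(p**2))
        s = int(np.count_nonzero(counts))
        inv_d = 1.0 / d
        rows.append(
            {"sample_id": sample, "D": d, "invD": inv_d, "S": s, "E": inv_d / s}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    _check_matrix(matrix)
    if len(matrix) < 2:
        raise ValueError("need at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("Bray-Curtis is undefined between two all-zero samples")
    n = len(matrix)
    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        denom = np.sum(x[i] + x[j])
        dist[i, j] = dist[j, i] = np.sum(np.abs(x[i] - x[j])) / denom
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


def hierarchical_cluster(dist: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of a distance matrix (group-average/UPGMA
    linkage by default).  Returns a scipy linkage matrix."""
    condensed = squareform(dist.to_numpy(), checks=True)
    return hierarchy.linkage(condensed, method=method)


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Export a linkage matrix as a newick string with branch lengths.

    Branch lengths are half the merge height minus the child's own height,
    i.e. an ultrametric dendrogram.
    """
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        height = node.dist / 2.0
        length = parent_height - height
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, height)
        right = walk(node.right, height)
        return f"({left},{right}):{length:.6g}"

    height = tree.dist / 2.0
    left = walk(tree.left, height)
    right = walk(tree.right, height)
    return f"({left},{right});"


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    groups: tuple[str, ...]


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / (n * (n - 1) / 4.0)


def anosim(
    dist: pd.DataFrame,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "permutation",
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    Distances are rank-transformed (mean ranks for ties) and
    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4).
    The p-value uses the add-one permutation estimator
    p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations) under random label
    permutation, or exhaustive enumeration of distinct label arrangements
    with ``method="exact"``.
    """
    labels = np.asarray([groups[s] for s in dist.index] if isinstance(groups, dict) else groups)
    if len(labels) != len(dist):
        raise ValueError("one group label per sample is required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if counts.max() < 2:
        raise ValueError("at least one group needs >= 2 samples")
    n = len(labels)
    condensed = squareform(dist.to_numpy(), checks=True)
    ranks = rankdata(condensed)
    pair_i, pair_j = np.triu_indices(n, k=1)

    def r_for(lab: np.ndarray) -> float:
        within = lab[pair_i] == lab[pair_j]
        return _anosim_r(ranks, within, n)

    r_obs = r_for(labels)

    if method == "exact":
        perms = _distinct_label_arrangements(labels)
        hits = sum(1 for p in perms if r_for(p) >= r_obs - 1e-12)
        return AnosimResult(r=r_obs, p_value=hits / len(perms),
                            n_permutations=len(perms), groups=tuple(uniq))
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'exact'")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if r_for(rng.permutation(labels)) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(r=r_obs, p_value=p, n_permutations=n_permutations, groups=tuple(uniq))


def _distinct_label_arrangements(labels: np.ndarray) -> list[np.ndarray]:
    """All distinct assignments of the multiset of labels to positions."""
    n = len(labels)
    uniq = sorted(set(labels.tolist()))
    out: list[np.ndarray] = []

    def rec(positions: list[int], remaining: dict, current: np.ndarray):
        if not positions:
            out.append(current.copy())
            return
        pos = positions[0]
        for lab in uniq:
            if remaining[lab] > 0:
                remaining[lab] -= 1
                current[pos] = lab
                rec(positions[1:], remaining, current)
                remaining[lab] += 1

    counts = {lab: int(np.sum(labels == lab)) for lab in uniq}
    total = math.factorial(n)
    for c in counts.values():
        total //= math.factorial(c)
    if total > 200_000:
        raise ValueError(f"{total} arrangements is too many for exact enumeration")
    rec(list(range(n)), counts, labels.copy())
    return out
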