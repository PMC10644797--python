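"""Patristic distances and between-community mean nearest taxon distance.

betaMNTD(k, m) is the abundance-weighted mean, over the taxa of each
community, of the phylogenetic distance to the closest relative in the other
community:

    betaMNTD(k,m) = 1/2 [ sum_{i in k} f_ik min_{j in m} d(i,j)
                        + sum_{j in m} f_jm min_{i in k} d(i,j) ]

where f are within-sample relative abundances and d the patristic distance.
A taxon shared by both communities is its own nearest neighbour (distance 0).
The unweighted variant replaces f by 1/richness.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .containers import OTUTable


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distance matrix of a tree."""
    dm = tree.tip_tip_distances()
    if (dm.data < 0).any():
        raise ValueError("negative patristic distances (negative branch lengths?)")
    return dm


def _support_and_weights(
    table: OTUTable, weighted: bool
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-sample present-taxon index lists and the weight matrix W (S x T)."""
    X = table.values().T  # samples x taxa
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"samples with zero total abundance: {bad}")
    supports = [np.flatnonzero(row > 0) for row in X]
    if weighted:
        W = X / totals[:, None]
    else:
        W = np.zeros_like(X)
        for s, idx in enumerate(supports):
            W[s, idx] = 1.0 / idx.size
    return supports, W


def _beta_mntd_values(
    D: np.ndarray, supports: list[np.ndarray], W: np.ndarray
) -> np.ndarray:
    """betaMNTD matrix given a taxa-ordered patristic matrix ``D``.

    For each sample m, M[m, i] = min_{j in m} D[i, j]; then
    betaMNTD = (W M' + (W M')') / 2 with a zero diagonal.
    """
    n_samples, n_taxa = W.shape
    M = np.empty((n_samples, n_taxa))
    for s, idx in enumerate(supports):
        M[s] = D[:, idx].min(axis=1)
    A = W @ M.T  # A[k, m] = sum_i W[k,i] * M[m,i]
    B = 0.5 * (A + A.T)
    np.fill_diagonal(B, 0.0)
    return B


def beta_mntd(
    table: OTUTable, dist: DistanceMatrix, weighted: bool = True
) -> DistanceMatrix:
    """Between-community mean nearest taxon distance for all sample pairs.

    Parameters
    ----------
    table : OTUTable
        Harmonized count table.
    dist : skbio DistanceMatrix
        Patristic distances whose ids cover every taxon with a nonzero count.
    weighted : bool
        Abundance-weighted (default) or presence/absence (equal 1/richness
        weights) variant.
    """
    present = table.counts.sum(axis=1) > 0
    needed = set(table.counts.index[present])
    missing = needed - set(dist.ids)
    if missing:
        raise ValueError(
            f"taxa with nonzero counts absent from distance matrix: {sorted(missing)[:5]}"
        )
    if not needed.issuperset(table.taxon_ids) and not set(dist.ids).issuperset(
        table.taxon_ids
    ):
        # zero-count taxa without distances contribute nothing; drop them
        table = table.select_taxa(sorted(needed))
    D = dist.filter(table.taxon_ids).data
    supports, W = _support_and_weights(table, weighted)
    B = _beta_mntd_values(D, supports, W)
    return DistanceMatrix(B, ids=table.sample_ids)
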