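"""Alpha diversity (Shannon, Chao1), rarefaction and Bray-Curtis."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.stats import subsample_counts
from skbio.stats.distance import DistanceMatrix

from .containers import OTUTable


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over taxa with p_i > 0.

    Natural log by default; pass ``base`` (e.g. 2) for other conventions.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("all-zero abundance vector")
    h = float(_skbio_shannon(counts))  # natural log in scikit-bio >= 0.6
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)),
    with F1/F2 the singleton/doubleton counts. Requires integer counts."""
    counts = np.asarray(counts)
    if not np.all(counts == np.round(counts)):
        raise ValueError("Chao1 requires integer counts")
    counts = counts.astype(np.int64)
    if (counts < 0).any():
        raise ValueError("negative counts")
    return float(_skbio_chao1(counts, bias_corrected=True))


def rarefy(table: OTUTable, depth: int, seed=None) -> OTUTable:
    """Single-draw rarefaction: subsample every sample to ``depth`` reads
    without replacement. Samples below ``depth`` raise."""
    if not table.is_integer():
        raise ValueError("rarefaction requires integer counts")
    X = table.values().astype(np.int64)
    totals = X.sum(axis=0)
    if (totals < depth).any():
        shallow = [s for s, t in zip(table.sample_ids, totals) if t < depth]
        raise ValueError(f"samples shallower than depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = subsample_counts(
            X[:, j], depth, seed=rng.integers(0, 2**31 - 1)
        )
    df = pd.DataFrame(out, index=table.taxon_ids, columns=table.sample_ids)
    return OTUTable(df)


def alpha_diversity(
    table: OTUTable, base: float | None = None
) -> pd.DataFrame:
    """Per-sample richness, Shannon and Chao1 (Chao1 only for integer tables)."""
    X = table.values()
    integer = table.is_integer()
    rows = []
    for j, s in enumerate(table.sample_ids):
        col = X[:, j]
        rows.append(
            {
                "sample_id": s,
                "richness": int((col > 0).sum()),
                "shannon": shannon(col, base=base),
                "chao1": chao1(col) if integer else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: OTUTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs:
    BC(k,m) = sum_i |x_ik - x_im| / sum_i (x_ik + x_im)."""
    X = table.values().T  # samples x taxa
    if (X.sum(axis=1) <= 0).any():
        raise ValueError("sample with zero total abundance")
    mat = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(mat, ids=table.sample_ids)
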