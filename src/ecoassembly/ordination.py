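"""Ordination and distance-based testing: PCoA, two-factor PERMANOVA
(sequential adonis), and RDA with per-variable permutation tests.

PCoA applies Gower double-centering to the squared distance matrix,
G = -1/2 J D^2 J with J = I - 11'/n, and eigendecomposes G. Negative
eigenvalues (non-Euclidean distances) are reported as-is; axis scores and
explained proportions are computed over the positive eigenvalues only.

PERMANOVA partitions tr(G) sequentially (Type I) across one or two
categorical factors via the hat-matrix trace identity SS(X) = tr(H G); p
comes from permuting sample identities, p = (#{F_perm >= F_obs} + 1) /
(perms + 1).

RDA regresses the (optionally Hellinger-transformed, column-centered)
community matrix on standardized environmental covariates; the PCA of the
fitted values gives the constrained axes; per-variable significance uses
permutation of reduced-model residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from skbio.stats.distance import DistanceMatrix

from .containers import OTUTable

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """Axis scores, eigenvalues and explained-variance proportions.

    For RDA, ``constrained_proportion`` is the total variance fraction
    captured by all constrained axes and ``env_pvalues`` the per-variable
    permutation p-values (marginal tests).
    """

    samples: pd.DataFrame
    eigenvalues: pd.Series
    proportion_explained: pd.Series
    constrained_proportion: float | None = None
    env_pvalues: pd.Series | None = None
    dropped_env: list[str] = field(default_factory=list)


def _as_distance(dist) -> tuple[np.ndarray, list[str]]:
    if isinstance(dist, DistanceMatrix):
        return dist.data.astype(float), list(dist.ids)
    arr = np.asarray(dist, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return arr, [str(i) for i in range(arr.shape[0])]


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    row = A.mean(axis=0, keepdims=True)
    col = A.mean(axis=1, keepdims=True)
    return A - row - col + A.mean()


def pcoa(dist) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix."""
    D, ids = _as_distance(dist)
    G = _gower_center(D)
    eigvals, eigvecs = eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > 1e-12 * max(eigvals.max(), 1.0)
    pos_sum = eigvals[positive].sum()
    scores = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    axes = [f"PC{i + 1}" for i in range(positive.sum())]
    proportions = np.where(positive, np.clip(eigvals, 0, None) / pos_sum, 0.0)
    return OrdinationResult(
        samples=pd.DataFrame(scores, index=ids, columns=axes),
        eigenvalues=pd.Series(
            eigvals, index=[f"PC{i + 1}" for i in range(len(eigvals))]
        ),
        proportion_explained=pd.Series(
            proportions, index=[f"PC{i + 1}" for i in range(len(eigvals))]
        ),
    )


def _hat(X: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    return Q @ Q.T


def _dummies(factor: pd.Series) -> np.ndarray:
    return pd.get_dummies(factor.astype(str), drop_first=True).to_numpy(float)


def permanova(
    dist,
    factors,
    perms: int = 999,
    seed=None,
) -> pd.DataFrame:
    """One- or two-factor PERMANOVA (sequential Type I, no interaction).

    ``factors`` is a Series/array (one factor) or a DataFrame / list of two,
    in the same sample order as the distance matrix. Factor order determines
    the sequential partition and is logged. Returns a DataFrame indexed by
    factor with columns df, SS, pseudo_F, p_value (plus a Residual row).
    """
    D, ids = _as_distance(dist)
    n = D.shape[0]
    if isinstance(factors, pd.DataFrame):
        factor_list = [factors[c] for c in factors.columns]
    elif isinstance(factors, (list, tuple)) and len(factors) in (1, 2) and not np.isscalar(factors[0]):
        factor_list = [pd.Series(f) for f in factors]
    else:
        factor_list = [pd.Series(factors)]
    if len(factor_list) > 2:
        raise ValueError("at most two factors are supported")
    names = []
    for i, f in enumerate(factor_list):
        name = f.name if f.name is not None else f"factor{i + 1}"
        names.append(str(name))
        if len(f) != n:
            raise ValueError("factor length does not match distance matrix")
        counts = f.astype(str).value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"factor {name!r} has levels with < 2 samples: {small}")
    logger.info("PERMANOVA sequential factor order: %s", " -> ".join(names))

    G = _gower_center(D)
    total_ss = np.trace(G)

    # nested hat matrices: intercept, +factor1, (+factor2)
    designs = [np.ones((n, 1))]
    for f in factor_list:
        designs.append(np.hstack([designs[-1], _dummies(f.reset_index(drop=True))]))
    hats = [_hat(X) for X in designs]
    model_df = [
        np.linalg.matrix_rank(designs[i + 1]) - np.linalg.matrix_rank(designs[i])
        for i in range(len(factor_list))
    ]
    if any(df == 0 for df in model_df):
        raise ValueError(
            "confounded factors: a factor adds no degrees of freedom given "
            "those before it"
        )
    resid_df = n - np.linalg.matrix_rank(designs[-1])
    if resid_df <= 0:
        raise ValueError("confounded factors: zero residual degrees of freedom")

    def _stats(Gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tr = np.array([np.einsum("ij,ji->", H, Gm) for H in hats])
        ss = np.diff(tr)
        ss_resid = np.trace(Gm) - tr[-1]
        F = (ss / model_df) / (ss_resid / resid_df)
        return ss, F

    ss_obs, f_obs = _stats(G)
    ss_resid_obs = total_ss - np.einsum("ij,ji->", hats[-1], G)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(factor_list))
    for _ in range(perms):
        idx = rng.permutation(n)
        _, f_perm = _stats(G[np.ix_(idx, idx)])
        exceed += f_perm >= f_obs
    pvals = (exceed + 1) / (perms + 1)

    rows = [
        {
            "df": int(model_df[i]),
            "SS": float(ss_obs[i]),
            "pseudo_F": float(f_obs[i]),
            "p_value": float(pvals[i]),
        }
        for i in range(len(factor_list))
    ]
    rows.append(
        {
            "df": int(resid_df),
            "SS": float(ss_resid_obs),
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    return pd.DataFrame(rows, index=names + ["Residual"])


def _hellinger(Y: np.ndarray) -> np.ndarray:
    totals = Y.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("sample with zero total abundance")
    return np.sqrt(Y / totals)


def rda(
    table: OTUTable,
    env: pd.DataFrame,
    transform: str = "hellinger",
    perms: int = 999,
    seed=None,
) -> OrdinationResult:
    """Redundancy analysis of community composition on environmental
    covariates, with marginal per-variable permutation-of-residuals tests."""
    if transform not in ("hellinger", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    env = env.loc[table.sample_ids].apply(pd.to_numeric)
    if env.isna().any().any():
        raise ValueError("environmental matrix contains missing values")
    Y = table.values().T  # samples x taxa
    if transform == "hellinger":
        Y = _hellinger(Y)
    Y = Y - Y.mean(axis=0)
    n = Y.shape[0]

    dropped: list[str] = []
    sd = env.std(ddof=1)
    for col in env.columns[sd == 0]:
        dropped.append(str(col))
        logger.warning("dropping zero-variance covariate %r", col)
    env = env.drop(columns=dropped)
    X = (env - env.mean()) / env.std(ddof=1)
    X = X.to_numpy(float)
    # drop collinear columns (rank-deficient design) with a warning; also cap
    # the design at n - 2 covariates so at least one residual df remains for
    # the permutation tests
    keep_cols = []
    for j in range(X.shape[1]):
        name = str(env.columns[j])
        if len(keep_cols) >= n - 2:
            dropped.append(name)
            logger.warning(
                "dropping covariate %r: design saturated (n - 2 covariates)", name
            )
            continue
        trial = X[:, keep_cols + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-8) == len(keep_cols) + 1:
            keep_cols.append(j)
        else:
            dropped.append(name)
            logger.warning("dropping collinear covariate %r", name)
    names = [str(env.columns[j]) for j in keep_cols]
    X = X[:, keep_cols]
    if X.shape[1] == 0:
        raise ValueError("no usable environmental covariates")

    def _q(Xm: np.ndarray) -> np.ndarray:
        Q, _ = np.linalg.qr(Xm - Xm.mean(axis=0))
        return Q

    Q_full = _q(X)
    Yhat = Q_full @ (Q_full.T @ Y)
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    rank = int((eig > 1e-12 * max(eig.max(), 1.0)).sum())
    eig = eig[:rank]
    total_var = Y.var(axis=0, ddof=1).sum()
    scores = U[:, :rank] * s[:rank]
    axes = [f"RDA{i + 1}" for i in range(rank)]

    # marginal permutation tests: reduced model without each variable
    rng = np.random.default_rng(seed)
    ss_full = float((Yhat**2).sum())
    ss_resid = float((Y**2).sum()) - ss_full
    df_resid = n - 1 - X.shape[1]
    pvals = {}
    for j, name in enumerate(names):
        Xr = np.delete(X, j, axis=1)
        Qr = _q(Xr) if Xr.shape[1] else np.zeros((n, 0))
        fit_r = Qr @ (Qr.T @ Y) if Xr.shape[1] else np.zeros_like(Y)
        resid_r = Y - fit_r
        ss_red = float((fit_r**2).sum())
        f_obs = ((ss_full - ss_red) / 1.0) / (ss_resid / df_resid)
        exceed = 0
        for _ in range(perms):
            Ystar = fit_r + resid_r[rng.permutation(n)]
            fit_full_star = Q_full @ (Q_full.T @ Ystar)
            ss_full_star = float((fit_full_star**2).sum())
            fit_red_star = Qr @ (Qr.T @ Ystar) if Xr.shape[1] else np.zeros_like(Y)
            ss_red_star = float((fit_red_star**2).sum())
            ss_resid_star = float((Ystar**2).sum()) - ss_full_star
            f_star = (ss_full_star - ss_red_star) / (ss_resid_star / df_resid)
            if f_star >= f_obs:
                exceed += 1
        pvals[name] = (exceed + 1) / (perms + 1)

    return OrdinationResult(
        samples=pd.DataFrame(scores, index=table.sample_ids, columns=axes),
        eigenvalues=pd.Series(eig, index=axes),
        proportion_explained=pd.Series(eig / total_var, index=axes),
        constrained_proportion=float(eig.sum() / total_var),
        env_pvalues=pd.Series(pvals),
        dropped_env=dropped,
    )
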