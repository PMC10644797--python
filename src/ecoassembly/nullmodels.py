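"""Null models for community assembly: betaNTI, Raup-Crick (Bray-Curtis),
five-process classification and per-group process fractions.

The beta nearest taxon index standardizes the observed betaMNTD of a sample
pair against a null distribution obtained by uniform random permutation of
tip labels on the phylogeny (abundances held fixed):

    betaNTI = (betaMNTD_obs - mean(betaMNTD_null)) / sd(betaMNTD_null)

|betaNTI| > 2 signals selection (deterministic assembly): > +2 heterogeneous
selection, < -2 homogeneous selection.

For the remaining pairs the abundance-based Raup-Crick metric (RC_bray) asks
whether taxonomic turnover (Bray-Curtis) deviates from a null that reassembles
each community preserving its richness and total abundance, drawing taxa with
probability proportional to metacommunity occupancy and filling individuals
proportionally to metacommunity relative abundance:

    RC = 2 * [ (#{BC_null < BC_obs} + 1/2 #{BC_null = BC_obs}) / reps ] - 1

RC > +0.95 indicates dispersal limitation, RC < -0.95 homogenizing dispersal
(mass effect), and intermediate values drift / undominated processes.
"""

from __future__ import annotations

import hashlib
import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .containers import OTUTable
from .phylo import (
    _beta_mntd_values,
    _support_and_weights,
    beta_mntd,
    patristic_matrix,
)

#: The five assembly processes, in the order fractions are reported.
PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

_RC_STREAM_TAG = 0x52435F42  # namespaces the per-pair Raup-Crick substreams


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _pair_substream(seed: int | None, a: str, b: str) -> np.random.Generator:
    """Per-pair RNG derived by stable hashing of the (sorted) sample-id pair,
    so results do not depend on pair evaluation order."""
    a, b = sorted((a, b))
    digest = hashlib.blake2b(f"{a}\x1f{b}".encode(), digest_size=8).digest()
    pair_key = int.from_bytes(digest, "big")
    entropy = [pair_key, _RC_STREAM_TAG]
    if seed is not None:
        entropy.append(int(seed))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _aligned_patristic(table: OTUTable, tree: TreeNode | None, dist) -> np.ndarray:
    if dist is None:
        if tree is None:
            raise ValueError("either tree or dist must be given")
        dist = patristic_matrix(tree)
    missing = set(table.taxon_ids) - set(dist.ids)
    if missing:
        raise ValueError(
            f"taxa absent from the phylogeny: {sorted(missing)[:5]} "
            "(run harmonize first)"
        )
    return dist.filter(table.taxon_ids).data


def beta_nti(
    table: OTUTable,
    tree: TreeNode | None = None,
    *,
    dist: DistanceMatrix | None = None,
    reps: int = 999,
    seed=None,
    weighted: bool = True,
    return_null: bool = False,
) -> pd.DataFrame:
    """betaNTI for every sample pair (square labeled DataFrame).

    With ``return_null=True`` also returns the null betaMNTD mean and sd
    matrices (as DataFrames), e.g. for convergence diagnostics.

    Each null replicate applies one uniform random permutation of tip labels
    (equivalently, of the rows/columns of the patristic matrix) and recomputes
    betaMNTD for all pairs; the null sd uses ddof=1. Deterministic given
    ``seed``. The diagonal is 0 by convention.

    A pair whose null distribution is degenerate (sd == 0) gets betaNTI = 0
    when the observed value equals the null mean (e.g. two samples with
    identical taxon support, where every permutation maps shared taxa
    together); otherwise a ``ValueError`` identifies the pair.
    """
    if reps < 2:
        raise ValueError("beta_nti requires reps >= 2 to estimate the null sd")
    D = _aligned_patristic(table, tree, dist)
    supports, W = _support_and_weights(table, weighted)
    obs = _beta_mntd_values(D, supports, W)

    rng = _as_generator(seed)
    n_taxa = D.shape[0]
    n_samples = W.shape[0]
    mean = np.zeros((n_samples, n_samples))
    m2 = np.zeros((n_samples, n_samples))
    for r in range(reps):  # Welford accumulation; avoids a reps x S x S array
        perm = rng.permutation(n_taxa)
        null = _beta_mntd_values(D[np.ix_(perm, perm)], supports, W)
        delta = null - mean
        mean += delta / (r + 1)
        m2 += delta * (null - mean)
    sd = np.sqrt(m2 / (reps - 1))

    degenerate = sd == 0
    mismatch = degenerate & ~np.isclose(obs, mean, rtol=1e-9, atol=1e-12)
    np.fill_diagonal(mismatch, False)
    if mismatch.any():
        i, j = np.argwhere(mismatch)[0]
        raise ValueError(
            "degenerate betaNTI null (sd = 0, obs != mean) for pair "
            f"({table.sample_ids[i]!r}, {table.sample_ids[j]!r}); "
            "does the pair contain at least 2 distinct taxa?"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        nti = (obs - mean) / sd
    nti[degenerate] = 0.0
    np.fill_diagonal(nti, 0.0)
    nti = 0.5 * (nti + nti.T)  # enforce exact symmetry against fp noise
    ids = table.sample_ids
    out = pd.DataFrame(nti, index=ids, columns=ids)
    if return_null:
        return (
            out,
            pd.DataFrame(mean, index=ids, columns=ids),
            pd.DataFrame(sd, index=ids, columns=ids),
        )
    return out


def _bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("pair with zero combined abundance")
    return float(np.abs(x - y).sum() / denom)


def _null_community(
    rng: np.random.Generator,
    richness: int,
    total: int,
    log_occ: np.ndarray,
    active: np.ndarray,
    p_abund: np.ndarray,
) -> np.ndarray:
    """One null assembly: draw ``richness`` taxa without replacement with
    probability proportional to occupancy (Gumbel top-k), seed each with one
    individual, then fill the remaining individuals multinomially with
    probability proportional to metacommunity relative abundance."""
    keys = log_occ + rng.gumbel(size=log_occ.size)
    chosen = active[np.argpartition(keys, keys.size - richness)[-richness:]]
    counts = np.zeros(p_abund.size, dtype=np.int64)
    counts[chosen] = 1
    remaining = total - richness
    if remaining > 0:
        pr = p_abund[chosen]
        s = pr.sum()
        pr = np.full(richness, 1.0 / richness) if s == 0 else pr / s
        counts[chosen] += rng.multinomial(remaining, pr)
    return counts


def rc_score(n_less: int, n_ties: int, reps: int) -> float:
    """Rank-transform of an observed dissimilarity within its null sample:
    RC = 2 * [(#{null < obs} + 1/2 #{null = obs}) / reps] - 1, in [-1, 1].
    Ties count one-half so RC = 0 is the exact-null expectation."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    return 2.0 * ((n_less + 0.5 * n_ties) / reps) - 1.0


def raup_crick_bray(
    table: OTUTable,
    *,
    reps: int = 999,
    seed: int | None = None,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Abundance-based Raup-Crick (Bray-Curtis) null deviation, in [-1, 1].

    The metacommunity is the full table: occupancy = fraction of samples a
    taxon occupies, relative abundance = its share of all individuals. Each
    null replicate reassembles both communities of a pair (richness and total
    abundance preserved) and compares their Bray-Curtis dissimilarity with the
    observed one; ties count one-half, so RC = 0 is the exact-null
    expectation. Per-pair RNG substreams are derived by stable hashing of the
    sample-id pair, so the result is independent of evaluation order.

    Returns a square DataFrame (all pairs) or, if ``pairs`` is given, a long
    DataFrame with columns sample_a, sample_b, bc_obs, rc.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not table.is_integer():
        raise ValueError("Raup-Crick requires integer counts")
    X = table.values().astype(np.int64)  # taxa x samples
    ids = table.sample_ids
    occupancy = (X > 0).sum(axis=1) / X.shape[1]
    active = np.flatnonzero(occupancy > 0)
    log_occ = np.log(occupancy[active])
    p_abund = X.sum(axis=1) / X.sum()
    richness = (X > 0).sum(axis=0)
    totals = X.sum(axis=0)
    if (richness == 0).any():
        bad = [s for s, r in zip(ids, richness) if r == 0]
        raise ValueError(f"samples with zero richness: {bad}")

    col = {s: i for i, s in enumerate(ids)}
    if pairs is None:
        pair_list = list(itertools.combinations(ids, 2))
    else:
        pair_list = [(a, b) for a, b in pairs]

    records = []
    for a, b in pair_list:
        ia, ib = col[a], col[b]
        obs = _bray_curtis_pair(X[:, ia], X[:, ib])
        rng = _pair_substream(seed, a, b)
        less = ties = 0
        for _ in range(reps):
            na = _null_community(rng, richness[ia], totals[ia], log_occ, active, p_abund)
            nb = _null_community(rng, richness[ib], totals[ib], log_occ, active, p_abund)
            bc = _bray_curtis_pair(na, nb)
            if np.isclose(bc, obs, rtol=1e-12, atol=1e-12):
                ties += 1
            elif bc < obs:
                less += 1
        records.append((a, b, obs, rc_score(less, ties, reps)))

    long = pd.DataFrame(records, columns=["sample_a", "sample_b", "bc_obs", "rc"])
    if pairs is not None:
        return long
    rc_mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b, _, rc in records:
        rc_mat.loc[a, b] = rc
        rc_mat.loc[b, a] = rc
    return rc_mat


def classify_pair(
    beta_nti: float, rc: float, t_nti: float = 2.0, t_rc: float = 0.95
) -> str:
    """Assign one of the five assembly processes to a sample pair.

    Strict inequalities at the thresholds: betaNTI > +t_nti heterogeneous
    selection, < -t_nti homogeneous selection; otherwise rc > t_rc dispersal
    limitation, rc < -t_rc homogenizing dispersal; everything else (including
    values exactly on a threshold) is drift / undominated.
    """
    if not (np.isfinite(beta_nti) and np.isfinite(rc)):
        raise ValueError(f"non-finite inputs: beta_nti={beta_nti}, rc={rc}")
    if beta_nti > t_nti:
        return "heterogeneous_selection"
    if beta_nti < -t_nti:
        return "homogeneous_selection"
    if rc > t_rc:
        return "dispersal_limitation"
    if rc < -t_rc:
        return "homogenizing_dispersal"
    return "drift"


def classify(
    beta_nti: np.ndarray, rc: np.ndarray, t_nti: float = 2.0, t_rc: float = 0.95
) -> np.ndarray:
    """Vectorized :func:`classify_pair` over aligned arrays."""
    beta_nti = np.asarray(beta_nti, dtype=float)
    rc = np.asarray(rc, dtype=float)
    if not (np.isfinite(beta_nti).all() and np.isfinite(rc).all()):
        raise ValueError("non-finite betaNTI or RC values")
    return np.select(
        [beta_nti > t_nti, beta_nti < -t_nti, rc > t_rc, rc < -t_rc],
        ["heterogeneous_selection", "homogeneous_selection",
         "dispersal_limitation", "homogenizing_dispersal"],
        default="drift",
    ).astype(object)


def process_fractions(
    results: pd.DataFrame,
    grouping: Mapping[str, object] | None = None,
    scope: str = "within_group",
) -> pd.DataFrame:
    """Per-group fractions of the five processes among pairwise comparisons.

    ``results`` is a long DataFrame with columns sample_a, sample_b,
    beta_nti, process (as produced by :func:`assembly_analysis`). With
    ``scope='within_group'`` only pairs whose two samples share a group are
    counted, per group; ``scope='all_pairs'`` pools everything into one row.
    Also reports ``deterministic_fraction`` = P(|betaNTI| > 2) and the median
    betaNTI per group. Groups with < 2 samples appear with ``n_pairs = 0``
    and NaN fractions.
    """
    results = results.copy()
    if scope == "all_pairs":
        results["group"] = "all_pairs"
        groups = ["all_pairs"]
    elif scope == "within_group":
        if grouping is None:
            if "group" not in results.columns:
                raise ValueError("within_group scope needs a grouping map")
            groups = sorted(results["group"].dropna().unique(), key=str)
        else:
            missing = (set(results["sample_a"]) | set(results["sample_b"])) - set(
                grouping
            )
            if missing:
                raise ValueError(f"samples without a group: {sorted(missing)[:5]}")
            ga = results["sample_a"].map(grouping)
            gb = results["sample_b"].map(grouping)
            results["group"] = ga.where(ga == gb)
            groups = sorted({str(g) for g in grouping.values()}, key=str)
            results["group"] = results["group"].astype(object)
        results = results.dropna(subset=["group"])
        results["group"] = results["group"].astype(str)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    rows = []
    for g in [str(g) for g in groups]:
        sub = results[results["group"] == g]
        n = len(sub)
        row = {"group": g, "n_pairs": n}
        if n == 0:
            for p in PROCESSES:
                row[p] = np.nan
            row["deterministic_fraction"] = np.nan
            row["median_beta_nti"] = np.nan
        else:
            vc = sub["process"].value_counts()
            for p in PROCESSES:
                row[p] = vc.get(p, 0) / n
            row["deterministic_fraction"] = float(
                (sub["beta_nti"].abs() > 2).mean()
            )
            row["median_beta_nti"] = float(sub["beta_nti"].median())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("group")
    return out


def assembly_analysis(
    table: OTUTable,
    tree: TreeNode,
    metadata: pd.DataFrame | None = None,
    *,
    grouping: Mapping[str, object] | None = None,
    group_by: str | Sequence[str] = "n_di_years",
    scope: str = "within_group",
    reps: int = 999,
    seed: int | None = None,
    weighted: bool = True,
    t_nti: float = 2.0,
    t_rc: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pairwise assembly-process analysis.

    Computes betaMNTD/betaNTI (tip-label permutation null), RC_bray
    (reassembly null) for the in-scope pairs, classifies every pair and
    aggregates per-group process fractions.

    Returns ``(pairs, fractions)``: a long DataFrame with one row per
    in-scope sample pair (sample_a, sample_b, group, beta_mntd_obs, beta_nti,
    bc_obs, rc, process) and the :func:`process_fractions` table.
    """
    if grouping is None:
        if metadata is None:
            raise ValueError("need metadata or an explicit grouping map")
        if isinstance(group_by, str):
            grouping = {s: str(v) for s, v in metadata[group_by].items()}
        else:
            joined = metadata[list(group_by)].astype(str).agg("|".join, axis=1)
            grouping = dict(joined)
    missing = set(table.sample_ids) - set(grouping)
    if missing:
        raise ValueError(f"samples without a group: {sorted(missing)[:5]}")

    dist = patristic_matrix(tree)
    obs_mntd = beta_mntd(table, dist, weighted=weighted)
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    nti = beta_nti(
        table, dist=dist, reps=reps, seed=np.random.default_rng(ss.spawn(1)[0]),
        weighted=weighted,
    )

    ids = table.sample_ids
    if scope == "within_group":
        pair_list = [
            (a, b)
            for a, b in itertools.combinations(ids, 2)
            if grouping[a] == grouping[b]
        ]
    elif scope == "all_pairs":
        pair_list = list(itertools.combinations(ids, 2))
    else:
        raise ValueError(f"unknown scope {scope!r}")

    rc_long = raup_crick_bray(table, reps=reps, seed=seed, pairs=pair_list)
    rc_long = rc_long.set_index(["sample_a", "sample_b"])

    records = []
    for a, b in pair_list:
        bc_obs, rc = rc_long.loc[(a, b), ["bc_obs", "rc"]]
        records.append(
            {
                "sample_a": a,
                "sample_b": b,
                "group": str(grouping[a]) if grouping[a] == grouping[b] else "",
                "beta_mntd_obs": obs_mntd[a, b],
                "beta_nti": nti.loc[a, b],
                "bc_obs": bc_obs,
                "rc": rc,
            }
        )
    pairs = pd.DataFrame(records)
    pairs["process"] = classify(
        pairs["beta_nti"].to_numpy(), pairs["rc"].to_numpy(), t_nti=t_nti, t_rc=t_rc
    )
    fractions = process_fractions(pairs, grouping=grouping, scope=scope)
    return pairs, fractions
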