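"""Synthetic community generator for the drip-irrigation chronosequence design.

Communities are assembled from a shared metacommunity (log-normal abundances
``m_k``) of taxa on a Yule phylogeny that carry a Brownian-motion
environmental-optimum trait. Counts are one multinomial draw of ``depth``
individuals from per-sample weights built per regime:

- ``homogeneous_selection``: every sample draws from one shared *clade pool*
  (phylogenetically conserved habitat association: the environment admits a
  single clade of ~subpool_fraction * n_taxa tolerant taxa), with weights
  m_k * exp(-(trait_k - E)^2 / (2 sigma_filter^2)) inside the pool and an
  independent per-sample establishment lottery thinning the pool. This
  yields low phylogenetic turnover relative to the tip-shuffle null
  (betaNTI << -2).
- ``heterogeneous_selection``: sample environments are drawn with sd
  ``env_spread`` and each sample is assigned the *disjoint* candidate clade
  whose mean trait is nearest its environment -> samples occupy distant
  clades, betaNTI >> +2.
- ``drift``: Dirichlet-perturbed metacommunity proportions (no trait term);
  the concentration is high enough that turnover stays within both nulls.
- ``dispersal_limitation``: each sample draws from its own random taxon
  subpool chosen independently of the tree, mixed with a small common
  background (weak mass effect) -> high taxonomic turnover with neutral
  phylogenetic turnover (RC -> +1, |betaNTI| <= 2).
- ``homogenizing_dispersal``: all samples are near-identical multinomial
  draws from one common pool with a long rare tail, mixed toward the pooled
  mean with weight ``migration`` -> observed turnover falls below the
  reassembly null (RC -> -1).

Why clade pools rather than a soft Gaussian band on the 1-D trait: a single
Brownian trait has weak tip-level phylogenetic signal (similar trait values
arise in distant clades), so band-filtered communities are not
phylogenetically clustered and betaNTI barely responds; habitat association
at clade level is the minimal mechanism that reliably produces the selection
signatures the null models are designed to detect (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import ENV_VARIABLES, OTUTable, SyntheticDataset, validate_metadata

REGIMES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)

#: sd of the log-normal metacommunity abundance distribution.
METACOMMUNITY_SIGMA = 1.0
#: Dirichlet concentration of drift-style compositional perturbation; chosen
#: so that drift-regime turnover stays within both null envelopes at the
#: default sequencing depth (lower = stronger drift, eventually read as
#: dispersal limitation by the Raup-Crick null).
DRIFT_CONCENTRATION = 4000.0
#: log-sd of the common pool used by homogenizing dispersal; the long rare
#: tail creates many borderline-occupancy taxa, which is what separates the
#: reassembly null from near-identical observed communities.
HOD_POOL_SIGMA = 1.8
#: weight of the shared metacommunity background mixed into each
#: dispersal-limited sample (weak mass effect keeping occupancy positive).
DL_BACKGROUND = 0.1
#: per-taxon establishment probability under homogeneous selection; the
#: establishment lottery generates presence/absence turnover among tolerant
#: taxa, which carries the betaNTI signal.
ESTABLISHMENT = 0.6
#: establishment probability under heterogeneous selection; higher, because
#: the signal there is the between-clade distance and higher within-sample
#: richness sharpens the null.
ESTABLISHMENT_HET = 0.85
#: minimum mean patristic separation between the clade pools used by
#: heterogeneous selection.
CLADE_SEPARATION = 0.9

#: The chronosequence layout: 14 site x N_DI fields, 6 replicates each (84
#: samples), sites Point_A-D, N_DI levels {5, 8, 10, 15, 18, 20, 25} years.
STUDY_FIELDS = (
    ("Point_A", 10),
    ("Point_A", 15),
    ("Point_A", 20),
    ("Point_B", 15),
    ("Point_B", 18),
    ("Point_B", 25),
    ("Point_C", 8),
    ("Point_C", 10),
    ("Point_C", 15),
    ("Point_C", 20),
    ("Point_D", 5),
    ("Point_D", 10),
    ("Point_D", 15),
    ("Point_D", 20),
)
STUDY_REPLICATES = 6


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class RegimeConfig:
    """Parameters of one simulated assembly regime.

    sigma_bm is the Brownian trait rate on the unit-depth tree (tip trait sd
    = sigma_bm); sigma_filter the Gaussian niche breadth applied to the
    optimum trait inside a selection pool (smaller = stronger within-pool
    selection); env_spread the between-sample environmental sd used by
    heterogeneous selection; migration in [0, 1] the mixing weight toward the
    common pool under homogenizing dispersal; subpool_fraction the fraction
    of taxa in a local pool (dispersal-limited subpools and selection clade
    pools alike).
    """

    regime: str
    n_taxa: int = 200
    n_samples: int = 10
    depth: int = 2000
    sigma_bm: float = 1.0
    sigma_filter: float = 0.5
    env_spread: float = 2.0
    migration: float = 0.97
    subpool_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")
        if self.n_taxa < 10:
            raise ValueError("n_taxa must be >= 10")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if self.sigma_filter <= 0:
            raise ValueError("sigma_filter must be > 0")
        if self.sigma_bm < 0:
            raise ValueError("sigma_bm must be >= 0")
        if not 0 <= self.migration <= 1:
            raise ValueError("migration must be in [0, 1]")
        if not 0 < self.subpool_fraction <= 1:
            raise ValueError("subpool_fraction must be in (0, 1]")


def simulate_tree(n_tips: int, seed=None) -> TreeNode:
    """Pure-birth (Yule) ultrametric tree, rescaled to unit depth.

    Tips are labeled OTU_0001 ... OTU_n (zero-padded so lexicographic order
    is natural order), assigned to the simulated tips in random order.
    Deterministic given seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = _as_generator(seed)
    root = TreeNode(name=None, length=0.0)
    first, second = TreeNode(length=0.0), TreeNode(length=0.0)
    root.append(first)
    root.append(second)
    active = [first, second]
    birth = {id(first): 0.0, id(second): 0.0}
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node.length = t - birth.pop(id(node))
        for _ in range(2):
            child = TreeNode(length=0.0)
            node.append(child)
            active.append(child)
            birth[id(child)] = t
    t += rng.exponential(1.0 / len(active))  # extend tips to the next event
    for node in active:
        node.length = t - birth[id(node)]
    for node in root.traverse(include_self=False):
        node.length /= t
    width = len(str(n_tips))
    labels = [f"OTU_{i + 1:0{width}d}" for i in range(n_tips)]
    for node, label in zip(active, rng.permutation(labels)):
        node.name = str(label)
    return root


def evolve_trait(tree: TreeNode, sigma_bm: float, seed=None) -> pd.Series:
    """Brownian-motion trait along branches from a root value of 0.

    Tip covariance equals sigma_bm^2 times shared root-to-tip path length.
    """
    if sigma_bm < 0:
        raise ValueError("sigma_bm must be >= 0")
    rng = _as_generator(seed)
    values = {id(tree): 0.0}
    traits = {}
    for node in tree.preorder(include_self=False):
        length = node.length or 0.0
        val = values[id(node.parent)] + rng.normal(0.0, sigma_bm * np.sqrt(length))
        values[id(node)] = val
        if node.is_tip():
            traits[node.name] = val
    return pd.Series(traits, name="trait").sort_index()


def _synthetic_env(
    n_di_years: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Soil covariates with realistic magnitudes. Only TDS (salinity proxy,
    g/kg) carries a designed trend — decreasing with years under drip
    irrigation; the rest are noise around field-plausible means."""
    n = len(n_di_years)
    ndi = np.asarray(n_di_years, dtype=float)
    env = {
        "TDS": np.clip(9.0 - 0.22 * ndi + rng.normal(0, 0.6, n), 0.3, None),
        "pH": 8.1 + rng.normal(0, 0.15, n),
        "OM": 12.0 + 0.10 * ndi + rng.normal(0, 1.5, n),
        "TN": 0.90 + 0.010 * ndi + rng.normal(0, 0.08, n),
        "TP": 0.85 + 0.012 * ndi + rng.normal(0, 0.07, n),
        "AP": 18.0 + rng.normal(0, 3.0, n),
        "AK": 180.0 + rng.normal(0, 25.0, n),
        "NH4": 5.0 + rng.normal(0, 1.0, n),
        "NO3": np.clip(16.0 - 0.15 * ndi + rng.normal(0, 2.5, n), 0.5, None),
        "ALP": 12.0 + rng.normal(0, 2.0, n),
        "PPO": 8.0 + rng.normal(0, 1.5, n),
        "urease": 6.0 + rng.normal(0, 1.0, n),
        "POD": 4.0 + rng.normal(0, 0.8, n),
    }
    return pd.DataFrame({k: env[k] for k in ENV_VARIABLES})


def _candidate_clades(
    tree: TreeNode, taxon_index: dict[str, int], target: int
) -> list[np.ndarray]:
    """Internal-node clades with a tip count near ``target`` (selection pools)."""
    lo = max(5, int(round(0.6 * target)))
    hi = max(int(round(1.6 * target)), lo + 2)
    clades = []
    for node in tree.non_tips():
        tips = [t.name for t in node.tips()]
        if lo <= len(tips) <= hi:
            clades.append(np.array(sorted(taxon_index[t] for t in tips)))
    if not clades:
        raise ValueError(
            f"tree has no clades of size {lo}..{hi}; "
            "increase n_taxa or subpool_fraction"
        )
    return clades


def _tightest_clade(clades: list[np.ndarray], D: np.ndarray) -> np.ndarray:
    """The candidate clade with the smallest mean internal patristic distance
    (the most phylogenetically coherent habitat pool)."""
    intra = [D[np.ix_(c, c)].mean() for c in clades]
    return clades[int(np.argmin(intra))]


def _distant_disjoint_clades(
    clades: list[np.ndarray],
    D: np.ndarray,
    dmin: float = CLADE_SEPARATION,
    kmin: int = 3,
) -> list[np.ndarray]:
    """Farthest-first subset of mutually disjoint candidate clades.

    Starts from the most distant disjoint pair and keeps adding the clade
    maximizing its minimum mean patristic distance to those already chosen,
    stopping once that distance drops below ``dmin`` (but not before ``kmin``
    clades). These are the distinct habitats of heterogeneous selection.
    """
    k = len(clades)
    sets = [set(c.tolist()) for c in clades]
    M = np.array([[D[np.ix_(a, b)].mean() for b in clades] for a in clades])
    best = None
    for i in range(k):
        for j in range(i + 1, k):
            if not (sets[i] & sets[j]) and (
                best is None or M[i, j] > M[best[0], best[1]]
            ):
                best = (i, j)
    if best is None:
        raise ValueError("no two disjoint clades available for distinct habitats")
    chosen = list(best)
    while True:
        rest = [
            c
            for c in range(k)
            if c not in chosen and not any(sets[c] & sets[x] for x in chosen)
        ]
        if not rest:
            break
        nxt = max(rest, key=lambda c: min(M[c][x] for x in chosen))
        if min(M[nxt][x] for x in chosen) < dmin and len(chosen) >= kmin:
            break
        chosen.append(nxt)
    return [clades[c] for c in chosen]


def _selection_weights(
    pool: np.ndarray,
    m: np.ndarray,
    trait: np.ndarray,
    env: float,
    sigma_filter: float,
    rng: np.random.Generator,
    establishment: float = ESTABLISHMENT,
) -> np.ndarray:
    """One sample's weights under selection: metacommunity abundance times a
    Gaussian trait filter inside the clade pool, thinned by an independent
    establishment lottery."""
    w = np.zeros(m.size)
    w[pool] = m[pool] * np.exp(
        -((trait[pool] - env) ** 2) / (2.0 * sigma_filter**2)
    )
    if not np.isfinite(w.sum()) or w.sum() <= 0:
        raise ValueError(
            f"all selection weights vanished: sigma_filter {sigma_filter} is "
            f"too narrow for environment {env:.3g} relative to the pool's "
            f"trait range [{trait[pool].min():.3g}, {trait[pool].max():.3g}]"
        )
    keep = rng.random(pool.size) < establishment
    if w[pool][keep].sum() > 0:
        thinned = np.zeros_like(w)
        thinned[pool[keep]] = w[pool[keep]]
        w = thinned
    return w / w.sum()


def _regime_weights(
    regime: str,
    cfg: RegimeConfig,
    m: np.ndarray,
    trait: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    clades: list[np.ndarray] | None = None,
    D: np.ndarray | None = None,
    pool: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample sampling-weight matrix (n_samples x n_taxa).

    ``clades`` supplies the candidate selection pools and ``D`` the
    taxa-aligned patristic matrix (both required for the two selection
    regimes); ``pool`` pins homogeneous selection to a specific clade (used
    by the chronosequence emulation to give each group its own pool).
    """
    n_taxa = m.size
    p_meta = m / m.sum()
    W = np.empty((n_samples, n_taxa))
    if regime == "homogeneous_selection":
        if pool is None:
            if clades is None or D is None:
                raise ValueError("selection regimes need candidate clades and D")
            pool = _tightest_clade(clades, D)
        env = float(trait[pool].mean())
        for s in range(n_samples):
            W[s] = _selection_weights(pool, m, trait, env, cfg.sigma_filter, rng)
    elif regime == "heterogeneous_selection":
        if clades is None or D is None:
            raise ValueError("selection regimes need candidate clades and D")
        # each sample's environment admits a different clade: round-robin over
        # a farthest-first disjoint clade set, so pairwise pools are distant
        habitats = _distant_disjoint_clades(clades, D)
        for s in range(n_samples):
            c = habitats[s % len(habitats)]
            env = float(trait[c].mean()) + rng.normal(
                0.0, 0.05 * cfg.env_spread
            )
            W[s] = _selection_weights(
                c, m, trait, env, cfg.sigma_filter, rng,
                establishment=ESTABLISHMENT_HET,
            )
    elif regime == "drift":
        alpha = DRIFT_CONCENTRATION * p_meta
        for s in range(n_samples):
            W[s] = rng.dirichlet(alpha)
    elif regime == "dispersal_limitation":
        k = max(2, int(round(cfg.subpool_fraction * n_taxa)))
        for s in range(n_samples):
            sub = rng.choice(n_taxa, size=k, replace=False)
            w = np.zeros(n_taxa)
            w[sub] = m[sub]
            w /= w.sum()
            W[s] = (1.0 - DL_BACKGROUND) * w + DL_BACKGROUND * p_meta
    elif regime == "homogenizing_dispersal":
        p_pool = rng.lognormal(0.0, HOD_POOL_SIGMA, n_taxa)
        p_pool /= p_pool.sum()
        alpha = DRIFT_CONCENTRATION * p_pool
        for s in range(n_samples):
            local = rng.dirichlet(alpha)
            w = (1.0 - cfg.migration) * local + cfg.migration * p_pool
            W[s] = w / w.sum()
    else:  # pragma: no cover - guarded by RegimeConfig
        raise ValueError(f"unknown regime {regime!r}")
    return W


def simulate_dataset(cfg: RegimeConfig) -> SyntheticDataset:
    """Simulate one dataset under a single assembly regime.

    All samples belong to one N_DI group (10 years) so the whole pairwise set
    is in scope for within-group process fractions; sites cycle Point_A-D to
    provide a second factor for ordination tests.
    """
    rng = _as_generator(cfg.seed)
    tree = simulate_tree(cfg.n_taxa, rng)
    trait_series = evolve_trait(tree, cfg.sigma_bm, rng)
    taxa = list(trait_series.index)
    trait = trait_series.to_numpy()
    m = rng.lognormal(0.0, METACOMMUNITY_SIGMA, cfg.n_taxa)

    clades = D = None
    if cfg.regime in ("homogeneous_selection", "heterogeneous_selection"):
        target = max(2, int(round(cfg.subpool_fraction * cfg.n_taxa)))
        clades = _candidate_clades(tree, {t: i for i, t in enumerate(taxa)}, target)
        D = tree.tip_tip_distances().filter(taxa).data
    W = _regime_weights(
        cfg.regime, cfg, m, trait, cfg.n_samples, rng, clades=clades, D=D
    )
    counts = np.empty((cfg.n_taxa, cfg.n_samples), dtype=np.int64)
    for s in range(cfg.n_samples):
        counts[:, s] = rng.multinomial(cfg.depth, W[s])

    width = len(str(cfg.n_samples))
    sample_ids = [f"S{j + 1:0{width}d}" for j in range(cfg.n_samples)]
    table = OTUTable(pd.DataFrame(counts, index=taxa, columns=sample_ids))

    n_di = np.full(cfg.n_samples, 10)
    meta = _synthetic_env(n_di, rng)
    meta.insert(0, "n_di_years", n_di)
    sites = [f"Point_{'ABCD'[j % 4]}" for j in range(cfg.n_samples)]
    meta.insert(0, "site", sites)
    meta.index = pd.Index(sample_ids, name="sample_id")
    meta = validate_metadata(meta)
    return SyntheticDataset(table=table, tree=tree, metadata=meta, truth={"10": cfg.regime})


def emulate_study_design(
    seed: int | None = None,
    n_taxa: int = 200,
    depth: int = 2000,
    sigma_filter: float = 0.5,
) -> SyntheticDataset:
    """Simulate the 84-sample chronosequence: 4 sites, 14 site x N_DI fields,
    6 replicates each, N_DI in {5, 8, 10, 15, 18, 20, 25} years.

    Groups with N_DI < 15 years assemble by drift; groups with N_DI >= 15
    years by homogeneous selection (one shared clade pool per N_DI level),
    reproducing the qualitative stochastic-to-deterministic transition along
    the chronosequence.
    """
    rng = _as_generator(seed)
    base = RegimeConfig(
        regime="drift", n_taxa=n_taxa, depth=depth, sigma_filter=sigma_filter
    )
    tree = simulate_tree(n_taxa, rng)
    trait_series = evolve_trait(tree, base.sigma_bm, rng)
    taxa = list(trait_series.index)
    trait = trait_series.to_numpy()
    m = rng.lognormal(0.0, METACOMMUNITY_SIGMA, n_taxa)

    levels = sorted({ndi for _, ndi in STUDY_FIELDS})
    truth = {
        str(ndi): ("homogeneous_selection" if ndi >= 15 else "drift")
        for ndi in levels
    }
    target = max(2, int(round(base.subpool_fraction * n_taxa)))
    clades = _candidate_clades(tree, {t: i for i, t in enumerate(taxa)}, target)
    D = tree.tip_tip_distances().filter(taxa).data
    # each selection-dominated N_DI level gets its own pool, tightest first
    ranked = sorted(clades, key=lambda c: D[np.ix_(c, c)].mean())
    sel_levels = [ndi for ndi in levels if truth[str(ndi)] == "homogeneous_selection"]
    level_pool = {
        ndi: ranked[i % len(ranked)] for i, ndi in enumerate(sel_levels)
    }

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for site, ndi in STUDY_FIELDS:
        regime = truth[str(ndi)]
        W = _regime_weights(
            regime, base, m, trait, STUDY_REPLICATES, rng,
            pool=level_pool.get(ndi),
        )
        for r in range(STUDY_REPLICATES):
            sample_id = f"{site}_Y{ndi:02d}_R{r + 1}"
            columns[sample_id] = rng.multinomial(depth, W[r])
            meta_rows.append({"sample_id": sample_id, "site": site, "n_di_years": ndi})

    sample_ids = sorted(columns)
    counts = np.column_stack([columns[s] for s in sample_ids])
    table = OTUTable(pd.DataFrame(counts, index=taxa, columns=sample_ids))

    meta = pd.DataFrame(meta_rows).set_index("sample_id").loc[sample_ids]
    env = _synthetic_env(meta["n_di_years"].to_numpy(), rng)
    env.index = meta.index
    meta = validate_metadata(pd.concat([meta, env], axis=1))
    return SyntheticDataset(table=table, tree=tree, metadata=meta, truth=truth)
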