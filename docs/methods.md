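# Methods

## The inference problem

Given an OTU count table, a rooted phylogeny over the OTUs and per-sample
metadata, the pipeline classifies every pairwise community comparison into one
of five assembly processes and aggregates the fractions per group (here the
number of years a field has been drip-irrigated, N_DI). The logic is
two-staged: a phylogenetic null first decides whether selection acted at all,
then a taxonomic null splits the non-selected remainder into dispersal-driven
and drift-like outcomes.

## betaMNTD and betaNTI

betaMNTD is the abundance-weighted mean distance from each taxon in one
community to its nearest relative in the other (shared taxa are their own
nearest neighbour at distance 0; the unweighted variant uses equal 1/richness
weights and is exposed via `weighted=False`). The null holds both communities'
abundances fixed and applies a uniform random permutation of tip labels across
the whole tree — equivalently of the rows and columns of the patristic matrix
— recomputing betaMNTD each time. betaNTI is the observed value standardized
by the null mean and standard deviation (ddof = 1, since the replicates are a
sample from the permutation population). Defaults: 999 replicates (the common
field convention; the acceptance-scale runs use 199), abundance-weighted.

Degenerate pairs: when the two samples have identical taxon support, every
permutation maps shared taxa together, all null values equal the observed 0
and the null sd vanishes. betaNTI is then defined as 0 (no deviation from the
null); a vanishing sd with a *different* observed value raises an error naming
the pair. The diagonal is 0 by convention.

## Raup–Crick (Bray–Curtis)

The abundance-based variant: for each pair, null communities preserve each
sample's observed richness and total abundance. A null assembly draws
richness-many taxa without replacement with probability proportional to
metacommunity occupancy (fraction of samples occupied) — implemented by the
Gumbel top-k trick, which realizes exactly the successive
weighted-without-replacement draw — seeds each drawn taxon with one
individual, and distributes the remaining individuals multinomially with
probability proportional to metacommunity relative abundance. RC is the rank
of the observed Bray–Curtis value in the null sample, rescaled to [−1, 1];
ties count one-half, so RC = 0 is the exact-null expectation. Ties are
detected with a 1e-12 relative tolerance (Bray–Curtis values are ratios of
integers; exact ties occur only in tiny communities).

Reproducibility: each pair gets its own RNG substream derived by stable
(BLAKE2) hashing of the sorted sample-id pair together with the master seed,
so results are independent of evaluation order and of which pair subset is
requested.

## Classification and aggregation

Strict inequalities, exactly as the thresholds are conventionally printed:
betaNTI > +2 heterogeneous selection; betaNTI < −2 homogeneous selection;
otherwise RC > +0.95 dispersal limitation, RC < −0.95 homogenizing dispersal;
everything else — including values exactly on a threshold — is drift (drift
and "undominated" are a single class). Aggregation defaults to within-group
pairs with groups given by N_DI pooled across sites (`group_by` accepts any
metadata column or combination, `scope="all_pairs"` pools everything). Each
group reports its five fractions, the deterministic fraction P(|betaNTI| > 2)
and the median betaNTI; groups with fewer than two samples are reported with
`n_pairs = 0` and NaN fractions.

## Diversity and ordination

Shannon uses the natural log by default (a `base` argument covers the log-2
convention); Chao1 is the bias-corrected estimator, robust when no doubletons
exist. Both delegate to scikit-bio. Rarefaction is a single draw without
replacement to a user depth — it is *not* applied automatically. PCoA applies
Gower double-centering to the squared distance matrix and reports the full
eigenvalue spectrum; negative eigenvalues (non-Euclidean dissimilarities) are
reported unchanged, with no Lingoes/Cailliez correction, and explained
proportions are taken over the positive eigenvalues only. PERMANOVA is the
McArdle–Anderson trace formulation with sequential (Type I) sums of squares
for one or two factors without interaction; factor order is the user's and is
logged; p-values use (count + 1)/(perms + 1) with whole-sample permutation.
RDA Hellinger-transforms counts by default, standardizes covariates, drops
zero-variance and collinear columns (and caps the design at n − 2 covariates
so a residual degree of freedom remains), and tests each covariate marginally
by permutation of reduced-model residuals.

## The synthetic generator

The generator's job is to produce datasets whose pairwise comparisons *should*
be classified into a known process, so every stage of the pipeline can be
validated end to end. All regimes share: a Yule (pure-birth) ultrametric tree
rescaled to unit depth; a Brownian-motion trait (tip-trait variance
sigma_bm^2 × root-to-tip depth) serving as each taxon's environmental
optimum; log-normal metacommunity abundances m_k (log-sd 1.0); and one
multinomial draw of `depth` individuals per sample, so column sums equal the
depth exactly.

A design note on selection. A Gaussian suitability band on a *single*
Brownian trait does not produce phylogenetically clustered communities: on a
unit-depth Yule tree the correlation between trait distance and patristic
distance is weak (~0.3), similar trait values arise in unrelated clades, and
betaNTI barely responds. Selection is therefore modeled as phylogenetically
conserved habitat association at clade level: a selection pool is the tip set
of an internal node with roughly subpool_fraction × n_taxa tips, taxa inside
the pool are weighted by m_k times a Gaussian filter around the pool's trait
optimum (width sigma_filter), and each sample passes the pool through an
independent establishment lottery (per-taxon establishment probability 0.6)
— the presence/absence turnover among tolerant close relatives is what the
nearest-taxon statistic detects.

- homogeneous_selection: every sample uses the single most coherent
  (smallest mean internal distance) candidate clade → betaNTI strongly
  negative.
- heterogeneous_selection: a farthest-first set of mutually disjoint clades
  (minimum mean separation 0.9; establishment 0.85) assigned round-robin →
  cross-habitat pairs give betaNTI strongly positive.
- drift: per-sample Dirichlet perturbation of the metacommunity proportions
  with concentration 4000 — inside the window where turnover stays within
  both null envelopes (much weaker perturbation collapses onto the iid
  multinomial draw, which the Raup–Crick null reads as homogenization;
  stronger perturbation reads as dispersal limitation).
- dispersal_limitation: each sample draws from its own random
  subpool_fraction × n_taxa taxon subpool (chosen independently of the tree,
  so the signal is taxonomic, not phylogenetic), mixed with a 10% shared
  metacommunity background. The background is necessary: without it the
  subpool statistics are exactly reproduced by the occupancy-weighted null
  and RC stays uniform; with it, each sample's private dominants occur
  everywhere at low abundance, the reassembly null levels them, and observed
  turnover exceeds the null (RC → +1).
- homogenizing_dispersal: all samples are near-identical draws from one
  common pool (migration weight 0.97 toward the pooled mean over weak
  Dirichlet locals). The pool has a longer rare tail (log-sd 1.8) than the
  shared metacommunity: the many borderline-occupancy taxa make the null's
  richness draw variable while observed pairs stay matched, pushing RC → −1.

`emulate_study_design` arranges 84 samples as 6 replicates in each of 14
site × N_DI fields (sites Point_A–D; N_DI ∈ {5, 8, 10, 15, 18, 20, 25}
years): fields under 15 years assemble by drift, fields at 15 years and above
by homogeneous selection with one clade pool per N_DI level (tightest clades
first), reproducing the qualitative stochastic-to-deterministic transition
along the chronosequence. Soil covariates (TDS, pH, OM, TN, TP, AP, AK,
NH4, NO3 and four enzyme activities) are generated at field-realistic
magnitudes; only TDS (salinity, g/kg) carries a designed trend — decreasing
with irrigation age — so ordination and PERMANOVA stages have a signal to
find. The covariates have no causal role in community assembly and are
qualitative stand-ins only.

What passing the regime-recovery suite shows — and what it does not: the
pipeline correctly attributes turnover generated by known, cleanly separated
mechanisms at realistic amplicon scales (200 taxa, depth 2000). Real soil
data mix processes within a single pair, have far more taxa, compositional
sequencing artifacts and tree-estimation error, none of which the generator
emulates; recovery rates here are upper bounds, not field expectations.

## Numerical choices and scale

Problem sizes were chosen so the full test suite and the acceptance run each
complete in minutes on one CPU: 199 null replicates for acceptance-scale
analyses (999 remains the library default), 200 taxa, 10 samples and depth
2000 for the regime benchmarks, and the 84-sample chronosequence for the
study-shaped run. betaNTI permutes the patristic matrix once per replicate
and evaluates all pairs simultaneously (Welford accumulation, no replicate
storage); Raup–Crick vectorizes the taxon draw via Gumbel top-k. Output TSVs
use a fixed `%.10g` float format, so identical inputs and seed give
byte-identical files.

## Known limitations

- The tip-shuffle null is the "taxa.labels" scheme only; within-group or
  abundance-constrained randomizations are not implemented.
- Raup–Crick requires integer counts; pre-normalized (relative) tables must
  be re-integerized or rarefied first.
- The two-factor PERMANOVA has no interaction term, matching common adonis
  usage for this design.
- The generator's five regimes are pure; mixed-process pairs and
  gradient-shaped selection are out of scope.
- RDA covariate tests are marginal (each variable against the full model);
  no forward selection is provided.
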