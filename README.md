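# ecoassembly

Null-model inference of soil microbial community assembly processes.

`ecoassembly` asks, for every pair of 16S community profiles, whether the
observed turnover between them could have arisen by chance — and when it could
not, which ecological process shaped it. It implements the two-stage
null-model framework used throughout microbial ecology to study disturbed
soils (here motivated by saline soils under multi-year drip irrigation, where
assembly shifts from stochastic to deterministic as salinity declines):

1. **Phylogenetic turnover.** The between-community mean nearest taxon
   distance,

   βMNTD(k,m) = ½ [ Σ_{i∈k} f_ik · min_{j∈m} d(i,j) + Σ_{j∈m} f_jm · min_{i∈k} d(i,j) ],

   with f the within-sample relative abundances and d the patristic distance,
   is standardized against a null built by shuffling tip labels across the
   whole phylogeny:

   βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null.

   βNTI < −2 → homogeneous selection; βNTI > +2 → heterogeneous selection.

2. **Taxonomic turnover.** For pairs with |βNTI| ≤ 2, the abundance-based
   Raup–Crick metric ranks the observed Bray–Curtis dissimilarity within a
   null of probabilistically reassembled community pairs (richness and total
   abundance preserved; taxa drawn by metacommunity occupancy, individuals
   filled by metacommunity relative abundance), rescaled to [−1, 1]:
   RC > +0.95 → dispersal limitation; RC < −0.95 → homogenizing dispersal
   (mass effect); otherwise drift/undominated.

Around this core the package provides alpha diversity (Shannon, bias-corrected
Chao1), Bray–Curtis distances, PCoA, one/two-factor PERMANOVA (sequential
adonis), RDA with per-variable permutation tests, harmonization of OTU table +
Newick tree + metadata, a CLI — and a synthetic community generator that
emulates an 84-sample drip-irrigation chronosequence (4 sites × 7 N_DI levels)
under five controllable assembly regimes, so the whole pipeline is testable
without any sequencing data.

## Worked example

Simulate ten communities assembled under homogeneous selection (all samples
filtered into the same clade-structured niche) and ask the null models which
process they detect:

```python
import ecoassembly as ea

ds = ea.simulate_dataset(ea.RegimeConfig(regime="homogeneous_selection", seed=1))
pairs, fractions = ea.assembly_analysis(ds.table, ds.tree, ds.metadata,
                                        reps=199, seed=1)
print(pairs.head(3).round(3).to_string(index=False))
print(fractions[["n_pairs", "homogeneous_selection", "drift",
                 "deterministic_fraction", "median_beta_nti"]].round(3))
```

```
sample_a sample_b group  beta_mntd_obs  beta_nti  bc_obs     rc               process
     S01      S02    10          0.068    -2.423   0.475  0.186 homogeneous_selection
     S01      S03    10          0.040    -2.142   0.346 -0.482 homogeneous_selection
     S01      S04    10          0.106    -2.628   0.760  0.990 homogeneous_selection

       n_pairs  homogeneous_selection  drift  deterministic_fraction  median_beta_nti
group
10          45                  0.911  0.089                   0.911           -2.642
```

Each row is one sample pair: its observed βMNTD, the standardized deviate
βNTI (−2.4: far less phylogenetic turnover than the tip-shuffle null, i.e.
both communities are confined to the same clades), the observed Bray–Curtis
dissimilarity, its Raup–Crick rank, and the resulting process label. The
aggregation shows 91% of pairs correctly attributed to homogeneous selection,
a deterministic fraction P(|βNTI| > 2) of 0.91, and a median βNTI of −2.6.

The same analysis from the shell:

```bash
ecoassembly --seed 1 simulate --regime homogeneous_selection --out sim/
ecoassembly --seed 1 nullmodel --table sim/table.tsv --tree sim/tree.nwk \
    --metadata sim/metadata.tsv --reps 199 --out nm/
ecoassembly classify --pairs nm/pairs.tsv --t-nti 2 --t-rc 0.95 --out cls/
```

`simulate --emulate-study` generates the full 84-sample chronosequence
(6 replicate samples in each of 14 site × N_DI fields, N_DI ∈ {5, 8, 10, 15,
18, 20, 25} years, drift below 15 years and homogeneous selection above);
`diversity` and `ordinate` cover the alpha-diversity and PCoA/RDA stages.

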