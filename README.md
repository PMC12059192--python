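# beetlenet

Species-interaction networks and between-habitat migration inference for
multi-habitat species biomass data.

## The problem

Freshwater invertebrate communities — the motivating case is water beetles
sampled from natural lakes (mesotrophic, eutrophic, dystrophic) and
post-exploitation water bodies (clay pits, gravel pits) — are observed as
species-by-sample wet-biomass tables. Two questions drive the analysis:

1. **Structure.** Within each habitat, which species co-vary after removing
   indirect effects, and how is the resulting interaction network organised
   (density, clustering, centralisation, which species hold it together)?
2. **Movement.** Between a lake habitat and a pit habitat, which species
   have systematically higher biomass on one side — read as a net migration
   tendency in that direction — and how strong is the aggregate flow?

`beetlenet` implements both stages as fit-able model objects, plus a
synthetic community generator that plants known correlation blocks and
migration signals so every stage can be validated against ground truth.

## Models

**Networks.** Per habitat, biomass columns are autoscaled and the species
network is built from full-order partial correlations,
P_ij = −Ω_ij/√(Ω_ii Ω_jj) with Ω the inverse of the shrinkage-regularised
correlation matrix (Schäfer–Strimmer intensity λ toward the identity).
Edges are kept when the Fisher-z test of P_ij (df = n − (S−2) − 3) gives
p ≤ α = 0.05; edge sign comes from the Pearson coefficient. Whole-network
attributes (density, mean degree, clustering, centralization,
heterogeneity, characteristic path length, ordered-pair shortest-path
count) and node/edge centralities (NDC, NCC, NBC, EBC — ordered-pair
conventions throughout) are computed from the unweighted graph.

**Migration.** For a (lake, pit) pair, samples are labelled class 0 (lake)
/ class 1 (pit) and a Newton-boosted tree ensemble (logistic loss, split
gain ½[G_L²/(H_L+λ)+G_R²/(H_R+λ)−(G_L+G_R)²/(H_L+H_R+λ)], leaf
−lr·G/(H+λ); defaults 1000 trees, depth 10, lr 0.001) is fitted on five
independent stratified 70/30 splits. Shapley values of the margin with an
interventional background attribute the classification to species; per
species, SW = mean over repeats of (mean |φ| signed by corr(biomass, φ)).
SW > 0 reads as migration toward the pit, SW < 0 toward the lake;
directional sums and their average summarise the pair.

See `docs/methods.md` for every convention and the design rationale.

## Worked example

```python
import beetlenet as bn

table = bn.generate_community(bn.default_config(seed=42))

net = bn.SpeciesNetworkModel(table, "clay_pit").fit()
print(net.summary())

mig = bn.MigrationModel(
    table, "dystrophic", "gravel_pit",
    n_trees=200, shapley_mode="montecarlo",
    n_permutations=4, background_size=30,
).fit(seed=7)
print(mig.summary(top=3))
```

Output:

```
Species partial-correlation network
===================================================
Habitat:                 clay_pit
Samples:                 229
Species analysed:        40 (0 dropped)
Edge threshold (alpha):  0.05
Shrinkage intensity:     0.3769
---------------------------------------------------
Number of nodes                       38
Number of edges                       45
Average number of neighbours          2.368
Network density                       0.064
Clustering coefficient                0.504
Network centralization                0.047
Network heterogeneity                 0.327
Characteristic path length            1.753
Shortest paths                        162

Habitat-pair migration model
=======================================================
Pair: dystrophic (class 0) vs gravel_pit (class 1)
Repeats: 5   trees: 200   depth: 10   lr: 0.001
Mean accuracy: train 0.708, test 0.709
-------------------------------------------------------
species                 SW        SD  direction
sp029               0.0637    0.0298  to-pit
sp025               0.0443    0.0267  to-pit
sp028               0.0383    0.0297  to-pit
-------------------------------------------------------
SW(sum) to gravel_pit  : 0.1983
SW(sum) to dystrophic  : 0.2236
SW(mean of sum)          : 0.2109
```

Reading it: 38 of 40 species kept at least one significant partial-
correlation edge; the network keeps 45 of 703 possible edges (density
0.064) and is strongly clustered (0.504) because the generator plants
correlated species blocks. In the migration model, `sp029` (an
argilophile, home habitat gravel pits) has the largest positive SW — its
biomass pattern pushes the classifier toward the pit class — while the
directional sums are roughly balanced here because no extra migration
signal was injected beyond the groups' habitat affinities.

There is also a CLI over the same pipeline:

```
beetlenet all --seed 1 --out run_out          # simulate -> report.json
beetlenet migrate --seed 1 --out run_out      # just the six habitat pairs
```

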