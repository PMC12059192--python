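# Methods

This note records the models and conventions behind `beetlenet`, the
choices made where conventions differ between tools, and what the synthetic
generator does and does not emulate.

## Data model

The observation unit is a **community table**: samples in rows, species in
columns, wet biomass in mg, with one habitat label per sample drawn from
five classes — two post-exploitation water bodies (`clay_pit`,
`gravel_pit`) and three natural lake types (`mesotrophic`, `eutrophic`,
`dystrophic`). A biomass of 0 encodes absence. Species carry an ecological
group label (eurybiont, tyrphophile, argilophile, rheophile, rheobiont)
describing their habitat preference.

## Partial-correlation species networks

Per habitat, species columns are **autoscaled** (zero mean, unit sample SD,
denominator n−1) after dropping species with zero variance or fewer than
`min_occurrence` (default 2) positive records — a species seen once cannot
support a correlation estimate. A flag switches to population-SD scaling;
the n−1 convention is the default because it is the one used by the
metabolomics-style correlation tooling this pipeline mirrors. Whether to
autoscale within each habitat or globally is not fixed by convention; we
scale within habitat because the networks are per-habitat objects.

The network uses **full-order partial correlations**: with R the sample
correlation matrix and Ω = R⁻¹, the partial correlation of species i and j
given all others is P_ij = −Ω_ij/√(Ω_ii Ω_jj). Because per-habitat species
counts can approach (or exceed) sample counts, R is regularised before
inversion by analytic shrinkage toward the identity, R* = λI + (1−λ)R,
with λ chosen by the Schäfer–Strimmer estimator (ratio of summed sampling
variances of the off-diagonal correlations to their summed squares, clipped
to [0,1]). Shrinkage can be disabled (`shrinkage="none"`), in which case a
near-singular matrix raises an error advising shrinkage.

Significance of each P_ij uses the Fisher z transform,
z = atanh(P_ij)·√df with **df = n − (S−2) − 3** (conditioning on the S−2
remaining species), floored at 3. Edges are kept at p ≤ α (default 0.05)
with no multiple-testing correction by default, matching the filtering
convention of the workflow this mirrors; a Benjamini–Hochberg flag is
available but off. Edge sign is taken from the **Pearson** coefficient
(the sign displayed on network figures); both the partial and Pearson
coefficients are stored on every edge. Species without any retained edge
are excluded from the node set.

### Network metrics and their conventions

All path-based metrics treat the graph as unweighted and undirected;
correlation magnitudes are attributes, not distances. Conventions, stated
because network analysers differ:

- **shortest-path count**: number of ordered pairs (s,t), s ≠ t, with
  finite distance — a connected graph on n nodes has n(n−1);
- **characteristic path length**: mean geodesic distance over connected
  ordered pairs only (defined on disconnected graphs);
- **density** = mean degree/(n−1); **average neighbours** = 2E/n;
- **clustering coefficient**: mean local clustering with degree-<2 nodes
  contributing 0 and included in the mean;
- **centralization** = (n/(n−2))·(max degree/(n−1) − density) for n ≥ 3,
  else 0 (1 for a star, 0 for any regular graph);
- **heterogeneity** = coefficient of variation of the degree distribution
  (population variance);
- **NDC** = degree; **NCC** = 1/(mean distance to reachable nodes), 0 for
  isolated nodes (both endpoints of an isolated pair score 1);
- **NBC** = Brandes betweenness over ordered pairs, normalised by
  (n−1)(n−2) with the global node count (a star hub scores 1);
- **EBC** = raw ordered-pair count of shortest paths through an edge
  (fractional under ties); its minimum is 2, from the edge's own endpoint
  pair in both directions.

Brandes betweenness and local clustering are delegated to networkx; the
test suite checks them against exhaustive path-enumeration oracles on
hundreds of small random graphs, exactly.

## Habitat-pair migration inference

For a (lake, pit) habitat pair, samples are labelled class 0 (lake) and
class 1 (pit) and a boosted-tree classifier learns to separate them from
species biomass alone. The ecological reading: if high biomass of a
species pushes the classifier toward the pit class, that species does
systematically better in the pit — interpreted as net migration toward the
pit; the mirror case reads as migration toward the lake; a species whose
attributions are zero does not respond.

### Boosting

Newton boosting with logistic loss, implemented natively: per round,
g_i = p_i − y_i and h_i = p_i(1−p_i); trees are grown greedily to
`max_depth` with the regularised gain
½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ)]; a leaf outputs
−lr·G/(H+λ); the base score is the log-odds of training prevalence.
Split search is histogram-based (≤64 quantile bins per feature), which
changes nothing about the model class. Defaults follow the reference
protocol: 1000 trees, depth 10, learning rate 0.001, λ = 1, 70/30
stratified split, 5 independent repeats. `min_child_weight` defaults to
1.0 (hessian mass), matching the xgboost default so that the optional
xgboost backend is comparable like-for-like; tests assert the two backends
agree in test accuracy within 2 points on synthetic pairs.

### Shapley attributions

Attributions are computed on the **margin (log-odds) scale** with the
interventional value function v(S) = mean over background rows b of
f(x_S, b_rest). `exact` mode enumerates all 2^F coalitions (F ≤ 15);
`montecarlo` mode averages marginal contributions over random feature
orderings and reports a permutation standard error. Both satisfy the
efficiency identity Σφ = f(x) − mean background margin exactly (the
permutation sum telescopes). The background is the repeat's training
partition, subsampled to `background_size` (default 100) rows with the run
seed; the explained set is the test partition by default (a flag explains
all rows). These two choices are stated explicitly because tree-explainer
defaults vary across libraries.

### Migration statistics

Per repeat and species, the signed statistic follows the ABS_SHAP recipe:
magnitude = mean |φ| over explained observations, signed by
corr(biomass, φ). **SW** is the mean of the signed values over repeats
(SD across repeats quantifies split-to-split variability). A plain signed
mean-of-φ convention is available behind a flag; the signed-magnitude
form is the default because directional sums of signed magnitudes are the
quantity the summary tables aggregate. Directional aggregates:
SW(sum)→pit = Σ SW over SW>0; SW(sum)→lake = Σ|SW| over SW<0;
SW(mean of sum) = their average. The identity
SW(mean of sum) = (SW(sum)→pit + SW(sum)→lake)/2 is asserted on every
constructed summary. "5 randomly run models" is interpreted as five
independent 70/30 splits with independent model seeds, since the reported
dispersion is across whole modelling runs.

## Synthetic community generator

The generator emulates the statistical structure the analyses assume:

- **zero-inflated log-normal biomass** — presence is an independent
  Bernoulli occupancy draw per habitat and species; positive biomass is
  exp(location + scale·Z), so absence is exactly 0 mg;
- **correlation blocks** — within a cluster of ecologically homogeneous
  species the latent Gaussians share a one-factor structure
  Z = √ρ·F + √(1−ρ)·ε, giving latent correlation ρ with one parameter;
  correlation acts only on magnitudes, occupancy draws are independent;
- **habitat affinity** — each ecological group has home habitats where
  occupancy and log-biomass location are elevated;
- **migration signal** — positive cells of selected species in a pit
  habitat are multiplied by exp(shift) for a signed log-scale shift.

Defaults: 40 species in groups with shares 40/20/15/20/5 % (eurybionts
dominant), clusters of 5, ρ = 0.85, occupancy 0.50 (0.80 in home
habitats), log-location 1.6 (≈5 mg) with +0.4 at home, scale 1.0, and
per-habitat sample counts 229/243/264/260/100 (total 1096), mirroring a
multi-season littoral survey in which the dystrophic class is sampled
least. Occupancy and ρ were chosen so the default community yields
networks at a realistic scale — most species retained as nodes and
densities near 0.06–0.08 — comparable to published beetle biomass
networks. What the generator does **not** emulate: spatial structure and
dispersal, temporal dynamics, abundance counts (N is defined as
positive-biomass records), taxon-specific biomass distributions, and
predator–prey induced negative correlations. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
effects, not field-data conclusions.

## Community statistics

S = species with positive biomass; N = positive-biomass records (for
biomass-only data); D = group percentage of N per habitat. Group
comparisons use the tie-corrected Kruskal–Wallis H with a χ²(k−1)
p-value (all-identical input returns H = 0, p = 1), followed by a
Dunn-type post-hoc on mean ranks with tie correction and **Bonferroni**
adjustment over all k(k−1)/2 pairs — Bonferroni because the classical
"multiple comparisons of mean ranks" procedure uses it. The post-hoc is
computed regardless of the omnibus outcome and flagged downstream.

## Numerical and test-scale choices

- Shrinkage intensity is clipped to [0,1]; partial correlations are
  symmetrised and clipped to [−1,1] after inversion; p-values are floored
  degrees-of-freedom Fisher-z as above.
- Ties in split gain resolve to the first (lowest feature index, lowest
  threshold) maximum, making fits bit-reproducible.
- All randomness flows from one root seed through
  `numpy.random.SeedSequence` substreams (per stage, per pair, per
  repeat); identical configuration + seed reproduces outputs byte-for-byte.
- The heavy stochastic checks (planted-shift recovery, six-pair runs in
  the acceptance script) run at a documented test scale: 200 boosting
  rounds, Monte-Carlo Shapley with 4 permutations and a 30-row background.
  These sizes keep a full run at minutes while leaving the recovery
  experiment's operating characteristics comfortable (sign recovery and
  magnitude ordering are stable across replicates at this scale).

## Known limitations

- Full-order partial correlations with analytic shrinkage are a
  regularised point estimate; no confidence intervals are attached to
  individual edges beyond the Fisher-z filter.
- The Fisher-z degrees of freedom are an approximation under shrinkage
  (the effective conditioning set is smaller than S−2 when λ > 0).
- Monte-Carlo Shapley standard errors are per-cell permutation SEs, not
  joint bands.
- The migration read-out is correlational: a positive SW says biomass is
  systematically higher in the pit class, which is consistent with — but
  not proof of — directional migration.
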