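# microniche

Tools for asking a classic community-ecology question of microbial count
data: **which taxa are generalists, which are habitat specialists, and who
holds the co-occurrence network together?** The package grew out of
continental-scale soil-fungal surveys (a few thousand ITS OTUs over ~200
cropland samples spanning subtropical to temperate regions) but runs on any
OTU/ASV-by-sample count table with per-sample region labels.

It provides, as composable scikit-learn-style estimators plus a CLI:

1. **Niche-breadth classification** (`NicheBreadthClassifier`). Levins'
   index `B_j = 1 / Σ_i P_ij²`, with `P_ij` the fraction of OTU j's reads
   in sample i, ranges from 1 (one sample) to N (even spread over N
   samples). Generalists have high global B (> 17 by default), occurrence
   in > 50% of samples, and non-negligible abundance (mean relative
   abundance ≥ 2×10⁻⁵); habitat specialists have low within-region B
   (< 12 / 17 / 17 for the three default regions) and in-region occurrence
   > 4.
2. **Ensemble co-occurrence network** (`EnsembleNetworkInference`). Five
   association measures per OTU pair (Pearson, Spearman, Bray–Curtis,
   symmetrized Kullback–Leibler, mutual information), raw p-values from a
   shared stream of sample-order permutations, Brown's dependent p-value
   combination with a permutation-estimated covariance,
   Benjamini–Hochberg control (α = 10⁻³), a ≥ 2-measure direction-consistent
   support rule, and bootstrap stability.
3. **Network topology** (`NetworkTopology`). Degree, component-scaled
   closeness, betweenness, eigenvector centrality (power iteration,
   max-normalized), Louvain modules, Zi/Pi node roles (module hub /
   connector / peripheral / kinless), B ~ centrality regressions, and
   one-way ANOVA with Tukey compact letters on degree by niche group.
4. **Path analysis** (`PathAnalysis`). Standardized OLS path coefficients
   and total effects (sums over directed paths of coefficient products) on
   a declared DAG of spatial/climatic/edaphic drivers and community
   summaries, with bootstrap significance and PCA-score composites.
5. **Synthetic communities** (`microniche.simulate`). Lognormal-multinomial
   tables with planted generalists, regional specialists, correlated OTU
   blocks, and linear-Gaussian covariate data — every downstream claim is
   testable against known truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import microniche as mn

# a synthetic community with planted truth: 3 regions x 60 samples,
# 20 generalists, 30 specialists per region, 320 medium OTUs
table, meta, truth = mn.generate_community(mn.SyntheticSpec(seed=42))

res = mn.classify(table, meta)
print(res["label"].value_counts().to_dict())

net = mn.infer_network(table, n_permutations=200, n_bootstraps=200,
                       random_state=11, apply_prevalence_filter=True)
print(len(net.nodes_), "nodes,", len(net.edges_), "edges")

topo = mn.NetworkTopology(random_state=0).fit(net.graph_, niche_results=res)
print(topo.report_.groupby(res["label"])["degree"].mean().round(2).to_dict())
```

prints

```
{'medium': 309, 'specialist:warm_temperate': 35, 'specialist:temperate': 33,
 'specialist:subtropical': 32, 'generalist': 20, 'filtered': 1}
430 nodes, 145 edges
{'filtered': 1.0, 'generalist': 6.35, 'medium': 0.32,
 'specialist:subtropical': 0.75, 'specialist:temperate': 0.58,
 'specialist:warm_temperate': 0.6}
```

All 20 planted generalists are recovered with no false positives (the 20
labeled generalists are exactly the planted ones), specialist
precision/recall are 0.90/1.00 against the 90 planted specialists, and the
planted generalist blocks make generalists by far the best-connected group
in the network — the one-way ANOVA on degree separates them from every
specialist group at p < 0.05.

The same chain runs from the shell:

```bash
microniche simulate --outdir out --seed 42
microniche classify --outdir out --seed 42
microniche network  --outdir out --seed 42 --n-permutations 200 --n-bootstraps 200
microniche topology --outdir out --seed 42
microniche effects  --outdir out --seed 42
# or monolithically, from a flat key=value config file:
microniche run --config pipeline.cfg
```

Outputs are TSV/GraphML files plus a JSON manifest recording every
parameter, derived stage seed, timing, and input checksum; identical
config + seed reproduces every numeric output byte for byte.

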