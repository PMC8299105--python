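# Methods

`microniche` implements an inference chain for soil-fungal (or any
microbial) community count tables: classify taxa as generalists or habitat
specialists by Levins' niche breadth, infer an ensemble co-occurrence
network with permutation support, characterize node roles in that network,
and estimate standardized path effects of spatial/climatic/edaphic drivers.
This note records the models, the parameter choices, and the numerical
conventions, in the order the pipeline runs them.

## Input model and normalizations

The data are an OTU-by-sample matrix of non-negative integer read counts
plus per-sample metadata (a bioclimatic region label, optional numeric
covariates). Sequencing depth varies across samples, so tables may first be
rarefied: each sample is subsampled **without replacement** (multivariate
hypergeometric) to a common depth; samples below the depth are dropped, not
padded, because padding would fabricate reads.

Two normalizations coexist and feed different statistics:

- *within-sample* relative abundance (columns sum to 1) feeds the
  mean-relative-abundance filter;
- *within-OTU* occupancy profiles `P_ij = n_ij / Σ_i n_ij` (rows sum to 1)
  feed the niche-breadth index. Only this normalization gives B its
  documented range `[1, N]`; classification thresholds like 17 over ~200
  samples are meaningless under the within-sample normalization.

## Niche breadth and classification

Levins' index for OTU j is `B_j = 1 / Σ_i P_ij²`: 1 when all reads sit in
one sample, N when they spread evenly over N samples, and never larger than
the number of occupied samples. Classification uses strict inequalities
throughout:

- **generalist** — mean within-sample relative abundance ≥ 2×10⁻⁵
  (rarer OTUs are labeled `filtered`), global B > 17, occurrence > 50% of
  samples;
- **habitat specialist** — within exactly one region, B computed over that
  region's samples (profiles renormalized to the region) below the region's
  cut (defaults 12 for subtropical, 17 for warm-temperate and temperate)
  with in-region occurrence > 4;
- **medium** — everything else.

Two ambiguities were resolved as package policy: a generalist call takes
precedence over any specialist call, and an OTU whose region-wise rule
fires in two or more regions is *not* a specialist (being "special" to
several regions contradicts the concept); the tie is reported in a
dedicated column. The abundance filter applies only to generalist
determination. An `auto_threshold` mode replaces the fixed cuts with Tukey
fences (Q3 + 1.5·IQR globally; Q1 − 1.5·IQR per region, floored at 1) of
the observed B distributions; the fixed cuts are the default.

## Ensemble co-occurrence network

Candidate pairs are all pairs of OTUs passing a prevalence filter
(occurrence ≥ 4 samples and ≥ 10 total reads, both inclusive). Five
association measures are computed per pair: Pearson and Spearman
correlation, Bray–Curtis dissimilarity, symmetrized Kullback–Leibler
divergence (vectors shifted by a 1-count pseudocount and renormalized), and
mutual information on equal-frequency discretizations (bins =
`min(ceil(√n), 10)`; tied values share a bin, so a constant vector has zero
entropy and zero MI).

**Permutation p-values.** All measures share one stream of sample-order
permutations (default 1,000; the recovery experiments below use 200).
Correlations and MI are tested two-sided around the permutation-null mean;
dissimilarities are tested in the observed tail — low tail = co-presence
(positive edge), high tail = exclusion (negative edge) — with the
one-tailed p doubled so the null p-distribution stays (super-)uniform. The
empirical p is `(1 + #extreme) / (n_perm + 1)`; when the observed score is
more extreme than *every* permutation the p saturates at its resolution
floor, and the tail is refined by a normal approximation of the null
(z-score against the permutation mean and sd, capped above by the empirical
floor). Without this refinement a five-measure merged p can never clear a
Benjamini–Hochberg gate at α = 10⁻³ with a few hundred permutations; with
it, p-values inside the permutation range are untouched, so null
calibration is unaffected. MI carries no sign; its direction is positive
when the observed MI exceeds the null mean — a convention that can disagree
with the correlation measures on exclusion pairs, which is why direction is
decided by *majority* among supporting measures (a bare tie discards the
pair).

**Merging and gates.** Per-pair p-values are merged with Brown's
covariance-aware extension of Fisher's method. The covariance of the
−2·ln p statistics is estimated from the same shared permutations: each
replicate is converted to its within-null pseudo-p (same tail conventions),
transformed, and the empirical covariance is rescaled to the theoretical
diagonal of 4. With a diagonal covariance the merge reduces exactly to
Fisher's method. Merged p-values are BH-adjusted across all pairs (one
family, post-merge). An edge is kept when (i) at least `min_support = 2`
measures are individually significant (raw p < 0.05) in the consensus
direction, (ii) the adjusted merged p < α = 10⁻³, and (iii) the edge is
bootstrap-stable: resampling samples with replacement (default 1,000, the
experiments use 200), an individual measure is stable when the central 95%
interval of its resampled scores excludes the permutation-null mean
(> 50% degenerate resamples = unstable), and the edge needs `min_support`
stable supporting measures. Stability is evaluated only for pairs that
already pass the first two gates — the result set is identical, the cost is
not. An optional minimum absolute consensus-correlation filter exists and
is off by default.

Determinism and symmetry: pairs are canonicalized by lexicographic OTU id,
the permutation stream is independent of row order, and per-pair bootstrap
seeds derive from the master seed plus the sorted id pair, so the inferred
network is invariant to the input row order and exactly reproducible under
a seed.

## Network topology

Degree, closeness, betweenness, and eigenvector centrality are computed on
the simple undirected edge set. Co-occurrence networks are routinely
disconnected, so closeness uses the Wasserman–Faust component scaling
`((k−1)/Σd) · ((k−1)/(n−1))` and isolated nodes score 0. Eigenvector
centrality is the dominant adjacency eigenvector by power iteration
(tolerance 10⁻¹⁰ in the sup norm, iterating on A + I so bipartite
components cannot oscillate), max-normalized to 1, computed on the full
graph by default (per-component available). Modules come from Louvain
modularity optimization at resolution 1.0 under a seed; the within-module
degree z-score Zi and participation coefficient Pi classify roles with the
standard cutoffs Zi ≥ 2.5 and Pi > 0.62 (module hub / connector / kinless /
peripheral). B ~ centrality relationships use OLS with the slope's t-test;
group degree differences use one-way ANOVA with Tukey-HSD compact letters
(degenerate cases are defined: zero between-group variance gives F = 0,
zero within-group variance with distinct means gives F = ∞).

## Path analysis

The covariance-based SEM of the source workflow is reduced to
observed-variable path analysis on a user-declared DAG: all variables are
z-scored, every endogenous node is regressed by OLS on its declared parents
(collinear parents beyond condition number 10⁸ are rejected by name), and
the standardized total effect of a source on a target is accumulated in
topological order (equivalently, the sum over all directed paths of the
products of edge coefficients). Composite blocks (e.g. `carbon = SOC + DOC`
in the DAG file) are represented by the sign-fixed first
principal-component score of their standardized indicators — an
approximation to AMOS-style composites; covariance-SEM fit indices are out
of scope and per-node r² is reported instead. Significance is a
row-resampling bootstrap (p = smoothed two-sided fraction of resampled
effects crossing zero); the reference workflow does not state its
procedure.

## Synthetic communities and what they do (not) show

The generator plants ground truth for every downstream stage. Defaults
describe the recovery community used throughout the tests: 3 regions × 60
samples, depth 10,000 per sample (multinomial, so column sums are exact),
20 generalists, 30 specialists per region, 320 medium OTUs. Baseline
abundances are lognormal with σ = 1.5, making a few OTUs hold a large share
of all reads. Generalists are present in each sample with probability 0.95
and carry no per-sample jitter — near-even occupancy profiles are their
defining trait; 2 × 8 of them additionally carry exchangeable-correlation
latent factors (ρ = 0.85), the planted network edges. Specialists occupy
exactly 8 samples of their own region. Medium OTUs draw an occupancy
uniformly from (0.10, 0.40) — deliberately intermediate between the
specialist (~4%) and generalist (95%) regimes and below the 50% generalist
occurrence rule — and, like specialists, carry independent lognormal
per-sample jitter with σ = 0.8. Two null-model helpers sample *rows
independently* (Poisson cells): fixed-depth multinomial closure itself
induces real correlations through the shared denominator, which a
false-positive calibration table must not contain. For the same reason the
planted-block table gives block rows the correlated latent as their only
per-sample variation, so the planted log-latent correlation is exactly the
nominal ρ.

What passing recovery tests shows is that the chain detects the structure
it claims to detect under lognormal-multinomial sampling with planted
block correlations and linear-Gaussian covariates. Real amplicon data add
compositional closure coupling (the permutation scheme shuffles sample
order and does not correct for it), taxon-specific amplification bias,
spatial autocorrelation of samples, and non-linear environmental
responses; none of these are emulated, and performance on them is not
established by these tests.

## Problem sizes and numerical conventions

The recovery experiments run at the sizes stated above with 200
permutations and 200 bootstraps; the null-control experiment averages 20
independent 60 OTU × 100 sample tables; path recovery uses n = 5,000; the
end-to-end determinism run uses a reduced community (3 × 20 samples, 105
OTUs, depth 5,000, 100 permutations/bootstraps) — sizes chosen so the whole
suite re-runs comfortably on one CPU. Quartiles use linear interpolation.
Permutation p-values are never 0 by construction; a p of exactly 0 passed
to the Brown merge is clamped to the smallest positive float with a
warning. The vectorized engine stores permutation nulls in float32 (scores
in [−1, 1] or O(1); the precision loss is far below the permutation
resolution). Louvain module ids are renumbered deterministically (largest
module first). Seeds: one master seed hashes (BLAKE2) into independent
31-bit child seeds per stage, per null replicate, and per bootstrap pair.

## Known limitations

- The permutation null does not address compositionality; on strongly
  compositional data (one taxon holding most reads) edges can reflect
  closure rather than ecology.
- Brown's method is an approximation; with heavy dependence among measures
  and very small p-values the merged p relies on the normal-tail
  refinement of the per-measure p-values.
- MI direction is a convention, not an inference; exclusion edges supported
  mainly by MI are penalized by the majority rule.
- The PCA-score composite is not an AMOS composite; coefficients involving
  composites are comparable only in sign and rough magnitude.
- `auto_threshold` fences depend on the observed B distribution and are not
  comparable across datasets.
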