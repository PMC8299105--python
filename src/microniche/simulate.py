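"""Synthetic community, correlated-block, and linear-Gaussian path datasets.

Everything downstream of the raw count table is testable against planted
ground truth: archetype labels (generalist / regional specialist / medium),
the set of truly correlated OTU pairs, and the standardized coefficients of
a path model. The generator emulates the structure of a continental-scale
soil-fungal survey: a few thousand OTUs over samples grouped into
bioclimatic regions, highly uneven lognormal abundances, broad-occupancy
even-abundance generalists, region-restricted low-occupancy specialists,
latent correlated OTU blocks, and fixed per-sample sequencing depth
(multinomial sampling).

Defaults are sized to the recovery experiments used throughout the test
suite: 3 regions x 60 samples, 20 generalists (16 of them inside two
correlated blocks), 30 specialists per region, 320 medium OTUs, depth
10,000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import OtuTable, SampleMetadata

CANONICAL_REGIONS = ("subtropical", "warm_temperate", "temperate")


@dataclass
class SyntheticSpec:
    """Configuration of a planted synthetic community.

    Notes on the free parameters (units in fractions of samples / reads):

    - ``generalist_occupancy``: Bernoulli presence probability per sample for
      planted generalists (0.95 -> present nearly everywhere).
    - ``specialist_occupancy_samples``: exact number of in-region samples in
      which a planted specialist is present (8 of 60 by default).
    - ``lognormal_sigma``: sd of the log baseline OTU weight; 1.5 makes a
      handful of OTUs hold most reads, matching highly uneven amplicon data.
    - ``sample_sigma``: sd of per-sample lognormal jitter applied to
      specialist/medium weights. Generalists carry no jitter — near-even
      occupancy profiles are their defining trait.
    - ``medium_occupancy_range``: uniform range of medium-OTU occupancy,
      deliberately intermediate between specialists (~4% of samples) and
      generalists (95%).
    - ``block_spec``: (size, latent rho) planted correlated blocks, laid over
      the leading generalist OTUs (and continuing into medium OTUs if larger
      than the generalist pool).
    """

    n_regions: int = 3
    samples_per_region: int = 60
    n_generalists: int = 20
    n_specialists_per_region: int = 30
    n_medium: int = 320
    depth: int = 10_000
    generalist_occupancy: float = 0.95
    specialist_occupancy_samples: int = 8
    lognormal_sigma: float = 1.5
    sample_sigma: float = 0.8
    medium_occupancy_range: tuple = (0.10, 0.40)
    block_spec: list = field(default_factory=lambda: [(8, 0.85), (8, 0.85)])
    seed: int = 0

    def __post_init__(self):
        for name in ("n_regions", "samples_per_region", "n_generalists",
                     "n_specialists_per_region", "n_medium", "depth",
                     "specialist_occupancy_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.generalist_occupancy <= 1):
            raise ValueError("generalist_occupancy must be in (0, 1]")
        for _, rho in self.block_spec:
            if not (-1 < rho < 1):
                raise ValueError("block latent correlation must be in (-1, 1)")

    def region_names(self) -> list:
        if self.n_regions == 3:
            return list(CANONICAL_REGIONS)
        return [f"region_{i + 1}" for i in range(self.n_regions)]


@dataclass
class TruthLabels:
    """Planted ground truth emitted alongside a synthetic table."""

    archetype: dict
    true_edges: set
    path_coefficients: dict = field(default_factory=dict)

    def of_kind(self, kind: str) -> list:
        """OTU ids whose archetype equals or starts with ``kind``."""
        return [o for o, a in self.archetype.items()
                if a == kind or a.startswith(kind + ":")]


def generate_correlated_block(n_samples: int, size: int, rho: float, seed: int) -> np.ndarray:
    """Exponentiated exchangeable-correlation Gaussian block (size x samples).

    Rows are multiplicative abundance factors exp(Z) with corr(Z_i, Z_j) =
    rho for i != j; applied on top of baseline weights so the planted
    correlation survives compositional multinomial sampling.
    """
    if size < 2:
        raise ValueError("block size must be >= 2")
    if not (-1 < rho < 1):
        raise ValueError("rho must be in (-1, 1)")
    if rho <= -1.0 / (size - 1):
        raise ValueError(
            f"rho={rho} makes the exchangeable correlation matrix of size "
            f"{size} non-positive-definite (needs rho > {-1.0 / (size - 1):.4f})"
        )
    rng = np.random.default_rng(seed)
    cov = np.full((size, size), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(size), cov, size=n_samples,
                                method="cholesky")
    return np.exp(z.T)


def generate_community(spec: SyntheticSpec):
    """Generate (OtuTable, SampleMetadata, TruthLabels) with planted structure.

    Per-sample counts are multinomial draws at ``spec.depth`` from lognormal
    relative-abundance weights masked by each archetype's occupancy pattern,
    so every column of the returned table sums exactly to the depth.
    """
    rng = np.random.default_rng(spec.seed)
    regions = spec.region_names()
    n_samples = spec.n_regions * spec.samples_per_region
    sample_ids = [f"s{j:04d}" for j in range(n_samples)]
    sample_region = np.repeat(np.arange(spec.n_regions), spec.samples_per_region)

    otu_ids, archetype = [], {}
    for g in range(spec.n_generalists):
        otu_ids.append(f"gen_{g:04d}")
        archetype[otu_ids[-1]] = "generalist"
    for r, region in enumerate(regions):
        for k in range(spec.n_specialists_per_region):
            otu_ids.append(f"spec_{region}_{k:04d}")
            archetype[otu_ids[-1]] = f"specialist:{region}"
    for m in range(spec.n_medium):
        otu_ids.append(f"med_{m:04d}")
        archetype[otu_ids[-1]] = "medium"
    n_otus = len(otu_ids)
    if n_otus == 0:
        raise ValueError("spec yields no OTUs")

    base = (np.ones(n_otus) if spec.lognormal_sigma == 0
            else rng.lognormal(0.0, spec.lognormal_sigma, n_otus))

    # occupancy masks
    mask = np.zeros((n_otus, n_samples), dtype=bool)
    row = 0
    for g in range(spec.n_generalists):
        if spec.generalist_occupancy >= 1.0:
            mask[row] = True
        else:
            mask[row] = rng.random(n_samples) < spec.generalist_occupancy
        row += 1
    for r in range(spec.n_regions):
        region_cols = np.flatnonzero(sample_region == r)
        k = min(spec.specialist_occupancy_samples, region_cols.size)
        for _ in range(spec.n_specialists_per_region):
            cols = rng.choice(region_cols, size=k, replace=False)
            mask[row, cols] = True
            row += 1
    lo, hi = spec.medium_occupancy_range
    for _ in range(spec.n_medium):
        f = rng.uniform(lo, hi)
        mask[row] = rng.random(n_samples) < f
        row += 1

    weights = base[:, None] * mask
    # per-sample heterogeneity for non-generalists; generalists stay even
    if spec.sample_sigma > 0 and n_otus > spec.n_generalists:
        jitter = rng.lognormal(0.0, spec.sample_sigma,
                               (n_otus - spec.n_generalists, n_samples))
        weights[spec.n_generalists:] *= jitter

    # planted correlated blocks over consecutive leading OTUs
    true_edges = set()
    start = 0
    for size, rho in spec.block_spec:
        stop = start + size
        if stop > n_otus:
            warnings.warn("block_spec exceeds the OTU pool; truncating")
            stop = n_otus
        if stop - start >= 2:
            latent = generate_correlated_block(
                n_samples, stop - start, rho,
                seed=rng.integers(2**31))
            weights[start:stop] *= latent
            block_ids = otu_ids[start:stop]
            for a in range(len(block_ids)):
                for b in range(a + 1, len(block_ids)):
                    true_edges.add(tuple(sorted((block_ids[a], block_ids[b]))))
        start = stop

    expected_active = mask.sum(axis=0).max(initial=0)
    if expected_active > spec.depth:
        warnings.warn(
            f"depth {spec.depth} cannot represent all {expected_active} "
            "planted-present OTUs in at least one sample")

    counts = np.zeros((n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        w = weights[:, j]
        tot = w.sum()
        p = np.full(n_otus, 1.0 / n_otus) if tot <= 0 else w / tot
        counts[:, j] = rng.multinomial(spec.depth, p)

    table = OtuTable(otu_ids, sample_ids, counts)
    meta = SampleMetadata(region={sid: regions[sample_region[j]]
                                  for j, sid in enumerate(sample_ids)})
    return table, meta, TruthLabels(archetype=archetype, true_edges=true_edges)


def generate_independent_table(
    n_otus: int,
    n_samples: int,
    depth: int = 10_000,
    lognormal_sigma: float = 1.5,
    sample_sigma: float = 0.8,
    seed: int = 0,
) -> OtuTable:
    """Null community: OTU count rows mutually independent.

    Used to calibrate the network's false-positive control. Each cell is an
    independent Poisson draw with rate depth * share_i * jitter, where
    shares come from lognormal baseline weights and the jitter is
    independent per-sample lognormal noise. Rows are sampled independently
    (no fixed-depth multinomial closure): a shared compositional
    denominator would itself induce real correlations, which is exactly
    what a null table must not contain. ``depth`` is therefore the
    *expected* per-sample total.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, lognormal_sigma, n_otus)
    share = base / base.sum()
    lam = (depth * share[:, None]
           * rng.lognormal(0.0, sample_sigma, (n_otus, n_samples)))
    counts = rng.poisson(lam).astype(np.int64)
    return OtuTable([f"otu_{i:04d}" for i in range(n_otus)],
                    [f"s{j:04d}" for j in range(n_samples)], counts)


def generate_block_table(
    n_otus: int,
    n_samples: int,
    block_spec,
    depth: int = 10_000,
    lognormal_sigma: float = 1.5,
    sample_sigma: float = 0.8,
    seed: int = 0,
):
    """Independent-row null table with planted correlated blocks.

    Identical to :func:`generate_independent_table` except that the leading
    OTUs' per-sample variation is replaced by multiplicative
    exchangeable-correlation latents per ``block_spec`` (list of
    (size, rho)), so the planted pairs' log-latent correlation is exactly
    rho; all other rows keep their own independent jitter. Returns
    ``(OtuTable, true_edges)``.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, lognormal_sigma, n_otus)
    share = base / base.sum()
    lam = (depth * share[:, None]
           * rng.lognormal(0.0, sample_sigma, (n_otus, n_samples)))
    ids = [f"otu_{i:04d}" for i in range(n_otus)]
    true_edges = set()
    start = 0
    for size, rho in block_spec:
        stop = min(start + size, n_otus)
        if stop - start >= 2:
            latent = generate_correlated_block(
                n_samples, stop - start, rho, seed=rng.integers(2**31))
            lam[start:stop] = depth * share[start:stop, None] * latent
            for a in range(start, stop):
                for b in range(a + 1, stop):
                    true_edges.add(tuple(sorted((ids[a], ids[b]))))
        start = stop
    counts = rng.poisson(lam).astype(np.int64)
    return (OtuTable(ids, [f"s{j:04d}" for j in range(n_samples)], counts),
            true_edges)


# ---------------------------------------------------------------------------
# linear-Gaussian path-model data
# ---------------------------------------------------------------------------

#: Default path-model truth used by the pipeline's synthetic mode and the
#: recovery experiments: space -> climate -> {generalist, specialist} ->
#: coexistence, with edaphic blocks (texture, carbon, nitrogen) acting on
#: both fungal nodes. Coefficients are standardized; specialists respond
#: more strongly to climate/edaphic drivers than generalists.
DEFAULT_PATH_COEFFICIENTS = {
    ("space", "climate"): 0.6,
    ("space", "specialist"): 0.2,
    ("climate", "generalist"): 0.2,
    ("climate", "specialist"): 0.45,
    ("texture", "generalist"): 0.25,
    ("texture", "specialist"): 0.3,
    ("carbon", "generalist"): 0.05,
    ("carbon", "specialist"): 0.25,
    ("nitrogen", "generalist"): 0.05,
    ("nitrogen", "specialist"): 0.2,
    ("generalist", "coexistence"): 0.4,
    ("specialist", "coexistence"): 0.1,
    ("climate", "coexistence"): 0.25,
}


def generate_sem_dataset(
    coefficients: dict,
    n: int,
    noise_sd: dict | None = None,
    seed: int = 0,
    variables: list | None = None,
) -> pd.DataFrame:
    """Simulate standardized observations from an acyclic linear path model.

    ``coefficients`` maps directed edges (parent, child) to standardized
    coefficients. Nodes are generated in topological order as
    sum(coef * parent) + Gaussian noise and finally z-scored. When
    ``noise_sd`` omits a node, the noise variance is chosen to make the
    node's marginal variance 1, so the supplied coefficients are the true
    standardized path coefficients.
    """
    g = nx.DiGraph()
    g.add_nodes_from(variables or [])
    for (a, b), c in coefficients.items():
        g.add_edge(a, b, coef=float(c))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("path model contains a cycle")
    order = list(nx.topological_sort(g))
    rng = np.random.default_rng(seed)
    noise_sd = dict(noise_sd or {})

    data = {}
    # analytic covariance bookkeeping to auto-standardize noise
    cov = pd.DataFrame(0.0, index=order, columns=order)
    for node in order:
        parents = list(g.predecessors(node))
        if not parents:
            sd = noise_sd.get(node, 1.0)
            data[node] = sd * rng.standard_normal(n)
            cov.loc[node, node] = sd**2
            continue
        coefs = np.array([g.edges[p, node]["coef"] for p in parents])
        signal = sum(c * data[p] for c, p in zip(coefs, parents))
        sig_var = float(coefs @ cov.loc[parents, parents].to_numpy() @ coefs)
        if node in noise_sd:
            sd = noise_sd[node]
        else:
            if sig_var > 1:
                raise ValueError(
                    f"{node}: implied signal variance {sig_var:.3f} > 1; "
                    "coefficients are not jointly standardizable")
            sd = float(np.sqrt(1.0 - sig_var))
        data[node] = signal + sd * rng.standard_normal(n)
        # propagate analytic covariance
        for other in order:
            if other == node:
                continue
            cov.loc[node, other] = cov.loc[other, node] = float(
                coefs @ cov.loc[parents, other].to_numpy())
        cov.loc[node, node] = sig_var + sd**2
    df = pd.DataFrame(data, columns=order)
    return (df - df.mean()) / df.std(ddof=0)
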