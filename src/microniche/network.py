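"""Ensemble co-occurrence network inference with permutation nulls.

For every OTU pair, five association measures are computed (Pearson,
Spearman, Bray-Curtis, symmetrized Kullback-Leibler, mutual information).
Raw p-values come from a shared stream of sample-order permutations; the
per-measure p-values are merged with Brown's covariance-aware extension of
Fisher's method (the covariance of the -2 ln p statistics is estimated from
the same shared permutations), adjusted across pairs by Benjamini-Hochberg,
and an edge is retained when

- at least ``min_support`` measures are individually significant in the
  edge's consensus direction,
- the BH-adjusted merged p is below ``alpha``, and
- the edge is stable under bootstrap resampling (the central 95% interval
  of resampled scores excludes the permutation-null mean for at least
  ``min_support`` supporting measures).

Tail conventions: correlation-like measures (Pearson, Spearman, MI) are
tested two-sided around the permutation-null mean; dissimilarities
(Bray-Curtis, KL) are tested in the observed tail with the one-tailed p
doubled, low tail meaning co-presence (positive edge) and high tail
exclusion (negative edge). MI carries no sign, so its direction is positive
when the observed MI exceeds the null mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._utils import derive_seed
from .io import OtuTable, prevalence_filter as _prevalence_filter

ALL_MEASURES = (
    "pearson",
    "spearman",
    "bray_curtis",
    "kullback_leibler",
    "mutual_information",
)

#: measure family drives the permutation-test tail convention
FAMILY = {
    "pearson": "corr",
    "spearman": "corr",
    "bray_curtis": "dissim",
    "kullback_leibler": "dissim",
    "mutual_information": "mi",
}


# ---------------------------------------------------------------------------
# scalar association measures
# ---------------------------------------------------------------------------


def _as_pair(x, y, min_len=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_len:
        raise ValueError(f"vectors must have length >= {min_len}")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation; NaN for a constant vector (undefined)."""
    x, y = _as_pair(x, y)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def spearman(x, y) -> float:
    """Pearson correlation of mid-ranks (average ranks on ties)."""
    x, y = _as_pair(x, y)
    return pearson(stats.rankdata(x), stats.rankdata(y))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) in [0, 1]."""
    x, y = _as_pair(x, y, min_len=1)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative vectors")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def kl_distance(x, y, pseudocount: float = 1.0) -> float:
    """Symmetrized Kullback-Leibler divergence D(p||q) + D(q||p).

    Vectors are shifted by ``pseudocount`` and normalized to probability
    distributions first; with a positive pseudocount the result is always
    finite and is 0 iff the normalized vectors are equal.
    """
    x, y = _as_pair(x, y, min_len=1)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("KL distance requires non-negative vectors")
    p = x + pseudocount
    q = y + pseudocount
    p = p / p.sum()
    q = q / q.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
        lq = np.where(q > 0, np.log(np.where(q > 0, q, 1.0)), 0.0)
        d = np.where(p > 0, p * lp, 0.0) - np.where(p > 0, p * lq, 0.0)
        d += np.where(q > 0, q * lq, 0.0) - np.where(q > 0, q * lp, 0.0)
        # infinite penalty when supports differ and pseudocount == 0
        if ((p > 0) & (q == 0)).any() or ((q > 0) & (p == 0)).any():
            return float("inf")
    return float(max(d.sum(), 0.0))


def default_mi_bins(n: int) -> int:
    """Default equal-frequency bin count: ceil(sqrt(n)) capped at 10."""
    return min(int(np.ceil(np.sqrt(n))), 10)


def _bin_labels(x, bins: int) -> np.ndarray:
    """Value-ordered equal-frequency bin labels; tied values share a bin.

    A constant vector therefore collapses to a single bin (zero entropy),
    so MI against a constant is exactly 0.
    """
    x = np.asarray(x, dtype=float)
    r = stats.rankdata(x, method="min") - 1
    return (r.astype(np.int64) * bins) // x.size


def _bin_labels_rows(X, bins: int) -> np.ndarray:
    r = stats.rankdata(X, method="min", axis=1) - 1
    return (r.astype(np.int64) * bins) // X.shape[1]


def mutual_information(x, y, bins: int | None = None) -> float:
    """MI (nats) between equal-frequency discretizations of x and y."""
    x, y = _as_pair(x, y, min_len=1)
    n = x.size
    if bins is None:
        bins = default_mi_bins(n)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if n < bins:
        raise ValueError("vector length must be >= bins")
    bx = _bin_labels(x, bins)
    by = _bin_labels(y, bins)
    joint = np.bincount(bx * bins + by, minlength=bins * bins).reshape(bins, bins)
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    n = joint.sum()
    r = joint.sum(axis=1)
    c = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(joint > 0, joint * np.log(joint), 0.0).sum()
        tr = np.where(r > 0, r * np.log(r), 0.0).sum()
        tc = np.where(c > 0, c * np.log(c), 0.0).sum()
    return float(max(t / n - tr / n - tc / n + np.log(n), 0.0))


_MEASURE_FUNCS = {
    "pearson": pearson,
    "spearman": spearman,
    "bray_curtis": bray_curtis,
    "kullback_leibler": kl_distance,
    "mutual_information": mutual_information,
}


def _score(measure, x, y, kl_pseudocount=1.0, mi_bins=None):
    if measure == "kullback_leibler":
        return kl_distance(x, y, pseudocount=kl_pseudocount)
    if measure == "mutual_information":
        return mutual_information(x, y, bins=mi_bins)
    return _MEASURE_FUNCS[measure](x, y)


# ---------------------------------------------------------------------------
# permutation p-values, bootstrap stability
# ---------------------------------------------------------------------------


def _tail_extend(p_count: float, obs: float, mu: float, sd: float, n: int) -> float:
    """Refine a permutation p beyond the 1/(n+1) resolution floor.

    When the observed score is more extreme than every permutation
    replicate, the empirical p saturates at 1/(n+1); the tail is then
    extrapolated with a normal approximation of the null (two-sided around
    the null mean), capped above by the empirical floor. Inside the
    empirical resolution the count-based p is returned unchanged, so the
    null distribution of the p-values stays (super-)uniform.
    """
    floor = 1.0 / (n + 1)
    if p_count > 2.0 * floor + 1e-12:  # observed inside the null range
        return p_count
    if sd <= 0:
        return p_count
    p_par = 2.0 * float(stats.norm.sf(abs(obs - mu) / sd))
    return min(p_count, max(p_par, np.finfo(float).tiny))


def _p_from_null(obs: float, null: np.ndarray, family: str):
    """(p, direction) from observed score and its permutation-null sample."""
    if not np.isfinite(obs):
        return float("nan"), None
    n = null.size
    mu = float(null.mean())
    sd = float(null.std())
    if family in ("corr", "mi"):
        cnt = int((np.abs(null - mu) >= abs(obs - mu)).sum())
        p = (1 + cnt) / (n + 1)
        p = _tail_extend(p, obs, mu, sd, n) if cnt == 0 else p
        if family == "corr":
            direction = "positive" if obs > 0 else "negative"
        else:
            direction = "positive" if obs >= mu else "negative"
        return p, direction
    # dissimilarity: observed-tail p, doubled to keep the null super-uniform
    if obs <= mu:
        cnt = int((null <= obs).sum())
        p = min(1.0, 2 * (1 + cnt) / (n + 1))
        if cnt == 0:
            p = min(p, _tail_extend(2.0 / (n + 1), obs, mu, sd, n))
        return p, "positive"
    cnt = int((null >= obs).sum())
    p = min(1.0, 2 * (1 + cnt) / (n + 1))
    if cnt == 0:
        p = min(p, _tail_extend(2.0 / (n + 1), obs, mu, sd, n))
    return p, "negative"


def permutation_pvalue(
    x,
    y,
    measure: str,
    n_permutations: int = 1000,
    seed: int = 0,
    kl_pseudocount: float = 1.0,
    mi_bins: int | None = None,
):
    """Permutation test of one measure on one pair.

    The sample order of ``y`` is shuffled ``n_permutations`` times; the p is
    (1 + #{null at least as extreme}) / (n + 1) with the tail conventions
    described in the module docstring. Returns ``(p, direction)`` where
    direction is 'positive' (co-presence) or 'negative' (exclusion), or
    ``(nan, None)`` when the measure is undefined on the pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = _score(measure, x, y, kl_pseudocount, mi_bins)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        null[k] = _score(measure, x, rng.permutation(y), kl_pseudocount, mi_bins)
    return _p_from_null(obs, null, FAMILY[measure])


def _bootstrap_score_rows(measure, xs, ys, kl_pseudocount=1.0, mi_bins=None):
    """Scores of a measure on row-paired resamples (vectorized over rows)."""
    if measure in ("pearson", "spearman"):
        if measure == "spearman":
            xs = stats.rankdata(xs, axis=1)
            ys = stats.rankdata(ys, axis=1)
        xs_c = xs - xs.mean(axis=1, keepdims=True)
        ys_c = ys - ys.mean(axis=1, keepdims=True)
        sx = np.sqrt((xs_c**2).sum(axis=1))
        sy = np.sqrt((ys_c**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xs_c * ys_c).sum(axis=1) / (sx * sy)
        r[(sx == 0) | (sy == 0)] = np.nan
        return r
    if measure == "bray_curtis":
        denom = xs.sum(axis=1) + ys.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.abs(xs - ys).sum(axis=1) / denom
        out[denom == 0] = np.nan
        return out
    if measure == "kullback_leibler":
        p = xs + kl_pseudocount
        q = ys + kl_pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        q = q / q.sum(axis=1, keepdims=True)
        return ((p - q) * (np.log(p) - np.log(q))).sum(axis=1)
    if measure == "mutual_information":
        n = xs.shape[1]
        bins = mi_bins or default_mi_bins(n)
        bx = _bin_labels_rows(xs, bins)
        by = _bin_labels_rows(ys, bins)
        out = np.empty(xs.shape[0])
        for k in range(xs.shape[0]):
            joint = np.bincount(bx[k] * bins + by[k], minlength=bins * bins)
            out[k] = _mi_from_joint(joint.reshape(bins, bins))
        return out
    raise ValueError(f"unknown measure {measure!r}")


def bootstrap_stability(
    x,
    y,
    measure: str,
    n_bootstraps: int,
    null_mean: float,
    seed: int = 0,
    kl_pseudocount: float = 1.0,
    mi_bins: int | None = None,
) -> bool:
    """True when the central 95% bootstrap interval excludes ``null_mean``.

    Samples are resampled with replacement jointly for x and y; degenerate
    resamples (constant vector, undefined score) are skipped, and more than
    50% degenerate replicates yields ``False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_bootstraps, n))
    scores = _bootstrap_score_rows(measure, x[idx], y[idx], kl_pseudocount, mi_bins)
    valid = scores[np.isfinite(scores)]
    if valid.size < 0.5 * n_bootstraps:
        return False
    lo, hi = np.percentile(valid, [2.5, 97.5])
    return bool(null_mean < lo or null_mean > hi)


# ---------------------------------------------------------------------------
# p-value combination
# ---------------------------------------------------------------------------


def brown_merge(p_values, covariance=None) -> float:
    """Brown's method: combine dependent p-values via a scaled chi-square.

    psi = -2 sum(ln p) is approximated as c * chi2(f) with c = Var/(2E),
    f = 2 E^2 / Var, E = 2k and Var the sum of the supplied covariance of
    the -2 ln p statistics (diagonal 4, the variance of -2 ln U). With a
    diagonal covariance this reduces exactly to Fisher's method.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to merge")
    if (p <= 0).any():
        warnings.warn("p-value of 0 clamped to machine minimum")
        p = np.maximum(p, np.finfo(float).tiny)
    if (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    k = p.size
    if covariance is None:
        cov = 4.0 * np.eye(k)
    else:
        cov = np.asarray(covariance, dtype=float)
        if cov.shape != (k, k):
            raise ValueError("covariance shape does not match p-values")
    psi = -2.0 * np.log(p).sum()
    e = 2.0 * k
    var = float(cov.sum())
    c = var / (2.0 * e)
    f = 2.0 * e * e / var
    return float(stats.chi2.sf(psi / c, f))


def estimate_p_covariance(null_scores: dict, families: dict | None = None) -> pd.DataFrame:
    """Covariance of -2 ln p across measures, from shared permutation nulls.

    ``null_scores`` maps measure name -> 1-D array of null scores computed
    on the *same* permutation replicates. Each replicate is converted to a
    pseudo p (its rank within the null sample, using the measure's tail
    convention), transformed to -2 ln p, and the empirical covariance is
    returned with the diagonal rescaled to the theoretical value 4.
    """
    names = list(null_scores)
    if not names:
        raise ValueError("no measures")
    n = len(np.asarray(null_scores[names[0]]))
    if n < 30:
        raise ValueError("need at least 30 permutations for a stable estimate")
    fams = families or FAMILY
    t = np.empty((len(names), n))
    for i, m in enumerate(names):
        s = np.asarray(null_scores[m], dtype=float)
        if s.size != n:
            raise ValueError("null score vectors differ in length")
        t[i] = -2.0 * np.log(_pseudo_p(s[:, None], fams.get(m, "corr"))[:, 0])
    cov = np.cov(t)
    cov = np.atleast_2d(cov)
    d = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(d, d)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(4.0 * corr, index=names, columns=names)


def _pseudo_p(null: np.ndarray, family: str) -> np.ndarray:
    """Within-null pseudo p of every replicate (rows: replicates axis=-1).

    ``null`` has shape (n_perm, ...); p computed along axis 0 treating each
    replicate in turn as the observation, self-inclusive so p in (0, 1].
    """
    n = null.shape[0]
    if family in ("corr", "mi"):
        d = np.abs(null - null.mean(axis=0, keepdims=True))
        # count of replicates with d >= d_k  (self-inclusive)
        ge = n - (stats.rankdata(d, method="min", axis=0) - 1)
        return ge / n
    le = stats.rankdata(null, method="max", axis=0)
    ge = n - (stats.rankdata(null, method="min", axis=0) - 1)
    mu = null.mean(axis=0, keepdims=True)
    p = np.where(null <= mu, 2.0 * le / n, 2.0 * ge / n)
    return np.minimum(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    NaN entries are ignored (returned as NaN) and do not count toward the
    number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# inference engine
# ---------------------------------------------------------------------------


@dataclass
class _MeasurePrep:
    """Per-measure precomputed row transforms (permutation-equivariant)."""

    kind: str
    data: dict
    invalid_rows: np.ndarray


class EnsembleNetworkInference(BaseEstimator):
    """Infer a co-occurrence network from an OTU count table.

    Parameters mirror the network configuration: the measure subset,
    permutation/bootstrap replicate counts, the per-measure support p
    threshold, the minimum number of direction-consistent supporting
    measures, the BH significance level, MI bin count and KL pseudocount,
    and an optional minimum absolute consensus correlation (off by
    default). ``random_state`` seeds the shared permutation stream and the
    per-pair bootstrap streams.

    Attributes
    ----------
    edges_ : pandas.DataFrame
        Retained edges with per-measure scores/p-values, direction, support
        count, merged and adjusted p, and the bootstrap verdict.
    nodes_ : list of str
        All OTU ids that entered pair testing.
    graph_ : networkx.Graph
        The retained network (every node present, isolated or not).
    n_pairs_ : int
        Number of OTU pairs tested.
    """

    def __init__(
        self,
        measures=ALL_MEASURES,
        n_permutations: int = 1000,
        n_bootstraps: int = 1000,
        min_support: int = 2,
        alpha: float = 0.001,
        measure_support_p: float = 0.05,
        mi_bins: int | None = None,
        kl_pseudocount: float = 1.0,
        min_abs_consensus: float | None = None,
        apply_prevalence_filter: bool = False,
        min_occurrence: int = 4,
        min_total_reads: int = 10,
        random_state: int = 0,
    ):
        self.measures = measures
        self.n_permutations = n_permutations
        self.n_bootstraps = n_bootstraps
        self.min_support = min_support
        self.alpha = alpha
        self.measure_support_p = measure_support_p
        self.mi_bins = mi_bins
        self.kl_pseudocount = kl_pseudocount
        self.min_abs_consensus = min_abs_consensus
        self.apply_prevalence_filter = apply_prevalence_filter
        self.min_occurrence = min_occurrence
        self.min_total_reads = min_total_reads
        self.random_state = random_state

    # -- vectorized all-pairs scoring -------------------------------------

    def _prepare(self, X: np.ndarray) -> dict:
        n = X.shape[1]
        preps = {}
        for m in self.measures:
            if m in ("pearson", "spearman"):
                v = stats.rankdata(X, axis=1) if m == "spearman" else X
                mu = v.mean(axis=1, keepdims=True)
                sd = v.std(axis=1, keepdims=True)
                invalid = sd[:, 0] == 0
                with np.errstate(invalid="ignore", divide="ignore"):
                    z = np.where(sd > 0, (v - mu) / sd, 0.0)
                preps[m] = _MeasurePrep("corrlike", {"z": z}, invalid)
            elif m == "bray_curtis":
                tot = X.sum(axis=1)
                preps[m] = _MeasurePrep("bc", {"x": X, "tot": tot}, tot == 0)
            elif m == "kullback_leibler":
                p = X + self.kl_pseudocount
                p = p / p.sum(axis=1, keepdims=True)
                lp = np.log(p)
                h = (p * lp).sum(axis=1)
                preps[m] = _MeasurePrep(
                    "kl", {"p": p, "lp": lp, "h": h}, np.zeros(X.shape[0], bool))
            elif m == "mutual_information":
                bins = self.mi_bins or default_mi_bins(n)
                if bins < 2:
                    raise ValueError("mi_bins must be >= 2")
                labels = _bin_labels_rows(X, bins)
                p_rows, _ = labels.shape
                onehot = np.zeros((p_rows * bins, n), dtype=np.float32)
                rows = (np.arange(p_rows)[:, None] * bins + labels).ravel()
                cols = np.tile(np.arange(n), p_rows)
                onehot[rows, cols] = 1.0
                marg = np.array([np.bincount(l, minlength=bins) for l in labels])
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = np.where(marg > 0, marg * np.log(marg), 0.0).sum(axis=1)
                tbl = np.zeros(n + 1)
                cs = np.arange(1, n + 1)
                tbl[1:] = cs * np.log(cs)
                preps[m] = _MeasurePrep(
                    "mi",
                    {"onehot": onehot, "term": term, "bins": bins, "tbl": tbl},
                    np.zeros(X.shape[0], bool),
                )
            else:
                raise ValueError(f"unknown measure {m!r}")
        return preps

    @staticmethod
    def _pair_scores(measure, prep: _MeasurePrep, ia, ib, perm=None):
        """Scores of measure(x_a, perm(x_b)) for the canonical pairs."""
        d = prep.data
        if prep.kind == "corrlike":
            z = d["z"]
            zp = z if perm is None else z[:, perm]
            n = z.shape[1]
            s = (z @ zp.T) / n
            return s[ia, ib]
        if prep.kind == "bc":
            x = d["x"]
            xp = x if perm is None else x[:, perm]
            num = cdist(x, xp, "cityblock")
            tot = d["tot"]
            with np.errstate(invalid="ignore", divide="ignore"):
                s = num / (tot[:, None] + tot[None, :])
            return s[ia, ib]
        if prep.kind == "kl":
            p, lp, h = d["p"], d["lp"], d["h"]
            pp = p if perm is None else p[:, perm]
            lpp = lp if perm is None else lp[:, perm]
            s = h[:, None] + h[None, :] - p @ lpp.T - lp @ pp.T
            return s[ia, ib]
        if prep.kind == "mi":
            m = d["onehot"]
            mp = m if perm is None else m[:, perm]
            j = m @ mp.T
            bins = d["bins"]
            p_rows = m.shape[0] // bins
            n = m.shape[1]
            jint = np.rint(j).astype(np.int32)
            np.clip(jint, 0, n, out=jint)
            tsum = d["tbl"][jint].reshape(p_rows, bins, p_rows, bins).sum(axis=(1, 3))
            term = d["term"]
            mi = tsum / n - (term[:, None] + term[None, :]) / n + np.log(n)
            np.maximum(mi, 0.0, out=mi)
            return mi[ia, ib]
        raise AssertionError(prep.kind)

    # -- fitting -----------------------------------------------------------

    def fit(self, table: OtuTable):
        """Run the full inference on a (prevalence-filtered) OTU table."""
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if table.n_samples < 3:
            raise ValueError("need at least 3 samples to infer a network")
        if self.apply_prevalence_filter:
            table = _prevalence_filter(
                table, self.min_occurrence, self.min_total_reads)

        # canonical order: lexicographic OTU id, so results are invariant to
        # the input row order
        order = sorted(range(table.n_otus), key=lambda i: table.otu_ids[i])
        ids = [table.otu_ids[i] for i in order]
        X = table.counts[order].astype(float)
        p_rows, n = X.shape
        measures = list(self.measures)
        self.nodes_ = ids
        if p_rows < 2:
            self.edges_ = _empty_edges(measures)
            self.n_pairs_ = 0
            self.graph_ = _to_graph(ids, self.edges_)
            return self

        ia, ib = np.triu_indices(p_rows, k=1)
        n_pairs = ia.size
        self.n_pairs_ = int(n_pairs)
        preps = self._prepare(X)

        obs = {m: np.asarray(
            self._pair_scores(m, preps[m], ia, ib), dtype=float)
            for m in measures}
        invalid = {m: preps[m].invalid_rows[ia] | preps[m].invalid_rows[ib]
                   for m in measures}
        for m in measures:
            obs[m][invalid[m]] = np.nan

        # shared permutation stream
        rng = np.random.default_rng(derive_seed(self.random_state, "permutations"))
        n_perm = int(self.n_permutations)
        null = {m: np.empty((n_perm, n_pairs), dtype=np.float32) for m in measures}
        for k in range(n_perm):
            perm = rng.permutation(n)
            for m in measures:
                null[m][k] = self._pair_scores(m, preps[m], ia, ib, perm)

        # per-measure raw p and direction
        raw_p = np.full((len(measures), n_pairs), np.nan)
        dir_sign = np.zeros((len(measures), n_pairs), dtype=np.int8)
        null_mean = np.full((len(measures), n_pairs), np.nan)
        for mi_, m in enumerate(measures):
            nm = null[m].astype(np.float64, copy=False)
            mu = nm.mean(axis=0)
            null_mean[mi_] = mu
            o = obs[m]
            fam = FAMILY[m]
            sd = nm.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(sd > 0, np.abs(o - mu) / np.where(sd > 0, sd, 1.0),
                             0.0)
                p_par = 2.0 * stats.norm.sf(z)
                p_par = np.maximum(p_par, np.finfo(float).tiny)
                if fam in ("corr", "mi"):
                    cnt = (np.abs(nm - mu) >= np.abs(o - mu)).sum(axis=0)
                    pv = (1.0 + cnt) / (n_perm + 1)
                    # beyond the permutation resolution: normal-tail refinement
                    ext = (cnt == 0) & (sd > 0)
                    pv = np.where(ext, np.minimum(pv, p_par), pv)
                    if fam == "corr":
                        dir_sign[mi_] = np.where(o > 0, 1, -1)
                    else:
                        dir_sign[mi_] = np.where(o >= mu, 1, -1)
                else:
                    le = (nm <= o).sum(axis=0)
                    ge = (nm >= o).sum(axis=0)
                    lower = o <= mu
                    cnt = np.where(lower, le, ge)
                    pv = np.minimum(2.0 * (1.0 + cnt) / (n_perm + 1), 1.0)
                    ext = (cnt == 0) & (sd > 0)
                    pv = np.where(ext, np.minimum(pv, p_par), pv)
                    dir_sign[mi_] = np.where(lower, 1, -1)
            pv = np.where(np.isfinite(o), pv, np.nan)
            dir_sign[mi_][~np.isfinite(o)] = 0
            raw_p[mi_] = pv

        # support and consensus direction
        sup = (raw_p < self.measure_support_p) & np.isfinite(raw_p)
        n_pos = (sup & (dir_sign > 0)).sum(axis=0)
        n_neg = (sup & (dir_sign < 0)).sum(axis=0)
        consensus = np.where(n_pos > n_neg, 1, np.where(n_neg > n_pos, -1, 0))
        conflict = (consensus == 0) & ((n_pos + n_neg) > 0)
        support_count = np.where(consensus > 0, n_pos,
                                 np.where(consensus < 0, n_neg, 0))

        # Brown covariance from pseudo-p of the shared permutation nulls
        t_arr = np.empty((len(measures), n_perm, n_pairs), dtype=np.float32)
        for mi_, m in enumerate(measures):
            pp = _pseudo_p(null[m].astype(np.float64, copy=False), FAMILY[m])
            t_arr[mi_] = (-2.0 * np.log(pp)).astype(np.float32)
        t_arr -= t_arr.mean(axis=1, keepdims=True)
        k_meas = len(measures)
        cov_pairs = np.empty((k_meas, k_meas, n_pairs), dtype=np.float64)
        chunk = 20000
        for s0 in range(0, n_pairs, chunk):
            s1 = min(s0 + chunk, n_pairs)
            blk = t_arr[:, :, s0:s1].astype(np.float64)
            cov_pairs[:, :, s0:s1] = np.einsum(
                "mkp,lkp->mlp", blk, blk) / max(n_perm - 1, 1)
        # rescale diagonals to the theoretical 4
        d = np.sqrt(np.einsum("mmp->mp", cov_pairs))
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = d[:, None, :] * d[None, :, :]
            cov_pairs = np.where(denom > 0, 4.0 * cov_pairs / denom, 0.0)
        for mi_ in range(k_meas):
            cov_pairs[mi_, mi_, :] = 4.0

        # merged p per pair over its defined measures
        defined = np.isfinite(raw_p)
        merged = np.full(n_pairs, np.nan)
        all_def = defined.all(axis=0)
        if all_def.any():
            logp = np.log(np.maximum(raw_p[:, all_def], np.finfo(float).tiny))
            psi = -2.0 * logp.sum(axis=0)
            var = cov_pairs[:, :, all_def].sum(axis=(0, 1))
            e = 2.0 * k_meas
            c = var / (2.0 * e)
            f = 2.0 * e * e / var
            merged[all_def] = stats.chi2.sf(psi / c, f)
        partial = ~all_def & defined.any(axis=0)
        for j in np.flatnonzero(partial):
            sel = defined[:, j]
            merged[j] = brown_merge(
                raw_p[sel, j], cov_pairs[np.ix_(sel, sel, [j])][:, :, 0])

        adjusted = bh_adjust(merged)

        candidate = (
            (support_count >= self.min_support)
            & ~conflict
            & np.isfinite(adjusted)
            & (adjusted < self.alpha)
        )
        if self.min_abs_consensus is not None:
            corr_rows = [i for i, m in enumerate(measures) if FAMILY[m] == "corr"]
            if corr_rows:
                cscore = np.nanmax(
                    np.where(sup[corr_rows], np.abs(
                        np.vstack([obs[measures[i]] for i in corr_rows])), 0.0),
                    axis=0)
                candidate &= cscore >= self.min_abs_consensus

        # bootstrap stability for candidate edges only (the last gate; pairs
        # failing earlier gates can never become edges, so skipping their
        # bootstrap leaves the result set unchanged)
        rows = []
        for j in np.flatnonzero(candidate):
            a, b = ids[ia[j]], ids[ib[j]]
            n_stable = 0
            for mi_, m in enumerate(measures):
                if not (sup[mi_, j] and dir_sign[mi_, j] == consensus[j]):
                    continue
                seed = derive_seed(self.random_state, f"boot:{a}|{b}|{m}")
                ok = bootstrap_stability(
                    X[ia[j]], X[ib[j]], m, int(self.n_bootstraps),
                    null_mean[mi_, j], seed=seed,
                    kl_pseudocount=self.kl_pseudocount, mi_bins=self.mi_bins)
                n_stable += int(ok)
            stable = n_stable >= self.min_support
            if not stable:
                continue
            row = {
                "otu_a": a,
                "otu_b": b,
                "direction": "positive" if consensus[j] > 0 else "negative",
                "support_count": int(support_count[j]),
                "merged_p": merged[j],
                "adjusted_p": adjusted[j],
                "stable": True,
            }
            for mi_, m in enumerate(measures):
                row[f"{m}_score"] = obs[m][j]
                row[f"{m}_p"] = raw_p[mi_, j]
            rows.append(row)

        self.edges_ = (pd.DataFrame(rows) if rows else _empty_edges(measures))
        self.graph_ = _to_graph(ids, self.edges_)
        return self


def _empty_edges(measures) -> pd.DataFrame:
    cols = ["otu_a", "otu_b", "direction", "support_count",
            "merged_p", "adjusted_p", "stable"]
    cols += [f"{m}_{s}" for m in measures for s in ("score", "p")]
    return pd.DataFrame(columns=cols)


def _to_graph(nodes, edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for _, r in edges.iterrows():
        g.add_edge(r["otu_a"], r["otu_b"],
                   direction=r["direction"],
                   support_count=int(r["support_count"]),
                   merged_p=float(r["merged_p"]),
                   adjusted_p=float(r["adjusted_p"]))
    return g


def infer_network(table: OtuTable, config=None, **kwargs):
    """Functional wrapper around :class:`EnsembleNetworkInference`.

    Returns the fitted estimator (edges in ``.edges_``, graph in
    ``.graph_``).
    """
    est = config if isinstance(config, EnsembleNetworkInference) else EnsembleNetworkInference()
    if kwargs:
        est = est.set_params(**kwargs)
    return est.fit(table)


def write_edges_tsv(est: EnsembleNetworkInference, path) -> None:
    est.edges_.to_csv(path, sep="\t", index=False)


def write_graphml(est: EnsembleNetworkInference, path) -> None:
    nx.write_graphml(est.graph_, path)
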