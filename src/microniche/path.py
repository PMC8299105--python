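"""Standardized path analysis over a declared acyclic diagram.

The covariance-based SEM of the source study is reduced to observed-variable
path analysis: every column is z-scored, each endogenous variable is
regressed (OLS) on its declared parents, and the standardized total effect
of a source on a target is the sum over all directed paths of the products
of edge coefficients, accumulated in topological order. Composite variables
(e.g. a "carbon" block built from SOC and DOC) are represented by the first
principal-component score of their standardized indicators, with the sign
fixed so the loading sum is positive. Edge/total-effect significance comes
from a nonparametric bootstrap (rows resampled with replacement, the whole
procedure refit).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.base import BaseEstimator

from ._utils import derive_seed

_COND_LIMIT = 1e8


def _pc1_score(block: pd.DataFrame) -> np.ndarray:
    """First principal-component score of z-scored indicators, z-scored.

    Sign convention: the sum of loadings is positive (falls back to the
    first indicator's loading when the sum is zero).
    """
    z = (block - block.mean()) / block.std(ddof=0)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    load = vt[0]
    sign = np.sign(load.sum()) or np.sign(load[0]) or 1.0
    score = z.to_numpy() @ (sign * load)
    return (score - score.mean()) / score.std()


class PathAnalysis(BaseEstimator):
    """Fit standardized path coefficients and total effects on a DAG.

    Parameters
    ----------
    edges : sequence of (parent, child)
        The declared acyclic diagram over observed/composite variables.
    composites : dict, optional
        name -> list of indicator columns; each composite becomes the
        sign-fixed first principal-component score of its indicators.

    Attributes
    ----------
    coefficients_ : dict (parent, child) -> float
        Standardized OLS path coefficients.
    r_squared_ : dict node -> float
        Explained variance of each endogenous node.
    total_effects_ : dict (source, target) -> float
        Standardized total effects (sum over directed paths of coefficient
        products); a node's effect on itself is 1, absent paths give 0.
    """

    def __init__(self, edges=(), composites: dict | None = None):
        self.edges = edges
        self.composites = composites

    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from((str(a), str(b)) for a, b in self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("declared path diagram contains a cycle")
        return g

    def _design(self, data: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for name, indicators in (self.composites or {}).items():
            missing = [c for c in indicators if c not in data.columns]
            if missing:
                raise ValueError(f"composite {name!r}: missing columns {missing}")
            cols[name] = _pc1_score(data[indicators])
        out = data.copy()
        for name, series in cols.items():
            out[name] = series
        return out

    def fit(self, data: pd.DataFrame):
        g = self._graph()
        data = self._design(pd.DataFrame(data))
        for v in g.nodes():
            if v not in data.columns:
                raise ValueError(f"variable {v!r} not found in the data")
        z = {}
        for v in g.nodes():
            col = data[v].to_numpy(dtype=float)
            sd = col.std()
            if sd == 0:
                raise ValueError(f"variable {v!r} has zero variance")
            z[v] = (col - col.mean()) / sd
        n = len(data)

        coefficients, r_squared = {}, {}
        for node in g.nodes():
            parents = list(g.predecessors(node))
            if not parents:
                continue
            if n <= len(parents) + 1:
                raise ValueError(
                    f"{node}: need n > number of parents + 1 to fit")
            xmat = np.column_stack([z[p] for p in parents])
            cond = np.linalg.cond(xmat.T @ xmat / n)
            if cond > _COND_LIMIT:
                corr = np.corrcoef(xmat.T)
                i, j = divmod(int(np.argmax(np.abs(corr - np.eye(len(parents))))),
                              len(parents))
                raise ValueError(
                    f"{node}: collinear parents ({parents[i]!r}, {parents[j]!r})")
            beta, *_ = np.linalg.lstsq(xmat, z[node], rcond=None)
            for p, b in zip(parents, beta):
                coefficients[(p, node)] = float(b)
            resid = z[node] - xmat @ beta
            r_squared[node] = float(1.0 - (resid @ resid) / (z[node] @ z[node]))

        self.coefficients_ = coefficients
        self.r_squared_ = r_squared
        self.graph_ = g
        self.n_ = n
        self.variables_ = list(g.nodes())
        self.total_effects_ = self._totals(g, coefficients)
        return self

    @staticmethod
    def _totals(g: nx.DiGraph, coefficients: dict) -> dict:
        order = list(nx.topological_sort(g))
        totals = {}
        for src in order:
            eff = {src: 1.0}
            for node in order:
                if node == src:
                    continue
                val = 0.0
                for p in g.predecessors(node):
                    val += coefficients.get((p, node), 0.0) * eff.get(p, 0.0)
                eff[node] = val
            for tgt in order:
                totals[(src, tgt)] = eff.get(tgt, 0.0)
        return totals

    def total_effect(self, source: str, target: str) -> float:
        if (source, target) not in self.total_effects_:
            raise KeyError(f"unknown variable pair ({source!r}, {target!r})")
        return self.total_effects_[(source, target)]

    def bootstrap_significance(self, data: pd.DataFrame, n_bootstrap: int = 1000,
                               seed: int = 0):
        """Two-sided bootstrap p for every edge coefficient and total effect.

        Rows are resampled with replacement and the whole fit (composites
        included) is repeated; p = 2 * min(#{b <= 0}+1, #{b >= 0}+1) /
        (B + 1), capped at 1. More than 10% failed refits is an error.
        """
        if n_bootstrap < 200:
            raise ValueError("n_bootstrap must be >= 200")
        data = pd.DataFrame(data)
        rng = np.random.default_rng(derive_seed(seed, "path-bootstrap"))
        n = len(data)
        coef_samples = {e: [] for e in self.coefficients_}
        tot_samples = {st: [] for st in self.total_effects_}
        failures = 0
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            try:
                boot = PathAnalysis(self.edges, self.composites).fit(
                    data.iloc[idx].reset_index(drop=True))
            except (ValueError, np.linalg.LinAlgError):
                failures += 1
                continue
            for e in coef_samples:
                coef_samples[e].append(boot.coefficients_.get(e, np.nan))
            for st in tot_samples:
                tot_samples[st].append(boot.total_effects_.get(st, np.nan))
        if failures > 0.1 * n_bootstrap:
            raise RuntimeError(
                f"{failures}/{n_bootstrap} bootstrap refits failed")

        def pval(samples):
            s = np.asarray(samples, dtype=float)
            s = s[np.isfinite(s)]
            b = s.size
            lo = (s <= 0).sum() + 1
            hi = (s >= 0).sum() + 1
            return min(1.0, 2.0 * min(lo, hi) / (b + 1))

        self.coefficient_p_ = {e: pval(v) for e, v in coef_samples.items()}
        self.total_effect_p_ = {st: pval(v) for st, v in tot_samples.items()
                                if st[0] != st[1]}
        return self.coefficient_p_, self.total_effect_p_


# ---------------------------------------------------------------------------
# functional wrappers and DAG text format
# ---------------------------------------------------------------------------


def fit_paths(data: pd.DataFrame, dag, composites: dict | None = None) -> PathAnalysis:
    """Fit a :class:`PathAnalysis` on ``data`` over the declared edges."""
    return PathAnalysis(edges=list(dag), composites=composites).fit(data)


def total_effects(model: PathAnalysis) -> dict:
    """Standardized total effects of a fitted path model."""
    return dict(model.total_effects_)


def effect_significance(model: PathAnalysis, data, n_bootstrap: int = 1000,
                        seed: int = 0):
    """Bootstrap p-values of a fitted model's edges and total effects."""
    return model.bootstrap_significance(data, n_bootstrap=n_bootstrap, seed=seed)


def parse_dag_file(path):
    """Parse the flat DAG declaration: ``parent -> child`` per line,
    composites as ``name = ind1 + ind2``; '#' starts a comment.

    Returns ``(edges, composites)``.
    """
    edges, composites = [], {}
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "->" in line:
                a, b = (s.strip() for s in line.split("->", 1))
                if not a or not b:
                    raise ValueError(f"line {ln}: malformed edge {raw!r}")
                edges.append((a, b))
            elif "=" in line:
                name, rhs = (s.strip() for s in line.split("=", 1))
                inds = [s.strip() for s in rhs.split("+") if s.strip()]
                if not name or not inds:
                    raise ValueError(f"line {ln}: malformed composite {raw!r}")
                composites[name] = inds
            else:
                raise ValueError(f"line {ln}: cannot parse {raw!r}")
    return edges, composites


def write_effects_tsv(model: PathAnalysis, path) -> None:
    rows = []
    for (a, b), c in sorted(model.coefficients_.items()):
        rows.append({"kind": "edge", "source": a, "target": b, "value": c,
                     "p": getattr(model, "coefficient_p_", {}).get((a, b), np.nan)})
    for (a, b), c in sorted(model.total_effects_.items()):
        if a == b:
            continue
        rows.append({"kind": "total", "source": a, "target": b, "value": c,
                     "p": getattr(model, "total_effect_p_", {}).get((a, b), np.nan)})
    for v, r2 in sorted(model.r_squared_.items()):
        rows.append({"kind": "r_squared", "source": v, "target": "", "value": r2,
                     "p": np.nan})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
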