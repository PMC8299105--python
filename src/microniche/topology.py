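"""Node-level topology of the co-occurrence network.

Centralities (degree, closeness, betweenness, eigenvector), Louvain modules
with the Guimera-Amaral within-module degree z-score (Zi) and participation
coefficient (Pi) node roles, the B-value ~ centrality regressions, and the
one-way ANOVA (with Tukey HSD compact letters) comparing node degree across
niche groups.

Conventions for disconnected graphs (the norm for co-occurrence networks):
closeness uses the Wasserman-Faust component scaling, so values remain
comparable across components; eigenvector centrality is computed on the full
graph by power iteration, where mass concentrates on the component(s) with
the largest spectral radius; isolated nodes score 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

#: Guimera-Amaral role cutoffs in the (Zi, Pi) plane.
ZI_CUTOFF = 2.5
PI_CUTOFF = 0.62


def _as_graph(graph_or_edges, nodes=None) -> nx.Graph:
    if isinstance(graph_or_edges, nx.Graph):
        g = graph_or_edges
    else:
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        g.add_edges_from(graph_or_edges)
    for u, v in g.edges():
        if u == v:
            raise ValueError(f"self-loop at node {u!r}")
    return g


def degree(edges, nodes=None) -> dict:
    """Incident-edge count per node of a simple undirected graph."""
    g = _as_graph(edges, nodes)
    return dict(g.degree())


def closeness(graph) -> dict:
    """Component-scaled closeness: ((k-1)/sum d) * ((k-1)/(n-1)); isolated 0."""
    g = _as_graph(graph)
    if g.number_of_nodes() == 0:
        return {}
    return nx.closeness_centrality(g, wf_improved=True)


def betweenness(graph) -> dict:
    """Betweenness centrality normalized by (n-1)(n-2)/2 pair counts."""
    g = _as_graph(graph)
    return nx.betweenness_centrality(g, normalized=True)


def eigenvector_centrality(graph, tol: float = 1e-10, max_iter: int = 100_000) -> dict:
    """Dominant adjacency eigenvector by power iteration, max-normalized.

    Starts from the uniform positive vector; convergence is declared when
    the normalized iterate changes by less than ``tol`` in the sup norm.
    An edgeless graph has no meaningful dominant eigenvector; all nodes
    score 0 by convention.
    """
    g = _as_graph(graph)
    nodes = list(g.nodes())
    if not nodes:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        return {v: 0.0 for v in nodes}
    # iterate on A + I: same eigenvectors, but the spectral shift breaks the
    # +/-lambda tie of bipartite components that would make plain power
    # iteration oscillate
    a = nx.to_numpy_array(g, nodelist=nodes) + np.eye(g.number_of_nodes())
    v = np.ones(len(nodes))
    v /= np.linalg.norm(v)
    for it in range(int(max_iter)):
        w = a @ v
        w /= np.linalg.norm(w)
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    else:
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} iterations")
    v = np.abs(v)
    v /= v.max()
    return {node: float(val) for node, val in zip(nodes, v)}


def detect_modules(graph, seed: int = 0):
    """Louvain modularity partition at resolution 1.0.

    Returns ``(module_id mapping, modularity Q)``. Module ids are assigned
    deterministically (largest module first, ties by smallest node label).
    """
    g = _as_graph(graph)
    if g.number_of_edges() == 0:
        raise ValueError("cannot detect modules on a graph without edges")
    comms = nx.community.louvain_communities(g, seed=seed, resolution=1.0)
    q = nx.community.modularity(g, comms)
    comms = sorted(comms, key=lambda c: (-len(c), min(str(v) for v in c)))
    assignment = {}
    for i, c in enumerate(comms):
        for v in c:
            assignment[v] = i
    return assignment, float(q)


def zi_pi(graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi), participation (Pi), and role.

    Roles follow the standard (Zi, Pi) plane cutoffs 2.5 / 0.62:
    module hub (high Zi, low Pi), connector (low Zi, high Pi), kinless
    (both high), peripheral otherwise. Zero-degree nodes get Pi = 0; a
    module whose within-degrees have zero spread gives Zi = 0.
    """
    g = _as_graph(graph)
    nodes = list(g.nodes())
    within = {}
    for v in nodes:
        counts = {}
        for u in g.neighbors(v):
            counts[modules[u]] = counts.get(modules[u], 0) + 1
        within[v] = counts
    own = {v: within[v].get(modules[v], 0) for v in nodes}
    by_module = {}
    for v in nodes:
        by_module.setdefault(modules[v], []).append(own[v])
    mstats = {m: (np.mean(ks), np.std(ks)) for m, ks in by_module.items()}
    rows = []
    for v in nodes:
        k = g.degree(v)
        mean, sd = mstats[modules[v]]
        zi = 0.0 if sd == 0 else (own[v] - mean) / sd
        pi = 0.0 if k == 0 else 1.0 - sum(
            (c / k) ** 2 for c in within[v].values())
        if zi >= ZI_CUTOFF and pi <= PI_CUTOFF:
            role = "module_hub"
        elif zi < ZI_CUTOFF and pi > PI_CUTOFF:
            role = "connector"
        elif zi >= ZI_CUTOFF and pi > PI_CUTOFF:
            role = "kinless"
        else:
            role = "peripheral"
        rows.append({"node": v, "module_id": modules[v], "Zi": zi,
                     "Pi": pi, "role": role})
    return pd.DataFrame(rows).set_index("node")


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress(x, y) -> RegressionSummary:
    """OLS of y on x with the slope's t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression input")
    if x.std() == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    letters: dict
    group_means: dict
    excluded: list


def compare_degree_groups(values, labels, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA on per-node values across niche groups + Tukey letters.

    Groups with fewer than 2 members are excluded (with a warning). Groups
    sharing a compact-display letter are not significantly different at
    ``alpha`` by Tukey's HSD.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    groups = {}
    for v, l in zip(values, labels):
        groups.setdefault(l, []).append(v)
    excluded = [g for g, vs in groups.items() if len(vs) < 2]
    for g in excluded:
        warnings.warn(f"group {g!r} has < 2 members; excluded from ANOVA")
        del groups[g]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    names = sorted(groups)
    arrs = [np.asarray(groups[g]) for g in names]
    grand = np.concatenate(arrs).mean()
    n_tot = sum(a.size for a in arrs)
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    dfb = len(arrs) - 1
    dfw = n_tot - len(arrs)
    msb = ssb / dfb
    msw = ssw / dfw if dfw > 0 else 0.0
    if msb == 0:
        f, p = 0.0, 1.0
    elif msw == 0:
        f, p = float("inf"), 0.0
    else:
        f = msb / msw
        p = float(stats.f.sf(f, dfb, dfw))
    letters = _tukey_letters(arrs, names, msw, dfw, alpha)
    return GroupComparison(
        f_statistic=float(f),
        p_value=float(p),
        letters=letters,
        group_means={g: float(a.mean()) for g, a in zip(names, arrs)},
        excluded=excluded,
    )


def _tukey_letters(arrs, names, msw, dfw, alpha) -> dict:
    """Compact letter display from pairwise Tukey HSD tests."""
    k = len(names)
    means = [a.mean() for a in arrs]
    sizes = [a.size for a in arrs]
    differ = np.zeros((k, k), dtype=bool)
    if msw > 0:
        qcrit = stats.studentized_range.ppf(1 - alpha, k, dfw)
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(msw / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
                q = abs(means[i] - means[j]) / se
                differ[i, j] = differ[j, i] = q > qcrit
    else:
        for i in range(k):
            for j in range(i + 1, k):
                differ[i, j] = differ[j, i] = means[i] != means[j]
    # insert-and-absorb: letters = maximal sets of mutually non-different
    # groups, assigned in descending mean order
    order = np.argsort([-m for m in means], kind="stable")
    letter_sets: list[set] = []
    for gi in order:
        placed = False
        for s in letter_sets:
            if all(not differ[gi, gj] for gj in s):
                s.add(gi)
                placed = True
        if not placed:
            letter_sets.append({gi})
    # drop subsets
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(i != j and s < t for j, t in enumerate(letter_sets))]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for li, s in enumerate(letter_sets):
        for gi in sorted(s):
            out[names[gi]] += alphabet[li % len(alphabet)]
    return {name: "".join(sorted(v)) for name, v in out.items()}


class NetworkTopology(BaseEstimator):
    """Compute the per-node topology report of a co-occurrence network.

    Parameters
    ----------
    random_state : int
        Seed for the Louvain module detection.
    use_giant_component : bool
        Restrict all statistics to the largest connected component.
    ec_per_component : bool
        Max-normalize eigenvector centrality within each component instead
        of over the full graph.

    Attributes
    ----------
    report_ : pandas.DataFrame indexed by node
        degree, closeness, betweenness, eigenvector centrality, module id,
        Zi, Pi, role (plus niche label and B if supplied to :meth:`fit`).
    modularity_ : float
        Modularity Q of the detected partition (NaN for edgeless graphs).
    """

    def __init__(self, random_state: int = 0, use_giant_component: bool = False,
                 ec_per_component: bool = False):
        self.random_state = random_state
        self.use_giant_component = use_giant_component
        self.ec_per_component = ec_per_component

    def fit(self, graph, niche_results: pd.DataFrame | None = None):
        g = _as_graph(graph)
        if self.use_giant_component and g.number_of_nodes():
            comps = list(nx.connected_components(g))
            if comps:
                g = g.subgraph(max(comps, key=len)).copy()
        nodes = list(g.nodes())
        deg = dict(g.degree())
        clo = closeness(g)
        bet = betweenness(g)
        if self.ec_per_component and g.number_of_nodes():
            ec = {}
            for comp in nx.connected_components(g):
                ec.update(eigenvector_centrality(g.subgraph(comp)))
        else:
            ec = eigenvector_centrality(g) if nodes else {}
        if g.number_of_edges() > 0:
            modules, q = detect_modules(g, seed=self.random_state)
        else:
            modules, q = {v: i for i, v in enumerate(nodes)}, float("nan")
        zp = zi_pi(g, modules) if nodes else pd.DataFrame(
            columns=["module_id", "Zi", "Pi", "role"])
        report = pd.DataFrame(
            {
                "degree": [deg[v] for v in nodes],
                "closeness": [clo[v] for v in nodes],
                "betweenness": [bet[v] for v in nodes],
                "eigenvector_centrality": [ec[v] for v in nodes],
                "module_id": [modules[v] for v in nodes],
            },
            index=pd.Index(nodes, name="node"),
        )
        report = report.join(zp[["Zi", "Pi", "role"]])
        if niche_results is not None:
            cols = [c for c in ("B_global", "label") if c in niche_results.columns]
            report = report.join(niche_results[cols], how="left")
        self.report_ = report
        self.modularity_ = q
        self.graph_ = g
        return self
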