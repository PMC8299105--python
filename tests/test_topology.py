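import itertools

import networkx as nx
import numpy as np
import pytest

from microniche import (degree, closeness, betweenness,
                        eigenvector_centrality, detect_modules, zi_pi,
                        regress, compare_degree_groups, NetworkTopology)


def star(n):
    g = nx.Graph()
    g.add_edges_from(("c", f"l{i}") for i in range(n - 1))
    return g


# ---------------------------------------------------------------------------
# independent brute-force oracles (exhaustive path enumeration / dense eigen)
# ---------------------------------------------------------------------------


def brute_distances(g):
    nodes = list(g.nodes())
    dist = {s: {t: (0 if s == t else np.inf) for t in nodes} for s in nodes}
    for u, v in g.edges():
        dist[u][v] = dist[v][u] = 1
    for k in nodes:          # Floyd-Warshall
        for i in nodes:
            for j in nodes:
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return dist


def brute_closeness(g):
    nodes = list(g.nodes())
    n = len(nodes)
    dist = brute_distances(g)
    out = {}
    for v in nodes:
        reach = [d for u, d in dist[v].items() if u != v and np.isfinite(d)]
        k = len(reach) + 1
        if not reach or n < 2:
            out[v] = 0.0
        else:
            out[v] = ((k - 1) / sum(reach)) * ((k - 1) / (n - 1))
    return out


def brute_betweenness(g):
    """Enumerate every simple path; count geodesics through each vertex."""
    nodes = list(g.nodes())
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        inner = [v for v in nodes if v not in (s, t)]
        for r in range(len(inner) + 1):
            for mid in itertools.permutations(inner, r):
                seq = (s, *mid, t)
                if all(g.has_edge(a, b) for a, b in zip(seq, seq[1:])):
                    paths.append(seq)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geos = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in geos if v in p)
            score[v] += through / len(geos)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: (s / norm if norm > 0 else 0.0) for v, s in score.items()}


def brute_eigenvector(g):
    nodes = list(g.nodes())
    a = nx.to_numpy_array(g, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, np.argmax(w)])
    vec /= vec.max()
    return dict(zip(nodes, vec))


def random_connected_graph(rng, max_nodes=7):
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        g = nx.gnp_random_graph(n, rng.uniform(0.3, 0.9),
                                seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            return g


class TestCentralityClosedForms:
    def test_degree_star_and_triangle(self):
        g = star(4)
        d = degree(g)
        assert d["c"] == 3 and all(d[f"l{i}"] == 1 for i in range(3))
        tri = nx.complete_graph(3)
        assert set(degree(tri).values()) == {2}

    def test_degree_rejects_self_loop(self):
        g = nx.Graph([("a", "a")])
        with pytest.raises(ValueError, match="self-loop"):
            degree(g)

    def test_closeness_path_interior(self):
        g = nx.path_graph(["a", "b", "c"])
        assert closeness(g)["b"] == pytest.approx(1.0)

    def test_closeness_isolated_zero_complete_one(self):
        g = nx.complete_graph(4)
        g.add_node("iso")
        c = closeness(g)
        assert c["iso"] == 0.0
        # component scaling: complete-graph nodes at (3/3)*(3/4)
        assert c[0] == pytest.approx(0.75)
        assert closeness(nx.complete_graph(4))[0] == pytest.approx(1.0)

    def test_betweenness_closed_forms(self):
        path = nx.path_graph(["a", "b", "c"])
        assert betweenness(path)["b"] == pytest.approx(1.0)
        tri = nx.complete_graph(3)
        assert all(v == 0.0 for v in betweenness(tri).values())
        s5 = star(5)
        assert betweenness(s5)["c"] == pytest.approx(1.0)

    def test_eigenvector_star_closed_form(self):
        g = star(5)
        ec = eigenvector_centrality(g)
        assert ec["c"] == pytest.approx(1.0)
        for i in range(4):
            assert ec[f"l{i}"] == pytest.approx(1 / np.sqrt(4), abs=1e-8)

    def test_eigenvector_complete_graph_uniform(self):
        ec = eigenvector_centrality(nx.complete_graph(5))
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in ec.values())


class TestCentralityOracles:
    def test_all_centralities_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            g = random_connected_graph(rng)
            c = closeness(g)
            bc = brute_closeness(g)
            b = betweenness(g)
            bb = brute_betweenness(g)
            e = eigenvector_centrality(g)
            be = brute_eigenvector(g)
            d = degree(g)
            for v in g.nodes():
                assert c[v] == pytest.approx(bc[v], abs=1e-8)
                assert b[v] == pytest.approx(bb[v], abs=1e-8)
                assert e[v] == pytest.approx(be[v], abs=1e-7)
                assert d[v] == sum(1 for _ in g.neighbors(v))


class TestModules:
    def test_two_triangles_q_half(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        modules, q = detect_modules(g, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(modules.values())) == 2
        assert modules[0] == modules[1] == modules[2]
        assert modules[3] == modules[4] == modules[5]

    def test_complete_graph_single_module(self):
        modules, _ = detect_modules(nx.complete_graph(6), seed=1)
        assert len(set(modules.values())) == 1

    def test_deterministic_under_seed(self):
        g = nx.gnp_random_graph(30, 0.15, seed=5)
        g.remove_nodes_from(list(nx.isolates(g)))
        m1, q1 = detect_modules(g, seed=42)
        m2, q2 = detect_modules(g, seed=42)
        assert m1 == m2 and q1 == q2

    def test_q_matches_definition(self):
        g = nx.gnp_random_graph(25, 0.2, seed=3)
        g.remove_nodes_from(list(nx.isolates(g)))
        modules, q = detect_modules(g, seed=7)
        # recompute Q from its definition
        m = g.number_of_edges()
        q_def = 0.0
        for u in g.nodes():
            for v in g.nodes():
                if modules[u] != modules[v]:
                    continue
                a = 1.0 if g.has_edge(u, v) else 0.0
                q_def += a - g.degree(u) * g.degree(v) / (2.0 * m)
        q_def /= 2.0 * m
        assert q == pytest.approx(q_def, abs=1e-12)

    def test_edgeless_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        with pytest.raises(ValueError):
            detect_modules(g, seed=0)


class TestZiPi:
    def test_all_links_inside_module_pi_zero(self):
        g = nx.complete_graph(4)
        modules = {v: 0 for v in g.nodes()}
        zp = zi_pi(g, modules)
        assert (zp["Pi"] == 0.0).all()
        assert (zp["Zi"] == 0.0).all()    # equal within-degrees

    def test_two_modules_participation(self):
        g = nx.Graph([("x", "a"), ("x", "b")])
        modules = {"x": 0, "a": 1, "b": 2}
        zp = zi_pi(g, modules)
        assert zp.loc["x", "Pi"] == pytest.approx(0.5)

    def test_hub_role_assignment(self):
        # one node linked to every member of its big module
        g = star(12)
        g.add_edges_from([(f"l{i}", f"l{i+1}") for i in range(0, 10, 2)])
        modules = {v: 0 for v in g.nodes()}
        zp = zi_pi(g, modules)
        assert zp.loc["c", "Zi"] >= 2.5
        assert zp.loc["c", "role"] == "module_hub"


class TestRegress:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3])
        r = regress(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_orthogonal_zero_slope(self):
        x = np.array([-1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0])      # symmetric -> slope 0
        r = regress(x, y)
        assert r.slope == pytest.approx(0.0)
        assert r.r_squared == pytest.approx(0.0)

    def test_hand_computed_example(self):
        r = regress([1, 2, 3], [1, 3, 2])
        assert r.slope == pytest.approx(0.5)
        assert r.r_squared == pytest.approx(0.25)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            regress([1, 1, 1], [1, 2, 3])


class TestCompareDegreeGroups:
    def test_identical_groups_f_zero_shared_letter(self):
        res = compare_degree_groups([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.f_statistic == 0.0
        assert res.letters["a"] == res.letters["b"]

    def test_separated_groups_known_f(self):
        res = compare_degree_groups([1, 2, 3, 101, 102, 103],
                                    ["lo"] * 3 + ["hi"] * 3)
        assert res.f_statistic == pytest.approx(15000.0)
        assert set(res.letters["lo"]) != set(res.letters["hi"])

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        from scipy.stats import f_oneway
        a, b, c = rng.random(10), rng.random(12) + 0.5, rng.random(8)
        res = compare_degree_groups(
            np.concatenate([a, b, c]),
            ["a"] * 10 + ["b"] * 12 + ["c"] * 8)
        f_ref, p_ref = f_oneway(a, b, c)
        assert res.f_statistic == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_singleton_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = compare_degree_groups([1, 2, 3, 4, 9],
                                        ["a", "a", "b", "b", "solo"])
        assert res.excluded == ["solo"]

    def test_null_f_centered_near_one(self):
        rng = np.random.default_rng(1)
        fs = []
        for _ in range(200):
            v = rng.random(30)
            labels = rng.permutation(["a"] * 15 + ["b"] * 15)
            fs.append(compare_degree_groups(v, labels).f_statistic)
        # mean of F(1, 28) is dfw/(dfw-2) ~ 1.08
        assert 0.7 < np.mean(fs) < 1.6


class TestNetworkTopologyEstimator:
    def test_report_fields_and_shapes(self):
        g = nx.gnp_random_graph(20, 0.2, seed=2)
        topo = NetworkTopology(random_state=0).fit(g)
        rep = topo.report_
        assert len(rep) == 20
        for col in ("degree", "closeness", "betweenness",
                    "eigenvector_centrality", "module_id", "Zi", "Pi", "role"):
            assert col in rep.columns
        assert rep["eigenvector_centrality"].max() == pytest.approx(1.0)
        # degree decomposes over modules
        assert (rep["degree"] >= 0).all()
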