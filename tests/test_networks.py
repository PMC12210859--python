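from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from amplistat import (FeatureTable, CorrelationMatrix, sparcc,
                       edge_significance, build_network, mcode_cores,
                       backbone, functional_group)
from amplistat.networks import CorrelationNetwork


def counts_table(arr, prefix="t"):
    arr = np.asarray(arr)
    return FeatureTable(pd.DataFrame(
        arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])]))


def lognormal_counts(rng, d, n, depth=30_000, cov=None, sigma=1.0):
    mean = rng.normal(0, 1.5, d)
    if cov is None:
        z = rng.normal(0, 1, size=(d, n))
    else:
        z = np.linalg.cholesky(cov + 1e-10 * np.eye(d)) @ rng.normal(0, 1, (d, n))
    lam = np.exp(mean[:, None] + sigma * z)
    out = np.empty((d, n), dtype=int)
    for s in range(n):
        out[:, s] = rng.multinomial(depth, lam[:, s] / lam[:, s].sum())
    return counts_table(out)


class TestSparcc:
    def test_three_taxa_closed_form_oracle(self):
        """D=3 basis variances have the closed form
        w_i = (t_ij + t_ik - t_jk) / 2; the linear-system solve must agree."""
        rng = np.random.default_rng(0)
        t = lognormal_counts(rng, 3, 40)
        est = sparcc(t, resample=False)
        frac = (t.counts + 1) / (t.counts + 1).sum(axis=0, keepdims=True)
        logf = np.log(frac)
        tv = np.zeros((3, 3))
        for i, j in combinations(range(3), 2):
            tv[i, j] = tv[j, i] = np.var(logf[i] - logf[j], ddof=1)
        w = np.array([
            (tv[0, 1] + tv[0, 2] - tv[1, 2]) / 2,
            (tv[0, 1] + tv[1, 2] - tv[0, 2]) / 2,
            (tv[0, 2] + tv[1, 2] - tv[0, 1]) / 2])
        for i, j in combinations(range(3), 2):
            expected = (w[i] + w[j] - tv[i, j]) / (2 * np.sqrt(w[i] * w[j]))
            assert est.rho[i, j] == pytest.approx(np.clip(expected, -1, 1),
                                                  abs=1e-9)

    def test_independent_taxa_null_correlations_small(self):
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            t = lognormal_counts(rng, 11, 200)
            est = sparcc(t, n_iterations=10, seed=seed)
            off = np.abs(est.rho[np.triu_indices(11, 1)])
            if off.max() < 0.3:
                hits += 1
        assert hits / n_seeds >= 0.9

    def test_planted_positive_pair_recovered(self):
        rng = np.random.default_rng(7)
        d = 10
        cov = np.eye(d)
        cov[0, 1] = cov[1, 0] = 0.8
        t = lognormal_counts(rng, d, 100, cov=cov)
        est = sparcc(t, n_iterations=10, seed=1)
        assert est.rho[0, 1] > 0
        row = np.abs(est.rho[0]).copy()
        row[0] = 0
        assert np.argmax(row) == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        t = lognormal_counts(rng, 8, 40)
        a = sparcc(t, n_iterations=5, seed=9)
        b = sparcc(t, n_iterations=5, seed=9)
        assert np.array_equal(a.rho, b.rho)


class TestEdgeSignificance:
    def test_q_at_least_p_and_planted_pair_significant(self):
        rng = np.random.default_rng(11)
        d = 8
        cov = np.eye(d)
        cov[0, 1] = cov[1, 0] = 0.8
        t = lognormal_counts(rng, d, 200, cov=cov)
        est = sparcc(t, n_iterations=5, seed=0)
        est = edge_significance(t, est, n_permutations=600, seed=0)
        iu = np.triu_indices(d, 1)
        assert (est.q[iu] >= est.p[iu] - 1e-12).all()
        assert est.q[0, 1] < 0.05
        assert abs(est.rho[0, 1]) > 0.4

    def test_shuffled_null_fdr_controlled(self):
        """Independent data: essentially no edges at q < 0.05."""
        false_rates = []
        for seed in range(8):
            rng = np.random.default_rng(500 + seed)
            t = lognormal_counts(rng, 10, 60)
            est = sparcc(t, n_iterations=5, seed=seed)
            est = edge_significance(t, est, n_permutations=150, seed=seed)
            iu = np.triu_indices(10, 1)
            false_rates.append(np.mean(est.q[iu] < 0.05))
        assert np.mean(false_rates) <= 0.05


class TestBuildNetwork:
    def make_corr(self, rho01, q01):
        d = 4
        rho = np.eye(d)
        rho[0, 1] = rho[1, 0] = rho01
        q = np.ones((d, d)) * 0.5
        q[0, 1] = q[1, 0] = q01
        np.fill_diagonal(q, 0)
        return CorrelationMatrix([f"t{i}" for i in range(d)], rho, q=q)

    def test_boundary_semantics(self):
        kept = build_network(self.make_corr(0.41, 0.04))
        assert ("t0", "t1") in kept.edges
        with pytest.warns(UserWarning, match="empty"):
            dropped_r = build_network(self.make_corr(0.40, 0.04))
        assert not dropped_r.edges  # strict |rho| > 0.4
        with pytest.warns(UserWarning, match="empty"):
            dropped_q = build_network(self.make_corr(0.9, 0.2))
        assert not dropped_q.edges

    def test_edge_count_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        d = 12
        rho = np.clip((lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, (d, d))), -1, 1)
        np.fill_diagonal(rho, 1)
        q = (lambda m: (m + m.T) / 2)(rng.uniform(0, 0.2, (d, d)))
        np.fill_diagonal(q, 0)
        corr = CorrelationMatrix([f"t{i}" for i in range(d)], rho, q=q)
        counts = [len(build_network(corr, r_min=r).edges)
                  for r in (0.2, 0.4, 0.6)]
        assert counts == sorted(counts, reverse=True)
        counts_q = [len(build_network(corr, q_max=qm, r_min=0.2).edges)
                    for qm in (0.15, 0.1, 0.05)]
        assert counts_q == sorted(counts_q, reverse=True)


def graph_network(edges):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, rho=0.5, q=0.01, sign="positive", backbone=False)
    return CorrelationNetwork(graph=g)


class TestMcode:
    def brute_force_densest(self, g, min_size=3):
        """Densest subgraph (density, then size) by subset enumeration."""
        best, best_key = None, (-1, 0)
        nodes = list(g.nodes)
        from itertools import combinations as comb
        for k in range(min_size, len(nodes) + 1):
            for sub in comb(nodes, k):
                sg = g.subgraph(sub)
                nn = sg.number_of_nodes()
                dens = 2 * sg.number_of_edges() / (nn * (nn - 1))
                key = (dens, nn)
                if key > best_key:
                    best_key, best = key, set(sub)
        return best

    def test_clique_with_pendants(self):
        clique = [f"c{i}" for i in range(5)]
        edges = [(a, b) for a, b in combinations(clique, 2)]
        edges += [("c0", "p0"), ("c1", "p1"), ("c2", "p2")]
        net = mcode_cores(graph_network(edges))
        assert net.clusters and set(net.clusters[0]) == set(clique)
        assert set(net.clusters[0]) == self.brute_force_densest(net.graph)
        for p in ("p0", "p1", "p2"):
            assert net.role_of(p) == "peripheral"
        for c in clique:
            assert net.role_of(c) == "core"

    def test_two_disjoint_cliques_deterministic_order(self):
        e = [(a, b) for a, b in combinations(["a1", "a2", "a3", "a4"], 2)]
        e += [(a, b) for a, b in combinations(["b1", "b2", "b3"], 2)]
        net = mcode_cores(graph_network(e))
        assert len(net.clusters) == 2
        assert net.clusters[0] == ["a1", "a2", "a3", "a4"]  # larger k-core first
        assert set(net.clusters[0]) == self.brute_force_densest(
            net.graph.subgraph(["a1", "a2", "a3", "a4"]))

    def test_edgeless_graph_no_cores(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        net = mcode_cores(CorrelationNetwork(graph=g))
        assert net.clusters == []

    def test_no_peripheral_peripheral_edges_within_annotation(self):
        clique = [f"c{i}" for i in range(4)]
        edges = [(a, b) for a, b in combinations(clique, 2)]
        edges += [("c0", "p0"), ("c1", "p1")]
        net = mcode_cores(graph_network(edges))
        periph = [v for v in net.graph.nodes if net.role_of(v) == "peripheral"]
        for u, v in combinations(periph, 2):
            assert not net.graph.has_edge(u, v)


class TestBackbone:
    def weighted_network(self, triples):
        g = nx.Graph()
        for u, v, r in triples:
            g.add_edge(u, v, rho=r, q=0.01,
                       sign="positive" if r > 0 else "negative",
                       backbone=False)
        return CorrelationNetwork(graph=g)

    def test_triangle_keeps_two_strongest(self):
        net = backbone(self.weighted_network(
            [("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.7)]))
        flags = {tuple(sorted((u, v))): d["backbone"]
                 for u, v, d in net.graph.edges(data=True)}
        assert flags[("a", "b")] and flags[("b", "c")]
        assert not flags[("a", "c")]

    def test_tree_input_all_flagged(self):
        net = backbone(self.weighted_network(
            [("a", "b", 0.5), ("b", "c", -0.6), ("c", "d", 0.7)]))
        assert all(d["backbone"] for _, _, d in net.graph.edges(data=True))

    def test_forest_size_invariant(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(12, 0.3, seed=3)
        triples = [(str(u), str(v), float(rng.uniform(0.4, 1)))
                   for u, v in g.edges]
        net = backbone(self.weighted_network(triples))
        n_flagged = sum(d["backbone"] for _, _, d in net.graph.edges(data=True))
        gg = net.graph
        assert n_flagged == gg.number_of_nodes() - nx.number_connected_components(gg)


class TestFunctionalGroup:
    def test_hand_traced_rule(self):
        hc = graph_network([("a", "b"), ("b", "c")])
        esin = graph_network([("a", "b"), ("c", "d")])
        escc = graph_network([("a", "c"), ("c", "d")])  # nodes a, c, d
        fg = functional_group(hc, esin, escc)
        assert fg.species == ["a"]
        assert fg.provenance["n_common_edges"] == 1

    def test_identical_networks_keep_all(self):
        net = graph_network([("a", "b"), ("b", "c")])
        fg = functional_group(net, net, net)
        assert fg.species == ["a", "b", "c"]

    def test_disjoint_edges_empty(self):
        hc = graph_network([("a", "b")])
        esin = graph_network([("c", "d")])
        escc = graph_network([("a", "c")])
        with pytest.warns(UserWarning, match="empty"):
            fg = functional_group(hc, esin, escc)
        assert fg.species == []

    def test_abundance_is_summed_relative(self, small_cohort):
        bacteria, _, _, _, _ = small_cohort
        hc = graph_network([("B_0001", "B_0002")])
        fg = functional_group(hc, hc, hc, abundance_table=bacteria)
        rel = bacteria.data.div(bacteria.data.sum(axis=0), axis=1)
        expected = rel.loc[["B_0001", "B_0002"]].sum(axis=0)
        pd.testing.assert_series_equal(fg.abundance, expected)


class TestGroupSpecificCoupling:
    def test_weakly_coupled_group_yields_sparser_network(self):
        """Carcinoma-style group (weaker planted correlations, same
        everything else) produces fewer edges and lower mean degree."""
        from amplistat import (SyntheticConfig, generate_tables, to_relative)
        block1 = [f"B_{i:04d}" for i in range(0, 8)]
        block2 = [f"B_{i:04d}" for i in range(8, 14)]
        r_map = {"HC": 0.8, "ESCC": 0.45}
        cfg = SyntheticConfig(
            seed=5, group_sizes={"HC": 35, "ESCC": 35},
            n_taxa_bacteria=200, n_taxa_fungi=20,
            dispersion_by_group={"HC": 0.6, "ESCC": 0.6},
            differential_taxa=[(t, ("HC", "ESCC"), 6.0)
                               for t in block1 + block2],
            correlation_blocks=[(block1, r_map), (block2, r_map)],
            clinical_tables={})
        bacteria, _, _, meta, _ = generate_tables(cfg)
        stats = {}
        for g in ("HC", "ESCC"):
            sub = bacteria.data[meta.samples_in(g)]
            sub = sub[sub.sum(axis=1) > 0]
            top = sub.sum(axis=1).nlargest(20).index
            t = FeatureTable(sub.loc[sorted(top)])
            corr = sparcc(t, n_iterations=5, seed=5)
            corr = edge_significance(t, corr, n_permutations=400, seed=5)
            net = build_network(corr)
            degrees = [d for _, d in net.graph.degree]
            stats[g] = (net.graph.number_of_edges(),
                        np.mean(degrees) if degrees else 0.0)
        assert stats["HC"][0] > stats["ESCC"][0]
        assert stats["HC"][1] > stats["ESCC"][1]
        assert stats["HC"][0] > 0
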