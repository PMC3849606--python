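import numpy as np
import pytest

import pathmi as pm


class TestGenerateNetwork:
    def test_chain_topology(self):
        cfg = pm.SimulationConfig(n_genes=5, topology="chain", seed=0)
        net = pm.generate_network(cfg)
        assert net.n_edges == 4
        assert pm.cyclicity(net) == 0.0
        assert ("G1", "G2") in net.edges

    def test_tree_is_acyclic_with_n_minus_one_edges(self):
        cfg = pm.SimulationConfig(n_genes=12, topology="tree", seed=3)
        net = pm.generate_network(cfg)
        assert net.n_edges == 11
        assert pm.cyclicity(net) == 0.0

    def test_deterministic_given_seed(self):
        cfg = pm.SimulationConfig(n_genes=10, topology="tree", seed=11)
        assert pm.generate_network(cfg).edges == pm.generate_network(cfg).edges

    def test_cycle_edges_added_and_measurable(self):
        cfg = pm.SimulationConfig(n_genes=21, topology="random-with-cycles",
                                  cycle_fraction=0.25, seed=2)
        net = pm.generate_network(cfg)
        assert net.n_edges == 20 + 5
        assert pm.cyclicity(net) > 0.0

    def test_cycle_fraction_on_acyclic_topology_errors(self):
        with pytest.raises(ValueError, match="cycle_fraction"):
            pm.SimulationConfig(topology="chain", cycle_fraction=0.2)

    def test_cyclicity_increases_with_cycle_fraction(self):
        """Monotone trend of mean measured cyclicity over 3 knob levels."""
        means = []
        for frac in (0.1, 0.3, 0.6):
            vals = [pm.cyclicity(pm.generate_network(
                pm.SimulationConfig(n_genes=15, topology="random-with-cycles",
                                    cycle_fraction=frac, seed=s)))
                    for s in range(20)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestSimulateExpression:
    def test_deterministic_given_seed(self):
        cfg = pm.SimulationConfig(n_genes=6, topology="tree", n_samples=50, seed=4)
        net = pm.generate_network(cfg)
        a = pm.simulate_expression(net, cfg)
        b = pm.simulate_expression(net, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_shape_and_labels(self):
        cfg = pm.SimulationConfig(n_genes=6, topology="chain", n_samples=30, seed=4)
        expr = pm.simulate_expression(pm.generate_network(cfg), cfg)
        assert expr.values.shape == (6, 30)
        assert expr.gene_ids == ("G1", "G2", "G3", "G4", "G5", "G6")

    def test_chain_triplet_obeys_dpi_ordering(self):
        """Two-step MI falls below both one-step MI values (strong signal)."""
        cfg = pm.SimulationConfig(n_genes=3, topology="chain", n_samples=2000, seed=0)
        expr = pm.simulate_expression(pm.generate_network(cfg), cfg)
        m = pm.estimate_mi_matrix(expr)
        iac = m.get("G1", "G3")
        assert iac < m.get("G1", "G2")
        assert iac < m.get("G2", "G3")

    def test_overwhelming_noise_approaches_independence_null(self):
        """With noise dwarfing the signal, pairwise MI sits at the level of
        the permutation null (which carries the plug-in estimator bias),
        while the strong-signal regime clearly exceeds it."""
        strong = pm.SimulationConfig(n_genes=3, topology="chain", n_samples=1000, seed=1)
        noisy = pm.SimulationConfig(n_genes=3, topology="chain", n_samples=1000,
                                    noise_sd=50.0, seed=1)
        net = pm.generate_network(strong)
        expr_noisy = pm.simulate_expression(net, noisy)
        m_noisy = pm.estimate_mi_matrix(expr_noisy)
        null_hi = pm.permutation_threshold(
            expr_noisy, pm.AracneConfig(n_permutations=30, significance_alpha=0.05, seed=1))
        null_med = pm.permutation_threshold(
            expr_noisy, pm.AracneConfig(n_permutations=30, significance_alpha=0.5, seed=1))
        assert m_noisy.get("G2", "G3") < null_hi * 1.5
        m_strong = pm.estimate_mi_matrix(pm.simulate_expression(net, strong))
        assert m_strong.get("G2", "G3") > null_hi + 0.5
        # noisy estimate within 25% of the null median; strong far outside
        assert abs(m_noisy.get("G2", "G3") - null_med) < 0.25 * null_med

    def test_cyclic_network_simulates_finite_values(self):
        net = pm.two_channel_cycle_network()
        cycle = pm.RegulatoryNetwork(("A", "B", "C"),
                                     frozenset({("A", "B"), ("B", "C"), ("C", "A")}))
        cfg = pm.SimulationConfig(n_genes=3, topology="chain", n_samples=20, seed=2)
        expr = pm.simulate_expression(cycle, cfg)
        assert np.all(np.isfinite(expr.values))
        expr2 = pm.simulate_expression(net, pm.SimulationConfig(
            n_genes=4, topology="chain", n_samples=20, seed=2))
        assert np.all(np.isfinite(expr2.values))


class TestGaussianTreeModel:
    def test_mi_matrix_matches_closed_form_on_an_edge(self):
        net, mi = pm.gaussian_tree_model(6, seed=1)
        # every tree edge's MI must equal -0.5*log(1-rho^2) for some rho in range
        for e in net.undirected_edge_set():
            a, b = sorted(e)
            v = mi.get(a, b)
            rho = np.sqrt(1 - np.exp(-2 * v))
            assert 0.5 <= rho <= 0.9 + 1e-12

    def test_nonadjacent_mi_below_adjacent(self):
        net, mi = pm.gaussian_tree_model(8, seed=2)
        direct = pm.dpi_classify(mi)
        genes = mi.gene_ids
        flagged = {frozenset((genes[i], genes[j]))
                   for i in range(8) for j in range(i + 1, 8) if direct[i, j]}
        assert flagged == set(net.undirected_edge_set())


class TestEndToEndRecovery:
    def test_chain_recovered_and_beats_random_baseline(self):
        """8-gene chain: the probabilistic shortest path recovers the chain
        and out-recalls random paths (fixed-seed stochastic check)."""
        recovered = 0
        recalls = []
        base_recalls = []
        for seed in range(3):
            cfg = pm.SimulationConfig(n_genes=8, topology="chain",
                                      n_samples=400, seed=seed)
            net = pm.generate_network(cfg)
            expr = pm.simulate_expression(net, cfg)
            res = pm.DirectPathModel(expr, n_boot=100).fit(seed=seed)
            path = res.most_probable_path("G1", "G8")
            if path.nodes == tuple(f"G{i}" for i in range(1, 9)):
                recovered += 1
            truth = pm.true_path(net, "G1", "G8")
            recalls.append(pm.score_path(path, truth, "edge-wise").recall)
            base = pm.random_baseline(net, net.gene_ids, seed=seed)
            scores = [pm.score_path(p, pm.true_path(net, p.root, p.target), "edge-wise").recall
                      for p in base if pm.true_path(net, p.root, p.target).n_edges >= 2]
            base_recalls.append(np.mean(scores))
        assert recovered >= 2
        assert np.mean(recalls) > np.mean(base_recalls)
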