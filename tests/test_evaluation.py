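import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

import pathmi as pm
from pathmi.evaluation import CorrelationResult, specificity


def chain_network(labels):
    edges = {(a, b) for a, b in zip(labels[:-1], labels[1:])}
    return pm.RegulatoryNetwork(tuple(labels), frozenset(edges))


class TestTruePath:
    def test_chain(self):
        net = chain_network(("A", "B", "C"))
        assert pm.true_path(net, "A", "C").nodes == ("A", "B", "C")

    def test_unreachable_is_none(self):
        net = pm.RegulatoryNetwork(("A", "B", "C"), frozenset({("A", "B")}))
        assert pm.true_path(net, "A", "C") is None

    def test_uses_undirected_view(self):
        net = chain_network(("A", "B", "C"))
        assert pm.true_path(net, "C", "A").nodes == ("C", "B", "A")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bfs_oracle(self, seed):
        r = np.random.default_rng(seed)
        genes = tuple(f"g{i}" for i in range(8))
        edges = {(genes[i], genes[j]) for i in range(8) for j in range(8)
                 if i != j and r.uniform() < 0.2}
        edges = {e for e in edges if e[0] != e[1]}
        net = pm.RegulatoryNetwork(genes, frozenset(edges))
        G = nx.Graph()
        G.add_nodes_from(genes)
        G.add_edges_from(edges)
        lengths = nx.single_source_shortest_path_length(G, genes[0])
        for t in genes[1:]:
            p = pm.true_path(net, genes[0], t)
            if t in lengths:
                assert p.n_edges == lengths[t]
            else:
                assert p is None


# hand-counted battery: (inferred nodes, true nodes, level, tp, fp, fn)
SCORE_BATTERY = [
    (("A", "B", "C"), ("A", "B", "D"), "edge-wise", 1, 1, 1),
    (("A", "B", "C"), ("A", "B", "C"), "edge-wise", 2, 0, 0),
    (("A", "B", "C"), ("A", "B", "C"), "node-wise", 1, 0, 0),
    (("A", "X", "D"), ("A", "B", "C", "D"), "node-wise", 0, 1, 2),
    (("A", "X", "D"), ("A", "B", "C", "D"), "edge-wise", 0, 2, 3),
    (("A", "D"), ("A", "B", "C", "D"), "edge-wise", 0, 1, 3),
    (("A", "D"), ("A", "B", "C", "D"), "node-wise", 0, 0, 2),
    (("A", "C", "B", "D"), ("A", "B", "C", "D"), "node-wise", 2, 0, 0),
    (("A", "C", "B", "D"), ("A", "B", "C", "D"), "edge-wise", 1, 2, 2),
    (("A", "B", "E", "D"), ("A", "B", "C", "D"), "node-wise", 1, 1, 1),
]


class TestScorePath:
    @pytest.mark.parametrize("inferred,true,level,tp,fp,fn", SCORE_BATTERY)
    def test_hand_counted_battery(self, inferred, true, level, tp, fp, fn):
        s = pm.score_path(pm.Path(inferred), pm.Path(true), level)
        assert (s.tp, s.fp, s.fn) == (tp, fp, fn)

    def test_precision_recall_formulas(self):
        s = pm.PathScore(tp=1, fp=1, fn=1, level="edge-wise")
        assert s.precision == pytest.approx(0.5)
        assert s.recall == pytest.approx(0.5)
        z = pm.PathScore(tp=0, fp=0, fn=0, level="node-wise")
        assert z.precision == 0.0 and z.recall == 0.0

    def test_edges_compared_as_unordered_pairs(self):
        s = pm.score_path(pm.Path(("C", "B", "A")), pm.Path(("A", "B", "C")), "edge-wise")
        assert (s.tp, s.fp, s.fn) == (2, 0, 0)

    def test_specificity_helper(self):
        assert specificity(tn=8, fp=2) == pytest.approx(0.8)
        assert specificity(tn=0, fp=0) == 0.0


class TestCyclicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_dag_is_zero(self, seed):
        cfg = pm.SimulationConfig(n_genes=10, topology="tree", seed=seed)
        assert pm.cyclicity(pm.generate_network(cfg)) == 0.0

    @pytest.mark.parametrize("n", range(3, 9))
    def test_directed_cycle_is_one_over_n(self, n):
        genes = tuple(f"g{i}" for i in range(n))
        edges = {(genes[i], genes[(i + 1) % n]) for i in range(n)}
        net = pm.RegulatoryNetwork(genes, frozenset(edges))
        assert pm.cyclicity(net) == pytest.approx(1.0 / n)

    def test_empty_network_is_zero(self):
        assert pm.cyclicity(pm.RegulatoryNetwork(("A", "B"), frozenset())) == 0.0


class TestRandomBaseline:
    def test_lmax_one_gives_direct_edges(self):
        net = pm.RegulatoryNetwork(("A", "B", "C"),
                                   frozenset({("A", "B"), ("B", "C"), ("A", "C")}))
        paths = pm.random_baseline(net, net.gene_ids, seed=0)
        assert all(p.n_edges == 1 for p in paths)

    def test_deterministic_given_seed(self):
        net = chain_network(tuple(f"g{i}" for i in range(6)))
        a = pm.random_baseline(net, net.gene_ids, seed=5)
        b = pm.random_baseline(net, net.gene_ids, seed=5)
        assert [p.nodes for p in a] == [p.nodes for p in b]

    def test_length_distribution_uniform(self):
        """With L_max = 3, drawn lengths are uniform on {1,2,3} (chi-square)."""
        net = chain_network(("A", "B", "C", "D"))
        counts = {1: 0, 2: 0, 3: 0}
        # ~12 pairs per seed; ~10,000 draws total
        for seed in range(850):
            for p in pm.random_baseline(net, net.gene_ids, seed=seed):
                counts[p.n_edges] += 1
        total = sum(counts.values())
        _, pval = stats.chisquare(list(counts.values()))
        assert total >= 10_000 - 200
        assert pval > 1e-4


class TestCorrelation:
    def _report(self, prob, perf):
        rows = []
        for i, (p, q) in enumerate(zip(prob, perf)):
            rows.append({"root": "R", "target": f"T{i}", "level": "edge-wise",
                         "tp": 1, "fp": 0, "fn": 0, "precision": q, "recall": q,
                         "true_path_length": 2, "probability": p})
        import pandas as pd
        return pm.EvaluationReport(scores=pd.DataFrame(rows), cyclicity=0.0)

    def test_proportional_gives_one(self):
        r = pm.probability_performance_correlation(
            self._report([0.1, 0.2, 0.4], [0.1, 0.2, 0.4]))
        assert r.defined and r.value == pytest.approx(1.0)

    def test_anti_ordered_gives_minus_one(self):
        r = pm.probability_performance_correlation(
            self._report([0.1, 0.2, 0.3], [0.9, 0.6, 0.3]))
        assert r.value == pytest.approx(-1.0)

    def test_constant_performance_flagged_undefined(self):
        r = pm.probability_performance_correlation(
            self._report([0.1, 0.2, 0.3], [0.5, 0.5, 0.5]))
        assert not r.defined and math.isnan(r.value)

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            pm.probability_performance_correlation(self._report([0.1, 0.2], [0.3, 0.4]))


class TestEvaluatePaths:
    def test_single_edge_true_paths_excluded(self):
        net = chain_network(("A", "B", "C", "D"))
        paths = [pm.Path(("A", "B"), probability=0.9, total_weight=-math.log(0.9)),
                 pm.Path(("A", "B", "C"), probability=0.5, total_weight=math.log(2))]
        report = pm.evaluate_paths(net, paths)
        assert report.n_skipped == 1
        assert set(report.scores["target"]) == {"C"}
        assert report.cyclicity == 0.0

    def test_perfect_inference_scores_one(self):
        net = chain_network(("A", "B", "C"))
        report = pm.evaluate_paths(net, [pm.Path(("A", "B", "C"), probability=0.8,
                                                 total_weight=-math.log(0.8))])
        assert (report.scores["precision"] == 1.0).all()
        assert (report.scores["recall"] == 1.0).all()
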