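# pathmi

Probabilistic inference and ranking of linear gene-regulatory pathways as a
shortest-path problem.

Whole-network inference from expression data yields "hairballs" that are hard
to act on. `pathmi` instead infers the single most likely *chain* of direct
regulatory interactions connecting two genes of interest, together with a
probability that can be used to prioritise laboratory validation.

## The method

For each pair of genes (A, B), mutual information I(A;B) is estimated from
their expression profiles (discrete plug-in estimate on equal-frequency
bins).  By the data processing inequality (DPI), if A influences C only
through B then

```
I(A;C) <= min(I(A;B), I(B;C))
```

so an edge is classified **direct** iff it is never strictly the least edge
in any triplet comparison.  Bootstrapping the samples and repeating the
classification gives each edge a **probability of directness**
P(DPI(AB)) — the fraction of bootstrap rounds the edge survives (Laplace
smoothed).  Assuming independent edges, the probability of a path p is
`prod_{AB in p} P(DPI(AB))`, and the maximum-probability path is found by
Dijkstra's algorithm with edge weights

```
w(A,B) = -log P(DPI(AB))
```

which are nonnegative, so minimising the summed weight maximises the joint
probability.  Two classic comparison methods are included: ARACNe-style
pruning (permutation-test MI threshold + DPI with a tolerance margin) and a
minimum spanning tree on transformed MI (Prim's algorithm), each followed by
unit-weight shortest-path extraction.  Path-level scoring (edge-wise and
node-wise precision/recall against the fewest-hop true path), network
cyclicity (fraction of DFS back edges), a random-path baseline, and a
synthetic network/expression simulator round out the toolkit.

## Worked example

```python
import pathmi as pm

cfg = pm.SimulationConfig(n_genes=8, topology="chain", n_samples=400, seed=1)
net = pm.generate_network(cfg)              # ground truth: G1 -> ... -> G8
expr = pm.simulate_expression(net, cfg)     # 8 genes x 400 samples

res = pm.DirectPathModel(expr, n_boot=100).fit(seed=1)
print(res.summary(top=8))
path = res.most_probable_path("G1", "G8")
print("->".join(path.nodes), path.probability)
```

prints

```
Direct-path inference results
=============================================
genes:            8
samples:          400
bootstraps:       100
MI estimator:     equal-frequency (bins=auto)
smoothing:        laplace
seed:             1

top 8 edges by probability of directness:
edge                   P(direct)    -log P
G1--G2                    0.9902    0.0099
G7--G8                    0.9902    0.0099
G4--G5                    0.9804    0.0198
G2--G3                    0.9804    0.0198
G6--G7                    0.9412    0.0606
G3--G4                    0.9314    0.0711
G5--G6                    0.9118    0.0924
G3--G8                    0.2647    1.3291
```

and recovers the exact chain `G1->G2->G3->G4->G5->G6->G7->G8` with joint
probability 0.7532 (total weight 0.2834 = -log 0.7532): the seven true chain
edges survive nearly every bootstrap's DPI comparisons, while shortcut edges
like G3–G8 are pruned in most rounds and receive large weights.  Ranking
queries sorts most-probable paths by joint probability:

```
G1->G4: G1->G2->G3->G4                    p=0.9042
G2->G7: G2->G3->G4->G5->G6->G7            p=0.7682
G1->G8: G1->G2->G3->G4->G5->G6->G7->G8    p=0.7532
```

(shorter paths multiply fewer uncertain edges, hence rank higher).

The same pipeline is scriptable from the shell:

```bash
pathmi simulate --genes 8 --samples 400 --seed 1 --out-expr expr.tsv --out-net net.tsv
pathmi infer-paths --input expr.tsv --root G1 --target G8 --boots 100 --seed 1 --out paths.tsv
pathmi evaluate --truth net.tsv --paths paths.tsv --out report.tsv
```

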