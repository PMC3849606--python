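# Methods

## Model

The unit of inference is a linear pathway between a root gene r and a target
gene t.  A path is taken to exist when every one of its edges is a direct
regulatory interaction; the method searches for the path most likely, given
the data, to be composed entirely of direct edges.

Directness is operationalised through the data processing inequality (DPI):
when A influences C only through B, I(A;C) <= min(I(A;B), I(B;C)), and in a
biological setting the inequality can be taken to be strict.  Edge (A,B) is
classified direct iff no third gene C satisfies
I(A,B) < min(I(A,C), I(B,C)).  On *true* MI values this classification would
exactly recover any acyclic dependency structure — the package ships a
closed-form Gaussian tree model (pairwise correlation = product of edge
correlations along the tree path, I = -½·log(1-ρ²)) on which the recovery is
provable and tested.

Estimated MI is noisy, so classification is repeated on bootstrap resamples
of the samples (columns resampled jointly across genes), and each edge's
**probability of directness** is the fraction of rounds it survives.  With
independent edges, a path's probability is the product of its edge
probabilities; taking -log turns the maximisation into a nonnegative-weight
shortest-path problem solved by Dijkstra's algorithm.  The independence
assumption is known to be imperfect — adjacent edges share triplet
comparisons — and the package implements the multiplicative model, not a
joint one.

## Estimator and numerical choices

- **MI estimator**: discrete plug-in estimate on binned data, natural log.
  Default equal-frequency (quantile) binning with n_bins = floor(sqrt(n)),
  clamped to [2, n]; equal-width binning is available.  Quantile binning is
  invariant to monotone transforms of expression, which suits the sigmoidal
  regulatory responses the simulator produces.  Ties at quantile boundaries
  are broken by stable sample order, and the contingency table is oriented
  canonically before summation so that I(X;Y) == I(Y;X) bit-exactly.
  Constant profiles have zero marginal entropy and return MI = 0.
- **No bias correction**: the plug-in estimate is biased upward (roughly
  (k-1)²/2n nats under independence), but DPI comparisons use a common
  estimator for all three edges of a triplet, so the shared bias largely
  cancels in the comparisons; the ARACNe permutation threshold absorbs it at
  the thresholding stage.
- **Tie rule**: pruning requires a strict inequality; ties leave the edge
  direct.  With two genes the single edge is trivially direct.
- **Smoothing**: raw bootstrap proportions can be 0 or 1, and -log(0) would
  silently delete an edge.  Default Laplace smoothing (c+1)/(B+2) keeps all
  probabilities inside (0,1); a probability floor of 1/(10·B) (B = bootstrap
  rounds) is applied after smoothing as a safety clamp bounding the dynamic
  range of weights.  The weighted graph stays complete: improbable edges get
  large finite weights rather than being removed.
- **Dijkstra**: binary-heap implementation; among equal-weight shortest
  paths the lexicographically smallest predecessor label wins, making
  reconstructed paths reproducible.  An optional hop cap switches to a
  layered (node, hops) search, since plain Dijkstra has no hop budget; the
  cap is off by default.
- **Ranking**: most-probable paths for a list of (root, target) queries are
  sorted by descending joint probability, ties broken by label order.  Note
  that paths of different lengths are compared on raw joint probability, so
  shorter paths are systematically favoured — this mirrors the method being
  characterised, not a defect of the implementation.

## Comparison methods

- **ARACNe-style**: MI threshold from a permutation test (each gene's sample
  order permuted independently; five random gene pairs per permutation round
  form the null; threshold = (1-α) null quantile) followed by DPI pruning
  with a *relative* tolerance margin: prune when
  I(A,B) < (1-τ)·min(I(A,C), I(B,C)).  Defaults τ = 0 (stringent) and
  α = 0.30 (permissive) reflect the regime in which path extraction from the
  pruned network works best.  Zero-MI edges are never kept.
- **MST**: Prim's algorithm on transformed MI, seeded at the smallest gene
  label with label-ordered tie-breaking; transforms 1 - I/I_max (default) or
  -log(I/I_max) (zero-MI edges excluded).  Both are strictly decreasing in
  MI, so they produce identical trees on all-positive matrices.
- Both comparators optionally run on the mean (or median) of bootstrap MI
  matrices, trading a little sensitivity for robustness to outliers.
- Paths are extracted from either inferred network by unit-weight shortest
  path (fewest hops).

## Evaluation

The reference for a query is the fewest-hop path through the undirected view
of the ground-truth network (inference is direction-blind because MI is
symmetric).  Scores are computed edge-wise (edges as unordered pairs) and
node-wise (interior nodes only; root and target are query inputs, so
counting them would inflate node-wise metrics).  Precision = tp/(tp+fp),
recall = tp/(tp+fn), both 0 on an empty denominator; specificity is provided
as a helper but excluded from reports because true negatives dwarf path
edges.  Only queries whose true path has at least two edges contribute,
keeping node-wise metrics meaningful.  Network cyclicity is the fraction of
back edges met in a label-ordered depth-first search of the directed truth
(0 for any DAG, 1/n for a directed n-cycle).  The random baseline draws, per
(root, target) pair with a defined true path, a uniformly random simple path
whose edge count is uniform on [1, L_max] (L_max = longest true-path edge
count) with uniformly chosen distinct intermediates.  The path-probability /
performance relationship is summarised by the Pearson correlation between
joint probability and (precision+recall)/2, flagged undefined when either
vector is constant.

## Synthetic data

The simulator stands in for in-silico benchmark generators.  Topologies:
chain (G1→…→Gn), random directed tree, or tree plus
round(cycle_fraction·(n-1)) extra edges each closing a directed cycle.
Expression: source genes draw from a standard normal; each regulated gene is
tanh(strength · mean of parents) + Gaussian noise.  Defaults — strength 1.5,
noise sd 0.2, 400 samples — put one regulatory step at a signal-to-noise
ratio of roughly 3:1, a strong-signal regime comparable to in-silico
benchmark data; the bounded tanh response gives the nonlinear dependence
that motivates MI over correlation.  Cyclic networks are resolved by 10
rounds of synchronous updates from a random initial state with source values
and noise held fixed — cheap, bit-reproducible, and sufficient to create the
multi-channel dependence behind the skipping failure mode.  All randomness
flows from a single seed through named streams (network, sources, noise,
initial state).

What the simulator does **not** emulate: thermodynamic ODE kinetics,
transcription/translation delays, measurement-platform noise profiles, or
the fixed published topologies of real benchmark networks.  Passing tests
therefore demonstrate correctness of the algorithms and qualitative trends
(DPI triplet ordering, chain recovery, skipping in cycles), not absolute
performance on any real dataset.

## Verification and problem sizes

The test suite checks every search against independent brute-force oracles
(exhaustive simple-path enumeration, triple-loop DPI, BFS, networkx
cross-checks) on graphs of up to 8–10 nodes, and runs the full pipeline at
the study conditions: 3-gene chains at 2,000 samples for the triplet
ordering rate (100 replicates), 8-gene chains at 400 samples with 100
bootstraps for end-to-end recovery (10 seeds), and the 4-gene two-channel
cycle at 400 samples for the skipping scenario (20 seeds).  These sizes make
the whole suite run in seconds while leaving the oracle enumerations exact.
The skipping check is demonstrative of a documented failure mode: its
per-seed occurrence probability is near one half, so the measured rate
fluctuates around the majority line across seed sets.

## Known limitations

- Direction of regulation is unrecoverable (MI symmetry): all inferred paths
  are undirected.
- Edge probabilities are treated as independent; the decisive triplet
  comparison induces dependence between adjacent edges.
- In cycles, parallel influence channels can sum to a strong shortcut signal
  that prunes true edges ("skipping"); the package reproduces and measures
  this failure mode rather than fixing it.
- The plug-in MI estimator is biased at small sample sizes; the pipeline
  relies on bias cancellation within triplets rather than on bias-corrected
  or Bayesian estimation.
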