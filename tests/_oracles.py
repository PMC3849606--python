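"""Independent brute-force oracles used to cross-check the implementation."""

import itertools
import math

import numpy as np


def all_simple_paths(n, root, target):
    """Every simple node-index path from root to target in a complete graph."""
    others = [v for v in range(n) if v not in (root, target)]
    for k in range(len(others) + 1):
        for mid in itertools.permutations(others, k):
            yield (root, *mid, target)


def min_weight_path(weights, root, target):
    """Exhaustive minimum-total-weight simple path; (weight, path) or None."""
    best = None
    for path in all_simple_paths(len(weights), root, target):
        w = sum(weights[a][b] for a, b in zip(path[:-1], path[1:]))
        if math.isfinite(w) and (best is None or w < best[0] or
                                 (w == best[0] and path < best[1])):
            best = (w, path)
    return best


def max_product_path(prob, root, target):
    """Exhaustive maximum-probability-product simple path; (prob, path)."""
    best = None
    for path in all_simple_paths(len(prob), root, target):
        p = 1.0
        for a, b in zip(path[:-1], path[1:]):
            p *= prob[a][b]
        if best is None or p > best[0] or (p == best[0] and path < best[1]):
            best = (p, path)
    return best


def brute_force_dpi(mi):
    """Triple loop over all (A,B,C): direct iff never strictly the least."""
    n = len(mi)
    direct = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            ok = True
            for c in range(n):
                if c in (a, b):
                    continue
                if mi[a][b] < min(mi[a][c], mi[b][c]):
                    ok = False
                    break
            direct[a][b] = ok
    return direct


def plug_in_mi(counts):
    """Hand evaluation of sum p(x,y) log[p(x,y)/(p(x)p(y))] in nats."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    total = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            if counts[i, j] > 0:
                pxy = counts[i, j] / n
                px = counts[i, :].sum() / n
                py = counts[:, j].sum() / n
                total += pxy * math.log(pxy / (px * py))
    return total
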