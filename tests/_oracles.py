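"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (explicit loops,
exhaustive enumeration) and shares no code with the package.
"""

import itertools
import math

import numpy as np


def wnodf_brute(X, component="combined"):
    """Naive loop implementation of weighted NODF on the matrix as given."""
    X = np.asarray(X, dtype=float)
    nr, nc = X.shape
    row_scores, col_scores = [], []
    for i in range(nr):
        for j in range(i + 1, nr):
            fi = sum(1 for k in range(nc) if X[i, k] > 0)
            fj = sum(1 for k in range(nc) if X[j, k] > 0)
            if fi <= fj or fj == 0:
                row_scores.append(0.0)
            else:
                hits = sum(1 for k in range(nc) if 0 < X[j, k] < X[i, k])
                row_scores.append(100.0 * hits / fj)
    for i in range(nc):
        for j in range(i + 1, nc):
            fi = sum(1 for k in range(nr) if X[k, i] > 0)
            fj = sum(1 for k in range(nr) if X[k, j] > 0)
            if fi <= fj or fj == 0:
                col_scores.append(0.0)
            else:
                hits = sum(1 for k in range(nr) if 0 < X[k, j] < X[k, i])
                col_scores.append(100.0 * hits / fj)
    if component == "rows":
        return sum(row_scores) / len(row_scores)
    if component == "columns":
        return sum(col_scores) / len(col_scores)
    return (sum(row_scores) + sum(col_scores)) / (len(row_scores) + len(col_scores))


def weighted_mpd_brute(D, weights):
    """Double loop over ordered pairs i != j."""
    D = np.asarray(D, dtype=float)
    w = np.asarray(weights, dtype=float)
    p = w / w.sum()
    num = den = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            if i != j:
                num += p[i] * p[j] * D[i, j]
                den += p[i] * p[j]
    return num / den


def rarefied_richness_brute(counts, m):
    """Exhaustive enumeration over all m-subsets of labelled individuals."""
    individuals = []
    for sp, n in enumerate(counts):
        individuals.extend([sp] * int(n))
    subsets = list(itertools.combinations(range(len(individuals)), m))
    total = 0
    for sub in subsets:
        total += len({individuals[i] for i in sub})
    return total / len(subsets)


def mst_total_length_brute(points):
    """Minimum over all spanning trees, enumerated via Pruefer sequences."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    if n == 2:
        return float(D[0, 1])
    best = math.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        # decode the Pruefer sequence into its unique spanning tree
        deg = [1] * n
        for s in seq:
            deg[s] += 1
        edges = []
        for node in seq:
            leaf = min(i for i in range(n) if deg[i] == 1)
            edges.append((leaf, node))
            deg[leaf] -= 1
            deg[node] -= 1
        last = [i for i in range(n) if deg[i] == 1]
        edges.append((last[0], last[1]))
        total = sum(D[a, b] for a, b in edges)
        if total < best:
            best = total
    return best


def feve_brute(points, abundances):
    """Direct evaluation of the functional-evenness formula with a brute MST."""
    pts = np.asarray(points, dtype=float)
    w = np.asarray(abundances, dtype=float)
    p = w / w.sum()
    S = len(w)
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    # brute MST by Kruskal with exhaustive sorting
    edges = sorted(
        ((D[i, j], i, j) for i in range(S) for j in range(i + 1, S)),
        key=lambda e: e[0],
    )
    parent = list(range(S))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    mst = []
    for d, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            mst.append((d, i, j))
    ew = [d / (p[i] + p[j]) for d, i, j in mst]
    pew = [e / sum(ew) for e in ew]
    ref = 1.0 / (S - 1)
    return (sum(min(x, ref) for x in pew) - ref) / (1 - ref)


def fspe_brute(pool_points, abundances):
    """Direct evaluation: weighted mean distance to the pool centroid / max."""
    pts = np.asarray(pool_points, dtype=float)
    w = np.asarray(abundances, dtype=float)
    centroid = pts.mean(axis=0)
    dists = [math.dist(pt, centroid) for pt in pts]
    p = w / w.sum()
    return sum(pi * di for pi, di in zip(p, dists)) / max(dists)


def subtree_length_brute(edges, tips_below, species, include_root=True):
    """Sum edge lengths whose subtree contains a selected species.

    *edges* is {child: length}; *tips_below* is {child: set of tip ids below
    (incl. itself if a tip)}.  An edge is in the minimal root-inclusive
    subtree iff at least one selected species sits below it.
    """
    sel = set(species)
    total = 0.0
    for child, length in edges.items():
        if tips_below[child] & sel:
            total += length
    return total


def wilcoxon_brute(diffs):
    """Exact two-sided signed-rank p by enumerating all sign flips."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = _rank(np.abs(d))
    w_plus = sum(r for r, x in zip(ranks, d) if x > 0)
    w_minus = sum(r for r, x in zip(ranks, d) if x < 0)
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        wm = sum(ranks) - wp
        if min(wp, wm) <= w_obs + 1e-9:
            count += 1
    return count / 2**n


def _rank(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks
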