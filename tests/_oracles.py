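"""Independent reference implementations used to cross-check the package.

Everything here is written from the textbook definitions with no code shared
with ``assemblyscope`` internals: brute-force enumeration, explicit
summations, and networkx shortest paths.
"""

import itertools
import math

import networkx as nx
import numpy as np


def simplex_counts_brute(A: np.ndarray, max_dim: int) -> np.ndarray:
    """Directed k-simplex counts by enumerating ordered vertex tuples."""
    n = A.shape[0]
    counts = np.zeros(max_dim + 1, dtype=np.int64)
    counts[0] = n
    for k in range(1, max_dim + 1):
        for tup in itertools.permutations(range(n), k + 1):
            if all(A[tup[i], tup[j]] for i in range(k + 1) for j in range(i + 1, k + 1)):
                counts[k] += 1
    return counts


def k_indegree_brute(A: np.ndarray, assembly, target: int, k: int) -> int:
    """k-simplices inside assembly \\ {target} whose every vertex hits target."""
    pool = [v for v in assembly if v != target and A[v, target]]
    total = 0
    for tup in itertools.permutations(pool, k + 1):
        if all(A[tup[i], tup[j]] for i in range(k + 1) for j in range(i + 1, k + 1)):
            total += 1
    return total


def mi_bits_from_joint(joint: np.ndarray) -> float:
    """I(X;Y) in bits by explicit summation over a joint count table."""
    joint = np.asarray(joint, dtype=float)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * math.log2(p[i, j] / (px[i] * py[j]))
    return total


def conditional_mi_bits(codes_x, y, codes_z) -> float:
    """I(X;Y|Z) in bits: sum_z p(z) I(X;Y | Z=z) by explicit summation."""
    codes_x = np.asarray(codes_x)
    y = np.asarray(y)
    codes_z = np.asarray(codes_z)
    n = y.size
    total = 0.0
    for z in np.unique(codes_z):
        m = codes_z == z
        xs, ys = codes_x[m], y[m]
        nx_codes = np.unique(xs)
        ny_codes = np.unique(ys)
        joint = np.zeros((nx_codes.size, ny_codes.size))
        for a, xv in enumerate(nx_codes):
            for b, yv in enumerate(ny_codes):
                joint[a, b] = np.sum((xs == xv) & (ys == yv))
        total += m.sum() / n * mi_bits_from_joint(joint)
    return total


def entropy_bits(y) -> float:
    y = np.asarray(y)
    total = 0.0
    for v in np.unique(y):
        p = np.mean(y == v)
        total -= p * math.log2(p)
    return total


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """Textbook Davies-Bouldin index (mean-distance dispersion, Euclidean)."""
    clusters = np.unique(labels)
    cents = np.array([X[labels == c].mean(axis=0) for c in clusters])
    disp = np.array(
        [np.mean(np.linalg.norm(X[labels == c] - cents[i], axis=1)) for i, c in enumerate(clusters)]
    )
    k = clusters.size
    total = 0.0
    for i in range(k):
        ratios = [
            (disp[i] + disp[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(k)
            if j != i
        ]
        total += max(ratios)
    return total / k


def coreness_direct(r: int, n: int, p: float, tail_mode: str = "gt") -> float:
    """-log10 binomial tail by explicit summation with math.comb."""
    lo = r + 1 if tail_mode == "gt" else r
    tail = sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(lo, n + 1))
    return -math.log10(max(tail, 1e-12))


def path_distances_nx(morph, synapses) -> np.ndarray:
    """All-pairs synapse path distances via networkx on the bare tree.

    A synapse is an interior point of one edge; on a tree the shortest path
    between interior points of distinct edges exits through one endpoint of
    each edge, so the distance is the minimum over the four endpoint
    combinations (same-edge pairs are |offset difference| apart).
    """
    G = nx.Graph()
    for child in morph.edges:
        G.add_edge(int(morph.parent[child]), int(child), weight=float(morph.length[child]))
    node_d = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
    n = synapses.n_synapses
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ei, ej = int(synapses.edge[i]), int(synapses.edge[j])
            oi, oj = float(synapses.offset[i]), float(synapses.offset[j])
            if ei == ej:
                d = abs(oi - oj)
            else:
                li, lj = float(morph.length[ei]), float(morph.length[ej])
                ends_i = [(int(morph.parent[ei]), oi), (ei, li - oi)]
                ends_j = [(int(morph.parent[ej]), oj), (ej, lj - oj)]
                d = min(ci + node_d[a][b] + cj for a, ci in ends_i for b, cj in ends_j)
            D[i, j] = D[j, i] = d
    return D


def emd_brute(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Equal-size EMD by trying every assignment."""
    a, b = np.atleast_2d(points_a), np.atleast_2d(points_b)
    n = len(a)
    best = np.inf
    for perm in itertools.permutations(range(n)):
        cost = sum(np.linalg.norm(a[i] - b[perm[i]]) for i in range(n))
        best = min(best, cost)
    return best / n


def best_match_jaccard(targets, candidates) -> float:
    """Mean over target sets of the best Jaccard with any candidate set."""
    vals = []
    for t in targets:
        st = set(np.asarray(t).tolist())
        best = 0.0
        for c in candidates:
            sc = set(np.asarray(c).tolist())
            if st | sc:
                best = max(best, len(st & sc) / len(st | sc))
        vals.append(best)
    return float(np.mean(vals))
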