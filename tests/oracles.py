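"""Independent naive reference implementations used as test oracles.

Deliberately written with elementary loops (Floyd-Warshall, triple-loop
triangle counts, explicit Pearson formulas) so they share no code path with
the package implementations they check.
"""

import itertools

import numpy as np


def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on inverse-weight lengths, O(n^3) DP."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def char_path_length(weights: np.ndarray) -> float:
    d = floyd_warshall(weights)
    vals = [d[i, j] for i in range(len(d)) for j in range(i + 1, len(d))
            if np.isfinite(d[i, j])]
    return sum(vals) / len(vals)


def local_efficiency(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    eff = np.zeros(n)
    for u in range(n):
        nb = [v for v in range(n) if weights[u, v] > 0]
        if len(nb) < 2:
            continue
        sub = weights[np.ix_(nb, nb)]
        d = floyd_warshall(sub)
        total = 0.0
        for a in range(len(nb)):
            for b in range(len(nb)):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    total += 1.0 / d[a, b]
        eff[u] = total / (len(nb) * (len(nb) - 1))
    return eff


def assortativity(weights: np.ndarray) -> float:
    """Pearson correlation of endpoint degrees over the symmetrized edges."""
    A = weights > 0
    k = A.sum(axis=0)
    xs, ys = [], []
    n = len(A)
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j]:
                xs += [k[i], k[j]]
                ys += [k[j], k[i]]
    x, y = np.array(xs, float), np.array(ys, float)
    return float(np.corrcoef(x, y)[0, 1])


def transitivity(weights: np.ndarray) -> float:
    A = weights > 0
    n = len(A)
    triangles = 0
    triples = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if j != i and k != i and j != k and A[i, j] and A[i, k]:
                    triples += 1
                    if A[j, k]:
                        triangles += 1
    return triangles / triples


def clustering(weights: np.ndarray) -> np.ndarray:
    A = weights > 0
    n = len(A)
    out = np.zeros(n)
    for u in range(n):
        nb = [v for v in range(n) if A[u, v]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nb, 2) if A[a, b])
        out[u] = 2.0 * links / (k * (k - 1))
    return out


def density(weights: np.ndarray) -> float:
    n = weights.shape[0]
    edges = sum(1 for i in range(n) for j in range(i + 1, n)
                if weights[i, j] > 0)
    return edges / (n * (n - 1) / 2)


def eccentricity(weights: np.ndarray) -> np.ndarray:
    d = floyd_warshall(weights)
    n = len(d)
    ecc = np.zeros(n)
    for i in range(n):
        finite = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        ecc[i] = max(finite) if finite else 0.0
    return ecc


def betweenness(weights: np.ndarray) -> np.ndarray:
    """Betweenness by explicit enumeration of all simple paths (small n)."""
    n = weights.shape[0]
    nodes = range(n)
    out = np.zeros(n)
    for s, t in itertools.combinations(nodes, 2):
        # enumerate all simple s-t paths and their lengths
        best = np.inf
        shortest = []
        stack = [(s, [s], 0.0)]
        while stack:
            u, path, length = stack.pop()
            if u == t:
                if length < best - 1e-12:
                    best = length
                    shortest = [path]
                elif abs(length - best) <= 1e-12:
                    shortest.append(path)
                continue
            for v in nodes:
                if weights[u, v] > 0 and v not in path:
                    stack.append((v, path + [v], length + 1.0 / weights[u, v]))
        if not shortest:
            continue
        for path in shortest:
            for v in path[1:-1]:
                out[v] += 1.0 / len(shortest)
    return out


def pairwise_pearson(X: np.ndarray) -> np.ndarray:
    """Entrywise Pearson correlations between rows of X."""
    n = X.shape[0]
    R = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            xi, xj = X[i], X[j]
            num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
            den = np.sqrt(((xi - xi.mean()) ** 2).sum()
                          * ((xj - xj.mean()) ** 2).sum())
            R[i, j] = num / den
    return R


def hotelling_T2(lesioned: np.ndarray, intact: np.ndarray) -> tuple:
    """Closed-form paired Hotelling's T2 with a plain matrix inverse."""
    D = lesioned - intact
    N, p = D.shape
    dbar = D.mean(axis=0)
    S = np.zeros((p, p))
    for row in D:
        S += np.outer(row - dbar, row - dbar)
    S /= (N - 1)
    T2 = N * float(dbar @ np.linalg.solve(S, dbar))
    F = (N - p) * T2 / (p * (N - 1))
    return T2, F


def random_connected_weights(n: int, p_edge: float, rng: np.random.Generator,
                             ) -> np.ndarray:
    """Random connected weighted graph (spanning path + Bernoulli edges)."""
    W = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        W[a, b] = W[b, a] = rng.lognormal(0, 0.5)
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] == 0 and rng.random() < p_edge:
                W[i, j] = W[j, i] = rng.lognormal(0, 0.5)
    return W
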