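"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the penalized-likelihood
oracle enumerates sign/zero patterns and solves smooth constrained problems
with scipy; the centrality oracle enumerates every simple path.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize


def glasso_bruteforce_3x3(S: np.ndarray, lam: float) -> np.ndarray:
    """Global minimizer of −logdet K + tr(SK) + λ Σ_{i≠j}|K_ij| for p = 3.

    Enumerates all 27 sign/zero patterns of the three off-diagonal entries;
    for each pattern the penalty is linear, so the restricted problem is
    smooth and solved with BFGS; the candidate with the lowest value of the
    true (absolute-value) objective is the global optimum, because the
    restricted problem matching the true pattern attains it.
    """
    pairs = [(0, 1), (0, 2), (1, 2)]

    def objective_true(K):
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            return np.inf
        off = sum(abs(K[i, j]) for i, j in pairs)
        return -logdet + float(np.sum(S * K)) + 2.0 * lam * off

    best_val, best_K = np.inf, None
    for pattern in itertools.product((0, 1, -1), repeat=3):
        active = [e for e, s in enumerate(pattern) if s != 0]

        def unpack(x):
            K = np.diag(x[:3])
            for t, e in enumerate(active):
                i, j = pairs[e]
                K[i, j] = K[j, i] = x[3 + t]
            return K

        def f(x):
            K = unpack(x)
            sign, logdet = np.linalg.slogdet(K)
            if sign <= 0 or np.any(np.diag(K) <= 0):
                return 1e10
            pen = sum(
                2.0 * lam * pattern[e] * x[3 + t] for t, e in enumerate(active)
            )
            return -logdet + float(np.sum(S * K)) + pen

        def grad(x):
            K = unpack(x)
            sign, _ = np.linalg.slogdet(K)
            if sign <= 0:
                return np.zeros_like(x)
            G = -np.linalg.inv(K) + S  # d/dK of smooth part
            g = np.empty_like(x)
            g[:3] = np.diag(G)
            for t, e in enumerate(active):
                i, j = pairs[e]
                g[3 + t] = 2.0 * G[i, j] + 2.0 * lam * pattern[e]
            return g

        x0 = np.concatenate(
            [1.0 / np.diag(S), [0.01 * pattern[e] for e in active]]
        )
        res = optimize.minimize(
            f, x0, jac=grad, method="BFGS",
            options={"gtol": 1e-12, "maxiter": 2000},
        )
        K = unpack(res.x)
        val = objective_true(K)
        if val < best_val:
            best_val, best_K = val, K
    return best_K


def _all_simple_paths(adj: dict[int, list[int]], s: int, t: int):
    """Yield every simple path from s to t as a node tuple."""
    stack = [(s, (s,))]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + (nxt,)))


def centrality_bruteforce(weights: np.ndarray, tol: float = 1e-12):
    """Closeness and betweenness by exhaustive simple-path enumeration.

    Returns (closeness, betweenness) arrays under the 1/|w| distance rule:
    closeness = 1 / Σ shortest distances to reachable nodes (0 if isolated);
    betweenness = endpoint-excluded fractional path counts normalized by
    (p−1)(p−2)/2.
    """
    p = weights.shape[0]
    adj = {
        i: [j for j in range(p) if j != i and weights[i, j] != 0.0]
        for i in range(p)
    }
    dist = {
        (i, j): 1.0 / abs(weights[i, j]) for i in range(p) for j in adj[i]
    }

    sum_d = np.zeros(p)
    credit = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            lengths, paths = [], []
            for path in _all_simple_paths(adj, s, t):
                paths.append(path)
                lengths.append(sum(dist[(a, b)] for a, b in zip(path, path[1:])))
            if not paths:
                continue
            dmin = min(lengths)
            sum_d[s] += dmin
            sum_d[t] += dmin
            shortest = [pa for pa, le in zip(paths, lengths) if le <= dmin + tol]
            sigma = len(shortest)
            for path in shortest:
                for v in path[1:-1]:
                    credit[v] += 1.0 / sigma

    closeness = np.array([1.0 / d if d > 0 else 0.0 for d in sum_d])
    betweenness = credit / ((p - 1) * (p - 2) / 2.0)
    return closeness, betweenness


def random_network(rng: np.random.Generator, p: int, density: float = 0.5):
    """Random symmetric weight matrix with ~density edges, weights in ±[0.1, 0.9]."""
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                mag = rng.uniform(0.1, 0.9)
                w[i, j] = w[j, i] = mag * rng.choice([-1.0, 1.0])
    return w
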