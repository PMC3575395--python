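"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the MST oracle
enumerates every labeled spanning tree via Prüfer sequences, and the
AutoCM oracle is a direct plain-Python transcription of the update
recursion with scalar loops.
"""

from __future__ import annotations

import itertools

import numpy as np


def prufer_to_edges(seq: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    """Decode a Prüfer sequence into the edge list of a labeled tree on n nodes."""
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    seq = list(seq)
    for x in seq:
        for leaf in range(n):
            if degree[leaf] == 1:
                edges.append((leaf, x))
                degree[leaf] -= 1
                degree[x] -= 1
                break
    last = [i for i in range(n) if degree[i] == 1]
    edges.append((last[0], last[1]))
    return edges


def bruteforce_mst_total(d: np.ndarray) -> float:
    """Minimum spanning-tree total distance by exhaustive enumeration.

    Iterates all n^(n-2) labeled trees (Cayley's formula); practical for
    n <= 6.
    """
    n = d.shape[0]
    if n == 2:
        return float(d[0, 1])
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        total = sum(d[i, j] for i, j in prufer_to_edges(seq, n))
        best = min(best, total)
    return float(best)


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random symmetric non-negative matrix with zero diagonal."""
    a = rng.uniform(0.1, 10.0, size=(n, n))
    d = (a + a.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def scalar_autocm_train(
    records: np.ndarray, C: float, epsilon: float, epochs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Plain-loop online AutoCM trainer: the brute-force recursion oracle.

    Runs exactly ``epochs`` epochs (no convergence test) with the update
    rules written out element by element.
    """
    n_records, n = records.shape
    v = [epsilon] * n
    w = [[epsilon] * n for _ in range(n)]
    for _ in range(epochs):
        for r in range(n_records):
            m_s = records[r]
            m_h = [m_s[i] * (1.0 - v[i] / C) for i in range(n)]
            net = [
                sum(w[i][j] * m_h[j] for j in range(n)) / C for i in range(n)
            ]
            m_t = [m_h[i] * (1.0 - net[i] / C) for i in range(n)]
            dv = [(m_s[i] - m_h[i]) * (1.0 - v[i] / C) for i in range(n)]
            dw = [
                [
                    (m_h[i] - m_t[i]) * (1.0 - w[i][j] / C) * m_h[j]
                    for j in range(n)
                ]
                for i in range(n)
            ]
            for i in range(n):
                v[i] += dv[i]
                for j in range(n):
                    w[i][j] += dw[i][j]
    return np.array(v), np.array(w)


def correlated_pair_fixture(
    seed: int, n_records: int, n_vars: int = 6, loading: float = 0.95
) -> np.ndarray:
    """Equal-marginal dataset where variables 0 and 1 share a latent factor.

    Pairwise correlation of the pair is loading**2 (~0.9 at the default);
    all other variables are independent noise with the same marginal.
    """
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n_records)
    X = np.empty((n_records, n_vars))
    for j in range(n_vars):
        e = rng.standard_normal(n_records)
        z = loading * f + np.sqrt(1 - loading**2) * e if j < 2 else e
        X[:, j] = 0.5 + 0.15 * z
    return np.clip(X, 0.0, 1.0)
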