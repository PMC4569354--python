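"""Brute-force reference implementations used by several test modules.

Deliberately naive (pure-Python loops, Floyd-Warshall) so they share no
code path with the package implementations they check.
"""

import numpy as np


def random_weighted_graph(rng, n, density=1.0):
    A = rng.uniform(0.05, 1.0, (n, n))
    mask = rng.uniform(size=(n, n)) < density
    A = np.where(mask, A, 0.0)
    A = np.triu(A, 1)
    return A + A.T


def oracle_strength(A):
    n = len(A)
    return np.array([sum(A[i][j] for j in range(n)) for i in range(n)])


def oracle_onnela(A):
    n = len(A)
    wmax = A.max()
    C = np.zeros(n)
    if wmax == 0:
        return C
    for i in range(n):
        k = sum(1 for j in range(n) if A[i][j] > 0)
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                acc += ((A[i][j] / wmax) * (A[j][h] / wmax) * (A[i][h] / wmax)) ** (1 / 3)
        C[i] = acc / (k * (k - 1))
    return C


def oracle_floyd_warshall_cpl(A):
    n = len(A)
    INF = float("inf")
    D = [[INF] * n for _ in range(n)]
    for i in range(n):
        D[i][i] = 0.0
        for j in range(n):
            if i != j and A[i][j] > 0:
                D[i][j] = 1.0 / A[i][j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][k] + D[k][j] < D[i][j]:
                    D[i][j] = D[i][k] + D[k][j]
    vals = [D[i][j] for i in range(n) for j in range(n) if i != j]
    return sum(vals) / len(vals)


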