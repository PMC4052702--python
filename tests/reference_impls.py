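"""Independent reference implementations used as test oracles.

These are deliberately naive (pure-Python loops, exact rational
arithmetic, O(n^2) recounts) and share no code with the package, so an
agreement test exercises two genuinely different routes to the same
quantity.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def pls1_reference(X, y, n_components):
    """Textbook PLS1 with explicit loops on Python lists.

    Returns (weights, scores, y_loadings, ssy, yhat, vip) as nested
    lists / floats.
    """
    X = [[float(v) for v in row] for row in X]
    y = [float(v) for v in y]
    n = len(X)
    p = len(X[0])
    W, T, Q, SSY = [], [], [], []
    for _ in range(n_components):
        w = [sum(X[i][j] * y[i] for i in range(n)) for j in range(p)]
        norm = math.sqrt(sum(v * v for v in w))
        if norm < 1e-12:
            break
        w = [v / norm for v in w]
        t = [sum(X[i][j] * w[j] for j in range(p)) for i in range(n)]
        tt = sum(v * v for v in t)
        pa = [sum(X[i][j] * t[i] for i in range(n)) / tt for j in range(p)]
        qa = sum(y[i] * t[i] for i in range(n)) / tt
        for i in range(n):
            for j in range(p):
                X[i][j] -= t[i] * pa[j]
            y[i] -= qa * t[i]
        W.append(w)
        T.append(t)
        Q.append(qa)
        SSY.append(qa * qa * tt)
    A = len(W)
    yhat = [sum(Q[a] * T[a][i] for a in range(A)) for i in range(n)]
    total = sum(SSY)
    vip = [
        math.sqrt(p * sum(SSY[a] * W[a][j] ** 2 for a in range(A)) / total)
        for j in range(p)
    ]
    return W, T, Q, SSY, yhat, vip


def hypergeom_enumerate(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by exhaustively enumerating all C(N, n) draws.

    The universe is 0..N-1 with the first K elements marked; every draw
    of size n is generated and the fraction with at least k marked
    elements is returned as an exact rational. Only feasible for small N.
    """
    marked = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x in marked) >= k:
            hits += 1
    return Fraction(hits, total)


def brute_force_degrees(nodes, edges):
    """Distinct-neighbor count per node by scanning all pairs."""
    deg = {}
    for v in nodes:
        neighbors = set()
        for a, b in edges:
            if a == v and b != v:
                neighbors.add(b)
            elif b == v and a != v:
                neighbors.add(a)
        deg[v] = len(neighbors)
    return deg
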