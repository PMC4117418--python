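"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain loops over the defining formulas, with
no code shared with the package, so agreement is a genuine two-route
check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_mstep(posteriors) -> list[float]:
    """Column means by explicit summation."""
    n = len(posteriors)
    m = len(posteriors[0])
    return [sum(posteriors[i][j] for i in range(n)) / n for j in range(m)]


def brute_kde(points, weights, h, u) -> float:
    """Weighted Gaussian KDE value at a single point u."""
    total = sum(weights)
    acc = 0.0
    for x, w in zip(points, weights):
        z = (u - x) / h
        acc += w * math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
    return acc / (total * h)


def brute_estep(density_values, mixing) -> list[list[float]]:
    """Posteriors from per-cell per-component density products.

    ``density_values[i][j]`` is ``prod_k f_jk(x_ik)`` for cell i and
    component j.
    """
    out = []
    for row in density_values:
        unnorm = [lam * f for lam, f in zip(mixing, row)]
        s = sum(unnorm)
        out.append([u / s for u in unnorm])
    return out


def brute_silhouette(X, labels) -> list[float]:
    """O(n^2) silhouette values with the singleton/degenerate conventions."""
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n = len(labels)

    def dist(i, j):
        return math.sqrt(sum((X[i, k] - X[j, k]) ** 2 for k in range(X.shape[1])))

    out = []
    clusters = sorted(set(labels))
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            out.append(0.0)
            continue
        a = sum(dist(i, j) for j in own) / len(own)
        b = math.inf
        for c in clusters:
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(dist(i, j) for j in members) / len(members))
        denom = max(a, b)
        out.append((b - a) / denom if denom > 0 else 0.0)
    return out


def brute_linear_stat(x, labels):
    """Linear statistic t, permutation mean mu and covariance Sigma by the
    exact conditional-moment formulas, coded with explicit loops."""
    x = [float(v) for v in x]
    labels = list(labels)
    n = len(x)
    classes = sorted(set(labels))
    q = len(classes)
    h = [[1.0 if labels[i] == c else 0.0 for c in classes] for i in range(n)]
    t = [sum(x[i] * h[i][j] for i in range(n)) for j in range(q)]
    Eh = [sum(h[i][j] for i in range(n)) / n for j in range(q)]
    gsum = sum(x)
    mu = [gsum * Eh[j] for j in range(q)]
    Vh = [
        [
            sum((h[i][j] - Eh[j]) * (h[i][k] - Eh[k]) for i in range(n)) / n
            for k in range(q)
        ]
        for j in range(q)
    ]
    factor = (n * sum(v * v for v in x) - gsum * gsum) / (n - 1)
    Sigma = [[Vh[j][k] * factor for k in range(q)] for j in range(q)]
    return np.array(t), np.array(mu), np.array(Sigma)


def brute_quad_stat(x, labels) -> float:
    """Quadratic-form statistic from the brute-force moments."""
    t, mu, Sigma = brute_linear_stat(x, labels)
    d = t - mu
    return float(d @ np.linalg.pinv(Sigma, hermitian=True) @ d)


def exact_perm_pvalue(x, labels) -> float:
    """Exact permutation p-value of the quadratic statistic (n <= 8)."""
    obs = brute_quad_stat(x, labels)
    perms = set(itertools.permutations(labels))
    hits = sum(1 for p in perms if brute_quad_stat(x, list(p)) >= obs - 1e-12)
    return hits / len(perms)


def brute_best_wcss_2partition(X):
    """Exhaustively minimize within-cluster sum of squares over 2-partitions."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    best, best_assign = math.inf, None
    for bits in range(1, 2 ** (n - 1)):  # fix point 0 in group 0
        assign = [(bits >> i) & 1 for i in range(n)]
        wcss = 0.0
        for g in (0, 1):
            members = X[[i for i in range(n) if assign[i] == g]]
            if len(members) == 0:
                wcss = math.inf
                break
            wcss += float(((members - members.mean(axis=0)) ** 2).sum())
        if wcss < best:
            best, best_assign = wcss, assign
    return np.array(best_assign)
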