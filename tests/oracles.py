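"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as directly as possible (double loops,
exhaustive enumeration) and shares no code with the package internals.
"""

from itertools import product

import numpy as np


def brute_force_db(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Davies-Bouldin by direct double loops."""
    k = centroids.shape[0]
    scatter = []
    for i in range(k):
        pts = X[labels == i]
        scatter.append(np.mean([np.linalg.norm(p - centroids[i]) for p in pts]))
    total = 0.0
    for i in range(k):
        worst = -np.inf
        for j in range(k):
            if j == i:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            worst = max(worst, (scatter[i] + scatter[j]) / d)
        total += worst
    return total / k


def brute_force_dunn(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Dunn's index by direct loops over all point pairs."""
    max_diam = 0.0
    for c in range(k):
        pts = X[labels == c]
        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                max_diam = max(max_diam, np.linalg.norm(pts[a] - pts[b]))
    min_sep = np.inf
    for ci in range(k):
        for cj in range(ci + 1, k):
            for p in X[labels == ci]:
                for q in X[labels == cj]:
                    min_sep = min(min_sep, np.linalg.norm(p - q))
    return min_sep / max_diam


def brute_force_dispersion(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    """W_k by the literal ordered-pairwise-squared-distance double sum."""
    w = 0.0
    for r in range(k):
        pts = X[labels == r]
        n_r = len(pts)
        if n_r == 0:
            continue
        d_r = 0.0
        for a in range(n_r):
            for b in range(n_r):
                d_r += float(((pts[a] - pts[b]) ** 2).sum())
        w += d_r / (2.0 * n_r)
    return w


def exhaustive_kmeans(X: np.ndarray, k: int) -> float:
    """Globally optimal k-means objective by enumerating every assignment
    of n points to k non-empty clusters.  Feasible only for tiny n."""
    n = X.shape[0]
    best = np.inf
    for assign in product(range(k), repeat=n):
        labels = np.asarray(assign)
        if len(set(assign)) < k:
            continue
        inertia = 0.0
        for c in range(k):
            pts = X[labels == c]
            inertia += float(((pts - pts.mean(axis=0)) ** 2).sum())
        best = min(best, inertia)
    return best
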