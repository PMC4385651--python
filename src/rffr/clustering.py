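"""Seeded k-means on the normalized cavity-feature matrix.

The trajectory is partitioned by Lloyd's algorithm with k-means++ seeding,
run as a best-of-restarts sweep over a range of cluster counts.  The
implementation is deliberately self-contained and bit-reproducible: nearest
centroid ties break toward the lowest cluster index, restarts consume a
deterministic seed stream, and a cluster that empties mid-iteration is
repaired by handing it the point currently farthest from its own centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MAX_ITER_DEFAULT = 300
N_RESTARTS_DEFAULT = 10


class InvalidKError(ValueError):
    """Requested cluster count is not a positive integer."""


class InfeasibleKError(ValueError):
    """More clusters requested than there are points."""


def _as_matrix(matrix) -> np.ndarray:
    """Accept a raw (n, d) array or any object exposing ``.values``."""
    values = getattr(matrix, "values", matrix)
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("feature matrix must be a non-empty 2-D array")
    return X


def child_seed(seed, *key: int) -> np.random.SeedSequence:
    """Derive a reproducible child seed from an integer or SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        base = seed.entropy
        spawn_key = tuple(seed.spawn_key) + key
    else:
        base = int(seed)
        spawn_key = key
    return np.random.SeedSequence(base, spawn_key=spawn_key)


@dataclass(frozen=True)
class Partition:
    """One k-means solution: labels over [0, k), centroids, and its inertia.

    ``inertia`` is the total within-cluster sum of squared Euclidean
    distances of points to their assigned centroid — the quantity Lloyd's
    algorithm locally minimises.
    """

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: object = 0
    n_restarts: int = N_RESTARTS_DEFAULT

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=float))

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def validate(self, X: np.ndarray, tie_tol: float = 1e-12, inertia_tol: float = 1e-9) -> None:
        """Check the partition invariants against its feature matrix."""
        X = _as_matrix(X)
        sizes = self.cluster_sizes()
        if self.n >= self.k and (sizes == 0).any():
            raise AssertionError("empty cluster in partition")
        d2 = _sq_dists(X, self.centroids)
        own = d2[np.arange(self.n), self.labels]
        if np.any(own > d2.min(axis=1) + tie_tol):
            raise AssertionError("label is not the nearest centroid")
        if abs(own.sum() - self.inertia) > inertia_tol * max(1.0, abs(self.inertia)):
            raise AssertionError("inertia does not match recomputation")


def _sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, (n, k), clipped at zero."""
    d2 = (
        (X * X).sum(axis=1)[:, None]
        - 2.0 * X @ C.T
        + (C * C).sum(axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    return d2


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids with D^2 weighting."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    idx = int(rng.integers(n))
    centers[0] = X[idx]
    closest = _sq_dists(X, centers[:1])[:, 0]
    for j in range(1, k):
        total = closest.sum()
        if total <= 0.0:
            idx = int(rng.integers(n))  # all points coincide with a centroid
        else:
            idx = int(rng.choice(n, p=closest / total))
        centers[j] = X[idx]
        np.minimum(closest, _sq_dists(X, centers[j : j + 1])[:, 0], out=closest)
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    n, _ = X.shape
    k = centers.shape[0]
    prev = None
    labels = None
    for _ in range(max_iter):
        d2 = _sq_dists(X, centers)
        labels = d2.argmin(axis=1)  # argmin ties -> lowest index
        sizes = np.bincount(labels, minlength=k)
        for j in np.flatnonzero(sizes == 0):
            # repair: give the empty cluster the point farthest from its
            # own centroid, never emptying another cluster in the process
            own = d2[np.arange(n), labels].copy()
            own[sizes[labels] <= 1] = -np.inf
            far = int(own.argmax())
            sizes[labels[far]] -= 1
            labels[far] = j
            sizes[j] = 1
        if prev is not None and np.array_equal(labels, prev):
            break
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
        prev = labels
    d2 = _sq_dists(X, centers)
    inertia = float(d2[np.arange(n), labels].sum())
    return labels, centers, inertia


def kmeans(
    matrix,
    k: int,
    seed=0,
    n_restarts: int = N_RESTARTS_DEFAULT,
    max_iter: int = MAX_ITER_DEFAULT,
) -> Partition:
    """Best-of-restarts k-means partition of the feature matrix.

    Parameters
    ----------
    matrix : (n, d) array or NormalizedFeatureMatrix
    k : number of clusters; must satisfy 1 <= k <= n.
    seed : int or numpy SeedSequence; the restart stream is derived from it.
    n_restarts : independent k-means++ initialisations; the lowest-inertia
        solution is returned (ties keep the earliest restart).
    max_iter : Lloyd iteration cap per restart; convergence is declared when
        no label changes.
    """
    X = _as_matrix(matrix)
    n = X.shape[0]
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise InvalidKError(f"k must be a positive integer, got {k!r}")
    if k > n:
        raise InfeasibleKError(f"k={k} exceeds the number of points n={n}")

    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for r in range(max(1, int(n_restarts))):
        rng = np.random.default_rng(child_seed(seed, r))
        centers = _kmeans_pp_init(X, k, rng)
        labels, centers, inertia = _lloyd(X, centers.copy(), max_iter)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    labels, centers, inertia = best
    return Partition(
        k=k,
        labels=labels,
        centroids=centers,
        inertia=inertia,
        seed=seed,
        n_restarts=int(n_restarts),
    )


def sweep(
    matrix,
    k_min: int,
    k_max: int,
    seed=0,
    n_restarts: int = N_RESTARTS_DEFAULT,
    max_iter: int = MAX_ITER_DEFAULT,
) -> list[Partition]:
    """One partition per k in [k_min, k_max], with per-k seeds derived
    deterministically from the master seed.

    Inertia is expected to be non-increasing in k; a violation (possible with
    few restarts) is logged as a warning, not raised.
    """
    X = _as_matrix(matrix)
    n = X.shape[0]
    if not (1 <= k_min <= k_max <= n):
        raise InvalidKError(
            f"need 1 <= k_min <= k_max <= n, got k_min={k_min}, k_max={k_max}, n={n}"
        )
    partitions = []
    prev_inertia = np.inf
    for k in range(int(k_min), int(k_max) + 1):
        part = kmeans(X, k, seed=child_seed(seed, k), n_restarts=n_restarts, max_iter=max_iter)
        part = Partition(
            k=part.k,
            labels=part.labels,
            centroids=part.centroids,
            inertia=part.inertia,
            seed=seed,
            n_restarts=int(n_restarts),
        )
        if part.inertia > prev_inertia * (1 + 1e-12):
            logger.warning(
                "inertia increased from k=%d to k=%d (%.6g -> %.6g); "
                "consider more restarts",
                k - 1, k, prev_inertia, part.inertia,
            )
        prev_inertia = part.inertia
        partitions.append(part)
    return partitions
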