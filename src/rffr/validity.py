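"""Cluster-validity indices and the partition selection rule.

Three classical indices score each partition of the trajectory:

* Davies-Bouldin (DB) — mean over clusters of the worst within-to-between
  scatter ratio; lower is better.
* Dunn's index — minimum single-linkage inter-cluster distance divided by
  the maximum intra-cluster diameter; higher is better.
* Gap statistic — expected log within-cluster dispersion under a uniform
  reference null minus the observed log dispersion; higher indicates
  stronger cluster structure.

The pooled within-cluster dispersion W_k is the sum over clusters r of
D_r / (2 n_r), with D_r the sum of squared Euclidean distances over all
ordered point pairs inside cluster r.  That double sum collapses
algebraically to the within-cluster sum of squares about the cluster mean,
which is how it is computed here; on a converged k-means partition it
therefore equals the k-means inertia.

When the three indices disagree on the optimal k, the gap value is the
decisive criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .clustering import Partition, _as_matrix, _sq_dists, child_seed, kmeans

logger = logging.getLogger(__name__)

B_REFS_DEFAULT = 50


class UndefinedIndexError(ValueError):
    """The index is not defined for this partition (e.g. k < 2)."""


class DegeneratePartitionError(ValueError):
    """The partition geometry makes the index undefined (coincident centroids)."""


class DegenerateDispersionError(ValueError):
    """W_k = 0: every cluster is a singleton or a set of duplicates."""


class EmptyInputError(ValueError):
    """An operation received an empty sweep or table."""


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

def davies_bouldin(matrix, partition: Partition) -> float:
    """DB = (1/k) sum_i max_{j!=i} (dbar_i + dbar_j) / d_ij.

    dbar_i is the mean Euclidean distance of cluster-i points to their
    centroid; d_ij is the Euclidean distance between centroids i and j.
    """
    X = _as_matrix(matrix)
    k = partition.k
    if k < 2:
        raise UndefinedIndexError("Davies-Bouldin requires k >= 2")
    dists = np.sqrt(_sq_dists(X, partition.centroids))
    scatter = np.array([
        dists[partition.labels == i, i].mean() for i in range(k)
    ])
    centroid_d = squareform(pdist(partition.centroids))
    if np.any(centroid_d[~np.eye(k, dtype=bool)] == 0.0):
        raise DegeneratePartitionError("coincident centroids")
    ratio = (scatter[:, None] + scatter[None, :]) / np.where(centroid_d == 0, np.inf, centroid_d)
    np.fill_diagonal(ratio, -np.inf)
    return float(ratio.max(axis=1).mean())


def dunn_index(matrix, partition: Partition, pairwise: np.ndarray | None = None) -> float:
    """Minimum inter-cluster distance over maximum intra-cluster diameter.

    Inter-cluster distance is single linkage (closest point pair between the
    two clusters); the diameter is the largest intra-cluster point pair
    distance.  A precomputed condensed or square pairwise-distance matrix may
    be supplied to amortise the O(n^2) cost across a sweep.
    """
    X = _as_matrix(matrix)
    k = partition.k
    if k < 2:
        raise UndefinedIndexError("Dunn's index requires k >= 2")
    if pairwise is None:
        pairwise = squareform(pdist(X))
    elif pairwise.ndim == 1:
        pairwise = squareform(pairwise)
    labels = partition.labels
    masks = [labels == i for i in range(k)]
    max_diam = 0.0
    for m in masks:
        sub = pairwise[np.ix_(m, m)]
        if sub.size:
            max_diam = max(max_diam, float(sub.max()))
    if max_diam == 0.0:
        raise UndefinedIndexError("all clusters are singletons: diameter is zero")
    min_sep = np.inf
    for i in range(k):
        for j in range(i + 1, k):
            min_sep = min(min_sep, float(pairwise[np.ix_(masks[i], masks[j])].min()))
    return min_sep / max_diam


def pooled_dispersion(matrix, labels: np.ndarray, k: int) -> float:
    """W_k = sum_r D_r / (2 n_r) over clusters, D_r the ordered pairwise
    squared-distance sum — computed via its closed form, the within-cluster
    sum of squares about each cluster mean."""
    X = _as_matrix(matrix)
    labels = np.asarray(labels, dtype=int)
    w = 0.0
    for r in range(k):
        pts = X[labels == r]
        if pts.shape[0] > 1:
            w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


# ---------------------------------------------------------------------------
# gap statistic
# ---------------------------------------------------------------------------

def gap_statistic(
    matrix,
    partitions: list[Partition],
    b_refs: int = B_REFS_DEFAULT,
    seed=0,
    max_iter: int = 300,
) -> pd.DataFrame:
    """Gap(k) = mean_b log W_k^(b) - log W_k over reference datasets.

    Each of the ``b_refs`` reference datasets is drawn uniformly over the
    per-column [min, max] box of the observed matrix and clustered with the
    same k-means settings (restarts, iteration cap) as the observed
    partitions.  Returns a frame with columns ``k, gap, gap_se, log_wk``
    where ``gap_se`` is sd_b[log W_k^(b)] * sqrt(1 + 1/b_refs).
    """
    X = _as_matrix(matrix)
    if b_refs < 2:
        raise ValueError("b_refs must be >= 2")
    ks = [p.k for p in partitions]
    n_restarts = partitions[0].n_restarts
    log_wk = np.empty(len(ks))
    for i, part in enumerate(partitions):
        w = pooled_dispersion(X, part.labels, part.k)
        if w <= 0.0:
            raise DegenerateDispersionError(f"W_k = 0 at k={part.k}")
        log_wk[i] = np.log(w)

    lo = X.min(axis=0)
    hi = X.max(axis=0)
    ref_log_w = np.empty((b_refs, len(ks)))
    for b in range(b_refs):
        rng = np.random.default_rng(child_seed(seed, 7, b))
        ref = rng.uniform(lo, hi, size=X.shape)
        for i, k in enumerate(ks):
            part = kmeans(ref, k, seed=child_seed(seed, 7, b, k),
                          n_restarts=n_restarts, max_iter=max_iter)
            w = pooled_dispersion(ref, part.labels, k)
            if w <= 0.0:
                raise DegenerateDispersionError(f"reference W_k = 0 at k={k}")
            ref_log_w[b, i] = np.log(w)

    gap = ref_log_w.mean(axis=0) - log_wk
    gap_se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / b_refs)
    return pd.DataFrame({"k": ks, "gap": gap, "gap_se": gap_se, "log_wk": log_wk})


# ---------------------------------------------------------------------------
# sweep evaluation and selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidityRecord:
    k: int
    db: float
    dunn: float
    gap: float
    gap_se: float
    log_wk: float
    b_refs: int


@dataclass
class ValiditySweep:
    """Per-k validity record for a clustering sweep, sorted by k."""

    records: list[ValidityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.k)
        ks = [r.k for r in self.records]
        if len(set(ks)) != len(ks):
            raise ValueError("duplicate k in validity sweep")
        for r in self.records:
            if r.db < 0 or r.dunn < 0:
                raise ValueError("DB and Dunn must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def evaluate_sweep(
    matrix,
    partitions: list[Partition],
    b_refs: int = B_REFS_DEFAULT,
    seed=0,
) -> ValiditySweep:
    """Score every partition of a sweep with DB, Dunn and the gap statistic."""
    X = _as_matrix(matrix)
    if not partitions:
        raise EmptyInputError("no partitions to evaluate")
    pairwise = squareform(pdist(X))
    gap_frame = gap_statistic(X, partitions, b_refs=b_refs, seed=seed)
    records = []
    for part, (_, row) in zip(partitions, gap_frame.iterrows()):
        records.append(ValidityRecord(
            k=part.k,
            db=davies_bouldin(X, part),
            dunn=dunn_index(X, part, pairwise=pairwise),
            gap=float(row["gap"]),
            gap_se=float(row["gap_se"]),
            log_wk=float(row["log_wk"]),
            b_refs=int(b_refs),
        ))
    return ValiditySweep(records)


@dataclass(frozen=True)
class SelectionResult:
    chosen_k: int
    candidate_db: int
    candidate_dunn: int
    candidate_gap: int
    rationale: str


def select_partition(sweep: ValiditySweep, gap_rule: str = "se") -> SelectionResult:
    """Pick the optimal k from a validity sweep.

    Each index nominates a candidate: DB its argmin, Dunn its argmax (ties
    toward smaller k), and the gap statistic its optimum within simulation
    tolerance.  Unanimity decides immediately; otherwise the gap value is
    the decisive criterion among the distinct candidates, with remaining
    ties broken by higher Dunn, then lower DB, then smaller k.

    The default gap candidate uses the one-standard-error rule — the
    smallest k with gap(k) >= gap(k+1) - se(k+1) — because past the optimum
    the gap curve flattens into a plateau whose Monte-Carlo noise makes a
    plain argmax drift toward large k.  ``gap_rule="max"`` selects the
    plain argmax instead.
    """
    if not sweep.records:
        raise EmptyInputError("empty validity sweep")
    recs = sweep.records
    by_k = {r.k: r for r in recs}

    candidate_db = min(recs, key=lambda r: (r.db, r.k)).k
    candidate_dunn = min(recs, key=lambda r: (-r.dunn, r.k)).k
    if gap_rule == "max":
        candidate_gap = min(recs, key=lambda r: (-r.gap, r.k)).k
    elif gap_rule == "se":
        candidate_gap = recs[-1].k
        for cur, nxt in zip(recs, recs[1:]):
            if cur.gap >= nxt.gap - nxt.gap_se:
                candidate_gap = cur.k
                break
    else:
        raise ValueError(f"unknown gap_rule {gap_rule!r}")

    lines = [
        f"DB candidate: k={candidate_db} (argmin DB)",
        f"Dunn candidate: k={candidate_dunn} (argmax Dunn)",
        f"gap candidate: k={candidate_gap} (rule={gap_rule})",
    ]
    candidates = sorted({candidate_db, candidate_dunn, candidate_gap})
    if len(candidates) == 1:
        chosen = candidates[0]
        lines.append(f"all criteria agree on k={chosen}")
    else:
        ranked = sorted(
            candidates,
            key=lambda k: (-by_k[k].gap, -by_k[k].dunn, by_k[k].db, k),
        )
        chosen = ranked[0]
        for k in candidates:
            r = by_k[k]
            lines.append(
                f"k={k}: gap={r.gap:.6g}, dunn={r.dunn:.6g}, db={r.db:.6g}"
            )
        lines.append(
            f"criteria disagree; gap is decisive -> k={chosen}"
        )
    return SelectionResult(
        chosen_k=chosen,
        candidate_db=candidate_db,
        candidate_dunn=candidate_dunn,
        candidate_gap=candidate_gap,
        rationale="\n".join(lines),
    )
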