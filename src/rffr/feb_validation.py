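"""Docking-based validation of a partition and reduced-ensemble selection.

Docking results (free energy of binding, FEB, kcal/mol; more negative is
more favorable) are joined with cluster labels, summarised as per-cluster
medians independently for each ligand, and scored for cross-ligand
agreement: if the partition captures binding-relevant cavity states, every
ligand should find its best (lowest) median FEB in the same cluster, and
the ligands should rank the clusters similarly.  The reduced ensemble
(RFFR) keeps a small number of representatives per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .clustering import Partition, _as_matrix, _sq_dists

logger = logging.getLogger(__name__)

DOCKING_COLUMNS = ("snapshot_id", "ligand_id", "run", "feb_kcal_mol")


class DockingTableError(ValueError):
    """The docking table violates its schema or uniqueness invariants."""


class JoinError(KeyError):
    """A docked snapshot has no cluster label."""


class UndefinedRankError(ValueError):
    """Rank consistency needs at least two clusters and two ligands."""


class MissingInputError(ValueError):
    """A selection mode requires an input that was not supplied."""


def read_docking_table(path) -> pd.DataFrame:
    """Read and validate a docking CSV (snapshot_id,ligand_id,run,feb_kcal_mol)."""
    df = pd.read_csv(path, dtype={"snapshot_id": str, "ligand_id": str})
    return validate_docking_table(df)


def validate_docking_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DOCKING_COLUMNS if c not in df.columns]
    if missing:
        raise DockingTableError(f"missing column(s): {', '.join(missing)}")
    if df.empty:
        raise DockingTableError("docking table is empty")
    if not np.isfinite(df["feb_kcal_mol"].to_numpy(dtype=float)).all():
        raise DockingTableError("non-finite FEB value")
    if df.duplicated(subset=["snapshot_id", "ligand_id", "run"]).any():
        raise DockingTableError("duplicate (snapshot_id, ligand_id, run) row")
    return df


def snapshot_feb(table: pd.DataFrame, policy: str = "min") -> pd.DataFrame:
    """Collapse docking runs to one FEB per (snapshot, ligand).

    The default ``min`` policy keeps the most favorable (lowest) energy over
    the runs, the usual docking convention; ``mean`` averages them.  The
    policy is recorded in the result's ``attrs``.
    """
    table = validate_docking_table(table)
    if policy not in ("min", "mean"):
        raise ValueError(f"unknown collapse policy {policy!r}")
    grouped = table.groupby(["snapshot_id", "ligand_id"], sort=True)["feb_kcal_mol"]
    out = (grouped.min() if policy == "min" else grouped.mean()).reset_index()
    out = out.rename(columns={"feb_kcal_mol": "feb"})
    out.attrs["collapse_policy"] = policy
    return out


@dataclass
class ClusterFEBSummary:
    """Per-(ligand, cluster) median FEB with the best-cluster concordance.

    ``medians`` has columns ligand_id, cluster, median_feb, n_snapshots;
    ``best_cluster`` maps each ligand to the cluster of its lowest median
    (argmin ties broken toward the lower cluster index and recorded);
    ``concordance`` is the fraction of ligands whose best cluster equals
    the modal best cluster.
    """

    medians: pd.DataFrame
    best_cluster: pd.Series
    modal_cluster: int
    concordance: float
    ties: dict = field(default_factory=dict)
    per_snapshot: pd.DataFrame | None = None

    @property
    def ligands(self) -> list[str]:
        return self.best_cluster.index.tolist()


def cluster_feb_summary(per_snapshot: pd.DataFrame, clusters) -> ClusterFEBSummary:
    """Median FEB per (ligand, cluster) and the cross-ligand concordance.

    ``clusters`` maps snapshot_id -> cluster index (a mapping or a pandas
    Series).  Every docked snapshot must have a label; clusters with no
    docked snapshot for a ligand are simply absent from that ligand's
    argmin (and logged).
    """
    if not isinstance(clusters, pd.Series):
        clusters = pd.Series(dict(clusters))
    docked = per_snapshot["snapshot_id"]
    unknown = set(docked.unique()) - set(clusters.index)
    if unknown:
        raise JoinError(f"docked snapshot(s) missing from partition: {sorted(unknown)[:5]}")
    joined = per_snapshot.copy()
    joined["cluster"] = clusters.loc[docked].to_numpy()
    medians = (
        joined.groupby(["ligand_id", "cluster"], sort=True)["feb"]
        .agg(median_feb="median", n_snapshots="size")
        .reset_index()
    )
    n_clusters = clusters.nunique()
    best = {}
    ties = {}
    for ligand, grp in medians.groupby("ligand_id", sort=True):
        if grp["cluster"].nunique() < n_clusters:
            logger.info("ligand %s: %d cluster(s) have no docked snapshot",
                        ligand, n_clusters - grp["cluster"].nunique())
        lo = grp["median_feb"].min()
        winners = sorted(grp.loc[grp["median_feb"] == lo, "cluster"].tolist())
        best[ligand] = int(winners[0])
        if len(winners) > 1:
            ties[ligand] = winners
    best = pd.Series(best, name="best_cluster")
    modal = int(best.mode().iloc[0])
    concordance = float((best == modal).mean())
    return ClusterFEBSummary(
        medians=medians,
        best_cluster=best,
        modal_cluster=modal,
        concordance=concordance,
        ties=ties,
        per_snapshot=per_snapshot,
    )


def rank_consistency(summary: ClusterFEBSummary) -> tuple[pd.DataFrame, float]:
    """Spearman rank correlation of cluster orderings (by median FEB)
    between every ligand pair, and the mean over pairs.

    A correlation of +1 for every pair means all ligands sort the clusters
    identically — the signature of a ligand-independent cavity-state
    ranking.
    """
    wide = summary.medians.pivot(index="cluster", columns="ligand_id", values="median_feb")
    if wide.shape[0] < 2:
        raise UndefinedRankError("rank consistency needs at least two clusters")
    ligands = list(wide.columns)
    if len(ligands) < 2:
        raise UndefinedRankError("rank consistency needs at least two ligands")
    rows = []
    for i, a in enumerate(ligands):
        for b in ligands[i + 1:]:
            pair = wide[[a, b]].dropna()
            rho = spearmanr(pair[a], pair[b]).statistic
            rows.append({"ligand_a": a, "ligand_b": b, "spearman_rho": float(rho)})
    frame = pd.DataFrame(rows)
    return frame, float(frame["spearman_rho"].mean())


@dataclass
class RFFRSelection:
    """The reduced snapshot ensemble: ids, per-cluster counts, and policy."""

    snapshot_ids: list[str]
    per_cluster: dict
    policy: dict

    def __len__(self) -> int:
        return len(self.snapshot_ids)


def build_rffr(
    partition: Partition,
    matrix,
    summary: ClusterFEBSummary | None = None,
    min_per_cluster: int = 2,
    mode: str = "medoids",
    row_ids: list[str] | None = None,
) -> RFFRSelection:
    """Select ``min_per_cluster`` representatives from every cluster.

    ``medoids`` mode takes, per cluster, the members nearest the centroid;
    ``best_feb`` mode (requires ``summary`` built from per-snapshot FEB)
    takes the members with the lowest per-snapshot FEB averaged over
    ligands.  Undersized clusters contribute all their members (logged).
    ``row_ids`` aligns snapshot ids with the partition labels; when omitted
    they are taken from the matrix (NormalizedFeatureMatrix.row_ids).
    """
    if min_per_cluster < 1:
        raise ValueError("min_per_cluster must be >= 1")
    if mode not in ("medoids", "best_feb"):
        raise ValueError(f"unknown selection mode {mode!r}")
    if row_ids is None:
        row_ids = getattr(matrix, "row_ids", None)
    if row_ids is None:
        raise MissingInputError("row_ids required when matrix carries no snapshot ids")
    X = _as_matrix(matrix)
    labels = partition.labels
    ids = np.asarray(row_ids, dtype=object)

    if mode == "best_feb":
        if summary is None or summary.per_snapshot is None:
            raise MissingInputError("best_feb mode requires a ClusterFEBSummary")

    selected: list[str] = []
    per_cluster: dict[int, int] = {}
    for c in range(partition.k):
        members = np.flatnonzero(labels == c)
        take = min(min_per_cluster, members.size)
        if members.size < min_per_cluster:
            logger.warning("cluster %d has only %d member(s); taking all", c, members.size)
        if mode == "medoids":
            d2 = _sq_dists(X[members], partition.centroids[c : c + 1])[:, 0]
            order = np.lexsort((members, d2))  # distance, then row order
        else:
            score = summary_mean_feb(summary, ids[members])
            order = np.lexsort((members, score))
        chosen = members[order[:take]]
        selected.extend(ids[chosen].tolist())
        per_cluster[c] = int(take)
    return RFFRSelection(
        snapshot_ids=selected,
        per_cluster=per_cluster,
        policy={"mode": mode, "min_per_cluster": int(min_per_cluster)},
    )


def summary_mean_feb(summary: ClusterFEBSummary, snapshot_ids: np.ndarray) -> np.ndarray:
    """Per-snapshot FEB averaged over ligands, for best_feb selection."""
    per_snap = summary.per_snapshot
    means = per_snap.groupby("snapshot_id", sort=False)["feb"].mean()
    return means.reindex(snapshot_ids).to_numpy(dtype=float)


def write_rffr(selection: RFFRSelection, path) -> None:
    Path(path).write_text("\n".join(selection.snapshot_ids) + "\n")
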