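"""Synthetic trajectory-feature and docking-score tables with planted structure.

The generator emulates the statistical shape of the data the analysis
consumes: an MD trajectory sampled at a fixed interval whose
binding-cavity descriptors fall into a small number of conformational
states (a Gaussian mixture over the four features), and a rigid-docking
results table in which the free energy of binding (FEB) of every ligand is
shifted by a cluster-dependent offset, with one distinguished "best"
conformational state that binds every ligand most favorably.

Defaults mirror a 20 ns trajectory sampled every 1 ps (20,000 snapshots),
10 conformational states, 20 ligands and 25 docking runs per
(snapshot, ligand) pair, on InhA-like cavity scales: areas of several
hundred A^2, volumes of 1-2 thousand A^3, a few hundred heavy atoms, and
RMSD of a few Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_io import FEATURE_COLUMNS, TrajectoryFeatureTable


class InvalidSpecError(ValueError):
    """The synthetic specification violates one of its invariants."""


class InvalidLabelError(ValueError):
    """A cluster label falls outside [0, n_clusters)."""


# per-feature sampling box for cluster means and the common within-cluster
# standard deviations, in (area A^2, volume A^3, heavy atoms, RMSD A)
_MEAN_LOW = np.array([450.0, 800.0, 250.0, 0.5])
_MEAN_HIGH = np.array([1150.0, 2000.0, 320.0, 3.5])
_DEFAULT_SD = np.array([7.0, 12.0, 0.7, 0.03])


def pooled_sd(cluster_sds: np.ndarray) -> float:
    """Scalar pooled within-cluster spread: the Euclidean norm of the
    root-mean-square per-feature standard deviation across clusters."""
    sds = np.asarray(cluster_sds, dtype=float)
    return float(np.sqrt((sds ** 2).mean(axis=0).sum()))


def separated_means(
    n_clusters: int,
    cluster_sds: np.ndarray | None = None,
    min_sep_sds: float = 12.0,
    seed: int = 20170913,
    max_tries: int = 100_000,
) -> np.ndarray:
    """Draw cluster mean vectors in the realistic feature box, rejecting any
    candidate closer than ``min_sep_sds`` pooled standard deviations to an
    already-placed mean.  Deterministic for a fixed seed."""
    sds = _DEFAULT_SD[None, :].repeat(n_clusters, axis=0) if cluster_sds is None \
        else np.asarray(cluster_sds, dtype=float)
    min_dist = min_sep_sds * pooled_sd(sds)
    rng = np.random.default_rng(seed)
    means: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = rng.uniform(_MEAN_LOW, _MEAN_HIGH)
        if all(np.linalg.norm(cand - m) >= min_dist for m in means):
            means.append(cand)
            if len(means) == n_clusters:
                return np.asarray(means)
    raise InvalidSpecError(
        f"could not place {n_clusters} means at separation {min_sep_sds} pooled sds"
    )


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    ``feb_cluster_offset`` must have a unique minimum: the distinguished
    best-binding conformational state.
    """

    n_clusters: int
    duration_ns: float
    interval_ps: float
    cluster_means: np.ndarray
    cluster_sds: np.ndarray
    mixing_weights: np.ndarray
    ligand_ids: tuple
    feb_base: np.ndarray
    feb_cluster_offset: np.ndarray
    feb_noise_sd: float
    runs_per_pair: int
    seed: int = 0
    constant_heavy_atoms: bool = False

    def __post_init__(self) -> None:
        self.cluster_means = np.asarray(self.cluster_means, dtype=float)
        self.cluster_sds = np.asarray(self.cluster_sds, dtype=float)
        self.mixing_weights = np.asarray(self.mixing_weights, dtype=float)
        self.feb_base = np.asarray(self.feb_base, dtype=float)
        self.feb_cluster_offset = np.asarray(self.feb_cluster_offset, dtype=float)
        self.ligand_ids = tuple(str(l) for l in self.ligand_ids)
        k = self.n_clusters
        if k < 1:
            raise InvalidSpecError("n_clusters must be positive")
        if self.duration_ns <= 0 or self.interval_ps <= 0:
            raise InvalidSpecError("duration_ns and interval_ps must be positive")
        if self.runs_per_pair < 1:
            raise InvalidSpecError("runs_per_pair must be positive")
        if self.feb_noise_sd < 0:
            raise InvalidSpecError("feb_noise_sd must be non-negative")
        if self.cluster_means.shape != (k, 4) or self.cluster_sds.shape != (k, 4):
            raise InvalidSpecError("cluster_means and cluster_sds must be (n_clusters, 4)")
        if (self.cluster_sds < 0).any():
            raise InvalidSpecError("cluster_sds must be non-negative")
        if self.mixing_weights.shape != (k,):
            raise InvalidSpecError("mixing_weights must have one entry per cluster")
        if (self.mixing_weights <= 0).any() or abs(self.mixing_weights.sum() - 1.0) > 1e-9:
            raise InvalidSpecError("mixing_weights must be positive and sum to 1")
        if self.feb_base.shape != (len(self.ligand_ids),):
            raise InvalidSpecError("feb_base must have one entry per ligand")
        if self.feb_cluster_offset.shape != (k,):
            raise InvalidSpecError("feb_cluster_offset must have one entry per cluster")
        off = self.feb_cluster_offset
        if k > 1 and (off == off.min()).sum() != 1:
            raise InvalidSpecError("exactly one cluster must attain the minimum FEB offset")

    @property
    def n_snapshots(self) -> int:
        return math.floor(self.duration_ns * 1000.0 / self.interval_ps)

    @property
    def best_cluster(self) -> int:
        return int(self.feb_cluster_offset.argmin())


def default_spec(seed: int = 0, n_clusters: int = 10, duration_ns: float = 20.0,
                 interval_ps: float = 1.0, n_ligands: int = 20,
                 runs_per_pair: int = 25) -> SyntheticSpec:
    """The default study conditions: 10 well-separated conformational
    states over a 20 ns / 1 ps trajectory, 20 ligands, 25 runs per pair,
    one state binding every ligand best by a 1.2 kcal/mol margin."""
    sds = _DEFAULT_SD[None, :].repeat(n_clusters, axis=0)
    means = separated_means(n_clusters, sds)
    rng = np.random.default_rng(20170913)
    feb_base = rng.uniform(-9.0, -6.0, size=n_ligands)
    offsets = rng.uniform(-0.8, 0.0, size=n_clusters)
    offsets[n_clusters // 2] = -2.0  # distinguished best-binding state
    return SyntheticSpec(
        n_clusters=n_clusters,
        duration_ns=duration_ns,
        interval_ps=interval_ps,
        cluster_means=means,
        cluster_sds=sds,
        mixing_weights=np.full(n_clusters, 1.0 / n_clusters),
        ligand_ids=tuple(f"LIG{i:02d}" for i in range(n_ligands)),
        feb_base=feb_base,
        feb_cluster_offset=offsets,
        feb_noise_sd=0.5,
        runs_per_pair=runs_per_pair,
        seed=seed,
    )


def snapshot_ids(n: int) -> list[str]:
    return [f"snap_{i:06d}" for i in range(1, n + 1)]


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Per-entry Gaussian draws resampled until non-negative (not clipped,
    so within-cluster distributions stay unimodal)."""
    out = rng.normal(mean, sd)
    bad = out < 0.0
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd[bad])
        bad = out < 0.0
    return out


def generate_feature_table(spec: SyntheticSpec) -> tuple[TrajectoryFeatureTable, np.ndarray]:
    """Sample the trajectory feature table and return it with the true
    cluster labels for recovery tests.

    Row i (1-based) is stamped at time i * interval_ps; its cluster is drawn
    from the mixing weights and its features from that cluster's Gaussian,
    truncated at zero, with the heavy-atom count rounded to the nearest
    non-negative integer.  Identical seeds give identical tables.
    """
    n = spec.n_snapshots
    if n < 1:
        raise InvalidSpecError("spec implies zero snapshots")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    labels = rng.choice(spec.n_clusters, size=n, p=spec.mixing_weights)
    means = spec.cluster_means[labels]
    sds = spec.cluster_sds[labels]
    feats = _truncated_normal(rng, means, sds)
    heavy = np.rint(feats[:, 2]).astype(int)
    if spec.constant_heavy_atoms:
        heavy = np.full(n, int(round(float(spec.cluster_means[:, 2].mean()))))
    frame = pd.DataFrame({
        "snapshot_id": snapshot_ids(n),
        "time_ps": np.arange(1, n + 1, dtype=float) * spec.interval_ps,
        "area_A2": feats[:, 0],
        "volume_A3": feats[:, 1],
        "heavy_atoms": heavy,
        "rmsd_A": feats[:, 3],
    })
    return TrajectoryFeatureTable(frame), labels


def generate_docking_table(spec: SyntheticSpec, labels: np.ndarray) -> pd.DataFrame:
    """Sample the docking FEB table for every (snapshot, ligand, run).

    FEB ~ Normal(feb_base[ligand] + feb_cluster_offset[label], feb_noise_sd),
    in kcal/mol.  Columns: snapshot_id, ligand_id, run, feb_kcal_mol.
    """
    labels = np.asarray(labels, dtype=int)
    n = spec.n_snapshots
    if labels.shape != (n,):
        raise InvalidSpecError(
            f"labels length {labels.shape} does not match the {n} snapshots the spec implies"
        )
    if labels.min() < 0 or labels.max() >= spec.n_clusters:
        raise InvalidLabelError("cluster label outside [0, n_clusters)")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    ids = snapshot_ids(n)
    n_lig = len(spec.ligand_ids)
    runs = spec.runs_per_pair
    total = n * n_lig * runs
    mean = (spec.feb_base[None, :, None] + spec.feb_cluster_offset[labels][:, None, None])
    feb = mean + rng.normal(0.0, spec.feb_noise_sd, size=(n, n_lig, runs)) \
        if spec.feb_noise_sd > 0 else np.broadcast_to(mean, (n, n_lig, runs))
    return pd.DataFrame({
        "snapshot_id": np.repeat(ids, n_lig * runs),
        "ligand_id": np.tile(np.repeat(spec.ligand_ids, runs), n),
        "run": np.tile(np.arange(1, runs + 1), n * n_lig),
        "feb_kcal_mol": np.asarray(feb, dtype=float).reshape(total),
    })


def write_true_labels(labels: np.ndarray, path) -> None:
    pd.DataFrame({"cluster": np.asarray(labels, dtype=int)}).to_csv(path, index=False)
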