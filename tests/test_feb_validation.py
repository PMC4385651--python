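"""FEB-based partition validation and reduced-ensemble selection."""

import numpy as np
import pandas as pd
import pytest

from rffr.clustering import Partition
from rffr.feb_validation import (
    DockingTableError,
    JoinError,
    MissingInputError,
    UndefinedRankError,
    build_rffr,
    cluster_feb_summary,
    rank_consistency,
    read_docking_table,
    snapshot_feb,
    validate_docking_table,
    write_rffr,
)
from rffr.feature_io import minmax_normalize
from rffr.synthetic_data import generate_docking_table, generate_feature_table, snapshot_ids

from conftest import make_spec


def docking_frame(rows):
    return pd.DataFrame(rows, columns=["snapshot_id", "ligand_id", "run", "feb_kcal_mol"])


class TestSnapshotFEB:
    def test_min_policy_keeps_most_favorable_run(self):
        table = docking_frame([("s1", "L", 1, -8.1), ("s1", "L", 2, -7.9),
                               ("s1", "L", 3, -8.4)])
        out = snapshot_feb(table)
        assert out.loc[0, "feb"] == pytest.approx(-8.4)
        assert out.attrs["collapse_policy"] == "min"

    def test_single_run_is_identity(self):
        out = snapshot_feb(docking_frame([("s1", "L", 1, -6.5)]))
        assert out.loc[0, "feb"] == pytest.approx(-6.5)

    def test_mean_policy(self):
        table = docking_frame([("s1", "L", 1, -8.0), ("s1", "L", 2, -6.0)])
        out = snapshot_feb(table, policy="mean")
        assert out.loc[0, "feb"] == pytest.approx(-7.0)

    def test_duplicate_run_rejected(self):
        table = docking_frame([("s1", "L", 1, -8.0), ("s1", "L", 1, -6.0)])
        with pytest.raises(DockingTableError):
            validate_docking_table(table)

    def test_round_trip_through_csv(self, tmp_path):
        table = docking_frame([("s1", "L", 1, -8.0), ("s2", "L", 1, -7.0)])
        path = tmp_path / "docking.csv"
        table.to_csv(path, index=False)
        back = read_docking_table(path)
        pd.testing.assert_frame_equal(back, table)


class TestClusterSummary:
    def test_odd_count_median(self):
        per_snap = pd.DataFrame({
            "snapshot_id": ["a", "b", "c"], "ligand_id": ["L"] * 3,
            "feb": [-8.0, -7.0, -9.0],
        })
        clusters = pd.Series({"a": 0, "b": 0, "c": 0})
        summary = cluster_feb_summary(per_snap, clusters)
        assert summary.medians.loc[0, "median_feb"] == pytest.approx(-8.0)
        assert summary.medians.loc[0, "n_snapshots"] == 3

    def test_planted_best_cluster_gives_full_concordance(self):
        spec = make_spec(n_clusters=3, n_rows=120, feb_noise_sd=0.1, seed=21)
        _, labels = generate_feature_table(spec)
        docking = generate_docking_table(spec, labels)
        per_snap = snapshot_feb(docking)
        clusters = pd.Series(labels, index=snapshot_ids(len(labels)))
        summary = cluster_feb_summary(per_snap, clusters)
        assert summary.modal_cluster == spec.best_cluster
        assert summary.concordance == pytest.approx(1.0)

    def test_two_ligands_with_opposite_best_clusters(self):
        rows = []
        for snap, cluster in [("a", 0), ("b", 1)]:
            rows.append((snap, "L1", 1, -9.0 if cluster == 0 else -6.0))
            rows.append((snap, "L2", 1, -6.0 if cluster == 0 else -9.0))
        per_snap = snapshot_feb(docking_frame(rows))
        summary = cluster_feb_summary(per_snap, pd.Series({"a": 0, "b": 1}))
        assert summary.concordance == pytest.approx(0.5)

    def test_missing_snapshot_label_is_join_error(self):
        per_snap = pd.DataFrame({
            "snapshot_id": ["a", "zzz"], "ligand_id": ["L", "L"], "feb": [-8.0, -7.0],
        })
        with pytest.raises(JoinError, match="zzz"):
            cluster_feb_summary(per_snap, pd.Series({"a": 0}))

    def test_medians_invariant_under_within_cluster_permutation(self):
        spec = make_spec(n_clusters=3, n_rows=60, seed=2)
        _, labels = generate_feature_table(spec)
        docking = generate_docking_table(spec, labels)
        per_snap = snapshot_feb(docking)
        clusters = pd.Series(labels, index=snapshot_ids(len(labels)))
        base = cluster_feb_summary(per_snap, clusters)
        shuffled = per_snap.sample(frac=1.0, random_state=0).reset_index(drop=True)
        again = cluster_feb_summary(shuffled, clusters)
        pd.testing.assert_frame_equal(base.medians, again.medians)


class TestRankConsistency:
    def _summary_from_offsets(self, offsets_by_ligand, n_clusters):
        rows = []
        for ligand, offsets in offsets_by_ligand.items():
            for c, off in enumerate(offsets):
                rows.append({"ligand_id": ligand, "cluster": c,
                             "median_feb": off, "n_snapshots": 5})
        medians = pd.DataFrame(rows)
        per = medians.rename(columns={"median_feb": "feb"})
        from rffr.feb_validation import ClusterFEBSummary
        best = medians.loc[medians.groupby("ligand_id")["median_feb"].idxmin()]
        series = pd.Series(best["cluster"].to_numpy(), index=best["ligand_id"])
        return ClusterFEBSummary(medians=medians, best_cluster=series,
                                 modal_cluster=int(series.mode().iloc[0]),
                                 concordance=float((series == series.mode().iloc[0]).mean()))

    def test_identical_orderings_give_unit_correlation(self):
        offsets = list(np.linspace(-2.0, 0.0, 5))
        summary = self._summary_from_offsets({f"L{i}": offsets for i in range(3)}, 5)
        pairs, mean_rho = rank_consistency(summary)
        assert np.allclose(pairs["spearman_rho"], 1.0)
        assert mean_rho == pytest.approx(1.0)

    def test_reversed_ligand_anticorrelates(self):
        offsets = list(np.linspace(-2.0, 0.0, 5))
        summary = self._summary_from_offsets(
            {"A": offsets, "B": offsets[::-1]}, 5)
        pairs, mean_rho = rank_consistency(summary)
        assert mean_rho == pytest.approx(-1.0)

    def test_null_random_febs_average_near_zero(self):
        means = []
        for rep in range(20):
            rng = np.random.default_rng(700 + rep)
            summary = self._summary_from_offsets(
                {f"L{i}": list(rng.normal(size=10)) for i in range(20)}, 10)
            _, mean_rho = rank_consistency(summary)
            means.append(mean_rho)
        assert abs(float(np.mean(means))) <= 0.25

    def test_single_cluster_undefined(self):
        summary = self._summary_from_offsets({"A": [-1.0], "B": [-2.0]}, 1)
        with pytest.raises(UndefinedRankError):
            rank_consistency(summary)


class TestBuildRFFR:
    def _partition_and_matrix(self, n_clusters=3, n_rows=90, seed=0):
        spec = make_spec(n_clusters=n_clusters, n_rows=n_rows, seed=seed)
        table, labels = generate_feature_table(spec)
        m = minmax_normalize(table)
        X = m.values
        centroids = np.vstack([X[labels == c].mean(axis=0) for c in range(n_clusters)])
        inertia = float(((X - centroids[labels]) ** 2).sum())
        part = Partition(k=n_clusters, labels=labels, centroids=centroids, inertia=inertia)
        return part, m

    def test_two_per_cluster_coverage(self):
        part, m = self._partition_and_matrix()
        sel = build_rffr(part, m, min_per_cluster=2)
        assert len(sel) == 2 * part.k
        assert all(v == 2 for v in sel.per_cluster.values())
        assert set(sel.snapshot_ids) <= set(m.row_ids)

    def test_selection_size_bounds(self):
        part, m = self._partition_and_matrix(n_rows=50)
        for mpc in (1, 2, 5):
            sel = build_rffr(part, m, min_per_cluster=mpc)
            assert len(sel) <= part.n
            assert len(sel) >= min(part.k * mpc, part.n)

    def test_undersized_cluster_contributes_all_members(self, caplog):
        X = np.array([[0.0], [0.1], [10.0]])
        part = Partition(k=2, labels=[0, 0, 1],
                         centroids=[[0.05], [10.0]], inertia=0.005)
        from types import SimpleNamespace
        m = SimpleNamespace(values=X, row_ids=["a", "b", "c"])
        with caplog.at_level("WARNING"):
            sel = build_rffr(part, m, min_per_cluster=2)
        assert sorted(sel.snapshot_ids) == ["a", "b", "c"]
        assert sel.per_cluster[1] == 1

    def test_medoid_of_singleton_is_the_member(self):
        X = np.array([[0.0], [10.0]])
        part = Partition(k=2, labels=[0, 1], centroids=[[0.0], [10.0]], inertia=0.0)
        from types import SimpleNamespace
        m = SimpleNamespace(values=X, row_ids=["a", "b"])
        sel = build_rffr(part, m, min_per_cluster=1)
        assert sel.snapshot_ids == ["a", "b"]

    def test_medoids_are_nearest_to_centroid(self):
        part, m = self._partition_and_matrix(seed=4)
        sel = build_rffr(part, m, min_per_cluster=1)
        X = m.values
        for c in range(part.k):
            members = np.flatnonzero(part.labels == c)
            d = np.linalg.norm(X[members] - part.centroids[c], axis=1)
            expected = m.row_ids[members[d.argmin()]]
            assert expected in sel.snapshot_ids

    def test_best_feb_mode_requires_summary(self):
        part, m = self._partition_and_matrix()
        with pytest.raises(MissingInputError):
            build_rffr(part, m, mode="best_feb")

    def test_best_feb_mode_selects_lowest_energy_snapshots(self):
        spec = make_spec(n_clusters=3, n_rows=60, seed=9, feb_noise_sd=0.2)
        table, labels = generate_feature_table(spec)
        m = minmax_normalize(table)
        docking = generate_docking_table(spec, labels)
        per_snap = snapshot_feb(docking)
        clusters = pd.Series(labels, index=snapshot_ids(len(labels)))
        summary = cluster_feb_summary(per_snap, clusters)
        X = m.values
        centroids = np.vstack([X[labels == c].mean(axis=0) for c in range(3)])
        part = Partition(k=3, labels=labels, centroids=centroids,
                         inertia=float(((X - centroids[labels]) ** 2).sum()))
        sel = build_rffr(part, m, summary=summary, min_per_cluster=1, mode="best_feb")
        mean_feb = per_snap.groupby("snapshot_id")["feb"].mean()
        for c in range(3):
            members = [m.row_ids[i] for i in np.flatnonzero(labels == c)]
            best = mean_feb.loc[members].idxmin()
            assert best in sel.snapshot_ids

    def test_write_rffr_one_id_per_line(self, tmp_path):
        part, m = self._partition_and_matrix()
        sel = build_rffr(part, m, min_per_cluster=2)
        path = tmp_path / "rffr.txt"
        write_rffr(sel, path)
        assert path.read_text().splitlines() == sel.snapshot_ids
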