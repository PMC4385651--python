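"""End-to-end orchestration: normalize -> sweep -> validity -> select ->
FEB validation -> reduced-ensemble build, with a reproducible manifest.

Every output file gets a sidecar JSON recording the configuration hash and
seed, so any artifact can be traced back to the exact run that produced it.
Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, feb_validation, feature_io, validity

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration violates its invariants."""


@dataclass
class PipelineConfig:
    features_csv: str
    out_dir: str
    docking_csv: str | None = None
    k_min: int = 2
    k_max: int = 15
    seed: int = 0
    n_restarts: int = 10
    b_refs: int = 50
    gap_rule: str = "se"
    min_per_cluster: int = 2
    feb_collapse: str = "min"
    rffr_mode: str = "medoids"
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ConfigError("k_min must be >= 2")
        if self.k_max < self.k_min:
            raise ConfigError("k_max must be >= k_min")
        if self.gap_rule not in ("max", "se"):
            raise ConfigError("gap_rule must be 'max' or 'se'")
        if self.feb_collapse not in ("min", "mean"):
            raise ConfigError("feb_collapse must be 'min' or 'mean'")
        if self.rffr_mode not in ("medoids", "best_feb"):
            raise ConfigError("rffr_mode must be 'medoids' or 'best_feb'")
        if self.min_per_cluster < 1:
            raise ConfigError("min_per_cluster must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_sidecar(path: Path, config: PipelineConfig, stage: str) -> None:
    meta = {"config_hash": config.digest(), "seed": config.seed, "stage": stage}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to the output
    directory as ``run_manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "outputs": {},
        "timings_s": {},
    }

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # annotate with the stage name, then abort
            raise StageError(name, exc) from exc
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", name, manifest["timings_s"][name])
        return result

    table = _stage("read", lambda: feature_io.read_feature_table(config.features_csv))
    if config.normalize:
        matrix = _stage("normalize", lambda: feature_io.minmax_normalize(table))
    else:
        from types import SimpleNamespace

        matrix = SimpleNamespace(
            values=table.feature_matrix(), row_ids=table.snapshot_ids,
        )

    partitions = _stage("sweep", lambda: clustering.sweep(
        matrix, config.k_min, config.k_max,
        seed=config.seed, n_restarts=config.n_restarts,
    ))
    for part in partitions:
        labels_path = out / f"labels_k{part.k:02d}.csv"
        pd.DataFrame({
            "snapshot_id": matrix.row_ids, "cluster": part.labels,
        }).to_csv(labels_path, index=False)
        _write_sidecar(labels_path, config, "sweep")
    centroids = pd.concat([
        pd.DataFrame(part.centroids, columns=list(feature_io.FEATURE_COLUMNS))
        .assign(k=part.k, cluster=range(part.k))
        for part in partitions
    ])
    centroids_path = out / "centroids.csv"
    centroids.to_csv(centroids_path, index=False)
    _write_sidecar(centroids_path, config, "sweep")
    manifest["outputs"]["labels"] = [
        str(out / f"labels_k{p.k:02d}.csv") for p in partitions
    ]
    manifest["outputs"]["centroids"] = str(centroids_path)

    vsweep = _stage("validity", lambda: validity.evaluate_sweep(
        matrix, partitions, b_refs=config.b_refs, seed=config.seed,
    ))
    report_path = out / "validity_report.csv"
    vsweep.to_frame().loc[:, ["k", "db", "dunn", "gap", "gap_se", "log_wk"]] \
        .to_csv(report_path, index=False)
    _write_sidecar(report_path, config, "validity")
    manifest["outputs"]["validity_report"] = str(report_path)

    selection = _stage("select", lambda: validity.select_partition(
        vsweep, gap_rule=config.gap_rule,
    ))
    select_path = out / "selection.json"
    select_path.write_text(json.dumps(dataclasses.asdict(selection), indent=1))
    _write_sidecar(select_path, config, "select")
    manifest["outputs"]["selection"] = str(select_path)
    manifest["chosen_k"] = selection.chosen_k
    chosen = next(p for p in partitions if p.k == selection.chosen_k)

    summary = None
    if config.docking_csv is not None:
        def _validate():
            docking = feb_validation.read_docking_table(config.docking_csv)
            per_snap = feb_validation.snapshot_feb(docking, policy=config.feb_collapse)
            clusters = pd.Series(chosen.labels, index=matrix.row_ids)
            return feb_validation.cluster_feb_summary(per_snap, clusters)
        summary = _stage("validate_feb", _validate)
        medians_path = out / "cluster_feb_medians.csv"
        summary.medians.to_csv(medians_path, index=False)
        _write_sidecar(medians_path, config, "validate_feb")
        pairs, mean_rho = feb_validation.rank_consistency(summary)
        feb_json = out / "feb_validation.json"
        feb_json.write_text(json.dumps({
            "best_cluster": {str(k): int(v) for k, v in summary.best_cluster.items()},
            "modal_cluster": summary.modal_cluster,
            "concordance": summary.concordance,
            "mean_spearman_rho": mean_rho,
        }, indent=1))
        _write_sidecar(feb_json, config, "validate_feb")
        manifest["outputs"]["cluster_feb_medians"] = str(medians_path)
        manifest["outputs"]["feb_validation"] = str(feb_json)
        manifest["concordance"] = summary.concordance

    rffr = _stage("build_rffr", lambda: feb_validation.build_rffr(
        chosen, matrix, summary=summary,
        min_per_cluster=config.min_per_cluster, mode=config.rffr_mode,
    ))
    rffr_path = out / "rffr_snapshots.txt"
    feb_validation.write_rffr(rffr, rffr_path)
    _write_sidecar(rffr_path, config, "build_rffr")
    manifest["outputs"]["rffr"] = str(rffr_path)
    manifest["rffr_size"] = len(rffr)

    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
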