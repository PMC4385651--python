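# rffr

Reduce a fully flexible receptor model — the ensemble of all snapshots of
a molecular-dynamics trajectory used as docking targets — to a small
representative subset (an RFFR model), by clustering snapshots on
substrate-binding-cavity descriptors and validating the partition with
docking energies.

Ensemble docking against every frame of a long MD trajectory is
prohibitively expensive: a 20 ns simulation sampled every 1 ps yields
20,000 receptor conformations per ligand.  `rffr` is for structural
bioinformaticians and virtual-screening practitioners who want a
principled reduction: snapshots whose binding cavities look alike are
grouped, the number of groups is chosen by cluster-validity criteria, and
a couple of representatives per group stand in for the whole ensemble.

## Method

Each snapshot is described by four cavity features: accessible surface
area (Å²), volume (Å³), heavy-atom count, and backbone RMSD of the cavity
residues versus the first frame (Å).  After min–max normalization onto
[0, 1], k-means partitions the trajectory for k = 2…15, and each
partition is scored by three validity indices:

- Davies–Bouldin: DB = (1/k) Σᵢ maxⱼ≠ᵢ (d̄ᵢ + d̄ⱼ)/dᵢⱼ (lower is better),
- Dunn: minᵢ≠ⱼ δ(Cᵢ, Cⱼ) / maxₗ diam(Cₗ) (higher is better),
- gap statistic: Gap(k) = E*[log W_k] − log W_k with
  W_k = Σ_r D_r/(2n_r), against B = 50 uniform reference datasets
  (higher is better).

When the indices disagree, the gap value is the decisive criterion among
their candidates.  The partition is then validated against docking
results: per-cluster median free energies of binding (FEB, kcal/mol) are
computed independently for each ligand, and the selection is credible
when every ligand finds its best median FEB in the same cluster
(concordance 1.0) and ligands rank clusters consistently (Spearman).
Finally at least two snapshots per cluster (medoids by default) form the
reduced ensemble.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Generate a synthetic trajectory with planted cavity states, run the full
pipeline, and inspect the result:

```python
from pathlib import Path
from rffr import (default_spec, generate_feature_table, generate_docking_table,
                  write_feature_table, PipelineConfig, run_pipeline)

spec = default_spec(seed=1, duration_ns=1.0, n_ligands=6, runs_per_pair=5)
table, labels = generate_feature_table(spec)          # 1,000 snapshots
write_feature_table(table, "features.csv")
generate_docking_table(spec, labels).to_csv("docking.csv", index=False)

manifest = run_pipeline(PipelineConfig(
    features_csv="features.csv", docking_csv="docking.csv",
    out_dir="out", k_min=2, k_max=15, seed=1, b_refs=20,
))
print(manifest["chosen_k"], manifest["concordance"], manifest["rffr_size"])
```

prints

```
10 1.0 20
```

meaning the validity criteria selected the 10-cluster partition (the
planted number of cavity states), every one of the 6 ligands had its best
median FEB in the same cluster, and the reduced ensemble keeps
10 × 2 = 20 snapshots out of 1,000.  `out/validity_report.csv` holds the
per-k DB/Dunn/gap curves, `out/selection.json` the selection trace, and
`out/rffr_snapshots.txt` the retained snapshot ids.

The same run from a shell:

```bash
rffr simulate --out-dir sim --seed 1
rffr run-all --features sim/features.csv --docking sim/docking.csv \
     --out-dir out --seed 1
```

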