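# Methods

## Problem and model

Ensemble (fully flexible receptor, FFR) docking treats every snapshot of a
molecular-dynamics trajectory as an alternative rigid receptor.  For a
20 ns trajectory sampled every 1 ps that is 20,000 docking targets per
ligand, which is rarely affordable.  `rffr` reduces the ensemble by
clustering snapshots on four substrate-binding-cavity descriptors —
accessible surface area (Å²), cavity volume (Å³), heavy-atom count, and
backbone RMSD of the cavity residues versus the first frame (Å) — on the
premise that snapshots with similar cavity geometry bind ligands
similarly, so a few representatives per cluster preserve the
conformational diversity that matters for docking.

The analysis runs in five stages:

1. **Normalization.**  Each descriptor column is mapped onto [0, 1] by
   `(x − min)/(max − min)`.  Min–max is the unique affine map onto the
   unit interval; it removes the wildly different units (hundreds of Å²
   vs. a couple of Å) without reweighting the features.  A constant
   column maps to all zeros (with a warning) rather than being dropped,
   so a trajectory with a fixed cavity heavy-atom count keeps a 4-column
   matrix.
2. **k-means sweep.**  Lloyd's algorithm with k-means++ seeding, 10
   restarts per k (best inertia kept), k = 2…15, at most 300 iterations,
   convergence on zero label changes.  Nearest-centroid ties break toward
   the lower cluster index and per-(k, restart) seeds derive
   deterministically from the master seed, so runs are bit-reproducible.
   A cluster that empties mid-iteration is repaired with the point
   farthest from its own centroid (never stealing a singleton), because
   the validity indices below require every cluster non-empty.
3. **Validity indices.**  For each partition:
   * Davies–Bouldin: DB = (1/k) Σᵢ maxⱼ≠ᵢ (d̄ᵢ + d̄ⱼ)/dᵢⱼ with d̄ᵢ the mean
     Euclidean distance of cluster-i members to their centroid and dᵢⱼ the
     centroid–centroid distance (the q = 1, p = 2 member of the DB
     family).  Lower is better.
   * Dunn: minimum single-linkage inter-cluster distance divided by the
     maximum intra-cluster diameter (the classical instantiation).
     Higher is better.
   * Gap statistic: Gap(k) = E*[log W_k] − log W_k, where
     W_k = Σ_r D_r/(2 n_r) and D_r is the ordered pairwise squared-distance
     sum within cluster r.  That double sum collapses algebraically to the
     within-cluster sum of squares about the cluster mean, which is how it
     is computed (and why W_k equals the k-means inertia on converged
     partitions — an identity the tests assert).  The reference
     expectation uses B = 50 datasets drawn uniformly over the per-column
     [min, max] box of the observed matrix — the natural null once the
     columns are min–max normalized — clustered with identical k-means
     settings; s_k = sd_B[log W_k^(b)]·√(1 + 1/B).
4. **Selection.**  DB nominates its argmin, Dunn its argmax, and the gap
   statistic its optimum.  If all agree, done.  Otherwise the gap value
   decides among the distinct candidates (remaining ties: higher Dunn,
   then lower DB, then smaller k), and the full comparison trace is kept
   in the result.

   The gap candidate uses the one-standard-error rule — the smallest k
   with Gap(k) ≥ Gap(k+1) − s_{k+1} — rather than a plain argmax.  This
   was a genuinely open design point and the plateau behaviour settles
   it: past the true cluster count the gap curve flattens, and the
   plateau's residual tilt plus Monte-Carlo noise make an unrestricted
   argmax drift toward the top of the sweep range (we observed drifts to
   k = 9…12 on data planted with 5 clusters, while DB and Dunn both
   recovered 5).  The one-SE rule is the standard quantification of
   "highest value within a tolerance"; plain argmax remains available as
   `gap_rule="max"`.
5. **FEB validation and reduction.**  Docking scores (FEB) for each
   (snapshot, ligand) are collapsed over repeated runs by the minimum —
   the most favorable pose, the usual docking convention; a mean mode
   exists.  Medians per (ligand, cluster) are compared across ligands:
   *concordance* is the fraction of ligands whose lowest-median cluster is
   the modal best cluster, and pairwise Spearman correlations of the
   cluster orderings quantify whether ligands rank the cavity states
   consistently.  The reduced ensemble takes at least 2 snapshots per
   cluster (medoids — nearest the centroid — by default, or the
   lowest-mean-FEB members), with undersized clusters contributing all
   members.

## Synthetic data

No trajectory or docking archive accompanies the methodology, so the
generator plants the statistical structure the analysis assumes and makes
every stage testable:

* Features are a Gaussian mixture: cluster means drawn once (fixed seed,
  rejection sampling) inside a realistic cavity box — area 450–1150 Å²,
  volume 800–2000 Å³, 250–320 heavy atoms, RMSD 0.5–3.5 Å — with any two
  means at least 12 pooled standard deviations apart; common
  within-cluster sds (7 Å², 12 Å³, 0.7 atoms, 0.03 Å) chosen proportional
  to the box spans so clusters stay roughly isotropic after
  normalization.  Draws are resampled (not clipped) at zero to keep
  within-cluster distributions unimodal; heavy-atom counts are rounded to
  non-negative integers (a constant-count mode exists, since real
  pipelines sometimes reuse one crystal-structure cavity definition).
* Row i carries time i·Δt with Δt the sampling interval, so 20 ns at
  1 ps gives exactly 20,000 rows; defaults are 10 clusters with equal
  mixing weights, 20 ligands, 25 docking runs per pair.
* FEB values are Normal(base_ligand + offset_cluster, σ = 0.5 kcal/mol)
  with ligand baselines in −9…−6 kcal/mol and one distinguished cluster
  offset at −2.0 kcal/mol against −0.8…0 for the rest, i.e. a
  1.2 kcal/mol margin — comfortably above the noise so the planted
  best-binding state is recoverable, as the cross-ligand behaviour the
  method is meant to detect.

What the generator does **not** emulate: temporal autocorrelation along
the trajectory (rows are i.i.d. given their cluster), non-Gaussian or
overlapping conformational basins, ligand-specific induced-fit effects
(offsets are shared across ligands up to noise), and docking-score
heavy tails.  Passing tests therefore demonstrate that the pipeline
recovers planted structure under its own assumptions, not that a real
trajectory has k = 10 states.

## Numerical choices and scales

* Distances are Euclidean throughout, on the normalized matrix.
* Partition invariants are checked to 1e-12 (nearest-centroid ties) and
  1e-9 (inertia recomputation); index implementations agree with
  brute-force double-loop oracles to 1e-9.
* Coincident centroids or all-singleton partitions raise typed errors
  rather than returning NaN.
* Test and acceptance problem sizes: model-selection recovery runs at
  2,000 snapshots with B = 50 gap references (about two minutes on one
  core); the recovery-rate replicates use 300 snapshots with B = 15 and
  4 restarts, which keeps 60 full sweeps tractable while leaving the
  planted structure unambiguous.

## Structural extraction

The optional PDB path computes cavity-backbone (N, CA, C, O) RMSD per
model against model 1 — by default after optimal least-squares rigid
superposition (Kabsch, via Biopython's SVD superimposer), matching the
convention of standard trajectory tools; a no-fit mode is kept because
raw coordinate deviations are sometimes wanted.  Heavy-atom counts treat
any element other than H/D as heavy.  Area and volume are *not*
computed; they are ingested as columns from a pocket-surface tool.

## Known limitations

* k-means with Euclidean distance assumes roughly spherical clusters in
  the normalized space; elongated or nested cavity states would call for
  the hierarchical alternatives deliberately left out of scope.
* The uniform-box gap reference ignores feature correlations; a
  principal-components box is a known refinement.
* Concordance is a coarse statistic (modal agreement); it says nothing
  about the margin by which the best cluster wins — the rank-consistency
  correlations partially fill that gap.
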