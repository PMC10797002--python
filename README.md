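# voxparc

Connectivity-based parcellation of a voxel mask from resting-state time
series, built as a tested, reusable pipeline:

- **QC** — run-level inclusion filters (fixation fraction, two-times-median
  mean-correlation outlier rule) plus zero-phase band-pass filtering
  (0.0025–0.05 Hz by default) and nuisance regression (white-matter,
  ventricle and head-motion series).
- **Connectivity** — voxel-by-voxel partial correlations per run, Fisher
  z-transform, two-stage group averaging (runs within subject, then
  subjects), and Euclidean distances between connectivity profiles.
- **Clustering** — unweighted average-linkage (UPGMA) hierarchical
  clustering with nested 2–10-cluster solutions, axis-based relabeling and
  Newick export.
- **Cluster validation** — three criteria: a subject-level permutation test
  on the cosine similarity of min-max-normalized seed fingerprints (exact
  enumeration when feasible, 100,000 iterations otherwise), mean
  silhouette, and the within-cluster sum-of-squares elbow; combined by
  majority vote with fingerprint precedence.
- **Seed-to-brain maps** — cluster-mean to brain-voxel correlation maps,
  Stouffer fixed-effects combination and strict z > 2.3 thresholding.
- **Task ROI statistics** — block-design builders, contrast-agent
  (sign-inverting) and BOLD HRF convolution, per-run OLS GLMs,
  beta-ratio percent signal change, one-tailed t-tests and
  Benjamini–Hochberg FDR across ROIs.
- **Synthetic data** — a first-class generator of multi-subject,
  multi-run voxel time series with planted communities, seed couplings,
  nuisance signals, null fingerprint pairs and task effects, used by the
  test suite to verify end-to-end recovery of the planted structure.

## Command line

```bash
voxparc simulate --config config.yaml -o data/        # synthetic dataset
voxparc cluster  -i data/ -o clust/                   # QC + UPGMA solutions
voxparc validate -i data/ -o val/                     # three criteria + consensus K
voxparc seedmap  -i data/ -k 4 -o maps/               # fixed-effects z maps
voxparc taskroi  -i data/ -k 4 -o task/               # planted-effect PSC stats
voxparc report   -d workdir/ -o summary.json          # aggregate manifests
```

Every subcommand writes a JSON manifest (config, seeds, checksums) next to
its outputs; reruns with the same configuration reproduce identical data
checksums. All analysis constants (filter band, fixation threshold,
outlier rule, permutation count, alpha, z threshold, seed radius, K range)
are named keys in the YAML config.

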