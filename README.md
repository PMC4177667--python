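# hmrfclust

Spatial clustering of binary single-cell / voxel gene-expression data with a
hidden Markov random field (HMRF).

## The problem

Wholemount in-situ hybridization and similar assays measure, voxel by voxel,
which genes are expressed across a whole tissue mapped onto a 3-D grid, where
each voxel roughly corresponds to one cell.  Clustering those voxels into
putative cell types from expression alone (hierarchical clustering, k-means,
mixture models) throws away a strong prior: cells of the same type tend to
sit next to each other.  `hmrfclust` clusters the voxels using both the
expression profiles and the spatial neighborhood structure, and lets each
cluster have its **own** degree of spatial cohesion — compact tissues can be
strongly smoothed while dispersed cell types are left alone.

## The model

Voxels are nodes of a 6-neighborhood graph built from their integer 3-D
coordinates.  Each voxel `i` carries a latent cluster label `z_i ∈ {1..K}`
distributed as a Markov random field with Gibbs measure `P(z) ∝ exp(−U(z))`
and a per-cluster ("extended Potts") pairwise energy

```
U(z) = − Σ_{(i,j) ∈ edges} β_{z_i} · 1[z_i = z_j],       β_k ≥ 0
```

so that every matched edge of cluster `k` is rewarded by its own interaction
strength `β_k`.  Given `z_i = k`, the `G` binary gene calls of voxel `i` are
independent Bernoulli with cluster profile `θ_{kg}`.

The field's partition function is intractable, so fitting uses mean-field
EM: posterior memberships `t_{ik} ∝ p(y_i|θ_k)·exp(β_k Σ_{j∈N(i)} t_{jk})`
(E-step), closed-form `θ` updates from the maximum-posterior-marginal
partition, and projected gradient ascent for `β` (M-step).  The number of
clusters is chosen by BIC (argmin, plus a plateau rule for near-symmetric
tissues whose BIC curve flattens instead of turning up).

The package also ships the two standard non-spatial baselines (independent
Bernoulli mixture EM, hierarchical clustering), a full synthetic-data /
resimulation harness for validation, partition-agreement and
gene-specificity scoring, and luminescence binarization (manual thresholds
or a Gaussian-mixture auto-thresholder).

## A worked example

```python
import numpy as np
import hmrfclust as hc

ref = hc.make_synthetic_reference(
    (8, 8, 6), n_clusters=3, n_genes=16, seed=1, theta_spec="separated", delta=0.5
)
y = hc.simulate_from_reference(ref, seed=2)
fit = hc.fit_hmrf(y, ref.graph, n_clusters=3, seed=3)

print(hc.jaccard_partitions(ref.partition, fit.partition))
print(np.round(fit.params.beta, 2))
```

This simulates 384 voxels × 16 genes from a 3-cluster spatially coherent
reference and refits the model.  Running it (see
`examples/01_fit_synthetic.py`) prints:

```
voxels: 384, genes: 16, clusters: 3
EM iterations: 4 (converged: True)
surrogate log-likelihood: -2014.85   BIC: 4333.18
fitted interaction strengths beta: [2.27 2.22 2.42]
Jaccard(truth, fit): 1.000   theta RMSE: 0.0319
```

A Jaccard coefficient of 1 means the true partition was recovered exactly
(up to relabeling); `β ≈ 2–4` reflects strong spatial cohesion of the
simulated regions; the θ error is at the binomial sampling floor.  The other
scripts in `examples/` walk through BIC-based choice of K, the
spatial-vs-mixture ablation, cluster marker-gene fingerprints and automatic
binarization.

## Command line

A thin CLI wraps the library for file-based runs:

```
hmrfclust simulate --grid 12 12 8 -k 7 -g 28 --seed 0 --outdir sim/
hmrfclust fit --expression sim/expression.tsv --coordinates sim/coordinates.tsv -k 7 --outdir fit/
hmrfclust sweep --expression sim/expression.tsv --coordinates sim/coordinates.tsv --k-min 2 --k-max 12 --outdir sweep/
hmrfclust evaluate --truth sim/reference_partition.tsv --prediction fit/partition.tsv --outdir eval/
hmrfclust binarize --luminescence lum.tsv --outdir bin/
```

All inputs and outputs are tab-delimited text (plus JSON metadata); every
command writes its effective configuration next to its outputs and is
reproducible from it.

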