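"""Simulate a small spatial expression dataset and fit the HMRF.

Builds a 3-cluster reference on a 8x8x6 voxel grid, Bernoulli-samples
binary expression from it, fits the spatial model at the true K and
reports how well truth was recovered.
"""

import numpy as np

import hmrfclust as hc

ref = hc.make_synthetic_reference(
    (8, 8, 6), n_clusters=3, n_genes=16, seed=1, theta_spec="separated", delta=0.5
)
y = hc.simulate_from_reference(ref, seed=2)
fit = hc.fit_hmrf(y, ref.graph, n_clusters=3, seed=3)

jac = hc.jaccard_partitions(ref.partition, fit.partition)
rmse = hc.aligned_theta_rmse(ref.theta, fit.params.theta, ref.partition, fit.partition)

print(f"voxels: {y.n_voxels}, genes: {y.n_genes}, clusters: 3")
print(f"EM iterations: {fit.n_iter} (converged: {fit.converged})")
print(f"surrogate log-likelihood: {fit.log_likelihood:.2f}   BIC: {fit.bic:.2f}")
print(f"fitted interaction strengths beta: {np.round(fit.params.beta, 2)}")
print(f"Jaccard(truth, fit): {jac:.3f}   theta RMSE: {rmse:.4f}")
print()
print("Jaccard 1.0 means the true partition was recovered exactly (up to")
print("relabeling); beta around 2-4 reflects the strong spatial cohesion of")
print("the simulated regions; theta RMSE is at the binomial sampling floor.")
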