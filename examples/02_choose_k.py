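"""Choose the number of clusters with a BIC sweep.

Simulates data with 4 true spatially coherent clusters, fits K = 2..7 and
reports the BIC curve with both selection rules (argmin and plateau).
"""

import hmrfclust as hc

ref = hc.make_synthetic_reference(
    (8, 8, 6), n_clusters=4, n_genes=16, seed=5, theta_spec="separated", delta=0.5
)
y = hc.simulate_from_reference(ref, seed=6)
res = hc.sweep_k(y, ref.graph, range(2, 8), n_restarts=3, seed=7)

ks, curve = res.bic_curve()
print("  K    BIC")
for k, b in zip(ks, curve):
    marker = "  <- argmin" if k == res.chosen_k_min else ""
    print(f"  {k}  {b:9.1f}{marker}")
print(f"argmin-BIC K: {res.chosen_k_min}   plateau K: {res.chosen_k_plateau}")
print()
print("The BIC drops sharply until the true K (4) and rises beyond it, so")
print("both rules agree; on nearly-symmetric tissues the curve flattens")
print("instead, and the plateau rule is the one to trust.")
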