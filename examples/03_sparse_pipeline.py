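"""Full sparse-correlation pipeline on simulated benchmark data.

Simulates the linear benchmark scenario (negative-binomial counts, 10
designed correlated pairs, sampling-fraction and efficiency biases), runs
the p-value-filtered Pearson variant and the distance variant, and scores
both against the known truth.
"""

from secom import secom, simulate_linear, tpr_fpr

table, truth = simulate_linear(n=80, d=40, dispersion=0.5, n_corr_pairs=10,
                               rho=0.9, seed=42)
print(f"simulated {table.n_taxa} taxa x {table.n_samples} samples, "
      f"{(table.counts == 0).mean():.0%} zeros, 10 truly correlated pairs")

for method in ("pearson2", "distance"):
    est = secom(table, method=method, alpha=0.005, n_permutations=399, seed=1)
    m = tpr_fpr(est.matrix, truth.R0)
    print(f"{method:9s}: {est.q:3d} edges kept, TPR = {m.tpr:.2f}, FPR = {m.fpr:.4f}")

print()
print("Both variants recover most designed pairs (TPR near 1) while flagging")
print("almost none of the truly independent pairs (FPR near the 0.005 cutoff).")
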