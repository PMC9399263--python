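# secom — sparse correlation estimation for microbiome count data

Observed microbiome counts are relative quantities: each sample captures an
unknown *sampling fraction* S_i of the ecosystem, and each taxon is measured
with its own *sequencing efficiency* C_j (gram-positive bacteria, for
example, are systematically under-extracted). Pearson or Spearman
correlations computed directly on such counts are dominated by these shared
nuisance factors and are routinely spurious. On top of that, microbial
interactions can be nonlinear, tables are high-dimensional (taxa ≫
samples) so only sparse correlation matrices are estimable, and excess
zeros make every pairwise statistic a missing-data problem.

This package is for microbiome researchers and statisticians who want
defensible within- and cross-ecosystem correlation networks from taxon ×
sample count tables (OTU/ASV/family level — any non-negative integer
table).

## Model and estimators

Counts are modeled multiplicatively, `O_ij = S_i C_j A_ij E_ij`, i.e.
additively on the log scale: `o_ij = s_i + c_j + a_ij + e_ij`. Both biases
are removed from the observable side:

1. **taxon centering** `o_ij − ō·_j` cancels `c_j` exactly;
2. the **sampling-fraction difference** `s_i − s̄·` is estimated by
   averaging those residuals within each sample over its observed taxa
   `d(i)` — either a plain mean or an inverse-variance weighted mean —
   giving the bias-corrected abundance
   `ŷ_ij = (o_ij − ō·_j) − (ŝ_i − s̄·)`,
   a proxy for the centered log absolute abundance.

Pairwise statistics on `ŷ` use complete-case analysis (only samples where
both taxa are nonzero; zeros are never logged or imputed):

- **Pearson / Spearman**: `μ̂_l` over n(l), `σ̂_lm` over n(l, m),
  `ρ̂_lm = σ̂_lm / √(σ̂_ll σ̂_mm)`, two-sided p-values from the t
  distribution with |n(l, m)| − 2 df;
- **distance correlation** (doubly centered distance matrices,
  `dCov²_n = n⁻² ΣΣ D_ij E_ij`) with permutation p-values — zero only
  under independence, so parabolic and other nonlinear relationships are
  detected;
- **sparsity** by soft thresholding `sign(R_n)(|R_n| − λ)₊` with λ chosen
  by repeated-split cross-validation (variants `pearson1` / `spearman1`),
  or by p-value filtering at an uncorrected α = 0.005 (`pearson2` /
  `spearman2` / `distance`).

Tables with ecosystem labels (body sites, time points) are corrected per
ecosystem and correlated across `(ecosystem, taxon)` features paired by
subject, so within-site estimates are identical whether a site is analyzed
alone or jointly.

## Worked example

```python
from secom import secom, simulate_linear, tpr_fpr

table, truth = simulate_linear(n=80, d=40, dispersion=0.5,
                               n_corr_pairs=10, rho=0.9, seed=42)
for method in ("pearson2", "distance"):
    est = secom(table, method=method, alpha=0.005, n_permutations=399, seed=1)
    m = tpr_fpr(est.matrix, truth.R0)
    print(method, est.q, round(m.tpr, 2), round(m.fpr, 4))
```

prints

```
pearson2 21 1.0 0.0143
distance 17 1.0 0.0091
```

All ten designed pairs are recovered by both variants (TPR = 1.0) while
only ~1% of the 770 truly independent pairs are flagged; `est.q` is the
number of edges kept after sparsification. `examples/` contains four
narrative scripts: bias correction vs raw log counts, nonlinear dependence
(`dCor = 1` for a linear map, ≈ 0.49 for a parabola with Pearson 0), the
full sparse pipeline, and a two-ecosystem analysis.

The same pipeline is available from the shell:

```bash
secom simulate --scenario linear --n 80 --d 40 --seed 42 --out sim/
secom run sim/counts.tsv --method pearson2 --out results/
secom evaluate results/correlation_matrix.tsv sim/truth_R0.tsv
```

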