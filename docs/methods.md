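# Methods

## Data model

A count table holds observed abundances O_ij for sample i = 1…n and taxon
j = 1…d. The generative model is multiplicative,

    O_ij = S_i · C_j · A_ij · E_ij,

with S_i the sample-specific sampling fraction (what portion of the
ecosystem the library captured), C_j the taxon-specific sequencing
efficiency, A_ij the true absolute abundance, and E_ij multiplicative
noise with E[log E_ij] = 0 and Var = σ_e². On the log scale (natural logs
throughout) the model is additive: o = s + c + a + e. Presence is tracked
by the indicator M_ij = 1{O_ij > 0}; all statistics are computed over
observed entries only (complete-case analysis, CCA), so zeros are never
logged or imputed.

Assumptions inherited from the model: (i) the true correlation matrix is
sparse (necessary for any d ≫ n estimation); (ii) the noise-to-signal
ratio σ_e²/σ⁰_jj is small, so correlations of the noisy centered
abundances approximate those of the true abundances; (iii) every taxon
pair is co-observed in at least a few samples — pairs never co-observed
are reported as 0 with a diagnostic flag rather than an error.

## Bias correction

Centering each taxon over its observed samples, o_ij − ō·_j, cancels c_j
exactly. The centered sampling fraction is estimated per sample from the
taxa observed in it, d(i):

- simple: the arithmetic mean of the residuals over d(i);
- weighted (default): a two-pass scheme — pass 1 uses the simple
  estimator, per-taxon residual variances are estimated from
  o_ij − ō·_j − ŝ_i^simple over each taxon's observed samples (ddof = 1,
  floored at 1e−8 before inversion), and pass 2 averages with weights
  w_j ∝ 1/Var_j normalized within each sample. One iteration only.

Estimates are re-centered to mean zero across samples (only the centered
quantity s_i − s̄· is identifiable; the shift is absorbed by the
downstream per-taxon means). The corrected abundance is
ŷ_ij = (o_ij − ō·_j) − (ŝ_i − s̄·), missing where M_ij = 0.

Exactness caveat: multiplying all counts of one taxon by a constant leaves
ŷ unchanged exactly, with or without zeros. Multiplying all counts of one
sample by a constant leaves ŷ unchanged exactly when the table is fully
observed; with zeros, the observed-only taxon means redistribute a small
part of the sample's bias (leakage of order 1/|n(j)| per taxon). The unit
suite asserts the exact version on complete tables; on zero-inflated
tables the estimator remains consistent but not exactly invariant.

With multiple ecosystems (body sites, time points), correction is run
independently within each ecosystem and the corrected blocks are stacked
as (ecosystem, taxon) features over subjects, pairing columns by subject
identifier (first sample by id order wins if a subject has replicates,
with a warning). This makes within-site correlation sub-matrices identical
to a per-site analysis by construction, and cross-site correlations
meaningful because each block's nuisance parameters were removed
separately.

## Linear correlation

For a pair (l, m), μ̂_l is the mean of ŷ over n(l) (the taxon's observed
samples) while σ̂_lm averages cross-products over n(l, m) (the shared
samples) with a 1/|n(l,m)| normalizer; ρ̂_lm = σ̂_lm/√(σ̂_ll σ̂_mm). The
mixed index-set convention can push |ρ̂| slightly past 1 under
missingness, so estimates are clipped to [−1, 1]. Spearman replaces each
taxon's observed values by midranks first. Two-sided p-values use the t
statistic with |n(l, m)| − 2 degrees of freedom and are deliberately not
corrected for multiplicity: downstream p-value filtering is a sparsity
device, not formal testing. Pairs with overlap below `min_overlap`
(default 5) are reported as 0 with p = 1 and flagged. The final matrix is
symmetrized by forcing a unit diagonal and taking the element-wise signed
minimum of (lm, ml); since the estimator is symmetric by construction this
is a formality, but the literal rule (plus a `min_abs` alternative) is
exposed because the signed minimum is not obviously what one wants when
the entries disagree in sign.

A `naive_pearson_baseline` computes the same complete-case Pearson on raw
log counts with no bias correction — the comparator whose correlations are
confounded by shared sampling-fraction variation.

## Distance correlation

The empirical distance correlation of a pair uses doubly centered
absolute-difference matrices D and E (full-matrix centering, diagonal
included): dCov²_n = n⁻² ΣΣ D_ij E_ij, dVar²_n = n⁻² ΣΣ D², dCor_n =
dCov_n/√(dVar_X dVar_Y) ∈ [0, 1]. dCor = 1 exactly for an affine map;
population dCor = 0 iff independence. Constant vectors (dVar = 0) get
dCor := 0 and p := 1. Complete cases are taken per pair; ranks may be
substituted first (`use_ranks`), which preserves general dependence —
default is raw ŷ.

Significance is a permutation test: one margin is shuffled, and because
double centering commutes with permutation and dVar is
permutation-invariant, permuted dCov² values are compared directly. The
add-one estimate p = (1 + #{perm ≥ obs})/(1 + B) is never zero; B = 999 by
default. Inside the matrix routine, permutations are evaluated in chunks
of 50 with sequential early termination: once 10 permuted statistics reach
the observed one the pair can no longer fall under any small α (the
flagging boundary needs the observed statistic to beat essentially every
permutation), so evaluation stops and the p-value is based on the
permutations drawn. Accept/reject decisions at α ≤ 0.01 are identical to
the full run; `dcor_pvalue(..., early_stop=False)` gives the exact-B
p-value and is what the uniformity property test uses.

## Sparsification

Two routes from the dense symmetrized estimate to a sparse matrix:

- **Soft thresholding** (variants `pearson1`, `spearman1`):
  R̂ = sign(R_n)(|R_n| − λ)₊ off the diagonal. λ is selected by repeated
  random-split cross-validation: 20 splits, training fraction
  ⌈n(1 − 1/log n)⌉/n, grid λ ∈ {0, 0.02, …, 1}; each split scores the
  Frobenius distance between the thresholded training-half estimate and
  the dense held-out-half estimate, and ties break toward the larger
  (sparser) λ. The split protocol and grid are package choices — the
  underlying objective only prescribes CV on the Frobenius loss. The
  positive-semidefinite constraint of the exact penalized formulation is
  dropped, as the soft-threshold operator replaces it; an eigenvalue
  clipping to the PSD cone could be added downstream but is intentionally
  not applied by default.
- **p-value filtering** (variants `pearson2`, `spearman2`, `distance`):
  entries with p ≥ α are zeroed, α = 0.005 by default, uncorrected. This
  is the only route offered for the distance measure: thresholding needs
  data splitting and therefore considerably larger samples.

The full pipeline (`secom`) is: prevalence filter (default: drop taxa
observed in < 10% of samples) → bias correction (multi-ecosystem aware)
→ dense correlation for the chosen measure → sparsification →
symmetrized sparse matrix with the support, the chosen λ or α, and the
dense estimate attached.

## Simulation design

The generator reproduces three benchmark scenarios with known truth; it
exists so every estimator is testable without any external data.

Layers (defaults in parentheses): per-taxon log-means α_j ~ U[2, 8];
latent log abundances Gaussian with variance σ⁰_jj = 4 (sd 2 natural-log
units, the scale of common log-normal fits to OTU abundances); designed
pairs correlated through this latent layer, which defines the recorded
truth R⁰; counts negative-binomial with variance μ + α_disp·μ² via a
gamma–Poisson mixture (linear and cross-ecosystem scenarios) or rounded
log-normal with extra log-variance α_disp (nonlinear scenario); observed
counts O = round(S·C·A·E) with log S_i ~ U[−2, 0], log C_j ~ U[−1, 1],
log E ~ N(0, σ_e²), σ_e² = 0.01·median(σ⁰_jj). "Adjacent pairs" means
the disjoint pairs (1,2), (3,4), …, so 25 designed pairs occupy the first
50 taxa. The log-mean, fraction and efficiency ranges and σ⁰ are explicit
reconstructions of an unpublished design, not transcriptions; they are
configurable module constants.

Nonlinear pairs follow the y = (x − c)² design: the driver's centered log
abundance is uniform (hence symmetric and light-tailed) and the partner is
the exact centered standardized square of the driver's realized log
abundance, rescaled to the common marginal variance. The pair's population
Pearson correlation is exactly 0 while the dependence is deterministic;
only the observation layer (counting noise, rounding, zeros) corrupts it.

Zeros arise naturally (NB draws of 0; products rounding below ½), at
roughly 5–15% of entries under the defaults; `inject_zeros` adds
controlled structural zeros (random entries forced to 0) or sampling zeros
(whole samples multiplied by small fractions and floored) on top for the
zero-mechanism experiments.

What the generator does **not** emulate: real marginal abundance
distributions fitted to a particular cohort, phylogenetic correlation
structure, longitudinal within-subject dependence, or heavy (50–90%)
zero inflation. Consequences observed in the benchmarks and worth knowing
about when interpreting passing tests:

- With zeros present, complete-case selection can censor one arm of a
  parabola for low-abundance quadratic pairs; the retained samples then
  show a genuinely monotone relation, so linear estimators flag a fraction
  of quadratic pairs that grows with the zero rate. This is a property of
  CCA on zero-inflated data, not an estimator bug.
- Null-pair p-values are approximately uniform, so p-value filtering at
  α = 0.005 flags about 0.005 × #null pairs false positives by design
  (≈ 25 of 4925 at d = 100); the permutation-filtered distance variant
  flags about B⁻¹-scale counts depending on the permutation budget.

## Numerical and degenerate-input choices

- Natural logs; zeros never logged. Variance floor 1e−8 before weight
  inversion; taxa observed once inherit the median variance for weighting.
- Correlation estimates clipped to [−1, 1]; diagonal forced to 1 where a
  taxon has ≥ 2 observations.
- dCov² clipped at 0 before the square root; permutation comparisons use a
  relative 1e−12 tolerance so exact ties count as exceedances.
- Pairs below the overlap threshold, or never co-observed, give 0/p = 1
  plus a flag — never an exception mid-matrix.
- All randomness flows from explicit seeds: the pipeline spawns separate
  streams for cross-validation splits and permutations from one master
  seed; generators are pure functions of their arguments (bit-identical
  regeneration is asserted in the suite).

## Benchmark problem sizes

The replicated experiments in the acceptance layer run at reduced scale
chosen as the package's own benchmark configuration: concordance at
n = 50, d = 100 with 25 replicates and 399 permutations (399 rather than
199 because the add-one p-value at 199 permutations bottoms out exactly at
0.005 and strict filtering at α = 0.005 could then never flag anything);
support-recovery TPR at n = 100, d = 100 with 20 replicates; the
loss-ratio comparison at n = 100, d = 200 with 20 replicates.

## Known limitations

- The weighted sampling-fraction estimator uses one variance per taxon;
  with very uneven missingness a per-(sample, taxon) variance could be
  better, but there is no principled one-pass estimate of it.
- Sample-bias invariance is exact only for complete tables (see above).
- p-value filtering controls no error rate; it is a sparsity device, and
  the support it selects inherits the ~α false-flag rate per null pair.
- The distance-correlation matrix is O(d²·B·n²) in the worst case;
  early termination and per-taxon caching make d ≈ a few hundred at
  n ≈ 100 practical on one core, but it remains the slowest path.
- Cross-ecosystem estimation requires shared subjects; ecosystems with
  disjoint subject sets yield only within-site results (flagged).
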