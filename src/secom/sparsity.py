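"""Sparsification of dense correlation estimates.

Two routes produce a sparse matrix from the dense complete-case estimate:

* **soft thresholding** — R̂ = sign(R_n)(|R_n| − λ)₊ with λ chosen by
  repeated sample-splitting cross-validation (minimize the Frobenius
  distance between the thresholded training-half estimate and the dense
  held-out-half estimate); ties broken toward larger λ (sparser). This is
  the route of the "Pearson1"/"Spearman1" variants and needs enough
  samples to split.
* **p-value filtering** — entries with p ≥ α are set to 0 (default
  α = 0.005, uncorrected). A sparsity device rather than formal testing;
  the only route offered for the distance measure, whose permutation
  p-values are cheap relative to data splitting.

`secom` runs the whole pipeline: prevalence filter → bias correction
(multi-ecosystem aware) → dense correlation → sparsification →
symmetrization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .bias_correction import BiasCorrectedTable, bias_correct_multi
from .distance_correlation import DEFAULT_N_PERMUTATIONS, dcor_matrix
from .io_tables import CountTable, filter_prevalence
from .linear_correlation import (
    DEFAULT_MIN_OVERLAP,
    CorrelationEstimate,
    pearson_cca,
    spearman_cca,
    symmetrize,
)

__all__ = [
    "SparseCorrelation",
    "soft_threshold",
    "select_lambda_cv",
    "filter_by_pvalue",
    "secom",
    "DEFAULT_ALPHA",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_ALPHA = 0.005
DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.02), 2))
DEFAULT_CV_SPLITS = 20

Method = Literal["pearson1", "pearson2", "spearman1", "spearman2", "distance"]


@dataclass
class SparseCorrelation:
    """Sparse correlation matrix with the choice that produced it."""

    matrix: np.ndarray
    taxon_ids: list[str]
    method: Literal["threshold", "pvalue_filter"]
    measure: str
    lambda_: float | None = None
    alpha: float | None = None
    cv_trace: dict | None = None
    dense: CorrelationEstimate | None = None
    ecosystem: list[str] | None = None

    @property
    def support(self) -> set[tuple[int, int]]:
        """Unordered off-diagonal index pairs with a nonzero estimate."""
        d = self.matrix.shape[0]
        return {
            (l, m)
            for l in range(d)
            for m in range(l + 1, d)
            if self.matrix[l, m] != 0
        }

    @property
    def q(self) -> int:
        return len(self.support)


def soft_threshold(R_n: np.ndarray, lambda_: float) -> np.ndarray:
    """Element-wise signed soft threshold on the off-diagonal; diagonal kept at 1.

    The result is symmetrized with the signed element-wise minimum rule.
    """
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    R_n = np.asarray(R_n, dtype=float)
    out = np.sign(R_n) * np.maximum(np.abs(R_n) - lambda_, 0.0)
    out = np.minimum(out, out.T)
    np.fill_diagonal(out, 1.0)
    return out


def _dense_estimate(
    y: BiasCorrectedTable,
    measure: str,
    min_overlap: int,
    n_permutations: int,
    seed: int | None,
) -> CorrelationEstimate:
    if measure == "pearson":
        return pearson_cca(y, min_overlap=min_overlap)
    if measure == "spearman":
        return spearman_cca(y, min_overlap=min_overlap)
    if measure == "distance":
        return dcor_matrix(
            y, min_overlap=min_overlap, n_permutations=n_permutations, seed=seed
        )
    raise ValueError(f"unknown measure {measure!r}")


def _subset_columns(y: BiasCorrectedTable, cols: np.ndarray) -> BiasCorrectedTable:
    from .bias_correction import _rebuild_mask

    sub = y.y_hat[:, cols]
    return BiasCorrectedTable(
        y_hat=sub,
        taxon_ids=list(y.taxon_ids),
        sample_ids=[y.sample_ids[c] for c in cols],
        mask=_rebuild_mask(sub),
        taxon_means=y.taxon_means,
        fraction=None,
        ecosystem=y.ecosystem,
    )


def select_lambda_cv(
    y: BiasCorrectedTable,
    measure: Literal["pearson", "spearman"] = "pearson",
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    n_splits: int = DEFAULT_CV_SPLITS,
    seed: int | None = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[float, dict]:
    """Cross-validated soft-threshold level λ*.

    Repeated random splits: the dense correlation is estimated on a
    training fraction of ⌈n(1 − 1/log n)⌉/n samples, thresholded at every
    λ on the grid, and scored by Frobenius distance to the dense estimate
    of the held-out samples. λ* minimizes the split-averaged loss; ties go
    to the larger (sparser) λ.
    """
    grid = list(lambda_grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    n = y.n_samples
    if n < 10:
        raise ValueError(
            "too few samples to split for cross-validation; use p-value "
            "filtering (method 'pearson2'/'spearman2'/'distance') instead"
        )
    n_train = int(np.ceil(n * (1.0 - 1.0 / np.log(n))))
    n_train = min(max(n_train, 2), n - 2)
    rng = np.random.default_rng(seed)
    losses = np.zeros((n_splits, len(grid)))
    for s in range(n_splits):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        r_train = _dense_estimate(_subset_columns(y, train), measure, min_overlap, 0, None).estimate
        r_test = _dense_estimate(_subset_columns(y, test), measure, 3, 0, None).estimate
        for g, lam in enumerate(grid):
            losses[s, g] = np.linalg.norm(soft_threshold(r_train, lam) - r_test)
    mean_loss = losses.mean(axis=0)
    # ties toward the larger lambda: scan from the sparse end
    best = len(grid) - 1 - int(np.argmin(mean_loss[::-1]))
    trace = {"lambda_grid": grid, "mean_loss": mean_loss.tolist(), "n_train": n_train}
    return float(grid[best]), trace


def filter_by_pvalue(est: CorrelationEstimate, alpha: float = DEFAULT_ALPHA) -> SparseCorrelation:
    """Zero out entries whose (uncorrected) p-value is ≥ α."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    keep = est.p_values < alpha
    matrix = np.where(keep, est.estimate, 0.0)
    np.fill_diagonal(matrix, 1.0)
    return SparseCorrelation(
        matrix=matrix,
        taxon_ids=list(est.taxon_ids),
        method="pvalue_filter",
        measure=est.measure,
        alpha=alpha,
        dense=est,
    )


def secom(
    table: CountTable,
    method: Method = "pearson2",
    min_prevalence: float = 0.10,
    fraction_estimator: Literal["simple", "weighted"] = "weighted",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    alpha: float = DEFAULT_ALPHA,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    cv_splits: int = DEFAULT_CV_SPLITS,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = 0,
) -> SparseCorrelation:
    """Full sparse-correlation pipeline on a count table.

    Variants: ``pearson1``/``spearman1`` use CV soft thresholding,
    ``pearson2``/``spearman2``/``distance`` use p-value filtering. Tables
    carrying ecosystem labels are corrected per ecosystem and correlated
    across (ecosystem, taxon) features paired by subject.
    """
    if method not in ("pearson1", "pearson2", "spearman1", "spearman2", "distance"):
        raise ValueError(f"unknown method {method!r}")
    measure = "distance" if method == "distance" else method[:-1]
    filtered = filter_prevalence(table, min_prevalence) if min_prevalence > 0 else table
    y = bias_correct_multi(filtered, method=fraction_estimator)

    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seed_cv, seed_perm = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    dense = _dense_estimate(y, measure, min_overlap, n_permutations, seed_perm)
    dense = symmetrize(dense)
    if method.endswith("1"):
        lam, trace = select_lambda_cv(
            y,
            measure=measure,  # type: ignore[arg-type]
            lambda_grid=lambda_grid,
            n_splits=cv_splits,
            seed=seed_cv,
            min_overlap=min_overlap,
        )
        matrix = soft_threshold(dense.estimate, lam)
        result = SparseCorrelation(
            matrix=matrix,
            taxon_ids=list(dense.taxon_ids),
            method="threshold",
            measure=measure,
            lambda_=lam,
            cv_trace=trace,
            dense=dense,
        )
    else:
        result = filter_by_pvalue(dense, alpha=alpha)
    result.ecosystem = y.ecosystem
    return result
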