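"""Empirical distance covariance / variance / correlation with permutation tests.

Distance correlation (dCor) quantifies general statistical dependence
between two variables: it is 0 at the population level if and only if the
variables are independent, 1 for exact linear maps, and strictly between
for nonlinear dependence (e.g., ~0.5 for a symmetric parabola). The
empirical estimator doubly centers the pairwise absolute-difference
matrices,

    D_ij = d_ij − d̄_i· − d̄_·j + d̄_··,   d_ij = |x_i − x_j|,

and sets dCov²_n = (1/n²) ΣΣ D_ij E_ij, dVar²_n(X) = (1/n²) ΣΣ D_ij²,
dCor_n = dCov_n / sqrt(dVar_n(X) dVar_n(Y)).

Significance comes from a permutation test: shuffling one variable breaks
any dependence, and the add-one p-value (1 + #{dCor_perm ≥ dCor_obs}) /
(1 + n_permutations) is never zero. Since dVar is invariant under
permutation, permuted dCov² values are compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bias_correction import BiasCorrectedTable
from .linear_correlation import (
    DEFAULT_MIN_OVERLAP,
    CorrelationEstimate,
    rank_transform,
)

__all__ = [
    "DistancePairComputation",
    "dcor_pair",
    "dcor_pvalue",
    "dcor_matrix",
    "DEFAULT_N_PERMUTATIONS",
]

DEFAULT_N_PERMUTATIONS = 999
_CHUNK = 50  # permutations evaluated per vectorized batch
_EARLY_STOP_COUNT = 10  # stop once this many permuted stats reach the observed


@dataclass
class DistancePairComputation:
    """Intermediate quantities of the empirical distance-correlation estimator."""

    D: np.ndarray
    E: np.ndarray
    dcov2: float
    dvarx2: float
    dvary2: float
    dcor: float


def _double_center(x: np.ndarray) -> np.ndarray:
    """Doubly centered pairwise absolute-difference matrix of a 1-D sample."""
    d = np.abs(x[:, None] - x[None, :])
    row = d.mean(axis=1, keepdims=True)
    col = d.mean(axis=0, keepdims=True)
    return d - row - col + d.mean()


def dcor_pair(x: np.ndarray, y: np.ndarray) -> DistancePairComputation:
    """Empirical distance covariance/variance/correlation for one pair.

    Inputs must be complete (no NaN) and of equal length n ≥ 4. If either
    vector is constant (dVar² = 0), dCor is defined as 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be complete cases (no NaN/inf)")
    D = _double_center(x)
    E = _double_center(y)
    n2 = n * n
    dcov2 = float(np.vdot(D, E)) / n2
    dvarx2 = float(np.vdot(D, D)) / n2
    dvary2 = float(np.vdot(E, E)) / n2
    if dvarx2 <= 0.0 or dvary2 <= 0.0:
        dcor = 0.0
    else:
        dcor = float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx2 * dvary2)))
        dcor = min(dcor, 1.0)
    return DistancePairComputation(D=D, E=E, dcov2=dcov2, dvarx2=dvarx2, dvary2=dvary2, dcor=dcor)


def _permuted_dcov2(
    D: np.ndarray,
    E: np.ndarray,
    dcov2_obs: float,
    n_permutations: int,
    rng: np.random.Generator,
    early_stop: bool,
) -> tuple[int, int]:
    """Count permuted dCov² values ≥ observed; returns (count, n_done).

    Permutation commutes with double centering, so permuting the rows and
    columns of the centered matrix E is equivalent to recomputing it from a
    permuted sample. With ``early_stop``, evaluation halts once the count
    reaches a bound that can no longer change the accept/reject decision at
    small α; the p-value is then based on the permutations actually drawn.
    """
    n = D.shape[0]
    n2 = n * n
    exceed = 0
    done = 0
    tol = 1e-12 * max(1.0, abs(dcov2_obs))
    while done < n_permutations:
        k = min(_CHUNK, n_permutations - done)
        idx = np.argsort(rng.random((k, n)), axis=1)
        e_perm = E[idx[:, :, None], idx[:, None, :]]
        stats = np.einsum("pij,ij->p", e_perm, D) / n2
        exceed += int(np.sum(stats >= dcov2_obs - tol))
        done += k
        if early_stop and exceed >= _EARLY_STOP_COUNT:
            break
    return exceed, done


def dcor_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | None = 0,
    early_stop: bool = False,
) -> float:
    """Permutation p-value for the empirical distance correlation.

    p = (1 + #{dCor_perm ≥ dCor_obs}) / (1 + n_permutations), reproducible
    under a fixed seed. Degenerate (constant) input gives p = 1.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    comp = dcor_pair(x, y)
    if comp.dvarx2 <= 0.0 or comp.dvary2 <= 0.0:
        return 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed, done = _permuted_dcov2(comp.D, comp.E, comp.dcov2, n_permutations, rng, early_stop)
    return (1.0 + exceed) / (1.0 + done)


def dcor_matrix(
    y: BiasCorrectedTable,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    use_ranks: bool = False,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = 0,
) -> CorrelationEstimate:
    """Pairwise complete-case distance correlation matrix D_n.

    Each pair is computed over the samples where both taxa are observed.
    With ``use_ranks``, per-taxon midranks replace the raw bias-corrected
    values first (ranks preserve general dependence). Pairs below
    ``min_overlap`` are reported as 0 with p = 1 and flagged.
    """
    if min_overlap < 4:
        raise ValueError("min_overlap must be at least 4 for distance correlation")
    data = rank_transform(y.y_hat) if use_ranks else y.y_hat
    d = data.shape[0]
    obs = np.isfinite(data)
    est = np.zeros((d, d))
    p = np.ones((d, d))
    overlap = obs.astype(np.int64) @ obs.astype(np.int64).T
    low = overlap < min_overlap
    np.fill_diagonal(low, False)
    rng = np.random.default_rng(seed)

    full = obs.all(axis=1)
    # centered distance matrices are reusable whenever a taxon has no missing entries
    cache: dict[int, np.ndarray] = {}

    def centered(l: int, sel: np.ndarray | None) -> np.ndarray:
        if sel is None:
            if l not in cache:
                cache[l] = _double_center(data[l])
            return cache[l]
        return _double_center(data[l, sel])

    for l in range(d):
        if np.isfinite(data[l]).sum() >= 2 and np.nanvar(data[l]) > 0:
            est[l, l] = 1.0
            p[l, l] = 0.0
        for m in range(l + 1, d):
            if low[l, m]:
                continue
            shared = obs[l] & obs[m]
            sel = None if (full[l] and full[m]) else shared
            if sel is None:
                D, E = centered(l, None), centered(m, None)
            else:
                D, E = _double_center(data[l, shared]), _double_center(data[m, shared])
            k = int(overlap[l, m])
            k2 = k * k
            dcov2 = float(np.vdot(D, E)) / k2
            dvarx2 = float(np.vdot(D, D)) / k2
            dvary2 = float(np.vdot(E, E)) / k2
            if dvarx2 <= 0.0 or dvary2 <= 0.0:
                continue
            dcor = min(float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx2 * dvary2))), 1.0)
            exceed, done = _permuted_dcov2(D, E, dcov2, n_permutations, rng, early_stop=True)
            est[l, m] = est[m, l] = dcor
            p[l, m] = p[m, l] = (1.0 + exceed) / (1.0 + done)

    return CorrelationEstimate(
        estimate=est,
        p_values=p,
        overlap=overlap,
        measure="distance",
        taxon_ids=list(y.taxon_ids),
        low_overlap=low | low.T,
    )
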