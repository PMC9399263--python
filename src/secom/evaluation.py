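"""Scoring estimated correlation matrices against simulation ground truth.

Accuracy is the relative norm loss ‖R̂ − R⁰‖ / ‖R⁰‖ under the Frobenius or
spectral norm. Support recovery is scored as

    TPR = #{(l,m): ρ̂_lm ≠ 0, ρ⁰_lm ≠ 0} / #{(l,m): ρ⁰_lm ≠ 0}
    FPR = #{(l,m): ρ̂_lm ≠ 0, ρ⁰_lm = 0} / #{(l,m): ρ⁰_lm = 0}

over unordered off-diagonal pairs ("nonzero" means exactly ≠ 0 for sparse
estimates; dense baselines are binarized by their own p < α convention
before scoring). The concordance analysis cross-tabulates the supports of
two sparse estimates against the true support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .linear_correlation import naive_pearson_baseline
from .sparsity import DEFAULT_ALPHA, SparseCorrelation, filter_by_pvalue, secom
from . import simulation as sim

__all__ = [
    "Metrics",
    "relative_norm_loss",
    "tpr_fpr",
    "support_set",
    "concordance",
    "run_benchmark",
]


@dataclass
class Metrics:
    frobenius_loss: float | None
    spectral_loss: float | None
    tpr: float | None
    fpr: float | None
    q_true: int
    q_hat: int


def relative_norm_loss(
    R_hat: np.ndarray,
    R0: np.ndarray,
    norm: Literal["frobenius", "spectral"] = "frobenius",
) -> float:
    """‖R̂ − R⁰‖ / ‖R⁰‖ for the chosen matrix norm."""
    R_hat = np.asarray(R_hat, dtype=float)
    R0 = np.asarray(R0, dtype=float)
    if R_hat.shape != R0.shape:
        raise ValueError(f"shape mismatch: {R_hat.shape} vs {R0.shape}")
    ord_ = "fro" if norm == "frobenius" else 2
    if norm not in ("frobenius", "spectral"):
        raise ValueError(f"unknown norm {norm!r}")
    return float(np.linalg.norm(R_hat - R0, ord_) / np.linalg.norm(R0, ord_))


def support_set(matrix: np.ndarray) -> set[tuple[int, int]]:
    """Unordered off-diagonal index pairs with nonzero entries."""
    matrix = np.asarray(matrix)
    d = matrix.shape[0]
    iu = np.triu_indices(d, k=1)
    nz = matrix[iu] != 0
    return set(zip(iu[0][nz].tolist(), iu[1][nz].tolist()))


def tpr_fpr(R_hat: np.ndarray, R0: np.ndarray) -> Metrics:
    """Support-recovery rates of R̂ against the true support of R⁰.

    ``R0`` may be a correlation matrix or a boolean dependence-support
    matrix (for nonlinear truths whose linear correlation is zero).
    """
    R_hat = np.asarray(R_hat)
    R0 = np.asarray(R0)
    if R_hat.shape != R0.shape:
        raise ValueError(f"shape mismatch: {R_hat.shape} vs {R0.shape}")
    est = support_set(R_hat)
    true = support_set(R0)
    d = R0.shape[0]
    n_pairs = d * (d - 1) // 2
    n_null = n_pairs - len(true)
    tp = len(est & true)
    fp = len(est - true)
    return Metrics(
        frobenius_loss=None,
        spectral_loss=None,
        tpr=tp / len(true) if true else None,
        fpr=fp / n_null if n_null else None,
        q_true=len(true),
        q_hat=len(est),
    )


def concordance(
    sparse_a: SparseCorrelation | np.ndarray,
    sparse_b: SparseCorrelation | np.ndarray,
    R0_support: np.ndarray,
) -> dict[str, int]:
    """Partition pairs flagged by two sparse estimates against the truth.

    Returns counts for pairs flagged by both estimates, only the first, and
    only the second, each split into true positives (truly dependent) and
    false positives.
    """
    sa = sparse_a.support if isinstance(sparse_a, SparseCorrelation) else support_set(sparse_a)
    sb = sparse_b.support if isinstance(sparse_b, SparseCorrelation) else support_set(sparse_b)
    true = support_set(R0_support)
    out = {}
    for name, pairs in (("both", sa & sb), ("only_a", sa - sb), ("only_b", sb - sa)):
        out[name] = len(pairs)
        out[f"{name}_tp"] = len(pairs & true)
        out[f"{name}_fp"] = len(pairs - true)
    return out


def _align_to_truth(est: SparseCorrelation, truth: sim.SimulationTruth, table_taxa: list[str],
                    ecosystems: list[str] | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Embed an estimate (possibly on a taxon subset) into truth coordinates.

    Taxa dropped by the prevalence filter contribute all-zero rows/columns,
    so a designed pair lost to filtering counts as undetected.
    """
    d0 = truth.R0.shape[0]
    full = np.zeros((d0, d0))
    np.fill_diagonal(full, 1.0)
    if ecosystems is None:
        index = {t: k for k, t in enumerate(table_taxa)}
        rows = [index[t] for t in est.taxon_ids]
    else:
        d_per = d0 // len(ecosystems)
        index = {}
        for e_ix, eco in enumerate(ecosystems):
            for k, t in enumerate(table_taxa):
                index[f"{eco}::{t}"] = e_ix * d_per + k
        rows = [index[t] for t in est.taxon_ids]
    rows_arr = np.asarray(rows)
    full[np.ix_(rows_arr, rows_arr)] = est.matrix
    return full, truth.R0, truth.support.astype(float) + np.eye(d0)


def _simulate(scenario: str, n: int, d: int, dispersion: float, seed: int):
    if scenario == "linear":
        return sim.simulate_linear(n=n, d=d, dispersion=dispersion, seed=seed)
    if scenario == "nonlinear":
        return sim.simulate_nonlinear(n=n, d=d, dispersion=dispersion, seed=seed)
    if scenario == "two_ecosystems":
        return sim.simulate_two_ecosystems(n=n, d=d, dispersion=dispersion, seed=seed)
    raise ValueError(f"unknown scenario {scenario!r}")


def run_benchmark(
    scenario: Literal["linear", "nonlinear", "two_ecosystems"],
    grid: Iterable[tuple[int, int, float]],
    methods: Sequence[str] = ("pearson1", "pearson2", "distance", "naive"),
    n_reps: int = 20,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = 399,
    min_prevalence: float = 0.10,
) -> pd.DataFrame:
    """Replicated benchmark over an (n, d, dispersion) grid.

    For every setting and method, reports the mean ± standard error (sample
    SD / √n_reps) of the relative norm losses, TPR and FPR across seeded
    replicates. ``naive`` is the standard log-count Pearson baseline,
    binarized at p < α for support metrics. Fully reproducible from the
    master seed.
    """
    master = np.random.SeedSequence(seed)
    records = []
    for n, d, dispersion in grid:
        setting_seeds = master.spawn(n_reps)
        per_method: dict[str, list[dict]] = {m: [] for m in methods}
        for rep, ss in enumerate(setting_seeds):
            rep_seed = int(ss.generate_state(1)[0] % (2**31))
            table, truth = _simulate(scenario, n, d, dispersion, rep_seed)
            ecosystems = sorted(set(table.ecosystem)) if table.ecosystem else None
            for method in methods:
                if method == "naive":
                    dense = naive_pearson_baseline(table)
                    est = filter_by_pvalue(dense, alpha=alpha)
                    est.measure = "naive"
                    # the dense (unfiltered) matrix is what the baseline estimates
                    loss_matrix_est = SparseCorrelation(
                        matrix=dense.estimate, taxon_ids=dense.taxon_ids,
                        method="pvalue_filter", measure="naive",
                    )
                else:
                    est = secom(
                        table,
                        method=method,  # type: ignore[arg-type]
                        alpha=alpha,
                        n_permutations=n_permutations,
                        min_prevalence=min_prevalence,
                        seed=rep_seed,
                    )
                    loss_matrix_est = est
                full_loss, R0, support = _align_to_truth(
                    loss_matrix_est, truth, table.taxon_ids, ecosystems
                )
                full_support, _, _ = _align_to_truth(est, truth, table.taxon_ids, ecosystems)
                m = tpr_fpr(full_support, support)
                records_metrics = {
                    "frobenius_loss": relative_norm_loss(full_loss, R0, "frobenius"),
                    "spectral_loss": relative_norm_loss(full_loss, R0, "spectral"),
                    "tpr": m.tpr,
                    "fpr": m.fpr,
                    "q_hat": m.q_hat,
                }
                per_method[method].append(records_metrics)
        for method, reps in per_method.items():
            row = {"scenario": scenario, "n": n, "d": d, "dispersion": dispersion,
                   "method": method, "n_reps": n_reps}
            for key in ("frobenius_loss", "spectral_loss", "tpr", "fpr", "q_hat"):
                vals = np.array([r[key] for r in reps if r[key] is not None], dtype=float)
                row[f"{key}_mean"] = float(vals.mean()) if vals.size else np.nan
                row[f"{key}_se"] = (
                    float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
                )
            records.append(row)
    return pd.DataFrame.from_records(records)
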