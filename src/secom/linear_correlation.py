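"""Complete-case Pearson and Spearman correlation on bias-corrected abundances.

For a pair of taxa (l, m), statistics are computed over the complete-case
set n(l, m) = samples where both taxa are observed, while each taxon's mean
μ̂_l is taken over its own observation set n(l):

    μ̂_l = (1/|n(l)|) Σ_{i∈n(l)} ŷ_il
    σ̂_lm = (1/|n(l,m)|) Σ_{i∈n(l,m)} (ŷ_il − μ̂_l)(ŷ_im − μ̂_m)
    ρ̂_lm = σ̂_lm / sqrt(σ̂_ll σ̂_mm)

The mixed index-set convention can push |ρ̂| marginally above 1 under
missingness; estimates are clipped to [−1, 1]. Two-sided p-values come from
the t statistic with |n(l,m)| − 2 degrees of freedom; they are deliberately
not corrected for multiplicity (p-value filtering downstream is a sparsity
device, not formal testing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .bias_correction import BiasCorrectedTable, build_presence_mask
from .io_tables import CountTable

__all__ = [
    "CorrelationEstimate",
    "pearson_cca",
    "spearman_cca",
    "symmetrize",
    "naive_pearson_baseline",
]

DEFAULT_MIN_OVERLAP = 5


@dataclass
class CorrelationEstimate:
    """Dense pairwise correlation estimate with p-values and overlap counts."""

    estimate: np.ndarray
    p_values: np.ndarray
    overlap: np.ndarray
    measure: Literal["pearson", "spearman", "distance"]
    taxon_ids: list[str]
    mu_hat: np.ndarray | None = None
    sigma_hat: np.ndarray | None = None
    low_overlap: np.ndarray | None = None  # True where |n(l,m)| < min_overlap


def _cca_pearson_from_matrix(
    y: np.ndarray, min_overlap: int, measure: str, taxon_ids: list[str]
) -> CorrelationEstimate:
    """Pairwise complete-case Pearson machinery shared by all linear paths."""
    if min_overlap < 3:
        raise ValueError("min_overlap must be at least 3")
    mask = np.isfinite(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(np.where(mask, y, np.nan), axis=1)
    z = np.where(mask, y - mu[:, None], 0.0)
    m_int = mask.astype(np.int64)
    overlap = m_int @ m_int.T
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = (z @ z.T) / overlap
        diag = np.diag(sigma).copy()
        denom = np.sqrt(np.outer(diag, diag))
        rho = sigma / denom
    rho = np.clip(rho, -1.0, 1.0)
    low = overlap < min_overlap
    np.fill_diagonal(low, False)
    bad = ~np.isfinite(rho)
    rho[bad] = 0.0
    rho[low] = 0.0
    n_l = np.diag(overlap)
    np.fill_diagonal(rho, np.where(n_l >= 2, 1.0, 0.0))

    df = overlap - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / (1.0 - rho**2))
    p = np.ones_like(rho)
    ok = (df > 0) & np.isfinite(t) & ~low & ~bad
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    # perfect correlations: t is infinite, p limits to 0
    perfect = (np.abs(rho) >= 1.0) & (df > 0) & ~low
    p[perfect] = 0.0
    np.fill_diagonal(p, 0.0)
    return CorrelationEstimate(
        estimate=rho,
        p_values=p,
        overlap=overlap,
        measure=measure,  # type: ignore[arg-type]
        taxon_ids=list(taxon_ids),
        mu_hat=mu,
        sigma_hat=sigma,
        low_overlap=low,
    )


def pearson_cca(
    y: BiasCorrectedTable, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> CorrelationEstimate:
    """Complete-case Pearson correlation matrix R_n on bias-corrected ŷ.

    Pairs with overlap below ``min_overlap`` (or never co-observed) are
    reported as estimate 0, p-value 1, and flagged in ``low_overlap``.
    """
    return _cca_pearson_from_matrix(y.y_hat, min_overlap, "pearson", y.taxon_ids)


def rank_transform(y: np.ndarray) -> np.ndarray:
    """Per-taxon midranks of the observed entries (NaN preserved)."""
    ranked = np.full(y.shape, np.nan)
    for j in range(y.shape[0]):
        obs = np.isfinite(y[j])
        if obs.any():
            ranked[j, obs] = stats.rankdata(y[j, obs], method="average")
    return ranked


def spearman_cca(
    y: BiasCorrectedTable, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> CorrelationEstimate:
    """Complete-case Spearman matrix S_n: midranks per taxon, then Pearson."""
    ranked = rank_transform(y.y_hat)
    est = _cca_pearson_from_matrix(ranked, min_overlap, "spearman", y.taxon_ids)
    return est


def symmetrize(
    est: CorrelationEstimate, rule: Literal["min_signed", "min_abs"] = "min_signed"
) -> CorrelationEstimate:
    """Force a symmetric estimate with unit diagonal.

    Each off-diagonal pair (ρ̂_lm, ρ̂_ml) is replaced by the element-wise
    minimum: ρ̂_lm I(ρ̂_lm ≤ ρ̂_ml) + ρ̂_ml I(ρ̂_lm > ρ̂_ml). With
    ``rule="min_abs"`` the entry of smaller magnitude is kept instead.
    p-values are symmetrized with the pairwise maximum. Idempotent.
    """
    r = est.estimate
    if r.shape[0] != r.shape[1]:
        raise ValueError("estimate matrix must be square")
    if rule == "min_signed":
        sym = np.minimum(r, r.T)
    elif rule == "min_abs":
        sym = np.where(np.abs(r) <= np.abs(r.T), r, r.T)
    else:
        raise ValueError(f"unknown symmetrization rule {rule!r}")
    sym = sym.copy()
    np.fill_diagonal(sym, 1.0)
    p = np.maximum(est.p_values, est.p_values.T)
    low = est.low_overlap
    if low is not None:
        low = low | low.T
    return CorrelationEstimate(
        estimate=sym,
        p_values=p,
        overlap=est.overlap,
        measure=est.measure,
        taxon_ids=list(est.taxon_ids),
        mu_hat=est.mu_hat,
        sigma_hat=est.sigma_hat,
        low_overlap=low,
    )


def naive_pearson_baseline(
    table: CountTable, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> CorrelationEstimate:
    """Standard Pearson correlation of log counts, with no bias correction.

    Complete-case over nonzero entries; the comparator that conflates true
    correlation with shared sampling-fraction/efficiency variation. Tables
    with multiple ecosystem labels are rearranged (without correction) into
    (ecosystem, taxon) features over subjects, so the baseline is scored on
    the same pairs as the corrected estimators.
    """
    if table.ecosystem is not None and len(set(table.ecosystem)) > 1:
        if table.subject is None:
            raise ValueError("subject identifiers required for multi-ecosystem tables")
        ecosystems = sorted(set(table.ecosystem))
        subjects = sorted(set(table.subject))
        subj_col = {s: k for k, s in enumerate(subjects)}
        rows, ids = [], []
        for eco in ecosystems:
            idx = [i for i, e in enumerate(table.ecosystem) if e == eco]
            chosen: dict[str, int] = {}
            for i in sorted(idx, key=lambda i: table.sample_ids[i]):
                chosen.setdefault(table.subject[i], i)
            block = np.full((table.n_taxa, len(subjects)), np.nan)
            for subj, i in chosen.items():
                col = table.counts[:, i].astype(float)
                vals = np.where(col > 0, np.log(np.maximum(col, 1.0)), np.nan)
                block[:, subj_col[subj]] = vals
            rows.append(block)
            ids.extend(f"{eco}::{t}" for t in table.taxon_ids)
        return _cca_pearson_from_matrix(np.vstack(rows), min_overlap, "pearson", ids)
    mask = build_presence_mask(table)
    logs = np.full(table.counts.shape, np.nan)
    logs[mask.mask] = np.log(table.counts[mask.mask].astype(float))
    return _cca_pearson_from_matrix(logs, min_overlap, "pearson", table.taxon_ids)
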