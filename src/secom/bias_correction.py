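"""Bias correction of observed microbiome counts.

Observed counts are modeled multiplicatively as

    O_ij = S_i * C_j * A_ij * E_ij,

where ``S_i`` is a sample-specific sampling fraction (the unknown portion
of the ecosystem captured by sequencing), ``C_j`` a taxon-specific
sequencing efficiency, ``A_ij`` the true absolute abundance and ``E_ij``
multiplicative noise. On the log scale this is additive,
``o_ij = s_i + c_j + a_ij + e_ij``, and both nuisance terms can be removed
from the observable log counts:

* centering each taxon across the samples in which it is observed removes
  the taxon-specific efficiency ``c_j``;
* the per-sample mean of those residuals estimates the centered sampling
  fraction ``s_i - s̄`` (either a simple arithmetic mean or an
  inverse-variance weighted mean over the taxa present in the sample).

The result, ``ŷ_ij = (o_ij − ō·_j) − (ŝ_i − s̄·)``, is a proxy for the
centered log absolute abundance; correlations among the ``ŷ`` columns
approximate correlations among the unobservable ``a`` columns when the
noise-to-signal ratio is small. Zeros are never logged: every statistic is
computed over the entries where a taxon is actually observed (complete-case
analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_tables import CountTable

__all__ = [
    "PresenceMask",
    "SamplingFractionEstimate",
    "BiasCorrectedTable",
    "build_presence_mask",
    "center_log_counts",
    "estimate_sampling_fraction_simple",
    "estimate_sampling_fraction_weighted",
    "bias_correct",
    "bias_correct_multi",
]

VARIANCE_FLOOR = 1e-8


class BiasCorrectionError(ValueError):
    pass


@dataclass
class PresenceMask:
    """Presence indicators M_ij and the derived complete-case index sets.

    ``mask`` is taxa x samples, True exactly where the observed count is
    positive. ``n_of_l[l]`` is the number of samples in which taxon ``l``
    is observed; ``n_of_lm[l, m]`` the number of samples where taxa ``l``
    and ``m`` are both observed; ``d_of_i[i]`` the number of observed taxa
    in sample ``i``.
    """

    mask: np.ndarray
    n_of_l: np.ndarray
    n_of_lm: np.ndarray
    d_of_i: np.ndarray
    empty_pairs: np.ndarray  # boolean, True for pairs never co-observed


@dataclass
class SamplingFractionEstimate:
    """Estimate of the centered log sampling fractions s_i − s̄·."""

    s_centered: np.ndarray
    method: Literal["simple", "weighted"]
    weights: np.ndarray | None = None  # per-taxon inverse-variance weights (unnormalized)


@dataclass
class BiasCorrectedTable:
    """Bias-corrected log abundances ŷ (taxa x samples; NaN where unobserved)."""

    y_hat: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    mask: PresenceMask
    taxon_means: np.ndarray
    fraction: SamplingFractionEstimate | None
    ecosystem: list[str] | None = None
    provenance: dict | None = None

    @property
    def n_taxa(self) -> int:
        return self.y_hat.shape[0]

    @property
    def n_samples(self) -> int:
        return self.y_hat.shape[1]


def build_presence_mask(table: CountTable) -> PresenceMask:
    """Presence mask and complete-case index-set sizes for a count table."""
    mask = table.counts > 0
    m_int = mask.astype(np.int64)
    n_of_lm = m_int @ m_int.T
    n_of_l = np.diag(n_of_lm).copy()
    d_of_i = m_int.sum(axis=0)
    empty = n_of_lm == 0
    np.fill_diagonal(empty, False)
    if empty.any():
        n_bad = int(empty.sum()) // 2
        warnings.warn(
            f"{n_bad} taxon pair(s) are never observed together; their "
            "correlations cannot be estimated and will be reported as 0",
            stacklevel=2,
        )
    return PresenceMask(mask=mask, n_of_l=n_of_l, n_of_lm=n_of_lm, d_of_i=d_of_i, empty_pairs=empty)


def center_log_counts(table: CountTable, mask: PresenceMask) -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon centered natural-log counts.

    Returns ``(residuals, taxon_means)`` where ``residuals[j, i] =
    o_ij − ō·_j`` on observed entries and NaN elsewhere. The mean ``ō·_j``
    is taken over the samples where taxon ``j`` is observed; centering
    cancels the taxon-specific efficiency ``c_j`` exactly.
    """
    if np.any(mask.n_of_l == 0):
        dead = [table.taxon_ids[j] for j in np.flatnonzero(mask.n_of_l == 0)]
        raise BiasCorrectionError(
            f"taxa observed in zero samples must be filtered upstream: {dead[:5]}"
        )
    logs = np.full(table.counts.shape, np.nan)
    logs[mask.mask] = np.log(table.counts[mask.mask].astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        taxon_means = np.nanmean(logs, axis=1)
    residuals = logs - taxon_means[:, None]
    return residuals, taxon_means


def estimate_sampling_fraction_simple(
    residuals: np.ndarray, mask: PresenceMask
) -> SamplingFractionEstimate:
    """Arithmetic-mean estimator of the sampling-fraction difference.

    ``ŝ_i − s̄· = (1/|d(i)|) Σ_{j∈d(i)} (o_ij − ō·_j)``. The estimates are
    re-centered to mean zero across samples (only the centered quantity is
    identifiable).
    """
    if np.any(mask.d_of_i == 0):
        bad = np.flatnonzero(mask.d_of_i == 0)
        raise BiasCorrectionError(f"sample index {bad[0]} has zero observed taxa")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.nanmean(residuals, axis=0)
    s = s - s.mean()
    return SamplingFractionEstimate(s_centered=s, method="simple")


def estimate_sampling_fraction_weighted(
    residuals: np.ndarray, mask: PresenceMask
) -> SamplingFractionEstimate:
    """Inverse-variance weighted estimator of the sampling-fraction difference.

    Two-pass scheme: a first pass uses the simple estimator; per-taxon
    residual variances are then estimated from ``o_ij − ō·_j − ŝ_i`` over
    the samples where the taxon is observed, and the second pass averages
    the residuals with weights ``w_j ∝ 1/Var_j`` normalized within each
    sample over its observed taxa.
    """
    first = estimate_sampling_fraction_simple(residuals, mask)
    adjusted = residuals - first.s_centered[None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(adjusted, axis=1, ddof=1)
    var = np.where(np.isfinite(var), var, np.nan)
    # taxa observed once have no variance estimate; give them the median variance
    if np.all(np.isnan(var)):
        var = np.ones_like(var)
    var = np.where(np.isnan(var), np.nanmedian(var), var)
    n_floored = int(np.sum(var < VARIANCE_FLOOR))
    if n_floored:
        warnings.warn(
            f"{n_floored} taxa with ~zero residual variance; weights capped "
            f"at 1/{VARIANCE_FLOOR:g}",
            stacklevel=2,
        )
    var = np.maximum(var, VARIANCE_FLOOR)
    inv = 1.0 / var
    w = np.where(mask.mask, inv[:, None], 0.0)
    w_sum = w.sum(axis=0)
    w = w / w_sum[None, :]
    s = np.nansum(np.where(mask.mask, residuals, 0.0) * w, axis=0)
    s = s - s.mean()
    return SamplingFractionEstimate(s_centered=s, method="weighted", weights=inv)


def bias_correct(
    table: CountTable,
    method: Literal["simple", "weighted"] = "weighted",
    ecosystem_label: str | None = None,
) -> BiasCorrectedTable:
    """Remove sample- and taxon-specific biases from a single-ecosystem table.

    ``ŷ_ij = (o_ij − ō·_j) − (ŝ_i − s̄·)`` on observed entries, NaN
    elsewhere. Invariant to multiplying any sample's counts, or any taxon's
    counts, by a positive constant.
    """
    mask = build_presence_mask(table)
    residuals, taxon_means = center_log_counts(table, mask)
    if method == "simple":
        frac = estimate_sampling_fraction_simple(residuals, mask)
    elif method == "weighted":
        frac = estimate_sampling_fraction_weighted(residuals, mask)
    else:
        raise BiasCorrectionError(f"unknown fraction estimator {method!r}")
    y_hat = residuals - frac.s_centered[None, :]
    return BiasCorrectedTable(
        y_hat=y_hat,
        taxon_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
        mask=mask,
        taxon_means=taxon_means,
        fraction=frac,
        ecosystem=[ecosystem_label] * table.n_taxa if ecosystem_label else None,
        provenance={"method": method, "ecosystem": ecosystem_label},
    )


def _rebuild_mask(y_hat: np.ndarray) -> PresenceMask:
    mask = np.isfinite(y_hat)
    m_int = mask.astype(np.int64)
    n_of_lm = m_int @ m_int.T
    empty = n_of_lm == 0
    np.fill_diagonal(empty, False)
    return PresenceMask(
        mask=mask,
        n_of_l=np.diag(n_of_lm).copy(),
        n_of_lm=n_of_lm,
        d_of_i=m_int.sum(axis=0),
        empty_pairs=empty,
    )


def bias_correct_multi(
    table: CountTable, method: Literal["simple", "weighted"] = "weighted"
) -> BiasCorrectedTable:
    """Bias-correct a multi-ecosystem table, ecosystem by ecosystem.

    Correction (centering and sampling-fraction estimation) is performed
    independently within each ecosystem, so the within-ecosystem blocks of
    the result are identical to what :func:`bias_correct` would give on
    that ecosystem alone. The corrected blocks are concatenated into one
    table whose rows are ``(ecosystem, taxon)`` features and whose columns
    are subjects; an entry is missing when the subject lacks a sample in
    that ecosystem or the taxon is zero there.
    """
    if table.ecosystem is None:
        return bias_correct(table, method=method)
    ecosystems = sorted(set(table.ecosystem))
    if len(ecosystems) == 1:
        result = bias_correct(table, method=method, ecosystem_label=ecosystems[0])
        return result
    if table.subject is None:
        raise BiasCorrectionError(
            "subject identifiers are required to pair samples across ecosystems"
        )
    subjects = sorted(set(table.subject))
    subj_col = {s: k for k, s in enumerate(subjects)}

    blocks, row_ids, row_eco, means = [], [], [], []
    provenance: dict = {"method": method, "ecosystems": ecosystems}
    seen_subjects: dict[str, set] = {}
    for eco in ecosystems:
        idx = [i for i, e in enumerate(table.ecosystem) if e == eco]
        # one sample per subject per ecosystem; replicates resolved by sample-id order
        by_subject: dict[str, int] = {}
        replicated = []
        for i in sorted(idx, key=lambda i: table.sample_ids[i]):
            subj = table.subject[i]
            if subj in by_subject:
                replicated.append(subj)
            else:
                by_subject[subj] = i
        if replicated:
            warnings.warn(
                f"ecosystem {eco!r}: subjects {sorted(set(replicated))[:5]} have "
                "replicate samples; keeping the first by sample-id order",
                stacklevel=2,
            )
        chosen = list(by_subject.values())
        sub = table.select_samples(chosen)
        corrected = bias_correct(sub, method=method, ecosystem_label=eco)
        block = np.full((sub.n_taxa, len(subjects)), np.nan)
        cols = [subj_col[table.subject[i]] for i in chosen]
        block[:, cols] = corrected.y_hat
        blocks.append(block)
        row_ids.extend(f"{eco}::{t}" for t in sub.taxon_ids)
        row_eco.extend([eco] * sub.n_taxa)
        means.append(corrected.taxon_means)
        seen_subjects[eco] = set(by_subject)
        provenance[eco] = {"n_samples": len(chosen), "fraction": corrected.fraction}

    for a in range(len(ecosystems)):
        for b in range(a + 1, len(ecosystems)):
            ea, eb = ecosystems[a], ecosystems[b]
            if not (seen_subjects[ea] & seen_subjects[eb]):
                warnings.warn(
                    f"no subjects shared between ecosystems {ea!r} and {eb!r}; "
                    "cross-ecosystem correlations for this pair are not estimable",
                    stacklevel=2,
                )
    y_hat = np.vstack(blocks)
    return BiasCorrectedTable(
        y_hat=y_hat,
        taxon_ids=row_ids,
        sample_ids=subjects,
        mask=_rebuild_mask(y_hat),
        taxon_means=np.concatenate(means),
        fraction=None,
        ecosystem=row_eco,
        provenance=provenance,
    )
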