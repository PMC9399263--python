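"""Synthetic microbiome count tables with known correlation ground truth.

Three benchmark scenarios, all distorted by sample-specific sampling
fractions and taxon-specific sequencing efficiencies:

* **linear** — negative-binomial counts whose latent log abundances carry
  linearly correlated adjacent taxon pairs;
* **nonlinear** — log-normal counts where each designed pair is
  quadratically related (symmetric parabola, so the population Pearson
  correlation is exactly 0 while dependence is total);
* **two_ecosystems** — matched taxa correlated across two ecosystems, with
  independent biases drawn per ecosystem and subjects linking the columns.

Generation layers, per entry (i = sample, j = taxon):

    a_ij  ~ latent Gaussian log abundance, mean α_j ~ U[2, 8], variance
            σ⁰_jj = 4 (sd of 2 natural-log units); designed pairs are
            correlated through this layer, and R⁰ is its correlation matrix
    A_ij  ~ integer abundance around exp(a_ij): negative binomial with
            variance μ + α_disp μ² (linear scenarios) or rounded log-normal
            with extra log-variance α_disp (nonlinear scenario)
    O_ij  = round(S_i · C_j · A_ij · E_ij), with log S_i ~ U[−2, 0],
            log C_j ~ U[−1, 1], log E_ij ~ N(0, σ_e²),
            σ_e² = 0.01 · median(σ⁰_jj)

Zeros arise naturally (A_ij = 0, or the product rounding below 1/2), and
`inject_zeros` adds controlled structural or sampling zeros on top. Every
generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_tables import CountTable

__all__ = [
    "SimulationTruth",
    "simulate_linear",
    "simulate_nonlinear",
    "simulate_two_ecosystems",
    "inject_zeros",
]

LOG_MEAN_RANGE = (2.0, 8.0)
LOG_FRACTION_RANGE = (-2.0, 0.0)
LOG_EFFICIENCY_RANGE = (-1.0, 1.0)
SIGMA0_JJ = 4.0
NOISE_FRACTION = 0.01  # sigma_e^2 = 0.01 * median(sigma0_jj)
DEFAULT_RHO = 0.8


class SimulationError(ValueError):
    pass


@dataclass
class SimulationTruth:
    """Ground truth of one simulated data set."""

    a: np.ndarray  # latent log abundances, taxa x samples
    R0: np.ndarray  # true (linear) correlation matrix of the latent layer
    Sigma0: np.ndarray
    support: np.ndarray  # boolean d x d: truly dependent pairs (incl. nonlinear)
    alpha_mean: np.ndarray
    s: np.ndarray  # log sampling fractions per sample
    c: np.ndarray  # log sequencing efficiencies per taxon
    sigma_e2: float
    dispersion: float
    seed: int | None


def _pair_indices(n_corr_pairs: int) -> list[tuple[int, int]]:
    """Disjoint adjacent pairs (0,1), (2,3), ... among the first 2p taxa."""
    return [(2 * k, 2 * k + 1) for k in range(n_corr_pairs)]


def _check_dims(n: int, d: int, n_corr_pairs: int) -> None:
    if n < 2 or d < 1:
        raise SimulationError(f"invalid dimensions n={n}, d={d}")
    if n_corr_pairs < 0 or 2 * n_corr_pairs > d:
        raise SimulationError(
            f"{n_corr_pairs} correlated pairs need {2 * n_corr_pairs} taxa, have {d}"
        )


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with mean mu and variance mu + dispersion*mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)
    return rng.poisson(lam)


def _observe(
    A: np.ndarray, s: np.ndarray, c: np.ndarray, sigma_e2: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply biases and noise: O = round(S C A E), taxa x samples."""
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=A.shape)
    scale = np.exp(s[None, :] + c[:, None] + e)
    return np.rint(A * scale).astype(np.int64)


def _truth_matrices(d: int, pairs: list[tuple[int, int]], rho: float):
    R0 = np.eye(d)
    support = np.zeros((d, d), dtype=bool)
    for l, m in pairs:
        R0[l, m] = R0[m, l] = rho
        support[l, m] = support[m, l] = True
    Sigma0 = SIGMA0_JJ * R0
    return R0, support, Sigma0


def simulate_linear(
    n: int,
    d: int,
    dispersion: float = 0.5,
    n_corr_pairs: int | None = None,
    rho: float = DEFAULT_RHO,
    seed: int | None = 0,
) -> tuple[CountTable, SimulationTruth]:
    """Linear scenario: NB counts, adjacent taxon pairs correlated at ``rho``.

    ``n_corr_pairs`` defaults to 25 correlated pairs among the first 50 taxa
    (capped at d // 2 for small tables).
    """
    if n_corr_pairs is None:
        n_corr_pairs = min(25, d // 2)
    _check_dims(n, d, n_corr_pairs)
    rng = np.random.default_rng(seed)
    pairs = _pair_indices(n_corr_pairs)
    alpha = rng.uniform(*LOG_MEAN_RANGE, size=d)
    R0, support, Sigma0 = _truth_matrices(d, pairs, rho)

    sd = np.sqrt(SIGMA0_JJ)
    z = rng.standard_normal((d, n))
    a = z.copy()
    for l, m in pairs:
        a[m] = rho * z[l] + np.sqrt(1.0 - rho**2) * z[m]
    a = alpha[:, None] + sd * a

    A = _nb_counts(np.exp(a), dispersion, rng)
    s = rng.uniform(*LOG_FRACTION_RANGE, size=n)
    c = rng.uniform(*LOG_EFFICIENCY_RANGE, size=d)
    sigma_e2 = NOISE_FRACTION * SIGMA0_JJ
    O = _observe(A, s, c, sigma_e2, rng)

    table = CountTable(
        counts=O,
        taxon_ids=[f"T{j + 1}" for j in range(d)],
        sample_ids=[f"S{i + 1}" for i in range(n)],
    )
    truth = SimulationTruth(
        a=a, R0=R0, Sigma0=Sigma0, support=support, alpha_mean=alpha,
        s=s, c=c, sigma_e2=sigma_e2, dispersion=dispersion, seed=seed,
    )
    return table, truth


def simulate_nonlinear(
    n: int,
    d: int,
    dispersion: float = 0.5,
    n_corr_pairs: int | None = None,
    seed: int | None = 0,
) -> tuple[CountTable, SimulationTruth]:
    """Nonlinear scenario: log-normal counts, quadratic adjacent pairs.

    For each designed pair (j, j+1) the partner's centered log abundance is
    the standardized centered square of the first taxon's, so the pair's
    population Pearson correlation is 0 while the dependence is
    deterministic. ``dispersion`` sets the extra log-normal count variance.
    """
    if n_corr_pairs is None:
        n_corr_pairs = min(25, d // 2)
    _check_dims(n, d, n_corr_pairs)
    rng = np.random.default_rng(seed)
    pairs = _pair_indices(n_corr_pairs)
    alpha = rng.uniform(*LOG_MEAN_RANGE, size=d)
    R0, support, Sigma0 = _truth_matrices(d, pairs, 0.0)
    for l, m in pairs:
        support[l, m] = support[m, l] = True

    sd = np.sqrt(SIGMA0_JJ)
    eta = rng.normal(0.0, np.sqrt(dispersion), size=(d, n)) if dispersion > 0 else np.zeros((d, n))
    a = alpha[:, None] + sd * rng.standard_normal((d, n)) + eta
    for l, m in pairs:
        # the y = (x-c)^2 design: driver symmetric (uniform) about its mean,
        # partner an exact centered quadratic of the driver's realized log
        # abundance, rescaled to the common marginal variance. Population
        # Pearson correlation is exactly 0 while the dependence is total.
        u = sd * rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=n)
        t = u + eta[l]
        var_t = sd**2 * (1.0 + dispersion / max(sd**2, 1e-12))
        q = t**2 - np.mean(t**2)
        q = q / max(np.std(q), 1e-12) * np.sqrt(var_t)
        a[l] = alpha[l] + t
        a[m] = alpha[m] + q
    A = np.rint(np.exp(a)).astype(np.int64)
    s = rng.uniform(*LOG_FRACTION_RANGE, size=n)
    c = rng.uniform(*LOG_EFFICIENCY_RANGE, size=d)
    sigma_e2 = NOISE_FRACTION * SIGMA0_JJ
    O = _observe(A, s, c, sigma_e2, rng)

    table = CountTable(
        counts=O,
        taxon_ids=[f"T{j + 1}" for j in range(d)],
        sample_ids=[f"S{i + 1}" for i in range(n)],
    )
    truth = SimulationTruth(
        a=a, R0=R0, Sigma0=Sigma0, support=support, alpha_mean=alpha,
        s=s, c=c, sigma_e2=sigma_e2, dispersion=dispersion, seed=seed,
    )
    return table, truth


def simulate_two_ecosystems(
    n: int,
    d: int,
    dispersion: float = 0.5,
    n_cross_pairs: int | None = None,
    rho: float = DEFAULT_RHO,
    seed: int | None = 0,
) -> tuple[CountTable, SimulationTruth]:
    """Two-ecosystem scenario: matched taxa correlated across ecosystems.

    Each of ``n`` subjects contributes one sample per ecosystem. Taxon j of
    ecosystem A is correlated at ``rho`` with taxon j of ecosystem B for
    j ≤ n_cross_pairs; everything else is independent within and between
    ecosystems. Sampling fractions and efficiencies are drawn independently
    per ecosystem. The truth matrices are 2d x 2d with ecosystem-A features
    first.
    """
    if n_cross_pairs is None:
        n_cross_pairs = min(50, d)
    if n_cross_pairs < 0 or n_cross_pairs > d:
        raise SimulationError(f"n_cross_pairs must lie in [0, {d}]")
    if n < 2 or d < 1:
        raise SimulationError(f"invalid dimensions n={n}, d={d}")
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(*LOG_MEAN_RANGE, size=2 * d)
    R0 = np.eye(2 * d)
    support = np.zeros((2 * d, 2 * d), dtype=bool)
    for j in range(n_cross_pairs):
        R0[j, d + j] = R0[d + j, j] = rho
        support[j, d + j] = support[d + j, j] = True
    Sigma0 = SIGMA0_JJ * R0

    sd = np.sqrt(SIGMA0_JJ)
    z = rng.standard_normal((2 * d, n))
    latent = z.copy()
    for j in range(n_cross_pairs):
        latent[d + j] = rho * z[j] + np.sqrt(1.0 - rho**2) * z[d + j]
    a = alpha[:, None] + sd * latent

    sigma_e2 = NOISE_FRACTION * SIGMA0_JJ
    blocks, s_all, c_all = [], [], []
    for block in (a[:d], a[d:]):
        A = _nb_counts(np.exp(block), dispersion, rng)
        s = rng.uniform(*LOG_FRACTION_RANGE, size=n)
        c = rng.uniform(*LOG_EFFICIENCY_RANGE, size=d)
        blocks.append(_observe(A, s, c, sigma_e2, rng))
        s_all.append(s)
        c_all.append(c)

    counts = np.hstack(blocks)  # d taxa x 2n samples (eco A samples first)
    subjects = [f"subj{i + 1}" for i in range(n)]
    table = CountTable(
        counts=counts,
        taxon_ids=[f"T{j + 1}" for j in range(d)],
        sample_ids=[f"A_{s}" for s in subjects] + [f"B_{s}" for s in subjects],
        ecosystem=["A"] * n + ["B"] * n,
        subject=subjects + subjects,
    )
    truth = SimulationTruth(
        a=a, R0=R0, Sigma0=Sigma0, support=support, alpha_mean=alpha,
        s=np.concatenate(s_all), c=np.concatenate(c_all),
        sigma_e2=sigma_e2, dispersion=dispersion, seed=seed,
    )
    return table, truth


def inject_zeros(
    table: CountTable,
    mode: str,
    rate: float,
    seed: int | None = 0,
    small_fraction_range: tuple[float, float] = (0.005, 0.05),
) -> CountTable:
    """Add structural or sampling zeros to a count table.

    ``structural`` zeroes a random subset of entries outright (true
    absences). ``sampling`` multiplies a random subset of samples' counts
    by small fractions and floors, so zeros concentrate in low-abundance
    taxa (abundances missed by a shallow sampling fraction).
    """
    if not 0.0 <= rate <= 0.95:
        raise SimulationError("rate must lie in [0, 0.95]")
    if rate == 0.0:
        return table
    rng = np.random.default_rng(seed)
    counts = table.counts.copy()
    if mode == "structural":
        zero = rng.random(counts.shape) < rate
        counts[zero] = 0
    elif mode == "sampling":
        cols = rng.random(table.n_samples) < rate
        frac = rng.uniform(*small_fraction_range, size=int(cols.sum()))
        counts[:, cols] = np.floor(counts[:, cols] * frac[None, :]).astype(np.int64)
    else:
        raise SimulationError(f"unknown zero mode {mode!r}")
    if (counts.sum(axis=0) == 0).any():
        raise SimulationError(
            "zero injection left at least one sample with no observed taxa; "
            "lower the rate or use a different seed"
        )
    return CountTable(
        counts=counts,
        taxon_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
        ecosystem=None if table.ecosystem is None else list(table.ecosystem),
        subject=None if table.subject is None else list(table.subject),
    )
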