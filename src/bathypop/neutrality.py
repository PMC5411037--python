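"""Neutrality/expansion tests for sequences and bottleneck tests for
microsatellites.

Sequence statistics: Tajima's D, Fu's Fs (via the Ewens sampling formula on
log-scale Stirling numbers) and Ramos-Onsins & Rozas' R2, with p-values from
neutral coalescent simulation conditioned on sample size and the observed
mean pairwise diversity.

Microsatellites: heterozygosity excess/deficiency tests against the
simulated mutation-drift-equilibrium distribution of expected
heterozygosity, per locus, combined across loci by one-tailed Wilcoxon
signed-rank tests (SMM and TPM mutation models).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import wilcoxon

from .io_formats import MISSING, GenotypeDataset, HaplotypeDataset
from .sim_engine import (
    neutral_haploid_sites,
    neutral_haploid_sites_batch,
    simulate_msat_locus,
    simulate_msat_locus_batch,
)

__all__ = [
    "tajimas_d",
    "fus_fs",
    "rozas_r2",
    "neutrality_pvalues",
    "bottleneck_test",
    "NeutralityResult",
    "BottleneckResult",
    "FS_SIGNIFICANCE_LEVEL",
]

# conventional significance threshold for Fu's Fs (its null rejection region
# at nominal 5% sits near the 2% tail)
FS_SIGNIFICANCE_LEVEL = 0.02


# ----------------------------------------------------------------------
# raw statistics, computable from an alignment or a 0/1 site matrix
# ----------------------------------------------------------------------


def _site_matrix(alignment: HaplotypeDataset) -> np.ndarray:
    """Variable sites as a small integer matrix (ambiguous bases excluded)."""
    seqs = alignment.sequences
    ok = (~np.isin(seqs, [b"N", b"-"])).all(axis=0)
    sub = seqs[:, ok]
    variable = (sub != sub[0]).any(axis=0)
    sub = sub[:, variable]
    if sub.shape[1] == 0:
        return np.zeros((seqs.shape[0], 0), dtype=int)
    cols = [np.unique(sub[:, j], return_inverse=True)[1] for j in range(sub.shape[1])]
    return np.column_stack(cols)


def _pairwise_mean_diffs(sites: np.ndarray) -> float:
    n = sites.shape[0]
    total = 0.0
    for j in range(sites.shape[1]):
        _, counts = np.unique(sites[:, j], return_counts=True)
        total += (n * n - np.sum(counts.astype(float) ** 2)) / 2.0
    return total / (n * (n - 1) / 2.0)


def _as_sites(data) -> np.ndarray:
    if isinstance(data, HaplotypeDataset):
        return _site_matrix(data)
    return np.asarray(data)


def tajimas_d(data: HaplotypeDataset | np.ndarray) -> float:
    """Tajima's D from an alignment (or a precomputed site matrix).

    ``D = (k - S/a1) / sqrt(e1*S + e2*S*(S-1))`` with the standard constants
    derived from harmonic sums of the sample size. Undefined when S = 0.
    """
    sites = _as_sites(data)
    n, S = sites.shape
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S == 0:
        raise ValueError("no segregating sites: D undefined")
    k = _pairwise_mean_diffs(sites)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log |S(n, k)| for k = 0..n (unsigned Stirling, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |S(m,k)| = |S(m-1,k-1)| + (m-1)|S(m-1,k)|
        with np.errstate(invalid="ignore"):
            shifted = np.concatenate(([-np.inf], row[:-1]))
            scaled = row + (math.log(m - 1) if m > 1 else -np.inf)
            new = np.logaddexp(shifted, scaled)
        row = new
    return tuple(row)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) under the Ewens sampling formula, k = 1..n."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_row = np.array(_log_stirling_row(n)[1:])
    ks = np.arange(1, n + 1)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    return log_row + ks * math.log(theta) - log_rising


def fus_fs(data: HaplotypeDataset | np.ndarray, k_obs: int | None = None) -> float:
    """Fu's Fs: ``ln(S'/(1-S'))`` with ``S' = P(K >= k_obs | theta = pi)``.

    K is the allele (haplotype) number under the Ewens sampling formula with
    theta set to the observed mean pairwise difference count. Stirling
    numbers are carried in log space (usable well beyond n = 60).
    """
    sites = _as_sites(data)
    n = sites.shape[0]
    if n < 3:
        raise ValueError("Fu's Fs needs n >= 3")
    theta = _pairwise_mean_diffs(sites) if sites.shape[1] else 0.0
    if k_obs is None:
        k_obs = np.unique(sites, axis=0).shape[0]
    if theta <= 0 or k_obs <= 1:
        raise ValueError("Fs undefined for monomorphic data")
    logp = ewens_log_pmf(n, theta)
    log_sp = logsumexp(logp[k_obs - 1 :])
    log_sp = min(log_sp, -1e-12)
    sp = math.exp(log_sp)
    return math.log(sp) - math.log1p(-sp)


def rozas_r2(data: HaplotypeDataset | np.ndarray) -> float:
    """Ramos-Onsins & Rozas' R2.

    ``R2 = sqrt(mean_i (U_i - k/2)^2) / S`` where U_i counts the singleton
    sites carried by sequence i and k is the mean pairwise difference count.
    Small values indicate a star-like genealogy (population growth).
    """
    sites = _as_sites(data)
    n, S = sites.shape
    if n < 3:
        raise ValueError("R2 needs n >= 3")
    if S == 0:
        raise ValueError("no segregating sites: R2 undefined")
    k = _pairwise_mean_diffs(sites)
    U = np.zeros(n)
    for j in range(S):
        vals, counts = np.unique(sites[:, j], return_counts=True)
        for v, c in zip(vals, counts):
            if c == 1:
                U[np.flatnonzero(sites[:, j] == v)[0]] += 1
    return float(np.sqrt(np.mean((U - k / 2.0) ** 2)) / S)


# ----------------------------------------------------------------------
# simulation p-values
# ----------------------------------------------------------------------


@dataclass
class NeutralityResult:
    D: float | None
    Fs: float | None
    R2: float | None
    p_D: float | None = None
    p_Fs: float | None = None
    p_R2: float | None = None


def neutrality_pvalues(
    alignment: HaplotypeDataset,
    reps: int = 10000,
    seed: int | None = None,
) -> NeutralityResult:
    """Lower-tail coalescent p-values for D, Fs and R2.

    Neutral constant-size coalescent samples are simulated conditioned on n
    and theta = observed mean pairwise differences; p is the fraction of
    simulated statistics <= the observed one (the conventional one-tailed
    usage for detecting expansion). Replicates where a statistic is
    undefined are dropped for that statistic.
    """
    if reps < 1000:
        warnings.warn("fewer than 1000 replicates: p-values are coarse")
    sites = _site_matrix(alignment)
    n = alignment.n_sequences
    if sites.shape[1] == 0:
        return NeutralityResult(None, None, None)
    theta = _pairwise_mean_diffs(sites)
    obs = NeutralityResult(
        D=tajimas_d(sites) if n >= 4 else None,
        Fs=_safe(fus_fs, sites),
        R2=_safe(rozas_r2, sites),
    )
    rng = np.random.default_rng(seed)
    hits = {"D": 0, "Fs": 0, "R2": 0}
    tot = {"D": 0, "Fs": 0, "R2": 0}
    for sim in neutral_haploid_sites_batch(n, theta, rng, reps):
        for name, func, ob in (
            ("D", tajimas_d, obs.D),
            ("Fs", fus_fs, obs.Fs),
            ("R2", rozas_r2, obs.R2),
        ):
            if ob is None:
                continue
            try:
                val = func(sim)
            except ValueError:
                continue
            tot[name] += 1
            if val <= ob + 1e-12:
                hits[name] += 1
    obs.p_D = _tail(hits["D"], tot["D"])
    obs.p_Fs = _tail(hits["Fs"], tot["Fs"])
    obs.p_R2 = _tail(hits["R2"], tot["R2"])
    return obs


def _safe(func, sites):
    try:
        return func(sites)
    except ValueError:
        return None


def _tail(h: int, t: int) -> float | None:
    return (h + 1) / (t + 1) if t > 0 else None


# ----------------------------------------------------------------------
# bottleneck heterozygosity tests
# ----------------------------------------------------------------------


@dataclass
class BottleneckResult:
    """Per-locus observed vs simulated-equilibrium heterozygosity."""

    table: pd.DataFrame  # locus, k, n_genes, he_obs, he_mean, he_sd, d
    p_excess: float
    p_deficiency: float
    model: str


def _unbiased_he(genes: np.ndarray) -> float:
    m = genes.size
    _, counts = np.unique(genes, return_counts=True)
    p = counts / m
    return (m / (m - 1)) * (1.0 - float(np.sum(p**2)))


def _expected_allele_count(
    n: int,
    theta: float,
    rng: np.random.Generator,
    reps: int,
    p_single_step: float,
    multistep_variance: float,
) -> float:
    ks = [
        np.unique(g).size
        for g in simulate_msat_locus_batch(
            n, theta, rng, reps, p_single_step, multistep_variance
        )
    ]
    return float(np.mean(ks))


_THETA_CACHE: dict[tuple, float] = {}


def _calibrate_theta(
    n: int,
    k_target: int,
    p_single_step: float,
    multistep_variance: float,
    reps: int = 80,
    iters: int = 10,
) -> float:
    """Bisection on log-theta so the simulated mean allele count matches k.

    Deterministic (internally seeded) and cached per (n, k, model), so loci
    and replicates with the same configuration share one calibration.
    """
    key = (n, k_target, round(p_single_step, 6), round(multistep_variance, 6))
    if key in _THETA_CACHE:
        return _THETA_CACHE[key]
    rng = np.random.default_rng(abs(hash(key)) % (2**31))
    lo, hi = 1e-3, 200.0
    for _ in range(iters):
        mid = math.sqrt(lo * hi)
        ek = _expected_allele_count(
            n, mid, rng, reps, p_single_step, multistep_variance
        )
        if ek < k_target:
            lo = mid
        else:
            hi = mid
    theta = math.sqrt(lo * hi)
    _THETA_CACHE[key] = theta
    return theta


def bottleneck_test(
    dataset: GenotypeDataset,
    population: str | None = None,
    model: str = "SMM",
    p_smm: float = 0.8,
    variance: float = 20.0,
    iterations: int = 1000,
    seed: int | None = None,
) -> BottleneckResult:
    """Heterozygosity excess/deficiency test against SMM/TPM equilibrium.

    For each polymorphic locus the equilibrium distribution of unbiased
    expected heterozygosity is simulated by the coalescent at a theta
    calibrated (bisection) so the expected allele count matches the
    observed one given the scored gene count. Wilcoxon signed-rank tests on
    the standardized differences give one-tailed p-values for excess (a
    bottleneck signal) and deficiency (an expansion signal).
    """
    if model == "SMM":
        p_single, var = 1.0, 0.0
    elif model == "TPM":
        if not (0.0 < p_smm <= 1.0):
            raise ValueError("p_smm must be in (0, 1]")
        p_single, var = p_smm, variance
    else:
        raise ValueError("model must be 'SMM' or 'TPM'")
    rng = np.random.default_rng(seed)
    idx = (
        np.arange(dataset.n_individuals)
        if population is None
        else dataset.indices_of(population)
    )
    rows = []
    for l, locus in enumerate(dataset.loci):
        calls = dataset.calls[idx, l, :]
        genes = calls[(calls != MISSING).all(axis=1)].ravel()
        if genes.size < 10:
            warnings.warn(f"locus {locus!r}: fewer than 10 genes, skipped")
            continue
        k = np.unique(genes).size
        if k < 2:
            continue
        he_obs = _unbiased_he(genes)
        theta = _calibrate_theta(genes.size, k, p_single, var)
        sims = np.array(
            [
                _unbiased_he(g)
                for g in simulate_msat_locus_batch(
                    genes.size, theta, rng, iterations, p_single, var
                )
            ]
        )
        sd = float(sims.std(ddof=1))
        rows.append(
            {
                "locus": locus,
                "k": k,
                "n_genes": int(genes.size),
                "he_obs": he_obs,
                "he_mean": float(sims.mean()),
                "he_sd": sd,
                "d": (he_obs - float(sims.mean())) / sd if sd > 0 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 4:
        raise ValueError("Wilcoxon test needs >= 4 polymorphic loci")
    diffs = table["d"].to_numpy()
    p_exc = float(wilcoxon(diffs, alternative="greater").pvalue)
    p_def = float(wilcoxon(diffs, alternative="less").pvalue)
    return BottleneckResult(table, p_exc, p_def, model)
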