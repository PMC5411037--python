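"""Power of a sampling design to detect a target level of differentiation.

Follows the drift-simulation design: every locality's allele frequencies
drift independently from common base frequencies for t generations in a
population of effective size Ne (multinomial resampling of 2Ne genes per
generation), genotype samples of the empirical sizes are drawn, and a
global test for allele-frequency heterogeneity is applied. The fraction of
replicates significant at alpha estimates the power at the expected
divergence ``FST = 1 - (1 - 1/(2Ne))^t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, combine_pvalues

__all__ = [
    "PowerDesign",
    "powsim_power",
    "expected_fst",
    "generations_for_fst",
]


def expected_fst(ne: int, t: int) -> float:
    """Expected FST after t generations of pure drift at size Ne (diploid)."""
    return 1.0 - (1.0 - 1.0 / (2.0 * ne)) ** t


def generations_for_fst(ne: int, target_fst: float) -> int:
    """Drift generations needed to reach a target expected FST (rounded)."""
    if not (0.0 <= target_fst < 1.0):
        raise ValueError("target FST must be in [0, 1)")
    if target_fst == 0.0:
        return 0
    return round(math.log(1.0 - target_fst) / math.log(1.0 - 1.0 / (2.0 * ne)))


@dataclass
class PowerDesign:
    """Base frequencies, drift schedule and sampling scheme."""

    base_frequencies: list[np.ndarray]  # per locus, frequencies summing to 1
    ne: int
    t: int
    sample_sizes: list[int]  # diploids per locality
    alpha: float = 0.05
    replicates: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        self.base_frequencies = [np.asarray(f, dtype=float) for f in self.base_frequencies]
        for f in self.base_frequencies:
            if abs(f.sum() - 1.0) > 1e-8:
                raise ValueError("base frequencies must sum to 1")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")

    @property
    def expected_fst(self) -> float:
        return expected_fst(self.ne, self.t)


def _drift(freqs: np.ndarray, ne: int, t: int, rng: np.random.Generator) -> np.ndarray:
    f = freqs.copy()
    for _ in range(t):
        f = rng.multinomial(2 * ne, f) / (2.0 * ne)
    return f


def _g_stat(table: np.ndarray) -> float:
    keep = table.sum(axis=0) > 0
    table = table[:, keep].astype(float)
    if table.shape[1] < 2:
        return 0.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return 2.0 * float(terms.sum())


def _locus_pvalue_permutation(
    counts: np.ndarray, rng: np.random.Generator, permutations: int
) -> float:
    """Permutation p for a localities x alleles gene-count table."""
    obs = _g_stat(counts)
    sizes = counts.sum(axis=1).astype(int)
    pool = np.repeat(np.arange(counts.shape[1]), counts.sum(axis=0).astype(int))
    hits = 0
    k = counts.shape[1]
    bounds = np.cumsum(sizes)[:-1]
    for _ in range(permutations):
        rng.shuffle(pool)
        tab = np.array(
            [np.bincount(chunk, minlength=k) for chunk in np.split(pool, bounds)]
        )
        if _g_stat(tab) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (permutations + 1)


def _locus_pvalue_chi2(counts: np.ndarray) -> float:
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    if counts.shape[1] < 2:
        return 1.0
    g = _g_stat(counts)
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return float(chi2.sf(g, df))


def powsim_power(
    design: PowerDesign,
    test: str = "fisher",
    permutations: int = 199,
) -> tuple[float, float, float]:
    """Estimate power and the realized mean FST of the drift design.

    ``test="fisher"`` combines per-locus permutation G-test p-values by
    Fisher's method; ``test="chi2"`` uses the asymptotic G-test instead
    (faster, adequate at the gene counts used here). Returns
    (power, binomial SE, mean realized FST across replicates computed from
    the drifted sampled allele counts).
    """
    if test not in ("fisher", "chi2"):
        raise ValueError("test must be 'fisher' or 'chi2'")
    rng = np.random.default_rng(design.seed)
    n_loc = len(design.sample_sizes)
    sig = 0
    fst_vals = []
    for _ in range(design.replicates):
        pvals = []
        a_sum = ab_sum = 0.0
        for base in design.base_frequencies:
            # independent drift per locality
            freqs = [_drift(base, design.ne, design.t, rng) for _ in range(n_loc)]
            counts = np.array(
                [
                    rng.multinomial(2 * s, f)
                    for s, f in zip(design.sample_sizes, freqs)
                ]
            )
            if np.count_nonzero(counts.sum(axis=0)) < 2:
                continue  # allele lost everywhere: locus uninformative
            if test == "chi2":
                pvals.append(_locus_pvalue_chi2(counts))
            else:
                pvals.append(_locus_pvalue_permutation(counts, rng, permutations))
            a, ab = _fst_components_haploid(counts)
            a_sum += a
            ab_sum += ab
        if not pvals:
            continue
        _, p_global = combine_pvalues(pvals, method="fisher")
        if p_global < design.alpha:
            sig += 1
        if ab_sum > 0:
            fst_vals.append(a_sum / ab_sum)
    power = sig / design.replicates
    se = math.sqrt(power * (1.0 - power) / design.replicates)
    return power, se, float(np.mean(fst_vals)) if fst_vals else float("nan")


def _fst_components_haploid(counts: np.ndarray) -> tuple[float, float]:
    """Weir-Cockerham-style variance components from gene-count tables
    (haploid formulation, adequate for drifted gene frequencies)."""
    ns = counts.sum(axis=1).astype(float)
    r = ns.size
    nbar = ns.mean()
    nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    a_sum = b_sum = 0.0
    total = counts.sum(axis=0)
    for j in np.flatnonzero(total > 0):
        p_i = counts[:, j] / ns
        pbar = float(np.sum(ns * p_i) / (r * nbar))
        s2 = float(np.sum(ns * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
        a_sum += a
        b_sum += b
    return a_sum, a_sum + b_sum
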