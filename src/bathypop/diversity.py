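"""Per-locus and per-population diversity statistics.

Microsatellites: observed heterozygosity (HO), Nei's unbiased expected
heterozygosity (HE), total gene diversity (HT), rarefied allelic richness
(Rs), Weir & Cockerham's within-population inbreeding coefficient (FIS) and
exact Hardy-Weinberg tests. mtDNA: haplotype number/diversity, nucleotide
diversity and segregating-site summaries.

All internal arithmetic is carried at full precision; rounding to the
3-decimal reporting convention happens only in the reporting helpers.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeDataset, HaplotypeDataset

__all__ = [
    "heterozygosity",
    "total_gene_diversity",
    "allelic_richness",
    "fis",
    "hwe_exact_test",
    "haplotype_diversity",
    "nucleotide_diversity",
    "segregating_sites",
    "diversity_table",
]

TRANSITIONS = {frozenset(b"AG"), frozenset(b"CT")}


# ----------------------------------------------------------------------
# microsatellites
# ----------------------------------------------------------------------


def _cell_counts(dataset: GenotypeDataset, locus: int, population: str | None):
    rows = (
        dataset.calls[:, locus, :]
        if population is None
        else dataset.calls[dataset.indices_of(population), locus, :]
    )
    scored = rows[(rows != MISSING).all(axis=1)]
    return scored


def heterozygosity(
    dataset: GenotypeDataset, population: str | None = None
) -> pd.DataFrame:
    """HO and unbiased HE per locus for one population (or the total sample).

    HO is the fraction of heterozygous individuals among scored ones; HE is
    Nei's unbiased estimator ``(2n/(2n-1)) * (1 - sum p_k^2)`` with n scored
    diploids. Cells with no scored individual are returned as NaN, not zero.
    """
    rows = []
    for l, locus in enumerate(dataset.loci):
        scored = _cell_counts(dataset, l, population)
        n = scored.shape[0]
        if n == 0:
            rows.append((locus, np.nan, np.nan, 0, 0))
            continue
        ho = float(np.mean(scored[:, 0] != scored[:, 1]))
        genes = scored.ravel()
        _, counts = np.unique(genes, return_counts=True)
        p = counts / genes.size
        he = 0.0
        if genes.size > 1:
            he = (genes.size / (genes.size - 1)) * (1.0 - float(np.sum(p**2)))
        rows.append((locus, ho, he, len(counts), n))
    return pd.DataFrame(rows, columns=["locus", "HO", "HE", "A", "n"]).set_index("locus")


def total_gene_diversity(dataset: GenotypeDataset) -> pd.Series:
    """Nei's total gene diversity HT per locus from pooled allele frequencies.

    Pooling weights every scored gene copy equally (i.e. populations weighted
    by sample size), with the unbiased small-sample correction.
    """
    het = heterozygosity(dataset, population=None)
    return het["HE"].rename("HT")


def allelic_richness(
    dataset: GenotypeDataset, g: int, population: str | None = None
) -> pd.Series:
    """Rarefied allelic richness per locus at gene count ``g``.

    ``Rs = sum_a [1 - C(N - N_a, g) / C(N, g)]`` over alleles with count
    ``N_a`` among ``N`` scored genes: the expected number of distinct alleles
    in a random subsample of ``g`` genes.
    """
    if g < 1:
        raise ValueError("rarefaction gene count must be >= 1")
    out = {}
    for l, locus in enumerate(dataset.loci):
        scored = _cell_counts(dataset, l, population)
        genes = scored.ravel()
        N = genes.size
        if N < g:
            raise ValueError(
                f"rarefaction count g={g} exceeds {N} scored genes at locus "
                f"{locus!r}" + (f" in {population!r}" if population else "")
            )
        _, counts = np.unique(genes, return_counts=True)
        # log-space hypergeometric tail for numerical stability
        rs = 0.0
        for na in counts:
            if N - na < g:
                rs += 1.0
            else:
                logp = (
                    gammaln(N - na + 1)
                    - gammaln(g + 1)
                    - gammaln(N - na - g + 1)
                    - (gammaln(N + 1) - gammaln(g + 1) - gammaln(N - g + 1))
                )
                rs += 1.0 - math.exp(logp)
        out[locus] = rs
    return pd.Series(out, name="Rs")


def _fis_components(scored: np.ndarray) -> tuple[float, float]:
    """Weir & Cockerham within-population variance components (b+c, c).

    For a single sample: per allele A with frequency p and observed
    heterozygote frequency h involving A,
    ``b = n/(n-1) * [p(1-p) - (2n-1)/(4n) h]`` and ``c = h/2``.
    Returns sums over alleles of (b + c, c).
    """
    n = scored.shape[0]
    if n < 2:
        return (np.nan, np.nan)
    genes = scored.ravel()
    alleles = np.unique(genes)
    bc = c_sum = 0.0
    for a in alleles:
        p = float(np.mean(genes == a))
        h = float(np.mean((scored[:, 0] == a) ^ (scored[:, 1] == a)))
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2.0
        bc += b + c
        c_sum += c
    return bc, c_sum


def fis(dataset: GenotypeDataset, population: str) -> pd.Series:
    """Weir & Cockerham's within-population f per locus plus multilocus.

    The multilocus value sums the variance components across loci before
    taking the ratio, the same weighting as the multilocus theta estimator.
    Loci monomorphic in the unit are undefined (NaN).
    """
    per_locus = {}
    tot_bc = tot_c = 0.0
    for l, locus in enumerate(dataset.loci):
        scored = _cell_counts(dataset, l, population)
        if scored.shape[0] < 2 or np.unique(scored).size < 2:
            per_locus[locus] = np.nan
            continue
        bc, c = _fis_components(scored)
        per_locus[locus] = 1.0 - c / bc if bc > 0 else np.nan
        tot_bc += bc
        tot_c += c
    per_locus["multilocus"] = 1.0 - tot_c / tot_bc if tot_bc > 0 else np.nan
    return pd.Series(per_locus, name="FIS")


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------


def _log_table_prob(het_matrix: np.ndarray, n: int, allele_counts: np.ndarray) -> float:
    """Log conditional probability of a genotype table given allele counts.

    Levene's distribution: P = n! * prod(m_a!) * 2^H / ((2n)! * prod(n_gg!)).
    ``het_matrix`` is the symmetric genotype count matrix (diagonal =
    homozygote counts, off-diagonal upper triangle = heterozygote counts).
    """
    k = het_matrix.shape[0]
    H = 0
    log_geno_fact = 0.0
    for i in range(k):
        log_geno_fact += gammaln(het_matrix[i, i] + 1)
        for j in range(i + 1, k):
            H += het_matrix[i, j]
            log_geno_fact += gammaln(het_matrix[i, j] + 1)
    return (
        gammaln(n + 1)
        + float(np.sum(gammaln(allele_counts + 1)))
        + H * math.log(2.0)
        - gammaln(2 * n + 1)
        - log_geno_fact
    )


def _genotype_matrix(scored: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    k = alleles.size
    index = {a: i for i, a in enumerate(alleles.tolist())}
    mat = np.zeros((k, k), dtype=int)
    for a, b in scored:
        i, j = sorted((index[a], index[b]))
        mat[i, j] += 1
    return mat


def _enumerate_tables_biallelic(allele_counts: np.ndarray):
    n1, n2 = int(allele_counts[0]), int(allele_counts[1])
    n = (n1 + n2) // 2
    hmin = n1 % 2
    for h in range(hmin, min(n1, n2) + 1, 2):
        mat = np.zeros((2, 2), dtype=int)
        mat[0, 1] = h
        mat[0, 0] = (n1 - h) // 2
        mat[1, 1] = (n2 - h) // 2
        yield mat, n


def hwe_exact_test(
    dataset: GenotypeDataset,
    population: str,
    locus: int,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> float:
    """Two-sided exact Hardy-Weinberg probability test for one cell.

    Sums the conditional (Levene) probabilities of all genotype tables with
    the same allele counts whose probability does not exceed the observed
    table's. Complete enumeration for two alleles; seeded Monte Carlo
    (default 1e5 draws) otherwise. Monomorphic cells return p = 1.
    """
    scored = _cell_counts(dataset, locus, population)
    if scored.shape[0] == 0:
        return float("nan")
    genes = scored.ravel()
    alleles, counts = np.unique(genes, return_counts=True)
    if alleles.size < 2:
        return 1.0
    n = scored.shape[0]
    obs = _genotype_matrix(scored, alleles)
    logp_obs = _log_table_prob(obs, n, counts)
    tol = 1e-12
    if alleles.size == 2:
        total = 0.0
        for mat, nn in _enumerate_tables_biallelic(counts):
            lp = _log_table_prob(mat, nn, counts)
            if lp <= logp_obs + tol:
                total += math.exp(lp)
        return min(total, 1.0)
    # Monte Carlo: shuffle the gene pool into diploid pairs
    rng = np.random.default_rng(seed)
    index = {a: i for i, a in enumerate(alleles.tolist())}
    pool = np.array([index[g] for g in genes.tolist()])
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        pairs = pool.reshape(n, 2)
        mat = np.zeros((alleles.size, alleles.size), dtype=int)
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        np.add.at(mat, (lo, hi), 1)
        if _log_table_prob(mat, n, counts) <= logp_obs + tol:
            hits += 1
    return (hits + 1) / (n_mc + 1)


# ----------------------------------------------------------------------
# mtDNA
# ----------------------------------------------------------------------


def haplotype_diversity(counts, n: int | None = None) -> float:
    """Unbiased haplotype diversity ``(n/(n-1)) * (1 - sum (c_i/n)^2)``."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    total = float(counts.sum())
    if n is None:
        n = int(total)
    elif n != total:
        raise ValueError("counts do not sum to n")
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = counts / n
    return (n / (n - 1)) * (1.0 - float(np.sum(p**2)))


def _pairwise_diff_counts(seqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair differing and comparable site counts with pairwise deletion.

    Sites holding N or '-' in either member of a pair are excluded for that
    pair only.
    """
    n = seqs.shape[0]
    valid = ~np.isin(seqs, [b"N", b"-"])
    diffs = np.zeros((n, n))
    comps = np.zeros((n, n))
    for i in range(n):
        ok = valid[i] & valid[i + 1 :]
        diffs[i, i + 1 :] = np.sum((seqs[i] != seqs[i + 1 :]) & ok, axis=1)
        comps[i, i + 1 :] = ok.sum(axis=1)
    return diffs + diffs.T, comps + comps.T


def nucleotide_diversity(alignment: HaplotypeDataset) -> float:
    """Mean pairwise proportion of differing sites over all sequence pairs."""
    if alignment.n_sequences < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    diffs, comps = _pairwise_diff_counts(alignment.sequences)
    iu = np.triu_indices(alignment.n_sequences, k=1)
    d, c = diffs[iu], comps[iu]
    if np.all(c == 0):
        raise ValueError("all sequence pairs fully ambiguous")
    with np.errstate(invalid="ignore"):
        props = np.where(c > 0, d / np.maximum(c, 1), np.nan)
    return float(np.nanmean(props))


@dataclass
class SiteSummary:
    S: int
    transitions: int
    transversions: int
    n_haplotypes: int


def segregating_sites(alignment: HaplotypeDataset) -> SiteSummary:
    """Count variable sites and classify biallelic ones as ts/tv.

    Ambiguity codes (N, -) are ignored when assessing variability; sites
    with three or more observed bases count toward S but are left out of the
    transition/transversion tally with a warning.
    """
    if alignment.n_sequences < 2:
        raise ValueError("need >= 2 sequences")
    seqs = alignment.sequences
    S = ts = tv = 0
    multi = 0
    for j in range(seqs.shape[1]):
        col = seqs[:, j]
        col = col[~np.isin(col, [b"N", b"-"])]
        states = set(np.unique(col).tolist())
        if len(states) < 2:
            continue
        S += 1
        if len(states) == 2:
            if frozenset(b"".join(sorted(states))) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
        else:
            multi += 1
    if multi:
        warnings.warn(f"{multi} site(s) with >2 states excluded from ts/tv tally")
    _, _, counts = alignment.haplotype_table()
    return SiteSummary(S, ts, tv, len(counts))


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------


def diversity_table(
    genotypes: GenotypeDataset | None = None,
    sequences: HaplotypeDataset | None = None,
    rarefaction_genes: int | None = None,
    decimals: int = 3,
) -> pd.DataFrame:
    """Per-population summary table mirroring the study's layout.

    Microsatellite columns: n, mean HO, mean HE, multilocus FIS, mean allele
    number A, mean rarefied richness Rs. mtDNA columns: N, Hn, Hd, pi.
    """
    pops = (genotypes or sequences).populations
    rows = []
    for pop in pops:
        row: dict[str, float | int | str] = {"population": pop}
        if genotypes is not None:
            het = heterozygosity(genotypes, pop)
            row["n_msat"] = int(genotypes.indices_of(pop).size)
            row["HO"] = round(float(het["HO"].mean()), decimals)
            row["HE"] = round(float(het["HE"].mean()), decimals)
            row["FIS"] = round(float(fis(genotypes, pop)["multilocus"]), decimals)
            row["A"] = round(float(het["A"].mean()), decimals)
            if rarefaction_genes is not None:
                row["Rs"] = round(
                    float(allelic_richness(genotypes, rarefaction_genes, pop).mean()),
                    decimals,
                )
        if sequences is not None and pop in sequences.populations:
            sub = sequences.subset(sequences.indices_of(pop))
            _, _, counts = sub.haplotype_table()
            row["N_mtdna"] = sub.n_sequences
            row["Hn"] = len(counts)
            row["Hd"] = (
                round(haplotype_diversity(counts), decimals)
                if sub.n_sequences >= 2
                else float("nan")
            )
            row["pi"] = (
                round(nucleotide_diversity(sub), 4) if sub.n_sequences >= 2 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("population")
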