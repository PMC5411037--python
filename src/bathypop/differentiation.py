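"""Differentiation statistics and spatial-structure machinery.

Implements Weir & Cockerham's theta for microsatellites, Phi-ST via AMOVA on
pairwise sequence differences, Jost's D_est, permutation significance with
Benjamini-Hochberg FDR control, hierarchical (three-level) AMOVA and the
grouping search, Mantel isolation-by-distance, PCA on frequency tables, and
mean between-group p-distances.

Significance everywhere is by seeded label permutation (the same
exchangeable null the classical exact/Markov-chain machinery targets).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    MISSING,
    GenotypeDataset,
    HaplotypeDataset,
    SampleGrouping,
    validate_grouping,
)

__all__ = [
    "fst_weir_cockerham",
    "phi_st",
    "jost_dest",
    "jost_dest_from_data",
    "pairwise_matrix",
    "g_test_allelic",
    "amova",
    "grouping_search",
    "mantel_ibd",
    "frequency_pca",
    "group_p_distance",
    "PairwiseStatMatrix",
    "AmovaResult",
    "IbdResult",
]


# ----------------------------------------------------------------------
# Weir & Cockerham theta
# ----------------------------------------------------------------------


def _wc_components_locus(dataset: GenotypeDataset, locus: int, units: list[str]):
    """Per-locus sums of the Weir-Cockerham variance components a, b, c."""
    ns, ps, hs, pools = [], [], [], []
    for u in units:
        rows = dataset.calls[dataset.indices_of(u), locus, :]
        scored = rows[(rows != MISSING).all(axis=1)]
        if scored.shape[0] >= 1:
            ns.append(scored.shape[0])
            pools.append(scored)
    r = len(ns)
    if r < 2:
        return 0.0, 0.0, 0.0
    ns = np.asarray(ns, dtype=float)
    alleles = np.unique(np.concatenate([s.ravel() for s in pools]))
    if alleles.size < 2:
        return 0.0, 0.0, 0.0
    nbar = ns.mean()
    nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = np.array([np.mean(s.ravel() == al) for s in pools])
        h_i = np.array([np.mean((s[:, 0] == al) ^ (s[:, 1] == al)) for s in pools])
        pbar = float(np.sum(ns * p_i) / (r * nbar))
        s2 = float(np.sum(ns * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(ns * h_i) / (r * nbar))
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def fst_weir_cockerham(
    dataset: GenotypeDataset, units: list[str] | None = None
) -> pd.Series:
    """Weir & Cockerham's theta per locus and multilocus.

    The multilocus estimate sums the a, b, c variance components across loci
    before taking the ratio a/(a+b+c). Loci monomorphic across all units
    contribute zero components and are excluded from the ratio. Negative
    estimates are reported as computed.
    """
    units = units if units is not None else dataset.populations
    if len(units) < 2:
        raise ValueError("need >= 2 units")
    per_locus = {}
    A = B = C = 0.0
    for l, locus in enumerate(dataset.loci):
        a, b, c = _wc_components_locus(dataset, l, units)
        denom = a + b + c
        per_locus[locus] = a / denom if denom != 0 else np.nan
        A += a
        B += b
        C += c
    per_locus["multilocus"] = A / (A + B + C) if (A + B + C) != 0 else np.nan
    return pd.Series(per_locus, name="theta")


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------


def sequence_difference_matrix(alignment: HaplotypeDataset) -> np.ndarray:
    """Pairwise nucleotide difference counts (pairwise deletion of N/-)."""
    from .diversity import _pairwise_diff_counts

    diffs, _ = _pairwise_diff_counts(alignment.sequences)
    return diffs


def genotype_difference_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """Allele non-identity distance between diploid multilocus genotypes.

    Per locus the distance between genotypes is 2 minus the size of the
    maximum allele matching (0 for identical genotypes, 1 for one shared
    allele copy, 2 for none); summed over loci scored in both individuals.
    """
    calls = dataset.calls
    n, L, _ = calls.shape
    s = np.sort(calls, axis=2)
    a1, a2 = s[:, :, 0], s[:, :, 1]
    D = np.zeros((n, n))
    for i in range(n):
        m_i = (a1[i] != MISSING)
        for j in range(i + 1, n):
            ok = m_i & (a1[j] != MISSING)
            x1, x2, y1, y2 = a1[i][ok], a2[i][ok], a1[j][ok], a2[j][ok]
            # shared copies under the best matching of two unordered pairs
            both = (x1 == y1) & (x2 == y2)
            cross = (x1 == y2) & (x2 == y1)
            two = both | cross
            one = (
                (x1 == y1) | (x1 == y2) | (x2 == y1) | (x2 == y2)
            ) & ~two
            d = 2.0 * np.sum(~(two | one)) + 1.0 * np.sum(one)
            D[i, j] = D[j, i] = d
    return D


# ----------------------------------------------------------------------
# AMOVA
# ----------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Variance components and fixation indices of a hierarchical AMOVA."""

    sigma2_among_groups: float
    sigma2_among_pops: float
    sigma2_within: float
    f_ct: float
    f_sc: float
    f_st: float
    p_ct: float | None = None
    p_sc: float | None = None
    grouping: dict = field(default_factory=dict)

    @property
    def total_variance(self) -> float:
        return self.sigma2_among_groups + self.sigma2_among_pops + self.sigma2_within


def _ss_within(D2: np.ndarray, idx: np.ndarray) -> float:
    sub = D2[np.ix_(idx, idx)]
    return float(sub.sum()) / (2.0 * idx.size)


def _amova_components(D2: np.ndarray, pop_of: np.ndarray, grp_of: np.ndarray):
    """Three-level AMOVA variance components from a squared-distance matrix.

    ``pop_of`` and ``grp_of`` give population and group index per individual.
    Returns (sigma_a, sigma_b, sigma_c) for among-group, among-population-
    within-group and within-population levels.
    """
    N = D2.shape[0]
    pops = np.unique(pop_of)
    grps = np.unique(grp_of)
    P, G = pops.size, grps.size
    ss_total = float(D2.sum()) / (2.0 * N)
    ss_wp = 0.0
    pop_sizes = {}
    pop_group = {}
    for p in pops:
        idx = np.flatnonzero(pop_of == p)
        ss_wp += _ss_within(D2, idx)
        pop_sizes[p] = idx.size
        pop_group[p] = grp_of[idx[0]]
    ss_wg = 0.0
    grp_sizes = {}
    for g in grps:
        idx = np.flatnonzero(grp_of == g)
        ss_wg += _ss_within(D2, idx)
        grp_sizes[g] = idx.size
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    df_ag = G - 1
    df_ap = P - G
    df_wp = N - P
    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    sigma_c = ms_wp
    sum_np2_over_ng = sum(
        pop_sizes[p] ** 2 / grp_sizes[pop_group[p]] for p in pops
    )
    sum_np2 = sum(pop_sizes[p] ** 2 for p in pops)
    sum_ng2 = sum(grp_sizes[g] ** 2 for g in grps)
    if df_ap > 0:
        n_prime = (N - sum_np2_over_ng) / df_ap
        ms_ap = ss_ap / df_ap
        sigma_b = (ms_ap - sigma_c) / n_prime if n_prime > 0 else 0.0
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n_dprime = (sum_np2_over_ng - sum_np2 / N) / df_ag
        n_tprime = (N - sum_ng2 / N) / df_ag
        ms_ag = ss_ag / df_ag
        sigma_a = (ms_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c


def amova(
    data: GenotypeDataset | HaplotypeDataset,
    grouping: SampleGrouping | None = None,
    permutations: int = 0,
    seed: int | None = None,
    distance_matrix: np.ndarray | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on pairwise differences.

    With a grouping (locality -> group) the design is three-level
    (groups / populations within groups / individuals); without one it is
    two-level and F_ST equals Phi-ST. Sequence data use nucleotide
    differences; genotype data the allele non-identity distance. Components
    are reported even when negative.

    Permutation p-values: populations permuted among groups for F_CT;
    individuals permuted among populations within groups for F_SC.
    """
    pops_labels = data.localities
    if distance_matrix is None:
        if isinstance(data, HaplotypeDataset):
            distance_matrix = sequence_difference_matrix(data)
        else:
            distance_matrix = genotype_difference_matrix(data)
    D2 = np.asarray(distance_matrix, dtype=float)

    unique_pops = data.populations
    pop_index = {p: i for i, p in enumerate(unique_pops)}
    pop_of = np.array([pop_index[p] for p in pops_labels])
    user_grouping = grouping is not None
    if grouping is None:
        grouping = {p: p for p in unique_pops}
    validate_grouping(grouping, unique_pops)
    groups = sorted(set(grouping[p] for p in unique_pops))
    if user_grouping and len(groups) > 1 and any(
        sum(1 for p in unique_pops if grouping[p] == g) == 1 for g in groups
    ):
        warnings.warn("grouping contains single-population group(s)")
    grp_index = {g: i for i, g in enumerate(groups)}
    grp_of_pop = np.array([grp_index[grouping[p]] for p in unique_pops])
    grp_of = grp_of_pop[pop_of]

    three_level = len(groups) > 1 and len(unique_pops) > len(groups)
    if three_level:
        sa, sb, sc = _amova_components(D2, pop_of, grp_of)
    else:
        # two-level: "groups" are the populations themselves
        sa2, sb2, sc2 = _amova_components(D2, pop_of, pop_of)
        sa, sb, sc = 0.0, sb2 + sa2, sc2  # among-unit variance in sigma_b slot
        if len(groups) > 1:  # every pop its own group in a >1 group design
            sa, sb = sb, 0.0
    tot = sa + sb + sc
    f_ct = sa / tot if tot != 0 else np.nan
    f_sc = sb / (sb + sc) if (sb + sc) != 0 else np.nan
    f_st = (sa + sb) / tot if tot != 0 else np.nan
    res = AmovaResult(sa, sb, sc, f_ct, f_sc, f_st, grouping=dict(grouping))

    if permutations:
        rng = np.random.default_rng(seed)
        # F_CT: permute whole populations among groups
        if three_level:
            hits_ct = 0
            for _ in range(permutations):
                perm = rng.permutation(grp_of_pop)
                g2 = perm[pop_of]
                a, b, c = _amova_components(D2, pop_of, g2)
                t = a + b + c
                if t != 0 and a / t >= f_ct - 1e-12:
                    hits_ct += 1
            res.p_ct = (hits_ct + 1) / (permutations + 1)
            # F_SC: permute individuals among populations within groups
            hits_sc = 0
            for _ in range(permutations):
                pop2 = pop_of.copy()
                for g in range(len(groups)):
                    idx = np.flatnonzero(grp_of == g)
                    pop2[idx] = pop2[idx][rng.permutation(idx.size)]
                a, b, c = _amova_components(D2, pop2, grp_of)
                if (b + c) != 0 and b / (b + c) >= f_sc - 1e-12:
                    hits_sc += 1
            res.p_sc = (hits_sc + 1) / (permutations + 1)
        else:
            hits = 0
            for _ in range(permutations):
                pop2 = pop_of[rng.permutation(pop_of.size)]
                a, b, c = _amova_components(D2, pop2, pop2)
                t = a + b + c
                stat = (a + b) / t if t != 0 else -np.inf
                if stat >= f_st - 1e-12:
                    hits += 1
            res.p_sc = res.p_ct = (hits + 1) / (permutations + 1)
    return res


def phi_st(
    alignment: HaplotypeDataset,
    units: list[str] | None = None,
    permutations: int = 0,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """Phi-ST from a two-level AMOVA on pairwise nucleotide differences.

    Returns (phi_st, p) where p is a seeded permutation p-value (None when
    ``permutations`` is 0).
    """
    units = units if units is not None else alignment.populations
    if len(units) < 2:
        raise ValueError("need >= 2 units")
    keep = [i for i, p in enumerate(alignment.localities) if p in units]
    sub = alignment.subset(keep)
    for u in units:
        if np.sum(np.array(sub.localities) == u) < 2:
            raise ValueError(f"unit {u!r} has fewer than 2 sequences")
    res = amova(sub, grouping=None, permutations=permutations, seed=seed)
    return res.f_st, res.p_ct if permutations else None


def grouping_search(
    data: GenotypeDataset | HaplotypeDataset,
    candidate_groupings: list[SampleGrouping],
    permutations: int = 0,
    seed: int | None = None,
) -> list[AmovaResult]:
    """AMOVA per candidate grouping, ranked by F_CT descending.

    Ties on F_CT are broken by smaller F_SC.
    """
    if len(candidate_groupings) < 2:
        raise ValueError("need >= 2 candidate groupings")
    if isinstance(data, HaplotypeDataset):
        D2 = sequence_difference_matrix(data)
    else:
        D2 = genotype_difference_matrix(data)
    results = [
        amova(data, g, permutations=permutations, seed=seed, distance_matrix=D2)
        for g in candidate_groupings
    ]
    results.sort(key=lambda r: (-(r.f_ct if np.isfinite(r.f_ct) else -np.inf), r.f_sc))
    return results


# ----------------------------------------------------------------------
# Jost's D
# ----------------------------------------------------------------------


def jost_dest(freqs: np.ndarray, sizes: np.ndarray) -> float:
    """Jost's D_est from per-unit frequency vectors (Nei-Chesser unbiased).

    ``freqs`` is a (k units x alleles) frequency table, ``sizes`` the gene
    counts per unit. Uses the harmonic-mean sample size correction:
    ``Hs = (ntilde/(ntilde-1)) (1 - mean_u sum_a p_ua^2)``,
    ``Ht = 1 - sum_a pbar_a^2 + Hs/(k*ntilde)``, and
    ``D = (k/(k-1)) (Ht - Hs)/(1 - Hs)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    k = freqs.shape[0]
    if k < 2:
        raise ValueError("need >= 2 units")
    ntilde = k / np.sum(1.0 / sizes)
    hs = (ntilde / (ntilde - 1.0)) * (1.0 - float(np.mean(np.sum(freqs**2, axis=1))))
    pbar = freqs.mean(axis=0)
    ht = 1.0 - float(np.sum(pbar**2)) + hs / (k * ntilde)
    if 1.0 - hs == 0.0:
        raise ValueError("Hs = 1: D_est undefined")
    return (k / (k - 1.0)) * (ht - hs) / (1.0 - hs)


def _unit_freq_table(
    data: GenotypeDataset | HaplotypeDataset, units: list[str], locus: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(k x alleles) frequency table + gene counts for one locus/haplotypes."""
    if isinstance(data, HaplotypeDataset):
        pops, mat = data.haplotype_counts_by_population()
        rows = np.array([mat[:, pops.index(u)] for u in units], dtype=float)
    else:
        counts = [data.allele_counts(locus, u) for u in units]
        alleles = sorted(set().union(*[c.keys() for c in counts]))
        rows = np.array(
            [[c.get(a, 0) for a in alleles] for c in counts], dtype=float
        )
    sizes = rows.sum(axis=1)
    if np.any(sizes == 0):
        raise ValueError("unit with no scored genes")
    return rows / sizes[:, None], sizes


def jost_dest_from_data(
    data: GenotypeDataset | HaplotypeDataset, units: list[str] | None = None
) -> float:
    """D_est from a dataset: haplotype-based for sequences; for genotype data
    the arithmetic mean of per-locus estimates (per-locus values via
    :func:`jost_dest`)."""
    units = units if units is not None else data.populations
    if isinstance(data, HaplotypeDataset):
        freqs, sizes = _unit_freq_table(data, units)
        return jost_dest(freqs, sizes)
    vals = []
    for l in range(data.n_loci):
        freqs, sizes = _unit_freq_table(data, units, locus=l)
        if freqs.shape[1] < 2:
            vals.append(0.0)
            continue
        vals.append(jost_dest(freqs, sizes))
    return float(np.mean(vals))


# ----------------------------------------------------------------------
# pairwise matrices with permutation significance
# ----------------------------------------------------------------------


@dataclass
class PairwiseStatMatrix:
    """Lower-triangular pairwise statistic with permutation p-values."""

    labels: list[str]
    stat: np.ndarray  # (k, k), NaN diagonal, symmetric
    p_raw: np.ndarray
    p_fdr_significant: dict[float, np.ndarray] = field(default_factory=dict)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.stat[i, j])

    def p(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.p_raw[i, j])

    def significant(self, a: str, b: str, alpha: float) -> bool:
        i, j = self.labels.index(a), self.labels.index(b)
        return bool(self.p_fdr_significant[alpha][i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stat, index=self.labels, columns=self.labels)


def _pair_stat(data, pair, stat: str) -> float:
    if stat == "fst":
        return float(fst_weir_cockerham(data, list(pair))["multilocus"])
    if stat == "phist":
        return phi_st(data, list(pair))[0]
    if stat == "dest":
        return jost_dest_from_data(data, list(pair))
    raise ValueError(f"unknown statistic {stat!r}")


def pairwise_matrix(
    data: GenotypeDataset | HaplotypeDataset,
    stat: str,
    permutations: int = 1000,
    alpha_levels: tuple[float, ...] = (0.05, 0.01, 0.001),
    seed: int | None = None,
) -> PairwiseStatMatrix:
    """All pairwise values of a statistic with permutation + BH-FDR decisions.

    The permutation null shuffles individuals between the two units of each
    pair (seeded); BH runs over the family of all pairwise tests at each
    alpha level.
    """
    if permutations < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse")
    units = data.populations
    k = len(units)
    if k < 2:
        raise ValueError("need >= 2 units")
    rng = np.random.default_rng(seed)
    statm = np.full((k, k), np.nan)
    pm = np.full((k, k), np.nan)
    pairs = list(itertools.combinations(range(k), 2))
    seq_dist = (
        sequence_difference_matrix(data)
        if isinstance(data, HaplotypeDataset) and stat == "phist"
        else None
    )
    for i, j in pairs:
        pair = (units[i], units[j])
        idx = np.concatenate([data.indices_of(pair[0]), data.indices_of(pair[1])])
        sub = data.subset(idx)
        obs = _pair_stat(sub, pair, stat)
        statm[i, j] = statm[j, i] = obs
        n1 = data.indices_of(pair[0]).size
        pop_of = np.array([0] * n1 + [1] * (idx.size - n1))
        if stat == "phist":
            # fast path: fixed distance matrix, permute unit assignment only
            D2 = seq_dist[np.ix_(idx, idx)]

            def stat_of(assign):
                a, b, c = _amova_components(D2, assign, assign)
                t = a + b + c
                return (a + b) / t if t != 0 else -np.inf

        else:
            labels = np.array(sub.localities)

            def stat_of(assign):
                shuffled = sub.subset(np.argsort(assign, kind="stable"))
                shuffled.localities = labels.tolist()
                return _pair_stat(shuffled, pair, stat)

        if not np.isfinite(obs):
            continue  # undifferentiable pair (e.g. fully monomorphic)
        hits = 0
        for _ in range(permutations):
            val = stat_of(pop_of[rng.permutation(pop_of.size)])
            if val >= obs - 1e-12:
                hits += 1
        pm[i, j] = pm[j, i] = (hits + 1) / (permutations + 1)
    res = PairwiseStatMatrix(units, statm, pm)
    iu = np.array(pairs)
    pvals = pm[iu[:, 0], iu[:, 1]]
    ok = np.isfinite(pvals)
    for alpha in alpha_levels:
        rej = np.zeros(len(pairs), dtype=bool)
        if ok.any():
            rej[ok], *_ = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")
        sig = np.zeros((k, k), dtype=bool)
        sig[iu[:, 0], iu[:, 1]] = rej
        sig |= sig.T
        res.p_fdr_significant[alpha] = sig
    return res


# ----------------------------------------------------------------------
# G-test
# ----------------------------------------------------------------------


def _g_statistic(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = rows @ cols / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return 2.0 * float(terms.sum())


def g_test_allelic(
    dataset: GenotypeDataset,
    pair: tuple[str, str],
    permutations: int = 1000,
    seed: int | None = None,
) -> tuple[pd.Series, float]:
    """Per-locus permutation G-tests for a unit pair + Fisher-combined p.

    The G statistic is computed on the 2 x alleles count table; its null
    distribution comes from permuting individuals between the units. The
    global pair test combines per-locus p-values by Fisher's method.
    """
    rng = np.random.default_rng(seed)
    idx = np.concatenate([dataset.indices_of(pair[0]), dataset.indices_of(pair[1])])
    sub = dataset.subset(idx)
    n1 = dataset.indices_of(pair[0]).size
    labels = np.array([0] * n1 + [1] * (idx.size - n1))

    def locus_tables(lab):
        tabs = []
        for l in range(sub.n_loci):
            rows = sub.calls[:, l, :]
            ok = (rows != MISSING).all(axis=1)
            genes0 = rows[ok & (lab == 0)].ravel()
            genes1 = rows[ok & (lab == 1)].ravel()
            alleles = np.unique(np.concatenate([genes0, genes1]))
            tab = np.array(
                [
                    [np.sum(genes0 == a) for a in alleles],
                    [np.sum(genes1 == a) for a in alleles],
                ]
            )
            tabs.append(tab)
        return tabs

    obs_g = np.array([_g_statistic(t) for t in locus_tables(labels)])
    hits = np.zeros(sub.n_loci)
    for _ in range(permutations):
        perm = labels[rng.permutation(labels.size)]
        g = np.array([_g_statistic(t) for t in locus_tables(perm)])
        hits += g >= obs_g - 1e-12
    p_locus = (hits + 1) / (permutations + 1)
    from scipy.stats import combine_pvalues

    _, p_global = combine_pvalues(p_locus, method="fisher")
    return pd.Series(p_locus, index=dataset.loci, name="p"), float(p_global)


# ----------------------------------------------------------------------
# isolation by distance
# ----------------------------------------------------------------------


@dataclass
class IbdResult:
    intercept: float
    slope: float
    mantel_p: float
    mantel_r: float


def mantel_ibd(
    genetic: np.ndarray | PairwiseStatMatrix,
    geographic: np.ndarray,
    permutations: int = 10000,
    transform: str = "raw",
    seed: int | None = None,
) -> IbdResult:
    """Regress genetic on geographic distance; Mantel permutation p-value.

    ``transform="linearized"`` uses FST/(1-FST). The Mantel test permutes
    rows/columns of the genetic matrix jointly (seeded) and counts
    correlations at least as extreme (one-tailed, positive association).
    """
    G = genetic.stat.copy() if isinstance(genetic, PairwiseStatMatrix) else np.asarray(genetic, dtype=float).copy()
    X = np.asarray(geographic, dtype=float)
    if G.shape != X.shape:
        raise ValueError("matrix shapes differ")
    if transform == "linearized":
        G = G / (1.0 - G)
    elif transform != "raw":
        raise ValueError("transform must be 'raw' or 'linearized'")
    n = G.shape[0]
    iu = np.triu_indices(n, k=1)
    y, x = G[iu], X[iu]
    if np.allclose(y, y[0]):
        return IbdResult(float(y[0]), 0.0, 1.0, 0.0)
    b, a = np.polyfit(x, y, 1)
    obs_r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        r = float(np.corrcoef(x, Gp[iu])[0, 1])
        if r >= obs_r - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return IbdResult(float(a), float(b), p, obs_r)


# ----------------------------------------------------------------------
# PCA on frequency tables
# ----------------------------------------------------------------------


@dataclass
class FrequencyPcaResult:
    labels: list[str]
    coordinates: np.ndarray  # units x axes
    inertia_fractions: np.ndarray
    axis_p: np.ndarray | None = None


def _full_freq_table(data: GenotypeDataset | HaplotypeDataset) -> np.ndarray:
    units = data.populations
    if isinstance(data, HaplotypeDataset):
        freqs, _ = _unit_freq_table(data, units)
        return freqs
    blocks = []
    for l in range(data.n_loci):
        freqs, _ = _unit_freq_table(data, units, locus=l)
        blocks.append(freqs)
    return np.hstack(blocks)


def frequency_pca(
    data: GenotypeDataset | HaplotypeDataset,
    randomizations: int = 0,
    seed: int | None = None,
) -> FrequencyPcaResult:
    """Centered PCA of the unit x allele/haplotype frequency table.

    Axis significance: individuals are permuted among units (sizes kept),
    frequencies and PCA recomputed, and each axis' inertia compared with the
    observed one (upper tail, seeded).
    """
    units = data.populations
    if len(units) < 3:
        raise ValueError("need >= 3 units for a PCA")
    table = _full_freq_table(data)
    n_axes = min(len(units) - 1, table.shape[1])
    pca = PCA(n_components=n_axes)
    coords = pca.fit_transform(table)
    frac = pca.explained_variance_ratio_
    inertia = pca.explained_variance_
    res = FrequencyPcaResult(units, coords, frac)
    if randomizations:
        rng = np.random.default_rng(seed)
        labels = np.array(data.localities)
        hits = np.zeros(n_axes)
        for _ in range(randomizations):
            shuffled = data.subset(rng.permutation(labels.size))
            shuffled.localities = labels.tolist()
            t = _full_freq_table(shuffled)
            p2 = PCA(n_components=n_axes).fit(t)
            ev = np.zeros(n_axes)
            ev[: p2.explained_variance_.size] = p2.explained_variance_
            hits += ev >= inertia - 1e-15
        res.axis_p = (hits + 1) / (randomizations + 1)
    return res


# ----------------------------------------------------------------------
# group p-distance
# ----------------------------------------------------------------------


def group_p_distance(
    alignment: HaplotypeDataset,
    grouping: SampleGrouping,
    bootstraps: int = 10000,
    weighting: str = "sequences",
    seed: int | None = None,
) -> tuple[float, float]:
    """Mean between-group p-distance with a site-bootstrap standard error.

    ``weighting="sequences"`` averages over all inter-group sequence pairs;
    ``weighting="haplotypes"`` first collapses each group to its distinct
    haplotypes and averages over inter-group haplotype pairs.
    """
    validate_grouping(grouping, alignment.populations)
    groups = sorted(set(grouping.values()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    members = {
        g: [i for i, p in enumerate(alignment.localities) if grouping[p] == g]
        for g in groups
    }
    if weighting == "haplotypes":
        sub_idx = []
        for g in groups:
            sub = alignment.subset(members[g])
            haps, assignment, _ = sub.haplotype_table()
            first = [int(np.flatnonzero(assignment == h)[0]) for h in range(len(haps))]
            sub_idx.append([members[g][i] for i in first])
        members = {g: idx for g, idx in zip(groups, sub_idx)}
    elif weighting != "sequences":
        raise ValueError("weighting must be 'sequences' or 'haplotypes'")

    seqs = alignment.sequences
    valid = ~np.isin(seqs, [b"N", b"-"])
    ia = np.array(members[groups[0]])
    ib = np.array(members[groups[1]])

    def mean_p(site_idx: np.ndarray) -> float:
        s = seqs[:, site_idx]
        v = valid[:, site_idx]
        vals = []
        for i in ia:
            ok = v[i] & v[ib]
            comp = ok.sum(axis=1)
            diff = np.sum((s[i] != s[ib]) & ok, axis=1)
            good = comp > 0
            if not np.all(good):
                warnings.warn("pair(s) with no comparable sites dropped")
            vals.extend((diff[good] / comp[good]).tolist())
        return float(np.mean(vals))

    L = alignment.length
    est = mean_p(np.arange(L))
    if bootstraps < 2:
        return est, 0.0
    rng = np.random.default_rng(seed)
    boots = np.array(
        [mean_p(rng.integers(0, L, size=L)) for _ in range(bootstraps)]
    )
    return est, float(boots.std(ddof=1))
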