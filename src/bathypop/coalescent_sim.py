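"""Two-population divergence simulator for microsatellite + mtDNA samples.

Four competing demographic scenarios describe an Atlantic (ATL) and a
Mediterranean (MED) population that split from a common ancestor t
generations ago:

* scenario 1 — constant sizes N_ATL / N_MED since the split;
* scenario 2 — MED changed size after the split (size Nb_MED between the
  split and t1, N_MED since t1); ATL constant;
* scenario 3 — ATL changed size after the split; MED constant;
* scenario 4 — both changed size after the split.

Times are in generations (backwards from the present); sizes are diploid
effective sizes. The mitochondrial locus is haploid and maternally
inherited, so its effective size is one quarter of the nuclear one.
Microsatellites mutate by the stepwise model at per-locus rates drawn
around a mean rate; the mtDNA sequence follows the Kimura two-parameter
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np

from . import sim_engine
from .io_formats import GenotypeDataset, HaplotypeDataset
from .sim_engine import msprime_seed, smm_alleles_on_tree

__all__ = [
    "ScenarioSpec",
    "ParameterDraw",
    "SimulatedSample",
    "default_priors",
    "draw_prior_parameters",
    "simulate_scenario",
    "summary_statistics",
    "SUMMARY_NAMES",
    "GENERATION_TIME_YEARS",
    "generations_to_years",
]

# generation time used to convert divergence times to years
GENERATION_TIME_YEARS = 9.0


def generations_to_years(generations: float, generation_time: float = GENERATION_TIME_YEARS) -> float:
    """Convert a time in generations to years before present."""
    return generations * generation_time


def default_priors() -> dict[str, tuple[float, float]]:
    """Uniform prior bounds for the divergence scenarios."""
    return {
        "N_ATL": (10, 2_000_000),
        "N_MED": (10, 500_000),
        "t": (1, 70_000),
        "t1": (1, 20_000),
        "Nb_ATL": (1, 40_000),
        "Nb_MED": (1, 40_000),
        "mu_msat": (1.0e-6, 5.0e-4),
        "mu_mtdna": (1.0e-9, 8.0e-8),
    }


@dataclass
class ScenarioSpec:
    """Topology + priors of one divergence scenario."""

    scenario: int  # 1..4
    priors: dict[str, tuple[float, float]] = field(default_factory=default_priors)
    n_anc_prior: tuple[float, float] | None = None  # default: N_anc = N_ATL draw

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4):
            raise ValueError("scenario must be 1..4")

    @property
    def atl_changes(self) -> bool:
        return self.scenario in (3, 4)

    @property
    def med_changes(self) -> bool:
        return self.scenario in (2, 4)


@dataclass
class ParameterDraw:
    scenario: int
    N_ATL: float
    N_MED: float
    Nb_ATL: float | None
    Nb_MED: float | None
    t: float
    t1: float | None
    N_anc: float
    mu_msat_mean: float
    mu_msat_locus: np.ndarray
    mu_mtdna: float

    def as_dict(self) -> dict[str, float]:
        d = {
            "scenario": self.scenario,
            "N_ATL": self.N_ATL,
            "N_MED": self.N_MED,
            "t": self.t,
            "N_anc": self.N_anc,
            "mu_msat_mean": self.mu_msat_mean,
            "mu_mtdna": self.mu_mtdna,
        }
        if self.t1 is not None:
            d["t1"] = self.t1
        if self.Nb_ATL is not None:
            d["Nb_ATL"] = self.Nb_ATL
        if self.Nb_MED is not None:
            d["Nb_MED"] = self.Nb_MED
        return d


@dataclass
class SimulatedSample:
    genotypes: GenotypeDataset
    sequences: HaplotypeDataset


# mean rates drawn per locus around the mean with a Gamma of this shape
MSAT_RATE_GAMMA_SHAPE = 2.0


def draw_prior_parameters(
    spec: ScenarioSpec,
    n_loci: int = 9,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ParameterDraw:
    """One parameter vector from the scenario's uniform priors.

    The constraint t1 < t is enforced by redrawing t1; per-locus
    microsatellite rates are Gamma-distributed around the drawn mean rate
    (shape 2), truncated to the prior support.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    pri = spec.priors

    def u(name):
        lo, hi = pri[name]
        return float(rng.uniform(lo, hi))

    n_atl, n_med, t = u("N_ATL"), u("N_MED"), u("t")
    needs_t1 = spec.atl_changes or spec.med_changes
    t1 = None
    if needs_t1:
        lo, hi = pri["t1"]
        if lo >= t:
            raise ValueError("t1 prior lies entirely above drawn t")
        t1 = float(rng.uniform(lo, min(hi, t)))
        while not (t1 < t):  # pragma: no cover - guarded by the min() above
            t1 = float(rng.uniform(lo, hi))
    nb_atl = u("Nb_ATL") if spec.atl_changes else None
    nb_med = u("Nb_MED") if spec.med_changes else None
    if spec.n_anc_prior is not None:
        n_anc = float(rng.uniform(*spec.n_anc_prior))
    else:
        n_anc = n_atl
    mu_mean = u("mu_msat")
    lo, hi = pri["mu_msat"]
    rates = rng.gamma(
        MSAT_RATE_GAMMA_SHAPE, mu_mean / MSAT_RATE_GAMMA_SHAPE, size=n_loci
    )
    rates = np.clip(rates, lo, hi)
    return ParameterDraw(
        spec.scenario,
        n_atl,
        n_med,
        nb_atl,
        nb_med,
        t,
        t1,
        n_anc,
        mu_mean,
        rates,
        u("mu_mtdna"),
    )


def _demography(draw: ParameterDraw, haploid_mtdna: bool) -> msprime.Demography:
    scale = 0.25 if haploid_mtdna else 1.0
    dem = msprime.Demography()
    dem.add_population(name="ATL", initial_size=draw.N_ATL * scale)
    dem.add_population(name="MED", initial_size=draw.N_MED * scale)
    dem.add_population(name="ANC", initial_size=draw.N_anc * scale)
    if draw.t1 is not None:
        if draw.Nb_ATL is not None:
            dem.add_population_parameters_change(
                time=draw.t1, population="ATL", initial_size=draw.Nb_ATL * scale
            )
        if draw.Nb_MED is not None:
            dem.add_population_parameters_change(
                time=draw.t1, population="MED", initial_size=draw.Nb_MED * scale
            )
    dem.add_population_split(time=draw.t, derived=["ATL", "MED"], ancestral="ANC")
    dem.sort_events()
    return dem


def simulate_scenario(
    draw: ParameterDraw,
    n_atl: int,
    n_med: int,
    n_loci: int = 9,
    seq_len: int = 613,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mtdna_per_diploid: float = 1.0,
) -> SimulatedSample:
    """Simulate one dataset (microsatellite genotypes + mtDNA sequences).

    ``n_atl``/``n_med`` are diploid sample sizes; the mtDNA sample takes
    ``mtdna_per_diploid`` haploid sequences per sampled diploid (rounded).
    """
    if n_atl < 1 or n_med < 1:
        raise ValueError("sample sizes must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if draw.mu_msat_locus.size < n_loci:
        raise ValueError("draw holds fewer per-locus rates than n_loci")

    # --- microsatellites ------------------------------------------------
    dem = _demography(draw, haploid_mtdna=False)
    calls = np.zeros((n_atl + n_med, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        ts = msprime.sim_ancestry(
            samples={"ATL": n_atl, "MED": n_med},
            demography=dem,
            sequence_length=1.0,
            random_seed=msprime_seed(rng),
        )
        alleles = smm_alleles_on_tree(ts, draw.mu_msat_locus[l], rng)
        calls[:, l, :] = alleles.reshape(-1, 2)
    ids = [f"atl{i + 1}" for i in range(n_atl)] + [f"med{i + 1}" for i in range(n_med)]
    labels = ["ATL"] * n_atl + ["MED"] * n_med
    genotypes = GenotypeDataset(ids, labels, [f"L{l + 1}" for l in range(n_loci)], calls)

    # --- mtDNA ----------------------------------------------------------
    m_atl = max(1, round(n_atl * mtdna_per_diploid))
    m_med = max(1, round(n_med * mtdna_per_diploid))
    dem_mt = _demography(draw, haploid_mtdna=True)
    ts = msprime.sim_ancestry(
        samples={"ATL": m_atl, "MED": m_med},
        demography=dem_mt,
        ploidy=1,
        sequence_length=seq_len,
        random_seed=msprime_seed(rng),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=draw.mu_mtdna,
        model=msprime.HKY(kappa=2.0),  # equal base frequencies: K2P
        random_seed=msprime_seed(rng),
    )
    base = rng.choice(list("ACGT"), size=seq_len)
    seq_arr = np.tile(base, (m_atl + m_med, 1)).astype("S1")
    for var in mts.variants():
        pos = int(var.site.position)
        states = np.array([var.alleles[g] for g in var.genotypes], dtype="S1")
        seq_arr[:, pos] = states
    mt_ids = [f"atl{i + 1}" for i in range(m_atl)] + [
        f"med{i + 1}" for i in range(m_med)
    ]
    mt_labels = ["ATL"] * m_atl + ["MED"] * m_med
    sequences = HaplotypeDataset(mt_ids, mt_labels, seq_arr)
    return SimulatedSample(genotypes, sequences)


# ----------------------------------------------------------------------
# summary statistics
# ----------------------------------------------------------------------

SUMMARY_NAMES = (
    # per-population microsatellite means
    "A_ATL", "A_MED", "HE_ATL", "HE_MED", "V_ATL", "V_MED",
    # per-population mtDNA
    "Hn_ATL", "Hn_MED", "Hd_ATL", "Hd_MED", "k_ATL", "k_MED", "D_ATL", "D_MED",
    # between-population
    "FST", "PHIST", "DAS", "SHARED_HAPS",
)

SENTINEL = -999.0


def summary_statistics(sample: SimulatedSample) -> np.ndarray:
    """The fixed, ordered summary vector used for observed and simulated data.

    Order per :data:`SUMMARY_NAMES`: mean allele number, mean unbiased
    heterozygosity and mean allele-size variance per population; haplotype
    number, haplotype diversity, mean pairwise differences and Tajima's D
    per population; and between populations the multilocus Weir-Cockerham
    FST, Phi-ST, the shared-allele distance and the shared haplotype count.
    Undefined entries carry the sentinel -999.
    """
    from .differentiation import fst_weir_cockerham, phi_st
    from .diversity import haplotype_diversity, heterozygosity
    from .neutrality import _pairwise_mean_diffs, _site_matrix, tajimas_d

    gen, seq = sample.genotypes, sample.sequences
    pops = ("ATL", "MED")
    out: list[float] = []
    het = {p: heterozygosity(gen, p) for p in pops}
    for p in pops:
        out.append(float(het[p]["A"].mean()))
    for p in pops:
        out.append(float(het[p]["HE"].mean()))
    for p in pops:
        idx = gen.indices_of(p)
        var = [
            float(np.var(genes))
            for l in range(gen.n_loci)
            for genes in [gen.calls[idx, l, :].ravel()]
        ]
        out.append(float(np.mean(var)))

    subs = {p: seq.subset(seq.indices_of(p)) for p in pops}
    hapsets = {}
    for p in pops:
        haps, _, counts = subs[p].haplotype_table()
        hapsets[p] = set(haps)
        out.append(float(len(counts)))
    for p in pops:
        _, _, counts = subs[p].haplotype_table()
        out.append(
            haplotype_diversity(counts) if subs[p].n_sequences >= 2 else SENTINEL
        )
    sitemats = {p: _site_matrix(subs[p]) for p in pops}
    for p in pops:
        sites = sitemats[p]
        out.append(_pairwise_mean_diffs(sites) if sites.size else 0.0)
    for p in pops:
        try:
            out.append(tajimas_d(sitemats[p]))
        except ValueError:
            out.append(SENTINEL)

    fst = float(fst_weir_cockerham(gen, list(pops))["multilocus"])
    out.append(fst if np.isfinite(fst) else SENTINEL)
    try:
        phist = phi_st(seq, list(pops))[0]
        out.append(phist if np.isfinite(phist) else SENTINEL)
    except ValueError:
        out.append(SENTINEL)
    out.append(_shared_allele_distance(gen, pops))
    out.append(float(len(hapsets["ATL"] & hapsets["MED"])))
    return np.array(out)


def _shared_allele_distance(gen: GenotypeDataset, pops) -> float:
    """1 - mean proportion of shared alleles between the two populations'
    pooled frequency spectra, averaged over loci."""
    total = 0.0
    for l in range(gen.n_loci):
        c1 = gen.allele_counts(l, pops[0])
        c2 = gen.allele_counts(l, pops[1])
        n1, n2 = sum(c1.values()), sum(c2.values())
        if n1 == 0 or n2 == 0:
            return SENTINEL
        shared = sum(
            min(c1.get(a, 0) / n1, c2.get(a, 0) / n2)
            for a in set(c1) | set(c2)
        )
        total += 1.0 - shared
    return total / gen.n_loci
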