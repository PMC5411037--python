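"""Low-level coalescent simulation helpers built on msprime.

msprime supplies the continuous-time coalescent with piecewise-constant
population sizes. Mutations are handled two ways:

* nucleotide sequences use msprime's HKY model with equal base frequencies,
  which is the Kimura two-parameter model;
* microsatellite stepwise mutations are dropped onto the simulated
  genealogy by a vectorized edge walk (Poisson mutation counts per branch,
  each mutation a +-1 repeat step, or a geometric multi-step under the
  two-phase model). This is orders of magnitude faster than a 251-state
  matrix mutation model and distributionally identical for summary
  statistics that depend only on sampled allele sizes.
"""

from __future__ import annotations

import math

import msprime
import numpy as np

__all__ = [
    "msprime_seed",
    "neutral_haploid_sites",
    "smm_alleles_on_tree",
    "simulate_msat_locus",
    "geometric_q_for_variance",
]

ALLELE_LO = 50
ALLELE_HI = 300
ROOT_ALLELE = 175


def msprime_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def neutral_haploid_sites(
    n: int, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """One neutral infinite-sites sample: (n x S) binary genotype matrix.

    ``theta`` is the locus-wide 2*N*mu (haploid), i.e. the expected pairwise
    difference count. S may be 0 (shape (n, 0)).
    """
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=1.0,
        sequence_length=1.0,
        discrete_genome=False,
        random_seed=msprime_seed(rng),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=theta / 2.0,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=msprime_seed(rng),
    )
    return mts.genotype_matrix().T % 2


def neutral_haploid_sites_batch(
    n: int, theta: float, rng: np.random.Generator, reps: int
):
    """Generator of neutral infinite-sites samples (amortized msprime setup)."""
    anc = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=1.0,
        sequence_length=1.0,
        discrete_genome=False,
        num_replicates=reps,
        random_seed=msprime_seed(rng),
    )
    for ts in anc:
        mts = msprime.sim_mutations(
            ts,
            rate=theta / 2.0,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=msprime_seed(rng),
        )
        yield mts.genotype_matrix().T % 2


def simulate_msat_locus_batch(
    n: int,
    theta: float,
    rng: np.random.Generator,
    reps: int,
    p_single_step: float = 1.0,
    multistep_variance: float = 0.0,
):
    """Generator of equilibrium microsatellite samples (amortized setup)."""
    anc = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=1.0,
        sequence_length=1.0,
        num_replicates=reps,
        random_seed=msprime_seed(rng),
    )
    for ts in anc:
        yield smm_alleles_on_tree(
            ts,
            theta / 2.0,
            rng,
            p_single_step=p_single_step,
            multistep_variance=multistep_variance,
        )


def geometric_q_for_variance(variance: float) -> float:
    """Success probability of a geometric step-size law with given variance."""
    if variance <= 0:
        return 1.0
    return (-1.0 + math.sqrt(1.0 + 4.0 * variance)) / (2.0 * variance)


def smm_alleles_on_tree(
    ts,
    mu: float,
    rng: np.random.Generator,
    root_allele: int = ROOT_ALLELE,
    lo: int = ALLELE_LO,
    hi: int = ALLELE_HI,
    p_single_step: float = 1.0,
    multistep_variance: float = 0.0,
) -> np.ndarray:
    """Sampled microsatellite allele sizes from a single-tree genealogy.

    Mutation counts per branch are Poisson(mu * branch length); each
    mutation moves the repeat count by +-1 (strict SMM) or, with probability
    ``1 - p_single_step``, by a +-Geometric step (two-phase model with the
    stated multi-step variance). Final allele sizes are reflected into
    [lo, hi].
    """
    tree = ts.first()
    n_nodes = ts.num_nodes
    times = ts.tables.nodes.time
    parent = np.full(n_nodes, -1, dtype=np.int64)
    for u in tree.nodes():
        parent[u] = tree.parent(u)
    has_parent = parent != -1
    bl = np.zeros(n_nodes)
    bl[has_parent] = times[parent[has_parent]] - times[has_parent]
    k = rng.poisson(mu * bl)
    if p_single_step >= 1.0:
        disp = 2 * rng.binomial(k, 0.5) - k
    else:
        disp = np.zeros(n_nodes, dtype=np.int64)
        q = geometric_q_for_variance(multistep_variance)
        for u in np.flatnonzero(k > 0):
            sizes = np.where(
                rng.random(k[u]) < p_single_step,
                1,
                rng.geometric(q, size=k[u]),
            )
            signs = rng.choice([-1, 1], size=k[u])
            disp[u] = int(np.sum(sizes * signs))
    allele = np.full(n_nodes, root_allele, dtype=np.int64)
    for u in np.argsort(-times):
        if parent[u] != -1:
            allele[u] = allele[parent[u]] + disp[u]
    out = allele[ts.samples()]
    width = hi - lo
    return np.abs((out - lo) % (2 * width) - width) + lo


def simulate_msat_locus(
    n: int,
    theta: float,
    rng: np.random.Generator,
    p_single_step: float = 1.0,
    multistep_variance: float = 0.0,
) -> np.ndarray:
    """Equilibrium single-population microsatellite sample of n genes.

    ``theta`` is 2*N*mu on the haploid coalescent time scale.
    """
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=1.0,
        sequence_length=1.0,
        random_seed=msprime_seed(rng),
    )
    return smm_alleles_on_tree(
        ts,
        theta / 2.0,
        rng,
        p_single_step=p_single_step,
        multistep_variance=multistep_variance,
    )
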