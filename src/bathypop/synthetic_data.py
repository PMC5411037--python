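"""Study-like synthetic datasets with controlled, recorded truth.

Emulates the sampling layout of the Atlantic-Mediterranean grenadier
survey: six localities in three regions (northern Atlantic MAR1/ROC,
southern Atlantic MAR2/MAR3, Mediterranean MED1/MED2), nine microsatellite
loci of widely varying polymorphism, and a 613-bp mtDNA fragment with two
haplogroups fixed for an A<->G transition at alignment position 91 and one
dominant haplotype per basin (82% of Atlantic samples, 74% of
Mediterranean ones).

The mtDNA side is built from an explicit haplotype tree (10 haplotypes, 11
variable sites: 9 transitions, 2 transversions), so network topology,
haplotype counts and inter-haplogroup distances are construction-
guaranteed. The nuclear side is simulated with the two-population
divergence coalescent and the split time calibrated by bisection until the
realized between-basin multilocus FST falls within +-30% of the target
(default 0.02); within-basin localities are exchangeable partitions of the
basin sample, so within-basin FST is ~0 by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .coalescent_sim import ParameterDraw, simulate_scenario
from .differentiation import fst_weir_cockerham
from .io_formats import GenotypeDataset, HaplotypeDataset

__all__ = [
    "StudyMimicConfig",
    "generate_study_like_dataset",
    "build_reference_haplotypes",
    "ATLANTIC",
    "MEDITERRANEAN",
]

ATLANTIC = ("MAR1", "MAR2", "MAR3", "ROC")
MEDITERRANEAN = ("MED1", "MED2")

# (locality, genotyped diploids, mtDNA sequences)
_DEFAULT_LAYOUT = (
    ("MAR1", 61, 30),
    ("MAR2", 13, 10),
    ("MAR3", 72, 38),
    ("ROC", 132, 49),
    ("MED1", 78, 48),
    ("MED2", 19, 18),
)

# variable sites: (1-based position, basin/background state, derived state)
_SITE_91 = (91, "A", "G")  # fixed between haplogroups, transition
_PRIVATE_SITES = {
    "s1": (150, "C", "T"),
    "s2": (210, "G", "A"),
    "s3": (270, "C", "A"),  # transversion
    "s4": (330, "T", "C"),
    "s5": (390, "A", "G"),
    "s6": (450, "G", "A"),
    "s7": (510, "C", "T"),
    "s8": (555, "T", "C"),
    "s9": (585, "G", "A"),
    "s10": (605, "A", "T"),  # transversion
}

# haplotype tree: private mutations on top of the basin-central haplotype
_HAPLOTYPE_TREE = {
    "H1": ("ATL", ("s1", "s2", "s3")),
    "H2": ("ATL", ()),
    "H3": ("ATL", ("s6",)),
    "H4": ("ATL", ("s1",)),
    "H5": ("ATL", ("s4",)),
    "H6": ("ATL", ("s7",)),
    "H7": ("ATL", ("s4", "s5")),
    "H8": ("MED", ()),
    "H9": ("MED", ("s8",)),
    "H10": ("MED", ("s9", "s10")),
}

# designed per-locality haplotype counts (northern Atlantic nearly fixed for
# H2; the southern ridge localities share the same derived haplotypes so the
# MAR2/MAR3 pair stays internally homogeneous)
_LOCALITY_HAPLOTYPES = {
    "MAR1": {"H2": 30},
    "MAR2": {"H2": 6, "H1": 3, "H5": 1},
    "MAR3": {"H2": 22, "H1": 12, "H7": 2, "H6": 2},
    "ROC": {"H2": 46, "H3": 2, "H4": 1},
    "MED1": {"H8": 34, "H10": 13, "H9": 1},
    "MED2": {"H8": 15, "H10": 2, "H9": 1},
}

_BACKBONE_SEED = 987654321  # fixed: haplotype sequences do not vary with config


@dataclass
class StudyMimicConfig:
    """Configuration of the study-like generator (defaults = study layout)."""

    layout: tuple = _DEFAULT_LAYOUT
    n_loci: int = 9
    target_fst: float = 0.02
    dominant_fraction_atl: float = 0.82
    dominant_fraction_med: float = 0.74
    seq_len: int = 613
    atlantic_substructure: bool = True
    nuclear_ne: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 or m <= 0 for _, n, m in self.layout):
            raise ValueError("locality sizes must be > 0")
        if not (0.0 < self.dominant_fraction_atl < 1.0):
            raise ValueError("dominant fractions must be in (0, 1)")
        if not (0.0 < self.dominant_fraction_med < 1.0):
            raise ValueError("dominant fractions must be in (0, 1)")
        if self.seq_len < max(p for p, _, _ in [_SITE_91] + list(_PRIVATE_SITES.values())):
            raise ValueError("seq_len too short for the designed variable sites")


# ----------------------------------------------------------------------
# mtDNA
# ----------------------------------------------------------------------


def build_reference_haplotypes(seq_len: int = 613) -> dict[str, str]:
    """The 10 designed haplotype sequences (synthetic stand-ins mirroring
    the printed structure of the deposited alignment)."""
    rng = np.random.default_rng(_BACKBONE_SEED)
    backbone = rng.choice(list("ACGT"), size=seq_len)
    pos91, atl_state, med_state = _SITE_91
    backbone[pos91 - 1] = atl_state
    for pos, anc, _ in _PRIVATE_SITES.values():
        backbone[pos - 1] = anc
    out = {}
    for name, (basin, muts) in _HAPLOTYPE_TREE.items():
        seq = backbone.copy()
        if basin == "MED":
            seq[pos91 - 1] = med_state
        for m in muts:
            pos, _, derived = _PRIVATE_SITES[m]
            seq[pos - 1] = derived
        out[name] = "".join(seq)
    return out


def _scaled_counts(config: StudyMimicConfig) -> dict[str, dict[str, int]]:
    """Per-locality haplotype counts honoring config sizes and dominant
    fractions (exact designed counts at the defaults)."""
    layout = {name: mt for name, _, mt in config.layout}
    out: dict[str, dict[str, int]] = {}
    for loc, design in _LOCALITY_HAPLOTYPES.items():
        if loc not in layout:
            continue
        n = layout[loc]
        total = sum(design.values())
        dominant = "H2" if loc in ATLANTIC else "H8"
        target_frac = (
            config.dominant_fraction_atl
            if loc in ATLANTIC
            else config.dominant_fraction_med
        )
        default_frac = 0.82 if loc in ATLANTIC else 0.74
        if n == total and abs(target_frac - default_frac) < 1e-9:
            out[loc] = dict(design)
            continue
        # rescale: keep the designed dominant share per locality, shifted by
        # the requested basin-level dominant fraction
        dom_share = design.get(dominant, 0) / total
        dom_share = min(0.99, max(0.01, dom_share + (target_frac - default_frac)))
        counts = {}
        minors = {h: c for h, c in design.items() if h != dominant}
        minor_total = sum(minors.values())
        dom_n = max(1, round(dom_share * n))
        rest = n - dom_n
        acc = 0
        for i, (h, c) in enumerate(sorted(minors.items())):
            if i == len(minors) - 1:
                counts[h] = rest - acc
            else:
                counts[h] = round(rest * c / minor_total)
                acc += counts[h]
        counts = {h: c for h, c in counts.items() if c > 0}
        counts[dominant] = n - sum(counts.values())
        out[loc] = counts
    return out


def _build_mtdna(config: StudyMimicConfig, rng: np.random.Generator) -> HaplotypeDataset:
    haps = build_reference_haplotypes(config.seq_len)
    counts = _scaled_counts(config)
    if not config.atlantic_substructure:
        # pool the Atlantic design and redraw each locality multinomially
        pooled = {}
        for loc in ATLANTIC:
            for h, c in counts.get(loc, {}).items():
                pooled[h] = pooled.get(h, 0) + c
        tot = sum(pooled.values())
        names = sorted(pooled)
        p = np.array([pooled[h] for h in names], dtype=float) / tot
        for loc in ATLANTIC:
            if loc not in counts:
                continue
            n = sum(counts[loc].values())
            draw = rng.multinomial(n, p)
            counts[loc] = {h: int(c) for h, c in zip(names, draw) if c > 0}
    ids, labels, seqs = [], [], []
    for loc, _, _ in config.layout:
        k = 0
        for h, c in sorted(counts[loc].items()):
            for _ in range(c):
                k += 1
                ids.append(f"{loc}_{k}_{h}")
                labels.append(loc)
                seqs.append(haps[h])
    return HaplotypeDataset.from_strings(seqs, ids=ids, localities=labels)


# ----------------------------------------------------------------------
# nuclear
# ----------------------------------------------------------------------


def _nuclear_draw(config: StudyMimicConfig, t: float) -> ParameterDraw:
    ne = config.nuclear_ne
    # per-locus rates spanning the 2-35 allele-count range (theta ~ 0.3-40)
    mus = np.geomspace(4.0e-6, 5.0e-4, config.n_loci)
    return ParameterDraw(
        scenario=1,
        N_ATL=ne,
        N_MED=ne,
        Nb_ATL=None,
        Nb_MED=None,
        t=t,
        t1=None,
        N_anc=ne,
        mu_msat_mean=float(mus.mean()),
        mu_msat_locus=mus,
        mu_mtdna=0.0,
    )


def _simulate_nuclear(
    config: StudyMimicConfig, t: float, rng: np.random.Generator
) -> GenotypeDataset:
    n_atl = sum(n for name, n, _ in config.layout if name in ATLANTIC)
    n_med = sum(n for name, n, _ in config.layout if name in MEDITERRANEAN)
    draw = _nuclear_draw(config, t)
    sample = simulate_scenario(
        draw, n_atl, n_med, n_loci=config.n_loci, seq_len=10,
        rng=rng, mtdna_per_diploid=1.0 / max(n_atl, n_med),  # mtDNA discarded
    )
    gen = sample.genotypes
    # partition each basin's exchangeable individuals into localities
    labels = []
    for basin, members in (("ATL", ATLANTIC), ("MED", MEDITERRANEAN)):
        for name, n, _ in config.layout:
            if name in members:
                labels.extend([name] * n)
    ids = [f"ind{i + 1}" for i in range(len(labels))]
    return GenotypeDataset(ids, labels, gen.loci, gen.calls.copy())


def _basin_fst(gen: GenotypeDataset) -> float:
    pooled = gen.relabel(
        {p: ("ATL" if p in ATLANTIC else "MED") for p in gen.populations}
    )
    return float(fst_weir_cockerham(pooled, ["ATL", "MED"])["multilocus"])


def generate_study_like_dataset(
    config: StudyMimicConfig | None = None,
) -> tuple[GenotypeDataset, HaplotypeDataset, dict]:
    """Generate the study-mimic dataset plus its truth record.

    The nuclear split time starts at the drift expectation
    ``t = 2*Ne*target_fst`` and is adjusted by bisection (re-simulating with
    seeds derived from the configured one) until the realized between-basin
    multilocus theta lies within +-30% of the target.
    """
    config = config or StudyMimicConfig()
    rng = np.random.default_rng(config.seed)
    mtdna = _build_mtdna(config, rng)

    target = config.target_fst
    lo, hi = 1.0, 16.0 * config.nuclear_ne * target
    t = 2.0 * config.nuclear_ne * target
    gen = None
    realized = None
    for attempt in range(12):
        child = np.random.default_rng((config.seed, 7, attempt))
        cand = _simulate_nuclear(config, t, child)
        realized = _basin_fst(cand)
        gen = cand
        if abs(realized - target) <= 0.3 * target:
            break
        if realized < target:
            lo = t
        else:
            hi = t
        t = (lo + hi) / 2.0
    else:
        raise RuntimeError(
            f"could not calibrate FST to {target} (last realized {realized:.4f}); "
            "try larger sample sizes or a weaker target"
        )

    truth = {
        "seed": config.seed,
        "target_fst": target,
        "realized_fst": realized,
        "split_time_generations": t,
        "nuclear_ne": config.nuclear_ne,
        "per_locus_mu": _nuclear_draw(config, t).mu_msat_locus.tolist(),
        "atlantic_localities": list(ATLANTIC),
        "mediterranean_localities": list(MEDITERRANEAN),
        "dominant_fraction_atl": config.dominant_fraction_atl,
        "dominant_fraction_med": config.dominant_fraction_med,
        "haplotype_design": {
            loc: dict(c) for loc, c in _scaled_counts(config).items()
        },
        "variable_positions": sorted(
            [p for p, _, _ in [_SITE_91] + list(_PRIVATE_SITES.values())]
        ),
        "basin_diagnostic_position": _SITE_91[0],
        "atlantic_substructure": config.atlantic_substructure,
    }
    return gen, mtdna, truth


def truth_to_json(truth: dict) -> str:
    return json.dumps(truth, indent=2, sort_keys=True)
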