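# bathypop

Population-genetic analysis of a deep-sea fish across the
Atlantic–Mediterranean transition, rebuilt as one tested, reusable Python
pipeline. The scientific question: does the shallow sill of the Strait of
Gibraltar (and, within the Atlantic, the Charlie-Gibbs Fracture Zone)
restrict gene flow in a bathyal grenadier sampled at six localities — four
Atlantic (MAR1, MAR2, MAR3 on the Mid-Atlantic Ridge; ROC at Rockall) and
two Mediterranean (MED1 western, MED2 eastern) — genotyped at nine
microsatellite loci and sequenced for a 613-bp mtDNA COI fragment?

The package is aimed at population geneticists who want every step of such
an analysis scriptable and reproducible: diversity tables, differentiation
statistics with permutation significance and FDR control, hierarchical
AMOVA with a grouping search, haplotype networks, neutrality and bottleneck
tests, a coalescent simulator of two-population divergence scenarios,
ABC model choice and parameter estimation, and a drift-based power
analysis — all exercisable on synthetic data with no downloads.

## The statistics at the core

* **Differentiation.** Weir & Cockerham's θ from variance components
  a/(a+b+c); Φ_ST from a two-level AMOVA on pairwise nucleotide
  differences; Jost's D̂_est = (k/(k−1))(H_T′−H_S′)/(1−H_S′) with
  Nei–Chesser unbiased H_S′, H_T′ (equal to 1 when samples share no
  alleles). Hierarchical AMOVA partitions variance into F_CT, F_SC, F_ST;
  the optimal grouping maximizes F_CT.
* **Diversity.** H_O, unbiased H_E = (2n/(2n−1))(1−Σp²), total gene
  diversity H_T, rarefied allelic richness, Weir & Cockerham's f (F_IS),
  exact Hardy–Weinberg tests; haplotype diversity
  H_d = (n/(n−1))(1−Σ(c_i/n)²) and nucleotide diversity π.
* **Demography.** Tajima's D, Fu's F_S via the Ewens sampling formula,
  Ramos-Onsins & Rozas' R2, coalescent p-values; heterozygosity
  excess/deficiency bottleneck tests under SMM/TPM.
* **Divergence inference.** A two-population coalescent (msprime ancestry,
  stepwise microsatellite mutations, K2P mtDNA) under four scenarios of
  post-split size change, with rejection + logistic-regression ABC model
  choice and local-linear regression posteriors; times convert to years at
  9 years/generation.

See `docs/methods.md` for estimator details, defaults and numerical
choices.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
dataset whose truth is known and recorded (`results/data/truth.json`):

```bash
python analysis/01_generate_data.py       # genepop + FASTA + truth record
python analysis/02_diversity_tables.py    # per-locality diversity + HWE
python analysis/03_differentiation.py     # pairwise stats, PCA, AMOVA, IBD
python analysis/04_haplotype_network.py   # median-joining network
python analysis/05_neutrality_bottleneck.py
python analysis/06_power.py
python analysis/07_abc_divergence.py      # scenario choice + split time
```

Selected output from a run at seed 1 (what it means in brackets):

```
realized between-basin FST: 0.0245 (target 0.02)
    [nuclear divergence across Gibraltar, calibrated within ±30% of 0.02]

pairwise dest_mtdna:
MAR1  ...  1.0000  1.0000
    [every Atlantic-vs-Mediterranean pair has Jost's D = 1: no shared
     haplotypes across the strait]

best mtdna grouping: {MAR1: N, ROC: N, MAR2: S, MAR3: S, MED1: MED, MED2: MED}
    (F_CT = 0.5732)
best msat grouping:  {all Atlantic} {MED}   (F_CT = 0.0413)
    [mtDNA splits the Atlantic across the Charlie-Gibbs Fracture Zone;
     nuclear markers see one panmictic Atlantic]

mtdna PCA: PC1 89% of inertia, axis-1 p = 0.002
    [the first axis separates the basins]

region      n      D     p_D      Fs    p_Fs     R2
MAR1/ROC   79  -1.31   0.021  -2.94   0.021  0.057
    [northern Atlantic: significant Fu's Fs and small R2, the signature of
     population expansion]

target FST 0.0028 (t=17): power 0.930
    [the sampling design detects FST ≈ 0.003 with ~95% confidence]

minimum Atlantic-Mediterranean distance: 1 mutation step(s)
    [the two haplogroups differ by a single transition at position 91]
```

The ABC driver then chooses among the four divergence scenarios, estimates
the split-time posterior and converts it to years before present, and runs
type I/II error and posterior-predictive model checks — at desk scale
(hundreds of simulations per scenario), which demonstrates the machinery
and its calibration rather than a full-fidelity posterior.

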