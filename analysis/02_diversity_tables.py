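"""Per-locality diversity table (microsatellites + mtDNA) and HWE tests.

Reads the dataset written by 01_generate_data.py and writes the diversity
summary (HO, HE, FIS, A, Rs; Hn, Hd, pi) and per-cell Hardy-Weinberg exact
p-values with BH-FDR decisions, under results/.
"""

import json
import pathlib

import pandas as pd
from statsmodels.stats.multitest import multipletests

from bathypop.diversity import diversity_table, hwe_exact_test, total_gene_diversity
from bathypop.io_formats import read_fasta_alignment, read_genepop

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    gen = read_genepop(str(ROOT / "data" / "genotypes.gen"))
    table = json.loads((ROOT / "data" / "localities.json").read_text())
    mt = read_fasta_alignment(str(ROOT / "data" / "coi_alignment.fasta"),
                              locality_table=table)

    min_genes = 2 * min(
        min((gen.calls[gen.indices_of(p), l, 0] != 0).sum() for l in range(gen.n_loci))
        for p in gen.populations
    )
    div = diversity_table(gen, mt, rarefaction_genes=min_genes)
    div.to_csv(ROOT / "diversity_table.csv")
    print(div)
    print("\nper-locus total gene diversity HT:")
    print(total_gene_diversity(gen).round(3))

    rows = []
    for pop in gen.populations:
        for l, locus in enumerate(gen.loci):
            rows.append({"population": pop, "locus": locus,
                         "p": hwe_exact_test(gen, pop, l, n_mc=20_000, seed=l)})
    hwe = pd.DataFrame(rows)
    hwe["significant_fdr_05"], *_ = multipletests(hwe["p"], 0.05, "fdr_bh")[:1]
    hwe.to_csv(ROOT / "hwe_tests.csv", index=False)
    n_sig = int(hwe["significant_fdr_05"].sum())
    print(f"\nHWE exact tests: {n_sig}/{len(hwe)} cells significant after FDR")


if __name__ == "__main__":
    main()
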