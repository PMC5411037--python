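"""Demographic history: neutrality tests per region and bottleneck tests.

mtDNA regions follow the three-cluster structure (MAR1/ROC, MAR2/MAR3,
MED); bottleneck heterozygosity tests run on the pooled Atlantic and
Mediterranean microsatellite samples under SMM and TPM.
"""

import json
import pathlib

import pandas as pd

from bathypop.io_formats import read_fasta_alignment, read_genepop
from bathypop.neutrality import bottleneck_test, neutrality_pvalues
from bathypop.synthetic_data import ATLANTIC

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"

MT_REGIONS = {"MAR1": "MAR1/ROC", "ROC": "MAR1/ROC",
              "MAR2": "MAR2/MAR3", "MAR3": "MAR2/MAR3",
              "MED1": "MED", "MED2": "MED"}


def main(reps: int = 2000, seed: int = 11) -> None:
    gen = read_genepop(str(ROOT / "data" / "genotypes.gen"))
    table = json.loads((ROOT / "data" / "localities.json").read_text())
    mt = read_fasta_alignment(str(ROOT / "data" / "coi_alignment.fasta"),
                              locality_table=table).relabel(MT_REGIONS)

    rows = []
    for region in mt.populations:
        sub = mt.subset(mt.indices_of(region))
        res = neutrality_pvalues(sub, reps=reps, seed=seed)
        rows.append({"region": region, "n": sub.n_sequences,
                     "D": res.D, "p_D": res.p_D, "Fs": res.Fs, "p_Fs": res.p_Fs,
                     "R2": res.R2, "p_R2": res.p_R2})
    neut = pd.DataFrame(rows)
    neut.to_csv(ROOT / "neutrality_tests.csv", index=False)
    print(neut.round(4))

    pooled = gen.relabel({p: ("ATL" if p in ATLANTIC else "MED")
                          for p in gen.populations})
    rows = []
    for region in ("ATL", "MED"):
        for model, kw in (("SMM", {}), ("TPM", {"p_smm": 0.8, "variance": 20.0})):
            res = bottleneck_test(pooled, region, model=model, iterations=500,
                                  seed=seed, **kw)
            rows.append({"region": region, "model": model,
                         "p_excess": res.p_excess, "p_deficiency": res.p_deficiency})
    bott = pd.DataFrame(rows)
    bott.to_csv(ROOT / "bottleneck_tests.csv", index=False)
    print("\n", bott.round(4))


if __name__ == "__main__":
    main()
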