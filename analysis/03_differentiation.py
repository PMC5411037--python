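"""Spatial structure: pairwise differentiation, PCA, AMOVA groupings, IBD.

Writes the pairwise Phi-ST / FST / Jost's D matrices with permutation
p-values and FDR stars, the frequency-PCA coordinates, the ranked AMOVA
grouping search for both marker types, and a Mantel isolation-by-distance
test within the Atlantic, under results/.
"""

import json
import pathlib

import numpy as np
import pandas as pd

from bathypop.differentiation import (
    frequency_pca,
    grouping_search,
    mantel_ibd,
    pairwise_matrix,
)
from bathypop.io_formats import read_fasta_alignment, read_genepop

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"

GROUPINGS = [
    {"MAR1": "ATL", "MAR2": "ATL", "MAR3": "ATL", "ROC": "ATL", "MED1": "MED", "MED2": "MED"},
    {"MAR1": "N", "ROC": "N", "MAR2": "S", "MAR3": "S", "MED1": "MED", "MED2": "MED"},
    {"MAR1": "MAR", "MAR2": "MAR", "MAR3": "MAR", "ROC": "ROC", "MED1": "MED", "MED2": "MED"},
    {"MAR1": "N", "ROC": "S", "MAR2": "N", "MAR3": "S", "MED1": "MED", "MED2": "MED"},
]

# great-circle-ish sea distances between localities (km), supplied as data
GEO_KM = pd.DataFrame(
    [
        [0, 640, 1300, 1600, 3200, 4600],
        [640, 0, 1000, 1700, 2900, 4300],
        [1300, 1000, 0, 1900, 2200, 3600],
        [1600, 1700, 1900, 0, 2900, 4200],
        [3200, 2900, 2200, 2900, 0, 1500],
        [4600, 4300, 3600, 4200, 1500, 0],
    ],
    index=["MAR1", "MAR2", "MAR3", "ROC", "MED1", "MED2"],
    columns=["MAR1", "MAR2", "MAR3", "ROC", "MED1", "MED2"],
)


def main(permutations: int = 499, seed: int = 7) -> None:
    gen = read_genepop(str(ROOT / "data" / "genotypes.gen"))
    table = json.loads((ROOT / "data" / "localities.json").read_text())
    mt = read_fasta_alignment(str(ROOT / "data" / "coi_alignment.fasta"),
                              locality_table=table)

    for name, data, stat in (
        ("phist", mt, "phist"),
        ("fst", gen, "fst"),
        ("dest_mtdna", mt, "dest"),
    ):
        mat = pairwise_matrix(data, stat, permutations=permutations, seed=seed)
        frame = mat.to_frame().round(4)
        frame.to_csv(ROOT / f"pairwise_{name}.csv")
        stars = pd.DataFrame(
            np.select(
                [mat.p_fdr_significant[a] for a in (0.001, 0.01, 0.05)],
                ["***", "**", "*"],
                default="",
            ),
            index=mat.labels,
            columns=mat.labels,
        )
        stars.to_csv(ROOT / f"pairwise_{name}_stars.csv")
        print(f"\npairwise {name}:\n", frame)

    for name, data in (("mtdna", mt), ("msat", gen)):
        ranked = grouping_search(data, GROUPINGS, permutations=permutations, seed=seed)
        rows = [
            {"rank": i + 1, "grouping": "; ".join(f"{k}={v}" for k, v in r.grouping.items()),
             "F_CT": r.f_ct, "F_SC": r.f_sc, "F_ST": r.f_st, "p_CT": r.p_ct}
            for i, r in enumerate(ranked)
        ]
        pd.DataFrame(rows).to_csv(ROOT / f"amova_groupings_{name}.csv", index=False)
        print(f"\nbest {name} grouping: {ranked[0].grouping} "
              f"(F_CT={ranked[0].f_ct:.4f})")

    for name, data in (("mtdna", mt), ("msat", gen)):
        pca = frequency_pca(data, randomizations=permutations, seed=seed)
        coords = pd.DataFrame(pca.coordinates, index=pca.labels)
        coords["inertia_pc1"] = pca.inertia_fractions[0]
        coords.to_csv(ROOT / f"pca_{name}.csv")
        print(f"{name} PCA: PC1 {pca.inertia_fractions[0]:.0%} of inertia, "
              f"axis-1 p = {pca.axis_p[0]:.3f}")

    # isolation by distance within the Atlantic (mtDNA)
    atl = [p for p in mt.populations if not p.startswith("MED")]
    sub = mt.subset([i for i, p in enumerate(mt.localities) if p in atl])
    mat = pairwise_matrix(sub, "phist", permutations=permutations, seed=seed)
    ibd = mantel_ibd(mat, GEO_KM.loc[mat.labels, mat.labels].to_numpy(),
                     permutations=2000, seed=seed)
    print(f"\nAtlantic IBD: a={ibd.intercept:.4f}, b={ibd.slope:.2e}, "
          f"Mantel p={ibd.mantel_p:.3f}")
    pd.Series({"intercept": ibd.intercept, "slope": ibd.slope,
               "mantel_p": ibd.mantel_p}).to_csv(ROOT / "ibd_atlantic.csv")


if __name__ == "__main__":
    main()
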