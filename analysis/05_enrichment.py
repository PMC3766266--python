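"""GSEA of the seed-gene networks in the r4-versus-r1 contrast.

Ranks all genes of dataset 1 by Signal2Noise (r4 high = positive score)
and tests each extracted network for enrichment with gene-set
permutation (1000 permutations, weighted statistic, set size 10-500).
"""

from pathlib import Path

import pandas as pd

from ntsig.gsea import gsea_many, network_list_frequency, rank_signal2noise
from ntsig.matrix import read_expression_tsv, read_gmt

COHORT = Path("results/cohort")
NETWORK = Path("results/network")
SAM = Path("results/sam")
OUT = Path("results/gsea")
SEED = 20240905


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    m = read_expression_tsv(COHORT / "expression_ds1.tsv", dataset_id="ds1", id_level="gene")
    ann = pd.read_csv(COHORT / "annotations.tsv", sep="\t")
    sub = ann[ann["dataset"] == "ds1"]
    r4 = sub.loc[sub["group"] == "r4", "sample_id"].tolist()
    r1 = sub.loc[sub["group"] == "r1", "sample_id"].tolist()
    ranked = rank_signal2noise(m, r4, r1)
    sets = read_gmt(NETWORK / "seed_networks.gmt")
    res = gsea_many(ranked, sets, n_perm=1000, seed=SEED)
    res.to_csv(OUT / "gsea_r4_vs_r1.tsv", sep="\t", index=False)
    print(res.to_string(index=False))

    up_list = pd.read_csv(SAM / "list_ds1_r4_vs_r1_up.tsv", sep="\t", index_col=0)
    for name, members in sets.items():
        pct = network_list_frequency(members, set(up_list.index))
        print(f"{name}: {pct:.0f}% of members in the r4-up gene list")


if __name__ == "__main__":
    main()
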