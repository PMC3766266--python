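"""SAM differential expression of r4 against r1 and r3, per dataset.

Applies the low-expression filter, runs the two-class unpaired SAM test
and exports the directional top-1000 / fold>2 gene lists per comparison,
direction and dataset.
"""

from pathlib import Path

import pandas as pd

from ntsig.matrix import read_expression_tsv
from ntsig.preprocess import filter_low_expression
from ntsig.sam import sam_two_class, top_gene_lists

COHORT = Path("results/cohort")
OUT = Path("results/sam")
COMPARISONS = [("r1", "r4"), ("r3", "r4")]
SEED = 20240902


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ann = pd.read_csv(COHORT / "annotations.tsv", sep="\t")
    for mat_path in sorted(COHORT.glob("expression_*.tsv")):
        ds = mat_path.stem.replace("expression_", "")
        m = filter_low_expression(read_expression_tsv(mat_path, dataset_id=ds, id_level="gene"))
        sub = ann[ann["dataset"] == ds]
        for ga, gb in COMPARISONS:
            a = sub.loc[sub["group"] == ga, "sample_id"].tolist()
            b = sub.loc[sub["group"] == gb, "sample_id"].tolist()
            stats = sam_two_class(m, a, b, n_perm=1000, seed=SEED)
            stats.to_csv(OUT / f"sam_full_{ds}_{gb}_vs_{ga}.tsv", sep="\t")
            up, down = top_gene_lists(stats, comparison=f"{gb}_vs_{ga}")
            for lst in (up, down):
                lst.entries.to_csv(OUT / f"list_{ds}_{lst.comparison}_{lst.direction}.tsv", sep="\t")
            top = stats.sort_values("d", ascending=False).head(3)
            print(f"{ds} {gb} vs {ga}: s0={stats.attrs['s0']:.3f}, "
                  f"{len(up.genes)} up / {len(down.genes)} down in top lists; "
                  f"top up genes: {', '.join(top.index)}")


if __name__ == "__main__":
    main()
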