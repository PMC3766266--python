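"""Intersect the per-dataset SAM lists and combine their evidence.

For each comparison and direction the gene lists of the two datasets are
intersected; for every intersected gene the variance-weighted combined
fold change and the sample-size-weighted combined p-value are computed,
with significance at the Bonferroni nominal cut-off 6.25e-6.
"""

from pathlib import Path

import pandas as pd

from ntsig.combine import combine_evidence, significance_cutoff
from ntsig.sam import DirectionalGeneList

SAM = Path("results/sam")
OUT = Path("results/combined")
COMPARISONS = ["r4_vs_r1", "r4_vs_r3"]
N_PER_DATASET = 40  # 20 + 20 samples in each compared pair


def _load(ds: str, comp: str, direction: str) -> DirectionalGeneList:
    df = pd.read_csv(SAM / f"list_{ds}_{comp}_{direction}.tsv", sep="\t", index_col=0)
    return DirectionalGeneList(comp, direction, df)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cutoff = significance_cutoff(0.05, 8000)
    for comp in COMPARISONS:
        for direction in ("up", "down"):
            ev = combine_evidence(
                _load("ds1", comp, direction), _load("ds2", comp, direction),
                n_1=N_PER_DATASET, n_2=N_PER_DATASET,
            )
            ev.to_csv(OUT / f"intersect_{comp}_{direction}.tsv", sep="\t")
            print(f"{comp} {direction}: {len(ev)} intersected genes, "
                  f"{int(ev['significant'].sum())} significant at P_comb < {cutoff:g}")
            if direction == "up" and "ERBB3" in ev.index:
                row = ev.loc["ERBB3"]
                print(f"  ERBB3: FC_comb={row['FC_comb']:.1f}, P_comb={row['P_comb']:.2e}")


if __name__ == "__main__":
    main()
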