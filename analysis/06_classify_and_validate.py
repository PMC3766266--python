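"""7-gene signature classification and agreement with planted histology.

Classifies every sample of both datasets with the reconstructed 7-gene
SD-rule table, maps classes to histology prediction classes (NB/GNB/GN),
crosstabulates against the generator's true histology labels and tests
agreement with Cohen's kappa (null-variance z-test).
"""

import json
from pathlib import Path

import pandas as pd

from ntsig.matrix import read_expression_tsv
from ntsig.signature import assign_all, load_rule_table
from ntsig.stats import cohen_kappa, crosstab_from_labels, row_agreement

COHORT = Path("results/cohort")
OUT = Path("results/classification")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ann = pd.read_csv(COHORT / "annotations.tsv", sep="\t")
    table = load_rule_table("7")
    frames = []
    for mat_path in sorted(COHORT.glob("expression_*.tsv")):
        ds = mat_path.stem.replace("expression_", "")
        m = read_expression_tsv(mat_path, dataset_id=ds, id_level="gene")
        frames.append(assign_all(m, table))
    res = pd.concat(frames, ignore_index=True).merge(ann, on="sample_id")
    res.to_csv(OUT / "assignments.tsv", sep="\t", index=False)

    ok = res["histology_prediction"] != "nd"
    print(f"{int(ok.sum())} of {len(res)} samples assignable ({100 * ok.mean():.0f}%)")
    t = crosstab_from_labels(res.loc[ok, "histology_prediction"], res.loc[ok, "histology"])
    t.to_csv(OUT / "crosstab.tsv", sep="\t")
    kr = cohen_kappa(t)
    agree = row_agreement(t)
    print("predicted x observed histology:")
    print(t.to_string())
    print(f"kappa = {kr.kappa:.3f}, z = {kr.z:.2f}, two-sided p = {kr.p_two_sided:.2e}")
    for label, pct in agree.items():
        print(f"row agreement {label}: {pct:.1f}%")
    with open(OUT / "validation.json", "w") as fh:
        json.dump(
            {"kappa": kr.kappa, "z": kr.z, "p": kr.p_two_sided,
             "row_agreement_pct": {k: float(v) for k, v in agree.items()}},
            fh, indent=1,
        )


if __name__ == "__main__":
    main()
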