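"""SD-rule signature classification of samples into molecular subgroups.

Expression of the signature genes is z-scored per gene across all samples
of a dataset; each class of a rule table demands per-gene conditions in
SD units (UP: z >= theta, DOWN: z <= -theta, ANY: always true, optionally
an upper bound for banded UP rules).  A sample qualifies for a class when
at least ``min_rules`` of its rules are met and every mandatory rule
holds; among qualifying classes the one with most rules met wins, ties
broken by the largest summed satisfaction margin, remaining ties give
"nd" (not determined).  Classes map onto histology prediction classes:
r1-r3 (NB-r1..NB-r3) -> NB, GNB-r4 -> GNB, GN-r4 -> GN.

The default rule tables shipped with the package are reconstructions of
the published 6/7-gene signatures from their narrative description; the
exact published SD cut-offs are not publicly available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ntsig.matrix import ExpressionMatrix

__all__ = [
    "SignatureRule",
    "RuleTable",
    "SubgroupAssignment",
    "load_rule_table",
    "zscore_matrix",
    "assign_subgroup",
    "assign_all",
    "predict_histology",
]

ND = "nd"


@dataclass(frozen=True)
class SignatureRule:
    group: str
    gene: str
    direction: str  # UP, DOWN or ANY
    threshold: float = 0.5
    mandatory: bool = False
    upper: float | None = None  # optional exclusive upper bound for UP bands

    def __post_init__(self) -> None:
        if self.direction not in ("UP", "DOWN", "ANY"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")

    def satisfied(self, z: float) -> bool:
        if self.direction == "ANY":
            return True
        if self.direction == "UP":
            return z >= self.threshold and (self.upper is None or z < self.upper)
        return z <= -self.threshold

    def margin(self, z: float) -> float:
        """Signed satisfaction margin in SD units (0 for ANY)."""
        if self.direction == "ANY":
            return 0.0
        return z - self.threshold if self.direction == "UP" else -self.threshold - z


@dataclass
class RuleTable:
    signature_name: str
    classes: list[str]
    rules: dict[str, dict[str, SignatureRule]]  # class -> gene -> rule
    min_rules: int = 5

    def __post_init__(self) -> None:
        genes = self.genes
        for cls in self.classes:
            missing = set(genes) - set(self.rules.get(cls, {}))
            if missing:
                raise ValueError(f"class {cls} lacks rules for {sorted(missing)}")
            if self.min_rules > len(self.rules[cls]):
                raise ValueError("min_rules exceeds the number of rules per class")

    @property
    def genes(self) -> list[str]:
        return sorted({g for cls in self.rules.values() for g in cls})


def load_rule_table(source: str | Path = "7") -> RuleTable:
    """Load a rule table from YAML; "6"/"7" name the bundled defaults."""
    if source in ("6", "7"):
        ref = resources.files("ntsig.data") / f"rules_{source}genesig.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    rules: dict[str, dict[str, SignatureRule]] = {}
    for cls, genes in raw["rules"].items():
        rules[cls] = {}
        for gene, spec in genes.items():
            rules[cls][gene] = SignatureRule(
                group=cls,
                gene=gene,
                direction=spec["direction"],
                threshold=float(spec.get("threshold", 0.5)),
                mandatory=bool(spec.get("mandatory", False)),
                upper=spec.get("upper"),
            )
    return RuleTable(
        signature_name=raw["signature_name"],
        classes=list(raw["classes"]),
        rules=rules,
        min_rules=int(raw.get("min_rules", 5)),
    )


def zscore_matrix(m: ExpressionMatrix, required_genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene z-scores across all samples of the dataset (ddof = 1).

    Zero-SD genes get z = 0 throughout.  When ``required_genes`` is given,
    their absence raises with the full missing list.
    """
    if m.n_samples < 3:
        raise ValueError("z-scoring needs at least 3 samples")
    if required_genes:
        missing = [g for g in required_genes if g not in m.values.index]
        if missing:
            raise KeyError(f"signature genes absent from matrix: {missing}")
    vals = m.values
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    z = vals.sub(mu, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return z


@dataclass
class SubgroupAssignment:
    sample_id: str
    assigned_class: str  # class label or "nd"
    rules_met: dict[str, int]
    margin: dict[str, float]
    histology_prediction: str  # NB, GNB, GN or "nd"


_HISTOLOGY = {"r1": "NB", "r2": "NB", "r3": "NB", "NB-r1": "NB", "NB-r2": "NB",
              "NB-r3": "NB", "GNB-r4": "GNB", "GN-r4": "GN"}


def predict_histology(assigned_class: str) -> str:
    """Map a signature class to its histology prediction class.

    r1-r3 and NB-r1..NB-r3 -> NB; GNB-r4 -> GNB; GN-r4 -> GN; r4 (6-gene
    signature, histology unresolved) and "nd" -> "nd".
    """
    return _HISTOLOGY.get(assigned_class, ND)


def assign_subgroup(z: pd.Series, table: RuleTable, sample_id: str = "sample") -> SubgroupAssignment:
    """Classify one sample from its signature-gene z-scores."""
    missing = [g for g in table.genes if g not in z.index]
    if missing:
        raise KeyError(f"z-scores missing for signature genes: {missing}")
    rules_met: dict[str, int] = {}
    margins: dict[str, float] = {}
    qualifying: list[str] = []
    for cls in table.classes:
        cls_rules = table.rules[cls]
        met = [r for r in cls_rules.values() if r.satisfied(float(z[r.gene]))]
        rules_met[cls] = len(met)
        margins[cls] = float(sum(r.margin(float(z[r.gene])) for r in met))
        mandatory_ok = all(
            r.satisfied(float(z[r.gene])) for r in cls_rules.values() if r.mandatory
        )
        if len(met) >= table.min_rules and mandatory_ok:
            qualifying.append(cls)
    assigned = ND
    if qualifying:
        best_met = max(rules_met[c] for c in qualifying)
        best = [c for c in qualifying if rules_met[c] == best_met]
        if len(best) > 1:
            best_margin = max(margins[c] for c in best)
            best = [c for c in best if margins[c] == best_margin]
        if len(best) == 1:
            assigned = best[0]
    return SubgroupAssignment(sample_id, assigned, rules_met, margins, predict_histology(assigned))


def assign_all(m: ExpressionMatrix, table: RuleTable) -> pd.DataFrame:
    """Classify every sample of a dataset matrix.

    Returns a frame (sample_id, assigned_class, rules_met of the winning
    class, histology_prediction).
    """
    z = zscore_matrix(m, required_genes=table.genes)
    rows = []
    for sample in m.sample_ids:
        a = assign_subgroup(z[sample], table, sample_id=sample)
        rows.append(
            {
                "sample_id": sample,
                "assigned_class": a.assigned_class,
                "rules_met": a.rules_met.get(a.assigned_class, 0),
                "histology_prediction": a.histology_prediction,
            }
        )
    return pd.DataFrame(rows)
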