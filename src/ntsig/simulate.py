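"""Synthetic neuroblastic-tumour expression cohorts with planted structure.

The generator emulates the statistical features the downstream analysis
relies on, on the log2 scale of normalised microarray data:

* four expression subgroups r1-r4 with histology labels (r4 samples are
  GNB or GN, r1-r3 are NB);
* subgroup-specific shifts of the seven signature markers
  (ALK, BIRC5, CCND1, MYCN, NTRK1, PHOX2B, ERBB3);
* a correlated hub block — an ERBB3-like hub and its partners loading on a
  shared per-sample latent factor;
* a cell-cycle gene block elevated in r2/r3 and a tumour-suppressor block
  depressed in r3;
* additive Gaussian noise and a small per-dataset shift modelling the
  two-platform (preamplified vs not) design.

Per gene g, sample j of subgroup k in dataset d:

    x_gj = baseline_g + effect(k, g) + shift_{g,d} + lambda_g * f_j + eps

with f_j a standard-Gaussian latent factor shared by hub members and
eps ~ N(0, noise_sd).  The model is a stand-in: no public generative model
exists for these cohorts, and the planted-truth file flags every
distributional choice as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ntsig.matrix import ExpressionMatrix

SIGNATURE_GENES = ["ALK", "BIRC5", "CCND1", "MYCN", "NTRK1", "PHOX2B"]
GROUPS = ["r1", "r2", "r3", "r4"]

# Default planted log2 shifts per (gene, subgroup).  Directions follow the
# subtype biology: r4 low in all six signature genes and high in ERBB3;
# r2/r3 proliferative (BIRC5/CCND1 up); r3 MYCN-driven; r1 NTRK1/PHOX2B high.
DEFAULT_MARKER_EFFECTS = pd.DataFrame(
    {
        "r1": {"ALK": -1.5, "BIRC5": -1.5, "CCND1": 0.0, "MYCN": -1.5, "NTRK1": 2.0, "PHOX2B": 1.5, "ERBB3": -0.5},
        "r2": {"ALK": 1.5, "BIRC5": 1.5, "CCND1": 1.5, "MYCN": -1.5, "NTRK1": -1.5, "PHOX2B": 1.5, "ERBB3": -0.5},
        "r3": {"ALK": 1.5, "BIRC5": 2.0, "CCND1": 1.5, "MYCN": 2.5, "NTRK1": -1.5, "PHOX2B": 0.0, "ERBB3": -0.5},
        "r4": {"ALK": -2.0, "BIRC5": -2.0, "CCND1": -1.5, "MYCN": -1.5, "NTRK1": -1.5, "PHOX2B": -2.0, "ERBB3": 7.5},
    }
)


@dataclass
class BlockSpec:
    """A co-regulated gene block with per-subgroup mean shifts."""

    name: str
    n_members: int
    shifts: dict[str, float] = field(default_factory=dict)


def default_block_specs() -> list[BlockSpec]:
    return [
        BlockSpec("cell_cycle", 30, {"r2": 1.5, "r3": 2.0}),
        BlockSpec("tumour_suppressor", 20, {"r3": -1.5}),
    ]


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator.

    ``hub_spec`` is (hub gene, number of partners, latent-factor loading in
    [0, 1]); the hub gene also carries the loading so that partners
    correlate with it.  ``gn_erbb3_bonus`` is the extra ERBB3 log2 shift
    given to GN-labelled r4 samples (GN tumours show the highest ERBB3).
    """

    n_genes: int = 2000
    group_sizes: tuple[int, int, int, int] = (20, 20, 20, 20)
    n_datasets: int = 2
    marker_effects: pd.DataFrame | None = None
    hub_spec: tuple[str, int, float] = ("ERBB3", 38, 0.8)
    hub_partner_r4_shift: float = 1.5
    block_specs: list[BlockSpec] | None = None
    baseline_mean_range: tuple[float, float] = (5.0, 12.0)
    noise_sd: float = 0.7
    dataset_shift_sd: float = 0.3
    gn_fraction: float = 0.5
    gn_erbb3_bonus: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("invalid config: every group size must be >= 2")
        hub, n_partners, loading = self.hub_spec
        if not (0.0 <= loading <= 1.0):
            raise ValueError("invalid config: hub loading must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("invalid config: noise_sd must be > 0")
        if not (0.0 <= self.gn_fraction <= 1.0):
            raise ValueError("invalid config: gn_fraction must lie in [0, 1]")
        if self.marker_effects is None:
            self.marker_effects = DEFAULT_MARKER_EFFECTS.copy()
        if self.block_specs is None:
            self.block_specs = default_block_specs()


@dataclass
class SyntheticCohort:
    """Generated matrices plus per-sample annotation and the planted truth."""

    matrices: list[ExpressionMatrix]
    annotations: pd.DataFrame  # sample_id, dataset, group, histology
    truth: dict

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for m in self.matrices:
            p = outdir / f"expression_{m.dataset_id}.tsv"
            m.to_tsv(p)
            written.append(p)
        p = outdir / "annotations.tsv"
        self.annotations.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = outdir / "truth.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(self.truth, fh, sort_keys=False)
        written.append(p)
        return written


def _gene_names(config: SimConfig) -> tuple[list[str], dict]:
    hub, n_partners, loading = config.hub_spec
    partners = [f"{hub}_P{i:02d}" for i in range(1, n_partners + 1)]
    blocks = {b.name: [f"{b.name.upper()}_{i:02d}" for i in range(1, b.n_members + 1)] for b in config.block_specs}
    markers = list(config.marker_effects.index)
    named = markers + ([hub] if hub not in markers else []) + partners
    for members in blocks.values():
        named += members
    if len(set(named)) != len(named):
        seen, dups = set(), set()
        for g in named:
            (dups if g in seen else seen).add(g)
        raise ValueError(f"invalid config: duplicate gene names across blocks: {sorted(dups)}")
    n_filler = config.n_genes - len(named)
    if n_filler < 0:
        raise ValueError("invalid config: n_genes smaller than the number of named genes")
    filler = [f"GENE{i:04d}" for i in range(1, n_filler + 1)]
    return named + filler, {"partners": partners, "blocks": blocks}


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one cohort per dataset under the planted additive model.

    Identical seed implies a bit-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    genes, named = _gene_names(config)
    n_genes = len(genes)
    hub, _, loading = config.hub_spec
    hub_members = [hub] + named["partners"]

    baseline = rng.uniform(*config.baseline_mean_range, size=n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    # effect(k, g) table covering markers and blocks
    effects = pd.DataFrame(0.0, index=genes, columns=GROUPS)
    for g in config.marker_effects.index:
        effects.loc[g, :] = config.marker_effects.loc[g, GROUPS].astype(float)
    for spec in config.block_specs:
        for g in named["blocks"][spec.name]:
            for k, shift in spec.shifts.items():
                effects.loc[g, k] = shift
    # hub partners rise with the hub in r4 (the network is differentially
    # expressed as a block, not only co-fluctuating)
    for g in named["partners"]:
        effects.loc[g, "r4"] = config.hub_partner_r4_shift

    lam = np.zeros(n_genes)
    for g in hub_members:
        lam[gene_idx[g]] = loading

    # sample layout (same design in each dataset, independent draws)
    groups = np.repeat(GROUPS, config.group_sizes)
    matrices, ann_rows = [], []
    for d in range(config.n_datasets):
        ds = f"ds{d + 1}"
        sample_ids = [f"{ds}_s{i + 1:03d}" for i in range(len(groups))]
        shift_d = rng.normal(0.0, config.dataset_shift_sd, size=n_genes) if d > 0 else np.zeros(n_genes)
        f = rng.normal(size=len(groups))
        eps = rng.normal(0.0, config.noise_sd, size=(n_genes, len(groups)))

        histology = []
        r4_count = 0
        n_r4 = int(np.sum(groups == "r4"))
        n_gn = int(round(config.gn_fraction * n_r4))
        for k in groups:
            if k == "r4":
                histology.append("GN" if r4_count < n_gn else "GNB")
                r4_count += 1
            else:
                histology.append("NB")

        eff = effects[pd.Index(groups)].to_numpy()  # genes x samples
        bonus = np.zeros((n_genes, len(groups)))
        is_gn = np.array([h == "GN" for h in histology])
        if hub in gene_idx:
            bonus[gene_idx[hub], is_gn] = config.gn_erbb3_bonus
        x = baseline[:, None] + eff + bonus + shift_d[:, None] + lam[:, None] * f[None, :] + eps
        matrices.append(
            ExpressionMatrix(pd.DataFrame(x, index=genes, columns=sample_ids), dataset_id=ds, id_level="gene")
        )
        for s, k, h in zip(sample_ids, groups, histology):
            ann_rows.append({"sample_id": s, "dataset": ds, "group": k, "histology": h})

    truth = {
        "note": "synthetic stand-in cohort; all distributional choices are invented plumbing",
        "marker_effects": {g: {k: float(effects.loc[g, k]) for k in GROUPS} for g in config.marker_effects.index},
        "hub_gene": hub,
        "hub_partners": named["partners"],
        "hub_loading": float(loading),
        "hub_partner_r4_shift": float(config.hub_partner_r4_shift),
        "gn_erbb3_bonus": float(config.gn_erbb3_bonus),
        "blocks": named["blocks"],
        "block_shifts": {b.name: dict(b.shifts) for b in config.block_specs},
        "noise_sd": float(config.noise_sd),
        "seed": int(config.seed),
    }
    return SyntheticCohort(matrices, pd.DataFrame(ann_rows), truth)


def generate_markov_triplet(n: int, rho: float, seed: int = 0) -> pd.DataFrame:
    """Sample the Markov chain X -> Y -> Z with corr(X, Y) = corr(Y, Z) = rho.

    Y = rho*X + sqrt(1-rho^2)*e1 and Z = rho*Y + sqrt(1-rho^2)*e2, all
    standard Gaussian marginals, so X and Z are conditionally independent
    given Y and corr(X, Z) = rho^2.  Used as ground truth for DPI pruning.
    """
    if n < 30:
        raise ValueError("invalid config: n must be >= 30")
    if not (0.0 < rho < 1.0):
        raise ValueError("invalid config: rho must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
    z = rho * y + np.sqrt(1 - rho**2) * rng.normal(size=n)
    return pd.DataFrame({"X": x, "Y": y, "Z": z})
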