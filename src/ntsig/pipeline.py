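"""End-to-end orchestration: simulate -> preprocess -> SAM -> combine ->
network -> GSEA -> classify -> validate, with deterministic seeding.

A single global seed is expanded into per-stage seeds through a fixed
counter scheme (one fixed spawn key per stage), so disabling one stage
never shifts the randomness of another.  Every stage writes its artifacts
under the output directory and registers them in a manifest with SHA-256
checksums; identical configuration and seed reproduce identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ntsig import combine as combine_mod
from ntsig import gsea as gsea_mod
from ntsig import network as network_mod
from ntsig import signature as signature_mod
from ntsig import stats as stats_mod
from ntsig.matrix import ExpressionMatrix, read_expression_tsv, write_gmt
from ntsig.preprocess import filter_low_expression
from ntsig.sam import sam_two_class, top_gene_lists
from ntsig.simulate import SimConfig, generate_cohort

log = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "sam", "combine", "network", "gsea", "classify", "validate"]
_STAGE_KEY = {name: i for i, name in enumerate(STAGES)}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) from the global seed."""
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(_STAGE_KEY[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    outdir: str = "ntsig_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # simulate
    sim: SimConfig | None = None
    # preprocess
    expression_threshold: float = 5.0
    # sam / lists
    comparisons: list[tuple[str, str]] = field(default_factory=lambda: [("r1", "r4"), ("r3", "r4")])
    n_perm: int = 1000
    top_n: int = 1000
    fc_min: float = 2.0
    # network
    network_top_var: int = 150
    aracne: network_mod.AracneConfig | None = None
    network_seeds: list[str] = field(
        default_factory=lambda: ["ALK", "BIRC5", "CCND1", "ERBB3", "MYCN", "NTRK1", "PHOX2B"]
    )
    # gsea
    gsea_n_perm: int = 1000
    # classify
    signature: str = "7"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        sim_raw = raw.pop("sim", None)
        aracne_raw = raw.pop("aracne", None)
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown pipeline option {k!r}")
            setattr(cfg, k, v)
        cfg.comparisons = [tuple(c) for c in cfg.comparisons]
        if sim_raw:
            cfg.sim = SimConfig(**sim_raw)
        if aracne_raw:
            cfg.aracne = network_mod.AracneConfig(**aracne_raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.entries: list[dict] = []

    def add(self, path: Path, stage: str) -> None:
        self.entries.append(
            {"file": str(path.relative_to(self.outdir)), "stage": stage, "sha256": _sha256(path)}
        )

    def write(self) -> Path:
        p = self.outdir / "manifest.json"
        with open(p, "w") as fh:
            json.dump(self.entries, fh, indent=1)
        return p


def run_pipeline(config: PipelineConfig) -> list[dict]:
    """Execute the enabled stages in order; returns the manifest entries."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    enabled = [s for s in STAGES if s in config.stages]

    matrices: list[ExpressionMatrix] = []
    annotations: pd.DataFrame | None = None
    lists: dict[tuple[str, str, str], list] = {}
    sam_results: dict[tuple[str, str], pd.DataFrame] = {}
    net = None
    gene_sets: dict[str, list[str]] = {}
    assignments: pd.DataFrame | None = None

    if "simulate" in enabled:
        sim = config.sim or SimConfig()
        sim.seed = stage_seed(config.seed, "simulate")
        cohort = generate_cohort(sim)
        for p in cohort.write(outdir):
            manifest.add(p, "simulate")
        matrices = cohort.matrices
        annotations = cohort.annotations
        log.info("simulate: %d datasets, %d genes", len(matrices), matrices[0].n_genes)
    else:
        for p in sorted(outdir.glob("expression_*.tsv")):
            ds = p.stem.replace("expression_", "")
            matrices.append(read_expression_tsv(p, dataset_id=ds, id_level="gene"))
        ann_path = outdir / "annotations.tsv"
        if ann_path.exists():
            annotations = pd.read_csv(ann_path, sep="\t")
        if not matrices:
            raise FileNotFoundError("simulate disabled and no expression_*.tsv in outdir")

    if "preprocess" in enabled:
        matrices = [filter_low_expression(m, config.expression_threshold) for m in matrices]
        for m in matrices:
            p = outdir / f"filtered_{m.dataset_id}.tsv"
            m.to_tsv(p)
            manifest.add(p, "preprocess")
        log.info("preprocess: %s genes retained", [m.n_genes for m in matrices])

    if "sam" in enabled:
        if annotations is None:
            raise FileNotFoundError("sam stage requires annotations.tsv")
        seed = stage_seed(config.seed, "sam")
        for m in matrices:
            ann = annotations[annotations["dataset"] == m.dataset_id]
            for ga, gb in config.comparisons:
                a = ann.loc[ann["group"] == ga, "sample_id"].tolist()
                b = ann.loc[ann["group"] == gb, "sample_id"].tolist()
                res = sam_two_class(m, a, b, n_perm=config.n_perm, seed=seed)
                sam_results[(m.dataset_id, f"{gb}_vs_{ga}")] = res
                up, down = top_gene_lists(res, config.top_n, config.fc_min, comparison=f"{gb}_vs_{ga}")
                for lst in (up, down):
                    lst.entries.attrs.update(res.attrs)
                    lists[(m.dataset_id, lst.comparison, lst.direction)] = lst
                    p = outdir / f"sam_{m.dataset_id}_{lst.comparison}_{lst.direction}.tsv"
                    lst.entries.to_csv(p, sep="\t")
                    manifest.add(p, "sam")

    if "combine" in enabled:
        datasets = sorted({k[0] for k in lists})
        if len(datasets) < 2:
            raise FileNotFoundError("combine stage needs SAM lists from two datasets")
        d1, d2 = datasets[:2]
        for ga, gb in config.comparisons:
            comp = f"{gb}_vs_{ga}"
            for direction in ("up", "down"):
                key1, key2 = (d1, comp, direction), (d2, comp, direction)
                if key1 not in lists or key2 not in lists:
                    raise FileNotFoundError(f"missing SAM list for {comp}/{direction}")
                ev = combine_mod.combine_evidence(lists[key1], lists[key2])
                p = outdir / f"intersect_{comp}_{direction}.tsv"
                ev.to_csv(p, sep="\t")
                manifest.add(p, "combine")

    if "network" in enabled:
        m = matrices[0]
        var = m.values.var(axis=1)
        keep = set(var.sort_values(ascending=False).head(config.network_top_var).index)
        keep |= set(g for g in config.network_seeds if g in m.values.index)
        sub = ExpressionMatrix(m.values.loc[sorted(keep)], m.dataset_id, m.id_level)
        # default to a desk-scale MI cut: synthetic cohorts cannot reach the
        # extreme 1e-7 null quantile (see docs/methods.md)
        ar = config.aracne or network_mod.AracneConfig(mi_p_cutoff=1e-3)
        ar.seed = stage_seed(config.seed, "network")
        net = network_mod.build_network(sub, ar)
        p = outdir / "network_edges.tsv"
        net.to_edge_tsv(p)
        manifest.add(p, "network")
        p = outdir / "network.sif"
        net.to_sif(p)
        manifest.add(p, "network")
        seeds_present = [s for s in config.network_seeds if s in net.members]
        gene_sets = network_mod.neighborhoods_to_gmt(net, seeds_present)
        p = outdir / "networks.gmt"
        write_gmt(gene_sets, p, description="first-neighbour network")
        manifest.add(p, "network")
        log.info("network: %d nodes, %d edges", len(net.members), net.graph.number_of_edges())

    if "gsea" in enabled:
        if annotations is None:
            raise FileNotFoundError("gsea stage requires annotations")
        if not gene_sets:
            raise FileNotFoundError("gsea stage requires network gene sets")
        m = matrices[0]
        ann = annotations[annotations["dataset"] == m.dataset_id]
        ga, gb = config.comparisons[-1]
        a = ann.loc[ann["group"] == gb, "sample_id"].tolist()  # phenotype A = contrast group
        b = ann.loc[ann["group"] == ga, "sample_id"].tolist()
        ranked = gsea_mod.rank_signal2noise(m, a, b)
        res = gsea_mod.gsea_many(
            ranked, gene_sets, n_perm=config.gsea_n_perm, seed=stage_seed(config.seed, "gsea")
        )
        p = outdir / f"gsea_{gb}_vs_{ga}.tsv"
        res.to_csv(p, sep="\t", index=False)
        manifest.add(p, "gsea")

    if "classify" in enabled:
        table = signature_mod.load_rule_table(config.signature)
        frames = []
        for m in matrices:
            frames.append(signature_mod.assign_all(m, table))
        assignments = pd.concat(frames, ignore_index=True)
        p = outdir / "assignments.tsv"
        assignments.to_csv(p, sep="\t", index=False)
        manifest.add(p, "classify")

    if "validate" in enabled:
        if assignments is None or annotations is None:
            raise FileNotFoundError("validate stage requires assignments and annotations")
        merged = assignments.merge(annotations, on="sample_id")
        ok = merged["histology_prediction"] != "nd"
        t = stats_mod.crosstab_from_labels(
            merged.loc[ok, "histology_prediction"], merged.loc[ok, "histology"]
        )
        kr = stats_mod.cohen_kappa(t)
        agree = stats_mod.row_agreement(t)
        p = outdir / "crosstab.tsv"
        t.to_csv(p, sep="\t")
        manifest.add(p, "validate")
        summary = {
            "n_assigned": int(ok.sum()),
            "n_total": int(len(merged)),
            "kappa": kr.kappa,
            "z": kr.z,
            "p_two_sided": kr.p_two_sided,
            "row_agreement_pct": {str(k): float(v) for k, v in agree.items()},
        }
        p = outdir / "validation.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=1)
        manifest.add(p, "validate")

    manifest.write()
    return manifest.entries
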