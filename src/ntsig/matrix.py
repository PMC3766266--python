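"""Expression matrix container and plain-text I/O (TSV, GMT, SIF)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Log2 expression values, rows = probe-sets or gene symbols, columns = samples.

    Parameters
    ----------
    values
        Genes x samples frame of finite log2 expression values.
    dataset_id
        Label of the originating data set.
    id_level
        ``"probe"`` or ``"gene"``; after mean-per-gene collapse the level is
        ``"gene"`` and row ids are unique.
    """

    values: pd.DataFrame
    dataset_id: str = "dataset"
    id_level: str = "probe"

    def __post_init__(self) -> None:
        if self.id_level not in ("probe", "gene"):
            raise ValueError(f"id_level must be 'probe' or 'gene', got {self.id_level!r}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.id_level == "gene" and self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids at gene level: {dups}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.values[list(sample_ids)], self.dataset_id, self.id_level)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "ID"
        out.to_csv(path, sep="\t", float_format="%.6g")


def read_expression_tsv(
    path: str | Path, dataset_id: str = "dataset", id_level: str = "probe"
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV whose first column ("ID") holds row ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float), dataset_id=dataset_id, id_level=id_level)


def read_probe_map(path: str | Path) -> pd.Series:
    """Two-column TSV (probe_id, gene_symbol) -> Series probe -> symbol."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene_symbol"], dtype=str)
    if df["probe_id"].duplicated().any():
        raise ValueError("probe map contains duplicate probe ids")
    return df.set_index("probe_id")["gene_symbol"]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
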