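"""Expression-matrix pre-processing: low-expression filter, mean-per-gene collapse.

Mirrors the standard treatment of gcRMA-normalised microarray data: probe
sets whose maximum log2 expression over all samples stays below a detection
threshold (default 5) are removed, then probe-level rows are collapsed to
one row per gene symbol by the arithmetic mean.
"""

from __future__ import annotations

import logging

import pandas as pd

from ntsig.matrix import ExpressionMatrix

log = logging.getLogger(__name__)


def filter_low_expression(m: ExpressionMatrix, threshold: float = 5.0) -> ExpressionMatrix:
    """Drop rows whose maximum over all samples is below ``threshold``.

    Rows with max exactly equal to the threshold are kept (strict reading
    of "filtered out if log2 expression < threshold").  Row order is
    preserved; filtering is idempotent.
    """
    if m.n_genes == 0:
        return m
    keep = m.values.max(axis=1) >= threshold
    if not keep.any():
        log.warning("low-expression filter removed every row (threshold=%g)", threshold)
    return ExpressionMatrix(m.values.loc[keep], m.dataset_id, m.id_level)


def collapse_mean_per_gene(
    m: ExpressionMatrix, probe_map: pd.Series, on_missing: str = "drop"
) -> ExpressionMatrix:
    """Collapse probe-level rows to mean-per-gene rows.

    Parameters
    ----------
    probe_map
        Series mapping probe id -> gene symbol.
    on_missing
        ``"drop"`` (default) removes probes absent from the map with a
        warning; ``"error"`` raises.
    """
    if m.id_level != "probe":
        raise ValueError("collapse_mean_per_gene expects a probe-level matrix")
    present = m.values.index.isin(probe_map.index)
    if not present.all():
        missing = m.values.index[~present].tolist()
        if on_missing == "error":
            raise KeyError(f"probes missing from probe map: {missing[:10]}")
        log.warning("dropping %d probes missing from the probe map", len(missing))
    vals = m.values.loc[present]
    symbols = probe_map.reindex(vals.index)
    collapsed = vals.groupby(symbols, sort=True).mean()
    collapsed.index.name = m.values.index.name
    return ExpressionMatrix(collapsed, m.dataset_id, id_level="gene")
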