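"""Two-class unpaired SAM differential expression.

The relative difference statistic for gene g between groups a and b is

    d_g = (xbar_b - xbar_a) / (s_g + s0)

with the gene-specific pooled scatter

    s_g = sqrt( (1/n_a + 1/n_b) * (SS_a + SS_b) / (n_a + n_b - 2) )

and a small exchangeability factor s0 chosen from the percentiles of
{s_g} to make the coefficient of variation of d flat in s.  Significance
comes from permuting the group labels: by default the permuted d values of
all genes form one pooled null.  The sign convention is d > 0 when the
gene is higher in ``group_b`` (the second-named group of a comparison such
as "r4 vs r1").  Fold change is 2^(xbar_b - xbar_a), reported on the
linear scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from ntsig.matrix import ExpressionMatrix

__all__ = ["sam_two_class", "choose_s0", "top_gene_lists", "DirectionalGeneList"]


def _pooled_scatter(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (mean_b - mean_a, s_g) for genes x samples blocks."""
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    ssa = ((xa - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((xb - mb[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))
    return mb - ma, s


def choose_s0(numerators: np.ndarray, s: np.ndarray, n_windows: int = 100) -> float:
    """Select the exchangeability factor s0.

    Searches the percentiles 0, 5, ..., 100 of {s_g} and picks the value
    that minimises the coefficient of variation of the d-statistic's
    spread across windows of s (the spread of d in each of ``n_windows``
    s-quantile windows is measured by the median absolute deviation).
    Falls back to median(s) for fewer than 20 genes.
    """
    numerators = np.asarray(numerators, float)
    s = np.asarray(s, float)
    if s.size == 0:
        raise ValueError("choose_s0 requires at least one gene")
    if s.size < 20:
        return float(np.median(s))
    if np.allclose(s, s[0]):
        return float(s[0])
    order = np.argsort(s, kind="stable")
    n_windows = min(n_windows, max(2, s.size // 5))
    windows = np.array_split(order, n_windows)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = numerators / (s + s0)
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w]))) for w in windows]) / 0.64
        mean = mads.mean()
        cv = mads.std(ddof=1) / mean if mean > 0 else np.inf
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


def _balanced_splits(n: int, na: int, n_perm: int, rng: np.random.Generator):
    """Index arrays assigning ``na`` of ``n`` pooled samples to group a.

    Exhaustive when C(n, na) <= n_perm, otherwise n_perm random draws.
    Returns (splits, exhaustive flag).
    """
    total = comb(n, na)
    if total <= n_perm:
        return [np.array(c) for c in itertools.combinations(range(n), na)], True
    splits = []
    for _ in range(n_perm):
        perm = rng.permutation(n)
        splits.append(np.sort(perm[:na]))
    return splits, False


def sam_two_class(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    s0: float | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    pooled_null: bool = True,
) -> pd.DataFrame:
    """SAM statistics for every gene, comparing ``group_b`` against ``group_a``.

    Returns a frame indexed by gene with columns mean_a, mean_b, d, s,
    fold_change, p_perm and rank (1 = largest |d|).  ``p_perm`` is the
    fraction of permuted |d| values at least as large as the observed |d|;
    with ``pooled_null`` the permuted values of all genes form one null
    set, otherwise each gene is compared with its own permutation null.
    Label splits are enumerated exhaustively when there are at most
    ``n_perm`` distinct ones, making the p-value seed-independent.
    """
    sa, sb = list(group_a), list(group_b)
    if set(sa) & set(sb):
        raise ValueError("groups overlap")
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs at least 2 samples")
    xa = m.subset_samples(sa).values.to_numpy(dtype=float)
    xb = m.subset_samples(sb).values.to_numpy(dtype=float)
    num, s = _pooled_scatter(xa, xb)
    if s0 is None:
        s0 = choose_s0(num, s)
    if np.any(s + s0 <= 0):
        raise ValueError("zero-variance genes with s0 = 0: supply a nonzero s0")
    d = num / (s + s0)

    # permutation null over pooled label splits
    pooled = np.concatenate([xa, xb], axis=1)
    n, na = pooled.shape[1], xa.shape[1]
    rng = np.random.default_rng(seed)
    splits, _ = _balanced_splits(n, na, n_perm, rng)
    null = np.empty((pooled.shape[0], len(splits)))
    all_idx = np.arange(n)
    for j, ia in enumerate(splits):
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        num_p, s_p = _pooled_scatter(pooled[:, ia], pooled[:, ib])
        null[:, j] = num_p / (s_p + s0)

    abs_d = np.abs(d)
    if pooled_null:
        flat = np.sort(np.abs(null), axis=None)
        ge = flat.size - np.searchsorted(flat, abs_d, side="left")
        p = ge / flat.size
    else:
        p = (np.abs(null) >= abs_d[:, None]).mean(axis=1)

    out = pd.DataFrame(
        {
            "mean_a": xa.mean(axis=1),
            "mean_b": xb.mean(axis=1),
            "d": d,
            "s": s,
            "fold_change": np.exp2(num),
            "p_perm": p,
        },
        index=m.values.index,
    )
    out["rank"] = out["d"].abs().rank(ascending=False, method="first").astype(int)
    out.attrs["s0"] = float(s0)
    out.attrs["n_a"], out.attrs["n_b"] = len(sa), len(sb)
    return out


@dataclass
class DirectionalGeneList:
    """Top differentially expressed genes in one direction of a comparison."""

    comparison: str
    direction: str  # "up" or "down"
    entries: pd.DataFrame  # SAM columns, ordered by |d| descending

    @property
    def genes(self) -> list[str]:
        return list(self.entries.index)


def top_gene_lists(
    stats: pd.DataFrame,
    top_n: int = 1000,
    fc_min: float = 2.0,
    comparison: str = "b_vs_a",
) -> tuple[DirectionalGeneList, DirectionalGeneList]:
    """Directional top lists: up = d > 0 and fold > fc_min, down analogous.

    Each list holds at most ``top_n`` genes ordered by |d| descending
    (the d-statistic sort); the fold filter uses the linear-scale fold, so
    the down list requires fold_change < 1/fc_min.
    """
    if stats.empty:
        raise ValueError("empty SAM result")
    up = stats[(stats["d"] > 0) & (stats["fold_change"] > fc_min)]
    up = up.sort_values("d", ascending=False, kind="stable").head(top_n)
    down = stats[(stats["d"] < 0) & (stats["fold_change"] < 1.0 / fc_min)]
    down = down.sort_values("d", ascending=True, kind="stable").head(top_n)
    return (
        DirectionalGeneList(comparison, "up", up),
        DirectionalGeneList(comparison, "down", down),
    )
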