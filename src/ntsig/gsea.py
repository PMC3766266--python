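"""Gene set enrichment analysis (weighted running-sum statistic).

Genes are ranked by the Signal2Noise metric between two phenotype groups,

    score_g = (mu_A - mu_B) / (sigma_A + sigma_B)

with each group standard deviation floored at 0.2 * |group mean| (or a
small constant when the mean is zero), the desktop-GSEA convention.  For a
gene set S of size N_h within a ranked list of N genes, the enrichment
score walks the list adding |score|^p / N_R at hits (N_R = sum of
|score|^p over hits) and subtracting 1 / (N - N_h) at misses; ES is the
running-sum value of maximal absolute deviation from zero, considering
both extremes ("real" sorting mode).  Significance uses gene-set
permutation: null ES values from random same-size sets drawn from the
ranked universe; NES divides ES by the mean |null ES| of the same sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ntsig.matrix import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "rank_signal2noise",
    "enrichment_score",
    "gsea_permutation",
    "gsea_many",
    "network_list_frequency",
    "EnrichmentResult",
]

_MIN_SD = 0.2  # desktop convention: floor when the group mean is zero


def rank_signal2noise(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    sort_abs: bool = False,
) -> pd.Series:
    """Signal2Noise score per gene, sorted descending (ties by gene symbol).

    ``sort_abs`` switches to the |score| ordering used for contrasts where
    both tails are of interest.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    xa = m.subset_samples(list(group_a)).values
    xb = m.subset_samples(list(group_b)).values
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
    sd_a, sd_b = xa.std(axis=1, ddof=1), xb.std(axis=1, ddof=1)

    def floor(sd: pd.Series, mu: pd.Series) -> pd.Series:
        lo = (0.2 * mu.abs()).where(mu != 0, _MIN_SD)
        return sd.where(sd > lo, lo)

    score = (mu_a - mu_b) / (floor(sd_a, mu_a) + floor(sd_b, mu_b))
    df = pd.DataFrame({"score": score, "gene": score.index})
    key = score.abs() if sort_abs else score
    df["key"] = key
    df = df.sort_values(["key", "gene"], ascending=[False, True])
    out = df["score"]
    out.index.name = None
    return out


def enrichment_score(
    ranked: pd.Series, gene_set: set[str], p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score of a gene set in a ranked list.

    Returns (ES, running sum over positions).  ES is the extreme of the
    running sum (positive or negative, whichever deviates more).
    """
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    n, nh = genes.size, int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if nh == n:
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(scores) ** p
    nr = w[hit].sum()
    if nr == 0:
        raise ValueError("all hit scores are zero: ES undefined")
    steps = np.where(hit, w / nr, -1.0 / (n - nh))
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    es = running[i_max] if abs(running[i_max]) >= abs(running[i_min]) else running[i_min]
    return float(es), running


@dataclass
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float  # nan when too few same-sign null values
    p_nominal: float
    fdr_q: float  # nan outside gsea_many
    n_perm: int


def _null_es(
    ranked: pd.Series, size: int, n_perm: int, rng: np.random.Generator, p: float
) -> np.ndarray:
    genes = ranked.index.to_numpy()
    out = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(genes, size=size, replace=False)
        out[i], _ = enrichment_score(ranked, set(pick), p=p)
    return out


def _nominal_p(es: float, null: np.ndarray) -> tuple[float, float, int]:
    """(p_nominal, nes, n_same_sign) against a null ES sample."""
    same = null[null >= 0] if es >= 0 else null[null < 0]
    if same.size == 0:
        return 1.0, float("nan"), 0
    p = float((np.abs(same) >= abs(es)).sum() / same.size)
    nes = float(es / np.abs(same).mean()) if same.size >= 10 else float("nan")
    return p, nes, int(same.size)


def gsea_permutation(
    ranked: pd.Series,
    gene_set: set[str],
    set_name: str = "set",
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 10,
    max_size: int = 500,
) -> EnrichmentResult | None:
    """Gene-set-permutation GSEA for one set; None when outside size bounds."""
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    members = set(gene_set) & set(ranked.index)
    if not (min_size <= len(members) <= max_size):
        log.info("set %s skipped: size %d outside [%d, %d]", set_name, len(members), min_size, max_size)
        return None
    es, _ = enrichment_score(ranked, members, p=weight)
    rng = np.random.default_rng(seed)
    null = _null_es(ranked, len(members), n_perm, rng, weight)
    p_nom, nes, _ = _nominal_p(es, null)
    return EnrichmentResult(set_name, len(members), es, nes, p_nom, float("nan"), n_perm)


def gsea_many(
    ranked: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """GSEA over a collection of sets with FDR q-values across them.

    FDR follows the reference recipe: observed and null ES are normalised
    by the same-sign null mean, and q(NES) is the ratio of the null
    fraction at least as extreme to the observed fraction at least as
    extreme, clamped to [0, 1].  Columns mirror the usual report: NAME,
    SIZE, ES, NES, NOM p-val, FDR q-val.
    """
    rng = np.random.default_rng(seed)
    rows, null_nes_all = [], []
    for name, members in gene_sets.items():
        inset = set(members) & set(ranked.index)
        if not (min_size <= len(inset) <= max_size):
            log.info("set %s skipped: size %d outside bounds", name, len(inset))
            continue
        es, _ = enrichment_score(ranked, inset, p=weight)
        null = _null_es(ranked, len(inset), n_perm, rng, weight)
        p_nom, nes, _ = _nominal_p(es, null)
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes_all.append(null_nes[np.isfinite(null_nes)])
        rows.append({"NAME": name, "SIZE": len(inset), "ES": es, "NES": nes, "NOM p-val": p_nom})
    if not rows:
        return pd.DataFrame(columns=["NAME", "SIZE", "ES", "NES", "NOM p-val", "FDR q-val"])
    df = pd.DataFrame(rows)
    pooled = np.concatenate(null_nes_all)
    obs = df["NES"].to_numpy()
    qs = []
    for nes in obs:
        if not np.isfinite(nes):
            qs.append(float("nan"))
            continue
        if nes >= 0:
            null_frac = (pooled[pooled >= 0] >= nes).mean() if (pooled >= 0).any() else 1.0
            obs_here = obs[np.isfinite(obs) & (obs >= 0)]
            obs_frac = (obs_here >= nes).mean() if obs_here.size else 1.0
        else:
            null_frac = (pooled[pooled < 0] <= nes).mean() if (pooled < 0).any() else 1.0
            obs_here = obs[np.isfinite(obs) & (obs < 0)]
            obs_frac = (obs_here <= nes).mean() if obs_here.size else 1.0
        qs.append(float(min(1.0, null_frac / max(obs_frac, 1e-12))))
    df["FDR q-val"] = qs
    return df.sort_values("NES", ascending=False, na_position="last").reset_index(drop=True)


def network_list_frequency(members: set[str] | list[str], gene_list: set[str] | list[str]) -> float:
    """Percentage of network members present in a gene list."""
    members = set(members)
    if not members:
        raise ValueError("empty network")
    return 100.0 * len(members & set(gene_list)) / len(members)
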