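"""Cross-dataset evidence combination for intersected SAM gene lists.

Two datasets measuring the same contrast contribute, per gene, a fold
change FC_i, the standard error SE_i of the mean log2 difference, a
p-value P_i, and the total sample count N_i of the two compared groups.
The combined quantities are

    FC_comb = FC_1^(V_2) * FC_2^(V_1),   V_i = SE_i^2 / (SE_1^2 + SE_2^2)

a cross-weighted geometric mean in which the more precise dataset (smaller
SE) receives the larger exponent, and

    P_comb = Phi( w_1 * Phi^-1(P_1) + w_2 * Phi^-1(P_2) ),  w_i = N_i / (N_1 + N_2)

a sample-size-weighted probit combination.  Because the weights sum to one
(rather than being root-sum-square normalised as in Stouffer's method) the
combination is conservative: P_1 = P_2 = p gives exactly p.  A calibrated
Stouffer variant is available behind ``stouffer=True``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from ntsig.sam import DirectionalGeneList

log = logging.getLogger(__name__)

_EPS = 1e-300


def intersect_lists(list_1: DirectionalGeneList, list_2: DirectionalGeneList) -> set[str]:
    """Genes present in both directional lists (same comparison & direction)."""
    if list_1.direction != list_2.direction:
        raise ValueError(f"direction mismatch: {list_1.direction} vs {list_2.direction}")
    if list_1.comparison != list_2.comparison:
        raise ValueError(f"comparison mismatch: {list_1.comparison} vs {list_2.comparison}")
    return set(list_1.genes) & set(list_2.genes)


def combine_fold_change(fc_1: float, se_1: float, fc_2: float, se_2: float) -> float:
    """Variance-minimising cross-weighted geometric mean of two fold changes."""
    if fc_1 <= 0 or fc_2 <= 0:
        raise ValueError("fold changes must be positive")
    if se_1 <= 0 or se_2 <= 0:
        raise ValueError("standard errors must be positive")
    tot = se_1**2 + se_2**2
    v1, v2 = se_1**2 / tot, se_2**2 / tot
    return float(fc_1**v2 * fc_2**v1)


def combine_pvalue(
    p_1: float, n_1: int, p_2: float, n_2: int, stouffer: bool = False
) -> float:
    """Sample-size-weighted probit combination of two p-values.

    Implemented exactly as stated (weights w_i = N_i/(N_1+N_2) summing to
    one, no variance renormalisation); ``stouffer=True`` instead divides
    by sqrt(w_1^2 + w_2^2) so the combined statistic is standard normal
    under the null.  P values of exactly 0 or 1 are clamped to the open
    interval with a warning.
    """
    if n_1 < 1 or n_2 < 1:
        raise ValueError("sample counts must be >= 1")
    ps = []
    for p in (p_1, p_2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
        if p <= 0.0 or p >= 1.0:
            log.warning("p-value %g clamped to the open interval", p)
            p = min(max(p, _EPS), 1.0 - 1e-16)
        ps.append(p)
    w1 = n_1 / (n_1 + n_2)
    w2 = n_2 / (n_1 + n_2)
    z = w1 * norm.ppf(ps[0]) + w2 * norm.ppf(ps[1])
    if stouffer:
        z /= np.sqrt(w1**2 + w2**2)
    return float(norm.cdf(z))


def significance_cutoff(alpha: float = 0.05, n_tests: int = 8000) -> float:
    """Bonferroni nominal threshold alpha / n_tests (0.05, 8000 -> 6.25e-6)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def combine_evidence(
    list_1: DirectionalGeneList,
    list_2: DirectionalGeneList,
    n_1: int | None = None,
    n_2: int | None = None,
    alpha: float = 0.05,
    n_tests: int = 8000,
    halve_two_sided: bool = True,
    stouffer: bool = False,
) -> pd.DataFrame:
    """Per-gene combined evidence over the intersection of two SAM lists.

    SE_i is the gene's pooled scatter s (the standard error of the
    between-group mean log2 difference) from the SAM result; P_i is the
    permutation p-value, halved to one-sided when ``halve_two_sided``
    since the lists are directional.  ``n_i`` defaults to the SAM result's
    recorded group sizes.  Output columns: FC_1, SE_1, P_1, FC_2, SE_2,
    P_2, FC_comb, P_comb, significant (P_comb below the Bonferroni
    nominal cut-off).
    """
    genes = sorted(intersect_lists(list_1, list_2))
    e1, e2 = list_1.entries, list_2.entries
    if n_1 is None:
        n_1 = e1.attrs.get("n_a", 0) + e1.attrs.get("n_b", 0)
    if n_2 is None:
        n_2 = e2.attrs.get("n_a", 0) + e2.attrs.get("n_b", 0)
    if min(n_1, n_2) < 4:
        raise ValueError("each dataset needs at least 4 samples across the two groups")
    cutoff = significance_cutoff(alpha, n_tests)
    min_p = 1.0 / 10**6  # permutation p-values of 0 are information-limited, not evidence of p=0
    rows = []
    for g in genes:
        fc1, se1, p1 = e1.loc[g, "fold_change"], e1.loc[g, "s"], e1.loc[g, "p_perm"]
        fc2, se2, p2 = e2.loc[g, "fold_change"], e2.loc[g, "s"], e2.loc[g, "p_perm"]
        if halve_two_sided:
            p1, p2 = p1 / 2.0, p2 / 2.0
        p1 = min(max(p1, min_p), 1 - 1e-12)
        p2 = min(max(p2, min_p), 1 - 1e-12)
        fc_comb = combine_fold_change(fc1, se1, fc2, se2)
        p_comb = combine_pvalue(p1, n_1, p2, n_2, stouffer=stouffer)
        rows.append(
            {
                "gene": g,
                "FC_1": fc1,
                "SE_1": se1,
                "P_1": p1,
                "FC_2": fc2,
                "SE_2": se2,
                "P_2": p2,
                "FC_comb": fc_comb,
                "P_comb": p_comb,
                "significant": p_comb < cutoff,
            }
        )
    cols = ["gene", "FC_1", "SE_1", "P_1", "FC_2", "SE_2", "P_2", "FC_comb", "P_comb", "significant"]
    return pd.DataFrame(rows, columns=cols).set_index("gene")
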