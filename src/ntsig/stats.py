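"""Agreement and association statistics: Cohen's kappa, Pearson r, Welch t.

Cohen's kappa measures chance-corrected agreement between predicted and
observed class labels on a square crosstab:

    kappa = (p_o - p_e) / (1 - p_e)

with p_o the observed and p_e the chance agreement from the marginals.
Approximate significance uses the null-hypothesis standard error

    se0 = sqrt( [p_e + p_e^2 - sum_i r_i c_i (r_i + c_i)] / (n (1 - p_e)^2) )

(r_i, c_i marginal proportions), z = kappa / se0, two-sided normal p —
the classical large-sample test reported by the common crosstab tools.
The non-null asymptotic standard error is also computed for confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KappaResult",
    "cohen_kappa",
    "crosstab_from_labels",
    "square_crosstab",
    "row_agreement",
    "pearson_cor",
    "welch_t",
]


@dataclass
class KappaResult:
    kappa: float
    p_o: float
    p_e: float
    se0: float  # standard error under kappa = 0
    ase: float  # non-null asymptotic standard error
    z: float
    p_two_sided: float


def square_crosstab(t: pd.DataFrame) -> pd.DataFrame:
    """Square a labelled crosstab on the union of row/column labels (zero fill)."""
    labels = sorted(set(t.index) | set(t.columns))
    return t.reindex(index=labels, columns=labels, fill_value=0).astype(int)


def crosstab_from_labels(predicted, observed, labels: list[str] | None = None) -> pd.DataFrame:
    """Square predicted-x-observed count table from paired label sequences."""
    t = pd.crosstab(pd.Series(predicted, name="predicted"), pd.Series(observed, name="observed"))
    t = square_crosstab(t)
    if labels is not None:
        t = t.reindex(index=labels, columns=labels, fill_value=0)
    return t


def cohen_kappa(t: pd.DataFrame | np.ndarray) -> KappaResult:
    """Cohen's kappa with null-variance z-test on a crosstab.

    A labelled frame is squared by label union first; a plain array must
    already be square with aligned categories.
    """
    if isinstance(t, pd.DataFrame):
        t = square_crosstab(t)
        counts = t.to_numpy(dtype=float)
    else:
        counts = np.asarray(t, dtype=float)
        if counts.shape[0] != counts.shape[1]:
            raise ValueError("array crosstab must be square")
    n = counts.sum()
    if n < 2:
        raise ValueError("crosstab needs at least 2 observations")
    p = counts / n
    r, c = p.sum(axis=1), p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(r @ c)
    if p_e >= 1.0:
        raise ValueError("expected agreement is 1: kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)

    se0 = float(np.sqrt(max(p_e + p_e**2 - float((r * c * (r + c)).sum()), 0.0) / (n * (1.0 - p_e) ** 2)))
    if se0 > 0:
        z = kappa / se0
        p_two = float(2.0 * sps.norm.sf(abs(z)))
    else:  # degenerate marginals (e.g. an all-zero row after squaring)
        z, p_two = float("nan"), float("nan")

    # non-null large-sample variance (Fleiss/Cohen/Everitt form)
    diag = np.diag(p)
    term1 = float((diag * (1.0 - (r + c) * (1.0 - kappa)) ** 2).sum())
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    weights = (c[:, None] + r[None, :]) ** 2  # cell (i, j): (c_i + r_j)^2
    term2 = float((1.0 - kappa) ** 2 * (off * weights).sum())
    term3 = (kappa - p_e * (1.0 - kappa)) ** 2
    ase = float(np.sqrt(max(term1 + term2 - term3, 0.0) / (n * (1.0 - p_e) ** 2)))

    return KappaResult(float(kappa), p_o, p_e, se0, ase, float(z), p_two)


def row_agreement(t: pd.DataFrame) -> pd.Series:
    """Diagonal percentage per predicted row of a labelled square crosstab."""
    t = square_crosstab(t)
    totals = t.sum(axis=1)
    diag = pd.Series(np.diag(t.to_numpy()), index=t.index)
    return 100.0 * diag / totals.where(totals > 0, np.nan)


def pearson_cor(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based p on n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired input of length >= 3 required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Satterthwaite df, two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("degenerate zero-variance groups with unequal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    df = (vx / x.size + vy / y.size) ** 2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)
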