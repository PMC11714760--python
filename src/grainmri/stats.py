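"""Statistics over trait tables: correlations, agreement, normality, power,
clustering and PCA.

The correlation P-values follow the classic transformation of r into a
t-statistic with N-2 degrees of freedom.  Method agreement between two
measurement techniques uses Bland-Altman difference analysis: the bias is
the mean paired difference and the limits of agreement are bias +/- 1.96
standard deviations of the differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA

from .errors import ValidationError


@dataclass
class CorrelationResult:
    """Pearson correlation of one trait pair with its two-sided P-value."""

    pair: tuple
    r: float
    n: int
    p: float


@dataclass
class AgreementResult:
    """Bland-Altman agreement between two paired measurement series."""

    bias: float                  # mean of differences a - b
    sd: float                    # sample SD of differences (N-1)
    loa: tuple                   # limits of agreement (low, high) = bias -/+ 1.96 SD
    bias_ci: tuple               # 95% CI of the bias (t-based)
    differences: np.ndarray
    relative_differences: np.ndarray   # (a - b) / b
    n: int = 0


def _pearson_p(r: float, n: int) -> float:
    """Two-sided P from the t transform with N-2 degrees of freedom."""
    if n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def pearson_matrix(table: pd.DataFrame, columns=None):
    """Pairwise-complete Pearson correlation matrix with P-values and N.

    Returns ``(r, p, n)`` DataFrames indexed by column.  Pairs with fewer
    than 3 complete rows, or involving a zero-variance column, are NaN with
    a warning.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(columns)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            x = table[columns[i]].to_numpy(dtype=float)
            y = table[columns[j]].to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y))
            m = int(keep.sum())
            n[i, j] = n[j, i] = m
            if m < 3:
                warnings.warn(f"fewer than 3 complete rows for pair "
                              f"({columns[i]}, {columns[j]})", stacklevel=2)
                continue
            xs, ys = x[keep], y[keep]
            if xs.std() == 0 or ys.std() == 0:
                warnings.warn(f"zero-variance column in pair ({columns[i]}, {columns[j]})",
                              stacklevel=2)
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            rij = float(np.corrcoef(xs, ys)[0, 1])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = _pearson_p(rij, m)
    idx = list(columns)
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx),
            pd.DataFrame(n, index=idx, columns=idx))


def pearson_pair(x, y) -> CorrelationResult:
    """Pearson r and N-2-df P for one pair of complete vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValidationError("need at least 3 complete pairs")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(pair=("x", "y"), r=r, n=len(x), p=_pearson_p(r, len(x)))


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman agreement of two paired measurement series.

    d = a - b; bias = mean(d); limits of agreement = bias +/- 1.96 * SD(d)
    with the sample (N-1) standard deviation; the 95% CI of the bias uses
    the t distribution.  Relative differences are d / b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValidationError("need at least 2 pairs")
    d = a - b
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tcrit = float(sps.t.ppf(0.975, n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(b != 0, d / b, np.nan)
    return AgreementResult(
        bias=bias, sd=sd,
        loa=(bias - 1.96 * sd, bias + 1.96 * sd),
        bias_ci=(bias - tcrit * sd / math.sqrt(n), bias + tcrit * sd / math.sqrt(n)),
        differences=d, relative_differences=rel, n=n)


def normality_check(x, alpha: float = 0.01):
    """D'Agostino-Pearson omnibus normality test plus QQ plot pairs.

    Returns ``(p, reject, qq)`` where ``reject`` is True iff p < alpha
    (default 0.01) and ``qq`` is an (N, 2) array of (theoretical normal
    quantile, order statistic) pairs.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 8:
        raise ValidationError("normality test needs at least 8 observations")
    if x.std() == 0:
        raise ValidationError("constant vector: normality undefined")
    _, p = sps.normaltest(x)
    order = np.sort(x)
    probs = (np.arange(1, x.size + 1) - 0.5) / x.size
    theo = sps.norm.ppf(probs, loc=x.mean(), scale=x.std(ddof=1))
    qq = np.column_stack([theo, order])
    return float(p), bool(p < alpha), qq


def required_sample_size(effect: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Per-group n for a two-sample comparison, normal approximation.

    n = ((z_{1-alpha/2} + z_{power}) / (delta/sigma))^2, rounded up.
    """
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValidationError("alpha and power must be in (0, 1)")
    if effect == 0:
        raise ValidationError("zero effect size requires infinite sample size")
    z_a = sps.norm.ppf(1 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    return int(math.ceil(((z_a + z_b) / abs(effect)) ** 2))


def cluster_traits(table: pd.DataFrame, groups, columns=None):
    """Complete-linkage hierarchical clustering of group-mean trait vectors.

    Columns are z-scored before Euclidean distances.  Returns the scipy
    linkage matrix (merge list with heights) plus the group labels in row
    order.  Missing values are refused rather than imputed.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    df = table[columns].copy()
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"missing values in columns {bad}; imputation refused")
    df["_g"] = np.asarray(groups)
    means = df.groupby("_g", sort=True).mean()
    if means.shape[0] < 2:
        raise ValidationError("need at least 2 groups to cluster")
    if means.isna().any().any():
        bad = means.columns[means.isna().any()].tolist()
        raise ValidationError(f"missing values in columns {bad}; imputation refused")
    z = (means - means.mean()) / means.std(ddof=0).replace(0, 1.0)
    merges = linkage(z.to_numpy(), method="complete", metric="euclidean")
    return merges, list(means.index)


def trait_pca(table: pd.DataFrame, columns=None):
    """PCA of standardized trait columns.

    Returns ``(scores, explained_variance_ratio)``; components are ordered
    by decreasing variance and the ratios over all components sum to 1.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    x = table[columns].to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 rows for PCA")
    if np.isnan(x).any():
        raise ValidationError("missing values in PCA input; complete columns required")
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    pca = PCA()
    scores = pca.fit_transform(z)
    return scores, pca.explained_variance_ratio_
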