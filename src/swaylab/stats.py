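"""Univariate group comparison of the 34 stabilometric parameters.

Each parameter is compared between the HOA and PD groups with the
Mann-Whitney U test; Shapiro-Wilk (normality, per group) and Levene
(variance homogeneity) screening p-values are recorded alongside but do
not branch the analysis.  Raw p-values receive both a Bonferroni
adjustment (family size fixed at 34) and Benjamini-Hochberg step-up FDR
control, reported separately.  Descriptives are the median and IQR
(linear-interpolation quartiles).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_NAMES

__all__ = [
    "describe",
    "shapiro_wilk",
    "levene",
    "mann_whitney_u",
    "bonferroni_adjust",
    "bh_adjust",
    "run_univariate",
]

#: Largest pooled sample size at which the Mann-Whitney p is computed by
#: exact enumeration (ties force the asymptotic path regardless).
EXACT_MW_LIMIT = 12


def describe(values: np.ndarray) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 1:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1)


def shapiro_wilk(values: np.ndarray) -> float:
    """Shapiro-Wilk normality p-value (screening only)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    return float(sps.shapiro(values).pvalue)


def levene(x: np.ndarray, y: np.ndarray) -> float:
    """Levene's test p-value for equality of variances (mean-centred)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Levene needs n >= 2 per group")
    res = sps.levene(x, y, center="mean")
    if np.isnan(res.pvalue):  # identical spread in both groups
        return 1.0
    return float(res.pvalue)


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U statistic (of ``x``, via midranks) and two-sided p.

    The p-value is exact (full enumeration) when the pooled sample size is
    at most 12 and there are no ties; otherwise the normal approximation
    with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MW_LIMIT and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(1, p * m)``."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m must be >= number of p-values")
    return np.minimum(1.0, p * m)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values), input order."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_univariate(
    table: pd.DataFrame, alpha: float = 0.05, m: int = 34
) -> pd.DataFrame:
    """Compare every canonical parameter between HOA and PD.

    Parameters
    ----------
    table : DataFrame
        Complete (or imputed) feature table with ``group`` labels.
    alpha : float
        Significance level applied to *adjusted* p-values.
    m : int
        Bonferroni family size (all tested parameters).

    Returns
    -------
    DataFrame with one row per parameter: group medians/IQRs, U statistic,
    raw p, Bonferroni p, BH q, screening p-values, and significance flags
    for each correction.
    """
    hoa = table[table["group"] == "HOA"]
    pd_grp = table[table["group"] == "PD"]
    if len(hoa) == 0 or len(pd_grp) == 0:
        raise ValueError("both groups must be non-empty")
    if table[list(FEATURE_NAMES)].isna().any().any():
        raise ValueError("feature table contains missing values; impute first")

    rows = []
    for name in FEATURE_NAMES:
        a = hoa[name].to_numpy(dtype=float)
        b = pd_grp[name].to_numpy(dtype=float)
        med_a, iqr_a = describe(a)
        med_b, iqr_b = describe(b)
        u, p = mann_whitney_u(a, b)
        rows.append(
            {
                "parameter": name,
                "hoa_median": med_a,
                "hoa_iqr": iqr_a,
                "pd_median": med_b,
                "pd_iqr": iqr_b,
                "u_stat": u,
                "p_raw": p,
                "shapiro_p_hoa": shapiro_wilk(a),
                "shapiro_p_pd": shapiro_wilk(b),
                "levene_p": levene(a, b),
            }
        )
    out = pd.DataFrame(rows)
    out["bonferroni_p"] = bonferroni_adjust(out["p_raw"].to_numpy(), m=m)
    out["bh_q"] = bh_adjust(out["p_raw"].to_numpy())
    out["sig_bonferroni"] = out["bonferroni_p"] < alpha
    out["sig_fdr"] = out["bh_q"] < alpha
    return out
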