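"""Paired group statistics: Lilliefors normality gate, Wilcoxon signed-rank /
paired t comparison per feature, and Benjamini-Hochberg FDR for the
region-level uptake screen.

The comparison contract follows the study design: per feature, normality of
each group is tested with a Monte-Carlo Lilliefors test; if either group
departs from normality at alpha the paired comparison uses the Wilcoxon
signed-rank test, otherwise the paired t-test. Two-sided p-values; no
correction across the 22 network features (BH is available and used for the
56-region uptake screen).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "lilliefors_statistic",
    "lilliefors_null_table",
    "lilliefors_test",
    "paired_group_compare",
    "fdr_bh",
    "region_uptake_screen",
]


@dataclass
class ComparisonResult:
    feature: str
    test: str  # "wilcoxon-signed-rank" | "paired-t"
    statistic: float
    p: float
    normality_p: tuple[float, float]


def lilliefors_statistic(sample: np.ndarray) -> float:
    """Kolmogorov-Smirnov statistic against a normal with estimated mean/SD."""
    x = np.asarray(sample, dtype=float)
    m, s = x.mean(), x.std(ddof=1)
    if s == 0:
        raise ValueError("constant sample: normality test undefined")
    return float(sps.kstest(x, "norm", args=(m, s)).statistic)


def lilliefors_null_table(n: int, n_mc: int = 10000, seed: int = 0) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the statistic at sample size n."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_mc)
    for i in range(n_mc):
        out[i] = lilliefors_statistic(rng.standard_normal(n))
    out.sort()
    return out


def lilliefors_test(
    sample: np.ndarray,
    n_mc: int = 10000,
    seed: int = 0,
    null_table: np.ndarray | None = None,
) -> float:
    """Monte-Carlo p-value of the Lilliefors normality test.

    A precomputed ``null_table`` (from :func:`lilliefors_null_table`) may be
    supplied to amortize the null simulation over many tests of the same
    sample size.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    d = lilliefors_statistic(x)
    if null_table is None:
        null_table = lilliefors_null_table(x.size, n_mc=n_mc, seed=seed)
    n_ge = null_table.size - np.searchsorted(null_table, d, side="left")
    return float((1 + n_ge) / (1 + null_table.size))


def paired_group_compare(
    features_case: pd.DataFrame,
    features_control: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
    n_mc: int = 2000,
) -> pd.DataFrame:
    """Per-feature paired comparison of two aligned feature tables.

    Rows of the two frames must correspond pair-for-pair (same order); columns
    are features. Returns a table with the test used, statistic, two-sided p
    and the per-group normality p-values.
    """
    if features_case.shape != features_control.shape:
        raise ValueError("paired feature tables must have identical shape")
    n = features_case.shape[0]
    null = lilliefors_null_table(n, n_mc=n_mc, seed=seed)
    rows = []
    for col in features_case.columns:
        a = features_case[col].to_numpy(float)
        b = features_control[col].to_numpy(float)
        try:
            pn_a = lilliefors_test(a, null_table=null)
            pn_b = lilliefors_test(b, null_table=null)
        except ValueError:  # constant feature
            pn_a = pn_b = 0.0
        diffs = a - b
        if np.all(diffs == 0):
            warnings.warn(f"feature {col}: all paired differences zero; p=1")
            rows.append(ComparisonResult(col, "wilcoxon-signed-rank", 0.0, 1.0,
                                         (pn_a, pn_b)))
            continue
        if pn_a < alpha or pn_b < alpha:
            res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
            rows.append(ComparisonResult(
                col, "wilcoxon-signed-rank", float(res.statistic), float(res.pvalue),
                (pn_a, pn_b),
            ))
        else:
            res = sps.ttest_rel(a, b)
            rows.append(ComparisonResult(
                col, "paired-t", float(res.statistic), float(res.pvalue),
                (pn_a, pn_b),
            ))
    return pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "test": [r.test for r in rows],
            "statistic": [r.statistic for r in rows],
            "p": [r.p for r in rows],
            "normality_p_case": [r.normality_p[0] for r in rows],
            "normality_p_control": [r.normality_p[1] for r in rows],
        }
    ).set_index("feature")


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mask, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")[:4]
    return mask


def region_uptake_screen(
    patients: np.ndarray, nc: np.ndarray, q: float = 0.05
) -> pd.DataFrame:
    """Region-level two-sample t screen of patient vs NC uptake with BH-FDR."""
    t, p = sps.ttest_ind(patients, nc, axis=0)
    return pd.DataFrame({"t": t, "p": p, "significant": fdr_bh(p, q=q)})
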