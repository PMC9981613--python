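"""Between-cluster phenotypic comparisons.

Numeric features are compared with the two-sample Student's t test using
the pooled standard-deviation estimate; categorical features with the
Pearson chi-squared test of homogeneity; p-values are adjusted for
multiple comparisons with the Holm-Bonferroni step-down procedure.  A
summary-statistic variant of the t test is provided because group
comparisons are often reported from (n, mean, SD) triples only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def pooled_t_test(sample_a, sample_b):
    """Equal-variance two-sample t test; returns (t, df, two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def pooled_t_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b):
    """Pooled t test from group summary statistics (n, mean, SD)."""
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                     equal_var=True)
    return float(res.statistic), n_a + n_b - 2, float(res.pvalue)


def chi2_homogeneity(table):
    """Pearson chi-squared homogeneity test, no continuity correction.

    All-zero rows/columns are dropped with a warning; returns
    (chi2, df, p).
    """
    t = np.asarray(table, dtype=float)
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping all-zero rows/columns from contingency table")
        t = t[keep_r][:, keep_c]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2 after pruning")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def holm_adjust(pvalues):
    """Holm-Bonferroni step-down adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class ComparisonRow:
    feature: str
    kind: str
    n_low: int
    n_high: int
    summary_low: str
    summary_high: str
    statistic: float
    df: float
    p_nominal: float
    p_holm: float | None = None
    testable: bool = True
    in_family: bool = True


def compare_clusters(features: pd.DataFrame, labels,
                     family: list[str] | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature low-vs-high comparison table.

    `labels` is an array of "low"/"high" aligned with `features`.
    `family` restricts the Holm correction to the given feature names
    (items shown only for completeness are left out of it); default is
    every testable feature.
    """
    y = np.asarray(labels)
    if set(np.unique(y)) - {"low", "high"}:
        raise ValueError("labels must be 'low'/'high'")
    lo, hi = y == "low", y == "high"
    rows: list[ComparisonRow] = []
    for name in features.columns:
        s = features[name]
        numeric = pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s)
        if numeric:
            a = s[lo].dropna().to_numpy(dtype=float)
            b = s[hi].dropna().to_numpy(dtype=float)
            summary = (f"{a.mean():.2f} ({a.std(ddof=1):.2f})" if len(a) > 1 else "-",
                       f"{b.mean():.2f} ({b.std(ddof=1):.2f})" if len(b) > 1 else "-")
            try:
                if len(np.unique(np.concatenate([a, b]))) < 2:
                    raise ValueError("constant feature")
                t, df, p = pooled_t_test(a, b)
                row = ComparisonRow(name, "numeric", len(a), len(b), *summary,
                                    t, df, p)
            except ValueError:
                row = ComparisonRow(name, "numeric", len(a), len(b), *summary,
                                    np.nan, np.nan, np.nan, testable=False)
        else:
            sub = pd.DataFrame({"v": s, "g": np.where(lo, "low", "high")}).dropna()
            table = pd.crosstab(sub["v"], sub["g"])
            counts = (table.get("low", pd.Series(dtype=int)),
                      table.get("high", pd.Series(dtype=int)))
            summary = tuple(
                "; ".join(f"{k}: {v}" for k, v in c.items()) or "-" for c in counts
            )
            try:
                chi2, df, p = chi2_homogeneity(table.to_numpy())
                row = ComparisonRow(name, "categorical",
                                    int(lo.sum() - s[lo].isna().sum()),
                                    int(hi.sum() - s[hi].isna().sum()),
                                    *summary, chi2, df, p)
            except ValueError:
                row = ComparisonRow(name, "categorical", int(lo.sum()),
                                    int(hi.sum()), *summary,
                                    np.nan, np.nan, np.nan, testable=False)
        rows.append(row)

    fam = set(family) if family is not None else {
        r.feature for r in rows if r.testable}
    fam_rows = [r for r in rows if r.feature in fam and r.testable]
    if fam_rows:
        adj = holm_adjust([r.p_nominal for r in fam_rows])
        for r, a in zip(fam_rows, adj):
            r.p_holm = float(a)
    for r in rows:
        r.in_family = r.feature in fam and r.testable
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["significant_nominal"] = out["p_nominal"] < alpha
    out["significant_holm"] = out["p_holm"] < alpha
    return out
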